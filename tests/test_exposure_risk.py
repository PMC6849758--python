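"""Dissimilarity arithmetic, ENM thresholding and the three rule engines,
including regression against the bundled case-study table."""

import itertools

import numpy as np
import pandas as pd
import pytest

from climvuln import (adaptive_sensitivity, assess, climate_dissimilarity,
                      combine_sensitivity, exposure_level, max_sss_threshold,
                      neutral_sensitivity, risk_level)
from climvuln.case_study import (climate_table, exposure_records,
                                 published_changes, risk_table)
from climvuln.exposure_risk import RISK_ORDER, round_half_away


class TestDissimilarity:
    @pytest.mark.parametrize("now, future, expected", [
        (25.3, 28.6, 3.3), (30.0, 36.9, 6.9), (10.0, 10.0, 0.0),
    ])
    def test_delta(self, now, future, expected):
        assert climate_dissimilarity(now, future) == pytest.approx(expected)

    @pytest.mark.parametrize("now, future, expected", [
        (61, 27, -55.7), (36, 28, -22.2), (80, 37, -53.8), (38, 40, 5.3),
    ])
    def test_percent(self, now, future, expected):
        assert climate_dissimilarity(now, future, as_percent=True) == expected

    def test_zero_baseline_percent_flagged(self):
        with pytest.raises(ZeroDivisionError):
            climate_dissimilarity(0.0, 5.0, as_percent=True)

    @pytest.mark.parametrize("x, expected", [
        (2.25, 2.3), (-2.25, -2.3), (1.04, 1.0), (-0.05, -0.1), (0.0, 0.0),
    ])
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected


class TestMaxSss:
    def test_separable(self):
        t = max_sss_threshold([0.9, 0.9, 0.9], [0.1, 0.1])
        assert t == pytest.approx(0.9)

    def test_interleaved_matches_exhaustive_oracle(self):
        pres = np.array([0.9, 0.6, 0.4])
        bg = np.array([0.5, 0.3, 0.2])
        t = max_sss_threshold(pres, bg)
        best, best_score = None, -np.inf
        for cand in sorted(np.concatenate([pres, bg])):
            score = np.mean(pres >= cand) + np.mean(bg < cand)
            if score > best_score + 1e-12:
                best, best_score = cand, score
        assert t == pytest.approx(best)
        assert t == pytest.approx(0.4)

    def test_label_swap_inverts_decision(self, rng):
        pres = rng.uniform(0.5, 1.0, 20)
        bg = rng.uniform(0.0, 0.5, 30)
        t = max_sss_threshold(pres, bg)
        t_swapped = max_sss_threshold(bg, pres)
        assert t_swapped <= t

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            max_sss_threshold([0.5, 0.5], [0.5])
        with pytest.raises(ValueError, match="at least one"):
            max_sss_threshold([], [0.5])


class TestExposureEngine:
    def test_case_study_ranks(self):
        published = risk_table().set_index("pop")["exposure"]
        for record in exposure_records():
            if record.pop not in published.index:
                continue
            ea = exposure_level(record)
            assert ea.level == published[record.pop], record.pop
            if record.pop == "Bizkaia":
                assert ea.rule_mismatch      # documented fallback assignment
            else:
                assert not ea.rule_mismatch

    def test_temperature_and_rain_bins(self):
        recs = {r.pop: r for r in exposure_records()}
        valencia = exposure_level(recs["Valencia"])
        assert (valencia.temp_class, valencia.rain_class) == ("medium", "high")
        valladolid = exposure_level(recs["Valladolid"])
        assert valladolid.temp_class == "high"

    def test_rain_increase_is_low_exposure_class(self):
        from climvuln import ExposureRecord

        rec = ExposureRecord("x", 20, 22, 50, 80, 90, 95, True, True)
        ea = exposure_level(rec)
        assert ea.rain_class == "low"
        assert ea.level == 1


class TestSensitivityEngines:
    @pytest.mark.parametrize("mean, frac, code", [
        (0.4, 0.5, "++"), (0.4, 0.2, "+"), (0.6, 0.1, "0"), (0.6, 0.0, "-"),
        (0.5, 0.0, "-"), (0.5, 0.3, "0"),
    ])
    def test_adaptive_codes(self, mean, frac, code):
        assert adaptive_sensitivity(mean, frac) == code

    def test_adaptive_input_validation(self):
        with pytest.raises(ValueError):
            adaptive_sensitivity(1.2, 0.0)

    @pytest.mark.parametrize("het, code", [
        (0.95, "-"), (0.844, "0"), (0.664, "+"), (0.9, "0"), (0.75, "0"),
        (0.91, "-"), (0.74, "+"),
    ])
    def test_neutral_codes(self, het, code):
        assert neutral_sensitivity(het) == code

    def test_combine_reproduces_case_study(self):
        for rec in risk_table().itertuples():
            assert combine_sensitivity(rec.adaptive_code, rec.neutral_code) \
                == rec.sensitivity, rec.pop

    @pytest.mark.parametrize("a, n, overall", [
        ("++", "-", "+"), ("+", "-", "0"), ("-", "0", "-"),
    ])
    def test_combine_examples(self, a, n, overall):
        assert combine_sensitivity(a, n) == overall

    def test_combine_rejects_bad_codes(self):
        with pytest.raises(ValueError):
            combine_sensitivity("x", "-")
        with pytest.raises(ValueError):
            combine_sensitivity("+", "++")


class TestRiskEngine:
    def test_case_study_risks(self):
        for rec in risk_table().itertuples():
            ra = risk_level(rec.exposure, rec.sensitivity, rec.range_shift)
            assert ra.risk == rec.risk, rec.pop

    @pytest.mark.parametrize("exp, sens, rng_flag, risk", [
        (4, "+", "-", "High"), (4, "-", "-", "Medium-high"),
        (1, "+", "+", "Low"), (3, "0", "+", "Medium"),
        (2, "-", "-", "Medium"),
    ])
    def test_rule_examples(self, exp, sens, rng_flag, risk):
        assert risk_level(exp, sens, rng_flag).risk == risk

    def test_unclassified_combinations_diagnosed(self):
        expected_unclassified = {(1, "0", "-"), (1, "+", "-"),
                                 (4, "-", "+"), (4, "0", "+")}
        observed = set()
        for exp, sens, rs in itertools.product((1, 2, 3, 4), "+0-", "+-"):
            ra = risk_level(exp, sens, rs)
            if ra.risk == "Unclassified":
                observed.add((exp, sens, rs))
                assert "no rule covers" in ra.rule_path
        assert observed == expected_unclassified

    def test_monotone_over_classified_lattice(self):
        sens_rank = {"-": 0, "0": 1, "+": 2}
        range_rank = {"+": 0, "-": 1}    # losing connectivity raises risk
        levels = {r: i for i, r in enumerate(RISK_ORDER)}
        points = {}
        for exp, sens, rs in itertools.product((1, 2, 3, 4), "+0-", "+-"):
            risk = risk_level(exp, sens, rs).risk
            if risk != "Unclassified":
                points[(exp, sens_rank[sens], range_rank[rs])] = levels[risk]
        for a, ra in points.items():
            for b, rb in points.items():
                if all(x <= y for x, y in zip(a, b)):
                    assert ra <= rb, (a, b)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            risk_level(5, "+", "-")
        with pytest.raises(ValueError):
            risk_level(2, "++", "-")
        with pytest.raises(ValueError):
            risk_level(2, "+", "high")


class TestAssess:
    def test_full_case_study_roundtrip(self):
        published = risk_table()
        out = assess(published[["pop", "exposure"]],
                     published[["pop", "adaptive_code", "neutral_code"]],
                     published[["pop", "range_shift"]])
        merged = out.merge(published, on="pop", suffixes=("_c", "_p"))
        assert (merged["risk_c"] == merged["risk_p"]).all()

    def test_id_mismatch_rejected(self):
        published = risk_table()
        bad = published[["pop", "range_shift"]].copy()
        bad.loc[0, "pop"] = "Atlantis"
        with pytest.raises(ValueError, match="match"):
            assess(published[["pop", "exposure"]],
                   published[["pop", "adaptive_code", "neutral_code"]], bad)

    def test_deterministic(self):
        published = risk_table()
        args = (published[["pop", "exposure"]],
                published[["pop", "adaptive_code", "neutral_code"]],
                published[["pop", "range_shift"]])
        pd.testing.assert_frame_equal(assess(*args), assess(*args))


def test_published_changes_arithmetic_consistency():
    """Published derived columns agree with the arithmetic except the one
    documented misprint (Granada's % suitability change)."""
    climate = climate_table().set_index("pop")
    published = published_changes().set_index("pop")
    for pop, row in climate.iterrows():
        assert climate_dissimilarity(row.tmax_now, row.tmax_future) \
            == published.loc[pop, "delta_tmax"]
        assert climate_dissimilarity(row.rain_now, row.rain_future) \
            == published.loc[pop, "delta_rain"]
        assert climate_dissimilarity(row.rain_now, row.rain_future,
                                     as_percent=True) \
            == published.loc[pop, "pct_change_rain"]
        computed = climate_dissimilarity(row.enm_now, row.enm_future,
                                         as_percent=True)
        if pop == "Granada":
            assert computed == -53.8
            assert published.loc[pop, "pct_change_enm"] == -52.5
        else:
            assert computed == published.loc[pop, "pct_change_enm"]
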