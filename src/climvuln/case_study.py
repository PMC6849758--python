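"""Bundled case-study inputs: grey long-eared bat populations in Iberia
and southern England.

These are the published per-population values the framework was first
demonstrated on: current and future (2070) maximum temperature (degC),
summer rainfall (mm) and ENM-predicted relative occurrence probability
(0-100), the binary suitable/unsuitable outcome of the future projection,
the published sensitivity codes (adaptive; neutral), range-shift flags and
final risk levels.  They serve as a worked regression fixture for the
exposure, sensitivity and risk engines; the genomic raw data behind the
sensitivity codes are not bundled.

One published derived value is internally inconsistent: Granada's percent
suitability change is reported as -52.5, but its own inputs give
(37 - 80) / 80 = -53.8.  The recomputed value is used wherever arithmetic
is checked; the exposure bin (change > 25%) is unaffected.
"""

from __future__ import annotations

import pandas as pd

# pop, region, tmax_now, rain_now, enm_now, tmax_2070, rain_2070, enm_2070,
# suitable_now, suitable_2070
_CLIMATE_ROWS = [
    ("Lisboa",     "Iberia",  25.3,  36, 100, 28.6,  28, 80, True, True),
    ("Bizkaia",    "Iberia",  23.6, 225,  38, 29.9, 120, 40, True, True),
    ("Girona",     "Iberia",  25.6, 159,  76, 32.1,  90,  7, True, False),
    ("Granada",    "Iberia",  30.0,  45,  80, 36.9,  39, 37, True, True),
    ("Albacete",   "Iberia",  31.6,  61,  34, 40.4,  27, 17, True, False),
    ("Valladolid", "Iberia",  29.3,  65,  56, 38.4,  34, 41, True, True),
    ("Valencia",   "Iberia",  28.5,  87,  44, 35.6,  42,  5, True, False),
    ("Devon",      "England", 19.8, 171,  90, 25.5, 107, 95, True, True),
    ("Dorset",     "England", 20.8, 164,  60, 27.4,  98, 63, True, True),
]

# published derived columns (delta tmax, delta rain, % rain, % ENM)
_PUBLISHED_CHANGES = {
    "Lisboa":     (+3.3,   -8, -22.2, -20.0),
    "Bizkaia":    (+6.3, -105, -46.7,  +5.3),
    "Girona":     (+6.5,  -69, -43.4, -90.8),
    "Granada":    (+6.9,   -6, -13.3, -52.5),   # -52.5 inconsistent, see docstring
    "Albacete":   (+8.8,  -34, -55.7, -50.0),
    "Valladolid": (+9.1,  -31, -47.7, -26.8),
    "Valencia":   (+7.1,  -45, -51.7, -88.6),
    "Devon":      (+5.7,  -64, -37.4,  +5.6),
    "Dorset":     (+6.6,  -66, -40.2,  +5.0),
}

# published risk-table components for the seven Iberian populations:
# exposure rank, adaptive code, neutral code, overall sensitivity,
# range-shift flag, risk level
_RISK_ROWS = [
    ("Lisboa",     1, "-",  "0", "-", "+", "Low"),
    ("Bizkaia",    1, "++", "-", "+", "+", "Low"),
    ("Granada",    2, "-",  "0", "-", "-", "Medium"),
    ("Girona",     3, "+",  "-", "0", "+", "Medium"),
    ("Valladolid", 3, "-",  "-", "-", "-", "Medium-high"),
    ("Albacete",   4, "-",  "-", "-", "-", "Medium-high"),
    ("Valencia",   4, "++", "-", "+", "-", "High"),
]

# published per-population heterozygosity values (neutral loci)
HETEROZYGOSITY = {"Dorset": 0.664, "Granada": 0.844, "Lisboa": 0.885}


def climate_table() -> pd.DataFrame:
    """Current/future climate and suitability per population."""
    return pd.DataFrame(_CLIMATE_ROWS, columns=[
        "pop", "region", "tmax_now", "rain_now", "enm_now",
        "tmax_future", "rain_future", "enm_future",
        "suitable_now", "suitable_future",
    ])


def published_changes() -> pd.DataFrame:
    """Published delta/percent columns (as printed, one known misprint)."""
    rows = [(k, *v) for k, v in _PUBLISHED_CHANGES.items()]
    return pd.DataFrame(rows, columns=[
        "pop", "delta_tmax", "delta_rain", "pct_change_rain", "pct_change_enm",
    ])


def risk_table() -> pd.DataFrame:
    """Published exposure/sensitivity/range/risk rows (Iberia only)."""
    return pd.DataFrame(_RISK_ROWS, columns=[
        "pop", "exposure", "adaptive_code", "neutral_code",
        "sensitivity", "range_shift", "risk",
    ])


def exposure_records():
    """ExposureRecord objects built from the bundled climate table."""
    from .exposure_risk import ExposureRecord

    recs = []
    for row in climate_table().itertuples():
        recs.append(ExposureRecord(
            pop=row.pop,
            tmax_now=row.tmax_now, tmax_future=row.tmax_future,
            rain_now=row.rain_now, rain_future=row.rain_future,
            suit_now=row.enm_now, suit_future=row.enm_future,
            suitable_now=row.suitable_now, suitable_future=row.suitable_future,
        ))
    return recs


def reproduce_risk_table() -> pd.DataFrame:
    """Recompute exposure, overall sensitivity and risk for the Iberian
    populations from the bundled inputs, alongside the published values."""
    from .exposure_risk import (assess, combine_sensitivity, exposure_level)

    published = risk_table()
    records = {r.pop: r for r in exposure_records()}
    rows = []
    for rec in published.itertuples():
        ea = exposure_level(records[rec.pop])
        overall = combine_sensitivity(rec.adaptive_code, rec.neutral_code)
        rows.append({
            "pop": rec.pop,
            "exposure_computed": ea.level,
            "exposure_published": rec.exposure,
            "exposure_rule_mismatch": ea.rule_mismatch,
            "sensitivity_computed": overall,
            "sensitivity_published": rec.sensitivity,
        })
    computed = pd.DataFrame(rows)
    risk = assess(
        published.rename(columns={"exposure": "exposure"})[["pop", "exposure"]],
        published[["pop", "adaptive_code", "neutral_code"]],
        published[["pop", "range_shift"]],
    ).rename(columns={"risk": "risk_computed"})
    out = computed.merge(risk[["pop", "risk_computed"]], on="pop")
    out["risk_published"] = published["risk"].to_numpy()
    return out
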