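"""PED/MAP parsing, PI_HAT, the exact HWE test and the QC filter chain."""

import numpy as np
import pytest

from climvuln import (GenotypeMatrix, QcThresholds, apply_qc, hwe_exact,
                      pi_hat, read_ped_map, write_ped_map)
from climvuln.matrix import MISSING


def _write(tmp_path, ped_lines, map_lines):
    ped = tmp_path / "t.ped"
    mp = tmp_path / "t.map"
    ped.write_text("\n".join(ped_lines) + "\n")
    mp.write_text("\n".join(map_lines) + "\n")
    return ped, mp


class TestPedMap:
    def test_hand_coded_file(self, tmp_path):
        ped, mp = _write(
            tmp_path,
            ["P1 S1 0 0 0 -9 A A", "P1 S2 0 0 0 -9 A G"],
            ["1 L1 0 1"],
        )
        gm = read_ped_map(ped, mp)
        assert gm.genotypes[:, 0].tolist() == [0, 1]   # A2 = G
        assert gm.alleles[0].tolist() == ["A", "G"]

    def test_missing_genotype(self, tmp_path):
        ped, mp = _write(
            tmp_path,
            ["P1 S1 0 0 0 -9 0 0 C C", "P1 S2 0 0 0 -9 A A C T"],
            ["1 L1 0 1", "1 L2 0 2"],
        )
        gm = read_ped_map(ped, mp)
        assert gm.genotypes[0, 0] == MISSING
        assert gm.genotypes[0, 1] == 0
        assert gm.genotypes[1, 1] == 1

    def test_het_allele_order_irrelevant(self, tmp_path):
        ped, mp = _write(
            tmp_path,
            ["P1 S1 0 0 0 -9 G A", "P1 S2 0 0 0 -9 A G"],
            ["1 L1 0 1"],
        )
        gm = read_ped_map(ped, mp)
        assert gm.genotypes[:, 0].tolist() == [1, 1]

    def test_roundtrip_identity(self, tmp_path, sim_small):
        gm = sim_small.genotypes
        write_ped_map(gm, tmp_path / "rt.ped", tmp_path / "rt.map")
        back = read_ped_map(tmp_path / "rt.ped", tmp_path / "rt.map")
        g0 = gm.genotypes
        poly = np.array([(col == 1).any()
                         or len(set(col[col != MISSING]) - {1}) > 1
                         for col in g0.T])
        assert np.array_equal(back.genotypes[:, poly], g0[:, poly])
        assert back.locus_ids == gm.locus_ids
        assert back.pop_ids == gm.pop_ids

    @pytest.mark.parametrize("ped_lines, match", [
        (["P1 S1 0 0 0 -9 A A", "P1 S2 0 0 0 -9 A"], "expected"),
        (["P1 S1 0 0 0 -9 A Z"], "unknown allele"),
    ])
    def test_parse_errors_name_line(self, tmp_path, ped_lines, match):
        ped, mp = _write(tmp_path, ped_lines, ["1 L1 0 1"])
        with pytest.raises(ValueError, match=match):
            read_ped_map(ped, mp)


class TestPiHat:
    def test_identical_individuals(self, sim_small):
        gm = sim_small.genotypes
        dup = GenotypeMatrix(
            np.vstack([gm.genotypes[0], gm.genotypes[0]]),
            ["a", "b"], ["P", "P"], gm.locus_ids, gm.alleles)
        # frequencies from the full data set, as in the QC chain
        assert pi_hat(dup, 0, 1, gm.allele_frequencies()) == pytest.approx(1.0)

    def test_parent_offspring_half(self, rng):
        # construct a parent-offspring pair sharing one allele at every locus
        n_loci = 2000
        p = rng.uniform(0.2, 0.8, n_loci)
        mother = rng.binomial(2, p)
        transmitted = np.where(mother == 1, rng.integers(0, 2, n_loci),
                               mother // 2)
        child = transmitted + rng.binomial(1, p)
        geno = np.vstack([mother, child]).astype(np.int8)
        gm = GenotypeMatrix(geno, ["m", "c"], ["P", "P"],
                            [f"L{i}" for i in range(n_loci)],
                            np.array([["A", "C"]] * n_loci))
        assert abs(pi_hat(gm, 0, 1, p) - 0.5) <= 0.1

    def test_unrelated_pairs_low(self, rng):
        low = 0
        n_reps = 20
        for _ in range(n_reps):
            p = rng.uniform(0.1, 0.9, 1500)
            geno = rng.binomial(2, p, size=(2, 1500)).astype(np.int8)
            gm = GenotypeMatrix(geno, ["a", "b"], ["P", "P"],
                                [f"L{i}" for i in range(1500)],
                                np.array([["A", "C"]] * 1500))
            low += pi_hat(gm, 0, 1, p) < 0.2
        assert low >= 0.95 * n_reps - 1

    def test_no_overlap_flagged(self):
        geno = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
        gm = GenotypeMatrix(geno, ["a", "b"], ["P", "P"], ["L1", "L2"],
                            np.array([["A", "C"]] * 2))
        with pytest.raises(ValueError, match="overlap"):
            pi_hat(gm, 0, 1, np.array([0.5, 0.5]))


class TestHweExact:
    def test_perfect_hwe(self):
        assert hwe_exact(25, 50, 25) > 0.5

    def test_extreme_het_deficit(self):
        assert hwe_exact(50, 0, 50) < 1e-6

    def test_monomorphic_convention(self):
        assert hwe_exact(1, 0, 0) == 1.0
        assert hwe_exact(0, 0, 7) == 1.0

    def test_symmetry_in_homozygote_labels(self):
        for counts in [(3, 4, 5), (1, 7, 2), (0, 3, 9)]:
            assert hwe_exact(*counts) == pytest.approx(
                hwe_exact(counts[2], counts[1], counts[0]))

    @pytest.mark.parametrize("counts", [(3, 4, 5), (2, 2, 8), (6, 1, 5)])
    def test_against_permutation_oracle(self, counts, rng):
        """Monte-Carlo pairing of the allele pool reproduces the exact p."""
        hom1, het, hom2 = counts
        n = hom1 + het + hom2
        pool = np.array([0] * (2 * hom1 + het) + [1] * (2 * hom2 + het))
        n_mc = 40_000
        het_counts = np.empty(n_mc, dtype=int)
        for b in range(n_mc):
            rng.shuffle(pool)
            pairs = pool.reshape(n, 2)
            het_counts[b] = int(np.sum(pairs[:, 0] != pairs[:, 1]))
        # two-sided exact convention: sum probabilities of configurations
        # at most as probable as the observed one
        values, freqs = np.unique(het_counts, return_counts=True)
        probs = freqs / n_mc
        p_obs = probs[values == het]
        assert p_obs.size == 1
        p_mc = probs[probs <= p_obs[0] * 1.0001].sum()
        assert abs(hwe_exact(*counts) - p_mc) < 0.02


class TestApplyQc:
    def _base_matrix(self, rng, n_ind=24, n_loci=60, n_pops=3):
        p = rng.uniform(0.2, 0.8, n_loci)
        geno = rng.binomial(2, p, size=(n_ind, n_loci)).astype(np.int8)
        per = n_ind // n_pops
        pops = [f"P{i // per + 1}" for i in range(n_ind)]
        return GenotypeMatrix(
            geno, [f"S{i:02d}" for i in range(n_ind)], pops,
            [f"L{i:02d}" for i in range(n_loci)],
            np.array([["A", "G"]] * n_loci))

    def test_stage_filters_and_reconciliation(self, rng):
        gm = self._base_matrix(rng)
        g = gm.genotypes.copy()
        g[0, : int(0.6 * gm.n_loci)] = MISSING       # individual 60% missing
        g[1:, 5] = MISSING                           # locus >30% missing
        g[3] = g[2]                                  # duplicate pair
        g[:, 7] = 0                                  # monomorphic -> MAF fail
        g[:, 8] = 0
        g[4, 8] = 1                                  # singleton: MAF < 0.03
        gm = GenotypeMatrix(g, gm.sample_ids, gm.pop_ids, gm.locus_ids,
                            gm.alleles)
        out, report = apply_qc(gm)
        assert "S00" in report.removed_ind_missing
        assert "L05" in report.removed_loci_missing
        assert {"L07", "L08"} <= set(report.removed_loci_maf)
        assert len(report.removed_ind_related) == 1
        assert report.removed_ind_related[0] in {"S02", "S03"}
        assert out.n_individuals == report.n_ind_out
        assert out.n_loci == report.n_loci_out
        assert 0.9 < report.genotyping_rate <= 1.0

    def test_hwe_filter_needs_three_populations(self, rng):
        gm = self._base_matrix(rng, n_ind=60, n_loci=30, n_pops=3)
        g = gm.genotypes.copy()
        # extreme heterozygote deficit in two populations only
        g[:40, 3] = np.where(np.arange(40) % 2 == 0, 0, 2)
        gm2 = GenotypeMatrix(g, gm.sample_ids, gm.pop_ids, gm.locus_ids,
                             gm.alleles)
        _, report2 = apply_qc(gm2)
        assert "L03" not in report2.removed_loci_hwe
        # and in all three -> removed
        g[:, 3] = np.where(np.arange(60) % 2 == 0, 0, 2)
        gm3 = GenotypeMatrix(g, gm.sample_ids, gm.pop_ids, gm.locus_ids,
                             gm.alleles)
        _, report3 = apply_qc(gm3)
        assert "L03" in report3.removed_loci_hwe

    def test_filter_order_is_canonical(self, rng):
        """An over-missing individual is removed before locus missingness is
        judged, so a locus whose missingness is driven by that individual
        survives; the reverse order would drop it."""
        gm = self._base_matrix(rng, n_ind=10, n_loci=40, n_pops=2)
        g = gm.genotypes.copy()
        g[0, :] = MISSING                    # individual: 100% missing
        g[1:3, 4] = MISSING                  # locus 4: 3/10 > 0.3 with S0...
        gm = GenotypeMatrix(g, gm.sample_ids, gm.pop_ids, gm.locus_ids,
                            gm.alleles)
        out, report = apply_qc(gm)
        # after removing the individual, locus 4 missingness is 2/9 < 0.3
        assert "L04" not in report.removed_loci_missing
        assert "L04" in out.locus_ids

    def test_relative_tiebreak_drops_more_missing(self, rng):
        gm = self._base_matrix(rng, n_ind=12, n_loci=50, n_pops=2)
        g = gm.genotypes.copy()
        g[5] = g[4]
        g[5, :10] = MISSING                  # the copy has more missing data
        gm = GenotypeMatrix(g, gm.sample_ids, gm.pop_ids, gm.locus_ids,
                            gm.alleles)
        _, report = apply_qc(gm)
        assert report.removed_ind_related == ["S05"]

    def test_min_pop_size_for_stats(self, sim_small):
        _, report = apply_qc(sim_small.genotypes)
        sizes = {}
        for p in report.pops_for_stats:
            sizes[p] = sum(1 for q in sim_small.genotypes.pop_ids if q == p)
        assert all(v >= 7 for v in sizes.values())

    def test_single_population_rejected(self, rng):
        gm = self._base_matrix(rng, n_ind=8, n_loci=20, n_pops=1)
        with pytest.raises(ValueError, match="two populations"):
            apply_qc(gm)
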