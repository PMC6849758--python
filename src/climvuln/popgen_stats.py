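"""Allele-frequency statistics: heterozygosity/F, Weir-Cockerham theta, AMOVA.

Heterozygosity follows the plink `--het` convention: per individual,
F = (Obs_Hom - Exp_Hom) / (Total - Exp_Hom), where the expected homozygote
count sums 1 - 2p(1-p) * n/(n-1) over the individual's non-missing loci
(p = whole-dataset allele frequency, n = number of non-missing alleles at
the locus).  Population heterozygosity is reported as 1 - mean(F), which
can exceed classical expected heterozygosity and is bounded above by ~1.

F_ST uses the Weir & Cockerham (1984) variance-components estimator theta,
combined across loci as a ratio of sums (numerators and denominators summed
separately), which is stable for the small per-population sample sizes this
pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MISSING, DistanceMatrix, GenotypeMatrix


# ----------------------------------------------------------------------
# Heterozygosity / inbreeding-style F
# ----------------------------------------------------------------------

def heterozygosity(gm: GenotypeMatrix,
                   exclude_loci: list[str] | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-individual (Obs_Hom, Exp_Hom, Total, F) and per-population
    (mean F, heterozygosity = 1 - mean F) tables.

    `exclude_loci` removes loci (e.g. selection outliers) before computing.
    """
    if exclude_loci:
        drop = set(exclude_loci)
        keep = [j for j, l in enumerate(gm.locus_ids) if l not in drop]
        gm = gm.take_loci(keep)

    g = gm.genotypes
    called = g != MISSING
    n_alleles = 2.0 * called.sum(axis=0)
    p = gm.allele_frequencies()
    # per-locus expected homozygosity with n/(n-1) small-sample correction
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_hom_locus = np.where(
            n_alleles > 1, 1.0 - 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1.0),
            np.nan,
        )
    usable = called & ~np.isnan(exp_hom_locus)

    rows = []
    for i in range(gm.n_individuals):
        u = usable[i]
        total = int(u.sum())
        if total == 0:
            rows.append({"sample": gm.sample_ids[i], "pop": gm.pop_ids[i],
                         "obs_hom": np.nan, "exp_hom": np.nan,
                         "total": 0, "F": np.nan, "flag": "no_data"})
            continue
        obs_hom = int(np.sum((g[i, u] == 0) | (g[i, u] == 2)))
        exp_hom = float(exp_hom_locus[u].sum())
        denom = total - exp_hom
        f = (obs_hom - exp_hom) / denom if denom != 0 else np.nan
        rows.append({"sample": gm.sample_ids[i], "pop": gm.pop_ids[i],
                     "obs_hom": obs_hom, "exp_hom": exp_hom, "total": total,
                     "F": f, "flag": "" if denom != 0 else "degenerate"})
    ind = pd.DataFrame(rows)

    pop = (ind.dropna(subset=["F"]).groupby("pop")["F"].mean()
           .rename("mean_F").to_frame())
    pop["heterozygosity"] = 1.0 - pop["mean_F"]
    pop["capped"] = pop["heterozygosity"] > 1.0
    return ind, pop.reset_index()


# ----------------------------------------------------------------------
# Weir-Cockerham theta
# ----------------------------------------------------------------------

def wc_components(gm: GenotypeMatrix, pops: list[str] | None = None,
                  loci: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham variance components (a, a+b+c).

    Returns arrays (numerator, denominator) of length n_loci; loci without
    data in >=2 populations get NaN.
    """
    if pops is not None:
        gm = gm.subset_pops(pops)
    if loci is not None:
        gm = gm.take_loci(np.asarray(loci))
    groups = list(gm.pop_indices().values())
    r_max = len(groups)
    if r_max < 2:
        raise ValueError("theta requires at least two populations")

    g = gm.genotypes
    L = gm.n_loci
    n_i = np.empty((r_max, L))
    p_i = np.empty((r_max, L))
    h_i = np.empty((r_max, L))
    for k, idx in enumerate(groups):
        sub = g[idx]
        called = sub != MISSING
        n_i[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n_i[k] > 0,
                              np.where(called, sub, 0).sum(axis=0) / (2 * n_i[k]),
                              np.nan)
            h_i[k] = np.where(n_i[k] > 0,
                              np.where(called, sub == 1, False).sum(axis=0) / n_i[k],
                              np.nan)

    valid = n_i > 0
    r = valid.sum(axis=0).astype(float)
    ok = r >= 2
    n = np.where(valid, n_i, 0.0)
    nbar = n.sum(axis=0) / np.maximum(r, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n.sum(axis=0) - (n**2).sum(axis=0) / n.sum(axis=0)) / (r - 1)
        pbar = np.nansum(n * p_i, axis=0) / (r * nbar)
        s2 = np.nansum(n * (p_i - pbar) ** 2, axis=0) / ((r - 1) * nbar)
        hbar = np.nansum(n * h_i, axis=0) / (r * nbar)

        a = (nbar / n_c) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0

    num = np.where(ok & (nbar > 1), a, np.nan)
    den = np.where(ok & (nbar > 1), a + b + c, np.nan)
    # monomorphic loci contribute 0/0; keep them NaN so ratio-of-sums skips them
    mono = (np.nan_to_num(pbar) <= 0) | (np.nan_to_num(pbar) >= 1)
    num[mono] = np.nan
    den[mono] = np.nan
    return num, den


def wc_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str,
           loci: np.ndarray | None = None) -> float:
    """Multi-locus ratio-of-sums theta between two populations."""
    num, den = wc_components(gm, [pop_a, pop_b], loci)
    total = np.nansum(den)
    if not np.isfinite(total) or total == 0:
        raise ValueError(f"no informative loci for pair ({pop_a}, {pop_b})")
    return float(np.nansum(num) / total)


def fst_per_locus(gm: GenotypeMatrix, pops: list[str] | None = None) -> np.ndarray:
    """Per-locus theta across the given populations (NaN where undefined)."""
    num, den = wc_components(gm, pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(np.abs(den) > 0, num / den, np.nan)


def mean_multilocus_fst(gm: GenotypeMatrix, pops: list[str] | None = None) -> float:
    """Ratio-of-sums theta over all loci and the given populations."""
    num, den = wc_components(gm, pops)
    return float(np.nansum(num) / np.nansum(den))


def fst_matrix(gm: GenotypeMatrix, pops: list[str] | None = None,
               loci: np.ndarray | None = None,
               name: str = "fst") -> DistanceMatrix:
    """Pairwise multi-locus theta as a `DistanceMatrix` (diagonal 0)."""
    if pops is None:
        pops = list(dict.fromkeys(gm.pop_ids))
    n = len(pops)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = wc_fst(gm, pops[i], pops[j], loci)
    return DistanceMatrix(pops, vals, name)


# ----------------------------------------------------------------------
# AMOVA (two-level, genotype allele-count distances)
# ----------------------------------------------------------------------

@dataclass
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    r2: float           # SS_among / SS_total
    p_value: float
    n_permutations: int


def _pairwise_sq_dist(gm: GenotypeMatrix) -> np.ndarray:
    """Squared allele-count distances between individuals.

    Missing data are handled by rescaling each pair's sum of squared dosage
    differences over co-called loci to the full locus count.
    """
    G = gm.genotypes.astype(float)
    M = G != MISSING
    A = np.where(M, G, 0.0)
    Mf = M.astype(float)
    S = A**2
    cross = A @ A.T
    part = S @ Mf.T
    shared = Mf @ Mf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = (part + part.T - 2 * cross) * (gm.n_loci / shared)
    d2[shared == 0] = np.nan
    np.fill_diagonal(d2, 0.0)
    return d2


def amova(gm: GenotypeMatrix, groups: list[str] | None = None,
          n_permutations: int = 999, seed: int = 0) -> AmovaResult:
    """Two-level AMOVA on genotype distances with a permutation test.

    `groups` assigns each individual to a stratum (defaults to its
    population); the p-value permutes individuals among strata.
    """
    labels = np.asarray(groups if groups is not None else gm.pop_ids)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("AMOVA requires at least two groups")
    d2 = _pairwise_sq_dist(gm)
    if np.isnan(d2).any():
        raise ValueError("pairs with no shared loci; AMOVA distances undefined")
    N = gm.n_individuals
    K = len(uniq)

    ss_total = d2[np.triu_indices(N, k=1)].sum() / N

    def ss_within_of(lbl: np.ndarray) -> float:
        ss = 0.0
        for gname in uniq:
            idx = np.flatnonzero(lbl == gname)
            if len(idx) < 1:
                continue
            sub = d2[np.ix_(idx, idx)]
            ss += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
        return ss

    ss_w = ss_within_of(labels)
    ss_a = ss_total - ss_w
    df_a, df_w = K - 1, N - K
    ms_a, ms_w = ss_a / df_a, ss_w / df_w
    sizes = np.array([np.sum(labels == gname) for gname in uniq], float)
    n0 = (N - (sizes**2).sum() / N) / (K - 1)
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n0
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom > 0 else np.nan

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        # smaller within-SS <=> larger among-SS <=> more extreme structure
        if ss_total - ss_within_of(perm) >= ss_a - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return AmovaResult(ss_a, ss_w, df_a, df_w, sigma_a, sigma_w, phi,
                       ss_a / ss_total if ss_total > 0 else np.nan,
                       p, n_permutations)
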