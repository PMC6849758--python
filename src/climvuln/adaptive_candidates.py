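"""Nominate climate-adaptive SNPs by strict intersection of evidence types.

A locus becomes a candidate only if it is (1) a differentiation outlier,
(2) flagged by the latent-factor genotype-environment scan (either
covariate, single-region scale by default), and (3) significantly
associated with the same covariate in the per-locus logistic regression.
This AND across evidence *types* (differentiation + association +
regression) is the load-bearing logic of the sensitivity assessment.

Each candidate locus is then oriented: the "warm-adaptive" allele is the
one whose frequency increases with maximum temperature (positive logistic
slope on the dosage allele), and the "dry-adaptive" allele the one whose
frequency increases as summer rainfall decreases (negative slope).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix


def intersect(outliers: pd.DataFrame, gea: dict, logit: pd.DataFrame,
              gea_scale: str = "region", logit_alpha: float = 0.05
              ) -> pd.DataFrame:
    """Strict AND across the three evidence sources.

    Parameters
    ----------
    outliers : frame from `outlier_scan.scan` (columns locus, outlier, ...).
    gea : {(scale, covariate): GeaScan} as returned by `run_two_scales`
        (or any mapping whose values expose `.table` with locus/q/flag).
    logit : frame with columns locus, covariate, slope, p.
    gea_scale : which scan scale provides the authoritative GEA evidence.

    Returns a candidate frame (possibly empty) with one row per locus and
    provenance columns; the supporting covariate is the GEA-flagged
    covariate with the smallest q that also has a significant logistic
    regression.
    """
    outlier_set = set(outliers.loc[outliers["outlier"], "locus"])
    logit_ok = {
        (r.locus, r.covariate): r
        for r in logit.itertuples()
        if r.p < logit_alpha
    }

    rows = []
    covariates = sorted({cov for (scale, cov) in gea if scale == gea_scale})
    gea_tables = {
        cov: gea[(gea_scale, cov)].table.set_index("locus")
        for cov in covariates
    }
    for locus in outliers["locus"]:
        if locus not in outlier_set:
            continue
        support = []
        for cov in covariates:
            t = gea_tables[cov]
            if locus in t.index and bool(t.loc[locus, "flag"]) \
                    and (locus, cov) in logit_ok:
                support.append((float(t.loc[locus, "q"]), cov))
        if not support:
            continue
        support.sort()
        q_best, cov_best = support[0]
        lr = logit_ok[(locus, cov_best)]
        rows.append({
            "locus": locus,
            "covariate": cov_best,
            "gea_q": q_best,
            "logit_slope": lr.slope,
            "logit_p": lr.p,
            "supporting_covariates": ",".join(c for _, c in support),
        })
    cols = ["locus", "covariate", "gea_q", "logit_slope", "logit_p",
            "supporting_covariates"]
    return pd.DataFrame(rows, columns=cols)


def orient_adaptive_allele(covariate: str, slope: float) -> tuple[str, bool]:
    """Assign the warm/dry-adaptive allele label from the regression slope.

    Dosage counts copies of A2, so a positive temperature slope means A2
    rises with temperature (warm-adaptive = A2); for rainfall, the
    dry-adaptive allele rises as rainfall falls (negative slope = A2).
    Returns (allele_label, ambiguous_flag).
    """
    if slope == 0 or not np.isfinite(slope):
        return "A2", True
    if covariate == "temperature":
        return ("A2" if slope > 0 else "A1"), False
    if covariate == "rainfall":
        return ("A2" if slope < 0 else "A1"), False
    raise ValueError(f"unknown covariate {covariate!r}")


def orient_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    """Add adaptive-allele orientation columns to a candidate frame."""
    out = candidates.copy()
    alleles, flags = [], []
    for r in out.itertuples():
        a, amb = orient_adaptive_allele(r.covariate, r.logit_slope)
        alleles.append(a)
        flags.append(amb)
    out["adaptive_allele"] = alleles
    out["orientation_ambiguous"] = flags
    return out


def population_summary(candidates: pd.DataFrame, gm: GenotypeMatrix,
                       pops: list[str] | None = None,
                       low_freq: float = 0.25) -> pd.DataFrame:
    """Per-population adaptive-allele frequency summary.

    Reports, per population: the mean frequency of the adaptive allele
    across candidate loci, and the count and fraction of candidate loci
    whose adaptive allele sits below `low_freq`.
    """
    if candidates.empty:
        raise ValueError("empty candidate set: no summary to compute")
    if "adaptive_allele" not in candidates.columns:
        candidates = orient_candidates(candidates)
    if pops is None:
        pops = list(dict.fromkeys(gm.pop_ids))
    else:
        missing = set(pops) - set(gm.pop_ids)
        if missing:
            raise ValueError(f"populations absent from genotypes: {sorted(missing)}")

    pop_freq = gm.pop_allele_frequencies()  # A2 frequency, pops x loci
    rows = []
    for pop in pops:
        freqs = []
        for r in candidates.itertuples():
            f_a2 = float(pop_freq.loc[pop, r.locus])
            freqs.append(f_a2 if r.adaptive_allele == "A2" else 1.0 - f_a2)
        freqs = np.asarray(freqs)
        n_low = int(np.sum(freqs < low_freq))
        rows.append({
            "pop": pop,
            "n_candidates": len(freqs),
            "mean_adaptive_freq": float(np.mean(freqs)),
            "n_below_025": n_low,
            "fraction_below_025": n_low / len(freqs),
        })
    return pd.DataFrame(rows)
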