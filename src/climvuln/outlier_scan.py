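"""FDist-style F_ST outlier detection against a simulated neutral envelope.

Loci with excess differentiation are detected by comparing each locus's
Weir-Cockerham theta with the conditional distribution of theta given
expected heterozygosity under a neutral Balding-Nichols island model,
simulated at the observed sample configuration.  The island-model F is
calibrated by bisection so the simulated multi-locus mean theta matches a
target (e.g. the observed neutral mean).  Per-outlier follow-up: logistic
(binomial GLM) regression of individual allele dosages on a standardized
environmental covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MISSING, GenotypeMatrix
from .popgen_stats import fst_per_locus
from .synthetic_data import _balding_nichols

_MIN_BIN_POINTS = 200
_BIN_HALF_WIDTH = 0.025


@dataclass
class NeutralEnvelope:
    """Simulated neutral (He, theta) cloud with conditional quantile lookup."""

    he: np.ndarray
    fst: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = np.argsort(self.he)
        self.he = np.asarray(self.he)[order]
        self.fst = np.asarray(self.fst)[order]

    def _window(self, he_value: float) -> np.ndarray:
        """Theta values in a sliding He bin around `he_value`.

        The bin starts at half-width 0.025 and widens until it holds at
        least `_MIN_BIN_POINTS` points (nearest-bin rule at the edges).
        """
        d = np.abs(self.he - he_value)
        if len(d) <= _MIN_BIN_POINTS:
            return self.fst
        inside = d <= _BIN_HALF_WIDTH
        if inside.sum() >= _MIN_BIN_POINTS:
            return self.fst[inside]
        k = _MIN_BIN_POINTS
        idx = np.argpartition(d, k)[:k]
        return self.fst[idx]

    def quantile_curve(self, he_values: np.ndarray, q: float) -> np.ndarray:
        """Conditional theta quantile q at each He value."""
        return np.array([np.quantile(self._window(h), q) for h in he_values])

    def empirical_quantile(self, he_value: float, fst_value: float) -> float:
        w = self._window(he_value)
        return float(np.mean(w <= fst_value))

    @property
    def support(self) -> tuple[float, float]:
        return float(self.he.min()), float(self.he.max())


def _simulate_neutral_theta(rng: np.random.Generator, fst: float,
                            sample_sizes: np.ndarray, n_loci: int
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate BN loci; return per-locus (num, den) components and He."""
    r = len(sample_sizes)
    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    p_pop = _balding_nichols(rng, p_anc[None, :].repeat(r, axis=0), fst, (r, n_loci))
    n_i = np.asarray(sample_sizes)[:, None] * np.ones((1, n_loci))
    # sample genotype counts per pop: n_het etc. via binomial draws
    counts_a2 = np.empty((r, n_loci))
    het = np.empty((r, n_loci))
    for k in range(r):
        g = rng.binomial(2, p_pop[k], size=(int(sample_sizes[k]), n_loci))
        counts_a2[k] = g.sum(axis=0)
        het[k] = (g == 1).sum(axis=0)
    p_i = counts_a2 / (2 * n_i)
    h_i = het / n_i

    # Weir-Cockerham components straight from the summary statistics
    nbar = n_i.mean(axis=0)
    n_tot = n_i.sum(axis=0)
    n_c = (n_tot - (n_i**2).sum(axis=0) / n_tot) / (r - 1)
    pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
    a = (nbar / n_c) * (
        s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    he = 2 * pbar * (1 - pbar)
    poly = (pbar > 0) & (pbar < 1)
    return np.where(poly, a, np.nan), np.where(poly, a + b + c, np.nan), he


def simulate_envelope(n_pops: int, sample_sizes, mean_fst_target: float,
                      n_sim_loci: int = 10_000, seed: int = 0,
                      calibration_loci: int = 2_000,
                      max_bisection_steps: int = 50) -> NeutralEnvelope:
    """Simulate the neutral (He, theta) envelope at a target mean theta.

    The Balding-Nichols F is calibrated by bisection until the simulated
    multi-locus (ratio-of-sums) mean theta is within 0.005 of
    `mean_fst_target`.
    """
    if not 0 < mean_fst_target < 1:
        raise ValueError("mean_fst_target must be in (0, 1)")
    sizes = np.asarray(sample_sizes, dtype=int)
    if len(sizes) != n_pops:
        raise ValueError("sample_sizes length must equal n_pops")

    def mean_theta(f: float, n_loci: int) -> float:
        # common random numbers across evaluations keep the curve monotone
        rng = np.random.default_rng([3, seed])
        num, den, _ = _simulate_neutral_theta(rng, f, sizes, n_loci)
        return float(np.nansum(num) / np.nansum(den))

    lo, hi = 1e-4, 0.95
    f = mean_fst_target
    for _ in range(max_bisection_steps):
        m = mean_theta(f, calibration_loci)
        if abs(m - mean_fst_target) <= 0.005:
            break
        if m < mean_fst_target:
            lo = f
        else:
            hi = f
        f = 0.5 * (lo + hi)
    else:
        raise RuntimeError(
            f"calibration failed: could not reach mean theta {mean_fst_target}"
        )

    rng = np.random.default_rng([4, seed])
    num, den, he = _simulate_neutral_theta(rng, f, sizes, n_sim_loci)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(np.abs(den) > 0, num / den, np.nan)
    keep = np.isfinite(theta) & np.isfinite(he)
    meta = {
        "n_loci": int(n_sim_loci), "n_pops": int(n_pops),
        "sample_sizes": sizes.tolist(), "target_mean_fst": mean_fst_target,
        "calibrated_f": f, "achieved_mean_fst": float(np.nansum(num) / np.nansum(den)),
        "seed": seed,
    }
    return NeutralEnvelope(he[keep], theta[keep], meta)


def scan(gm: GenotypeMatrix, envelope: NeutralEnvelope, alpha: float = 0.01,
         pops: list[str] | None = None) -> pd.DataFrame:
    """Flag loci whose theta exceeds the neutral q_{1-alpha}(He) curve.

    Returns a frame with per-locus theta, He, the empirical neutral
    quantile, the outlier flag and an out-of-support flag (nearest-bin rule
    applied where observed He lies outside the simulated He range).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if pops is not None:
        gm = gm.subset_pops(pops)
    theta = fst_per_locus(gm)
    p = gm.allele_frequencies()
    he = 2 * p * (1 - p)

    lo, hi = envelope.support
    out_of_support = (he < lo) | (he > hi)
    if alpha >= 1.0:
        thresh = np.full(gm.n_loci, -np.inf)
    else:
        thresh = envelope.quantile_curve(he, 1.0 - alpha)
    quantiles = np.array([
        envelope.empirical_quantile(h, t) if np.isfinite(t) and np.isfinite(h)
        else np.nan
        for h, t in zip(he, theta)
    ])
    flagged = np.isfinite(theta) & (theta > thresh)
    return pd.DataFrame({
        "locus": gm.locus_ids,
        "fst": theta,
        "he": he,
        "quantile": quantiles,
        "outlier": flagged,
        "out_of_support": out_of_support,
    })


# ----------------------------------------------------------------------
# Per-locus logistic environmental regression
# ----------------------------------------------------------------------

@dataclass
class LogisticFit:
    slope: float
    se: float
    p_value: float
    method: str          # "wald" or "lrt" (separation fallback)
    converged: bool


def logistic_env_regression(dosages: np.ndarray, env: np.ndarray) -> LogisticFit:
    """Binomial GLM of per-individual allele dosage (out of 2) on a
    standardized covariate; Wald p, with a likelihood-ratio fallback when
    the fit is separated.
    """
    import statsmodels.api as sm

    dosages = np.asarray(dosages, dtype=float)
    env = np.asarray(env, dtype=float)
    ok = (dosages != MISSING) & np.isfinite(dosages) & np.isfinite(env)
    dosages, env = dosages[ok], env[ok]
    if dosages.size < 3:
        raise ValueError("too few genotyped individuals for regression")
    if np.ptp(env) == 0:
        raise ValueError("constant covariate: regression undefined")
    if np.ptp(dosages) == 0:
        raise ValueError("no genotype variation at locus")

    z = (env - env.mean()) / env.std(ddof=0)
    X = np.column_stack([np.ones_like(z), z])
    endog = np.column_stack([dosages, 2.0 - dosages])
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=100)
            converged = bool(res.converged)
        except Exception:
            res = model.fit(maxiter=100, method="lbfgs")
            converged = False
        slope = float(res.params[1])
        se = float(res.bse[1])
        separated = (not converged) or (not np.isfinite(se)) or abs(slope) > 15
        if separated:
            null = sm.GLM(endog, X[:, :1], family=sm.families.Binomial()).fit()
            lr = 2.0 * (res.llf - null.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            return LogisticFit(slope, se, p, "lrt", converged)
        p = float(2.0 * stats.norm.sf(abs(slope / se)))
        return LogisticFit(slope, se, p, "wald", converged)
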