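"""Multiple regression on distance matrices (MRDM) with permutation tests.

Distance matrices are vectorized on their strict lower triangles and fit
by ordinary least squares; inference uses simultaneous row/column
permutations of the response matrix (the convention required for valid
distance-matrix inference), with p = (#{permuted statistic >= observed} + 1)
/ (n_permutations + 1).  Per-predictor p-values use the pseudo-t statistic
under the same permutation scheme.

The stepwise residual procedure first regresses the genetic distance on
geographic distance, reassembles the residuals into a symmetric matrix,
and then tests landscape predictors (singly and in combination) against
that residual response; the best model is the highest-R2 model whose
predictors are all significant at 0.05.  A collinearity screen drops
landscape predictors whose lower-triangle R2 with geography (or an
already-retained predictor) exceeds 0.70.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .matrix import DistanceMatrix


@dataclass
class MrdmFit:
    predictor_names: list[str]
    coefficients: np.ndarray      # intercept first
    r2: float
    f_stat: float
    p_overall: float
    p_per_predictor: dict[str, float]
    n_permutations: int
    seed: int
    n_pops: int
    residual_matrix: DistanceMatrix | None = field(default=None, repr=False)


def _design(response: DistanceMatrix, predictors: dict[str, DistanceMatrix]
            ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    labels = response.labels
    y = response.lower_triangle()
    cols, names = [], []
    for name, mat in predictors.items():
        aligned = mat.align(labels)
        v = aligned.lower_triangle()
        if np.ptp(v) == 0:
            raise ValueError(f"constant predictor {name!r}")
        cols.append(v)
        names.append(name)
    X = np.column_stack([np.ones_like(y)] + cols)
    return y, X, names


def _fit_stats(X: np.ndarray, Y: np.ndarray, pinv: np.ndarray,
               xtx_inv_diag: np.ndarray) -> tuple[np.ndarray, ...]:
    """OLS stats for one or many response vectors (columns of Y)."""
    B = pinv @ Y
    resid = Y - X @ B
    rss = (resid**2).sum(axis=0)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    m, p = X.shape
    k = p - 1
    df = m - p
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
        f = (r2 / max(k, 1)) / np.maximum((1.0 - r2) / df, 1e-300)
        sigma2 = rss / df
        se = np.sqrt(np.maximum(sigma2[None, :] * xtx_inv_diag[:, None], 1e-300))
        t = B / se
    return B, resid, r2, f, t


def mrdm_fit(response: DistanceMatrix, predictors: dict[str, DistanceMatrix],
             n_permutations: int = 10_000, seed: int = 0) -> MrdmFit:
    """Fit one MRDM model and test it by row/column permutation."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if response.n < 4:
        raise ValueError("MRDM needs at least 4 populations")
    y, X, names = _design(response, predictors)
    pinv = np.linalg.pinv(X)
    xtx_inv_diag = np.diag(np.linalg.pinv(X.T @ X))
    B, resid, r2, f, t = _fit_stats(X, y[:, None], pinv, xtx_inv_diag)
    B, r2, f, t = B[:, 0], float(r2[0]), float(f[0]), t[:, 0]

    # permutation null: permute rows/columns of the response matrix
    rng = np.random.default_rng(seed)
    n = response.n
    il, jl = np.tril_indices(n, k=-1)
    M = response.values
    Y_perm = np.empty((len(y), n_permutations))
    for b in range(n_permutations):
        perm = rng.permutation(n)
        Y_perm[:, b] = M[perm[il], perm[jl]]
    _, _, r2_perm, f_perm, t_perm = _fit_stats(X, Y_perm, pinv, xtx_inv_diag)

    p_overall = float((np.sum(r2_perm >= r2 - 1e-12) + 1) / (n_permutations + 1))
    p_pred = {}
    for k_i, name in enumerate(names, start=1):
        exceed = np.sum(np.abs(t_perm[k_i]) >= abs(t[k_i]) - 1e-12)
        p_pred[name] = float((exceed + 1) / (n_permutations + 1))

    res_mat = np.zeros((n, n))
    res_mat[il, jl] = resid[:, 0]
    res_mat = res_mat + res_mat.T
    return MrdmFit(names, B, r2, f, p_overall, p_pred, n_permutations, seed,
                   n, DistanceMatrix(list(response.labels), res_mat, "residual"))


def collinearity_screen(predictors: dict[str, DistanceMatrix],
                        geo: DistanceMatrix,
                        r2_max: float = 0.70) -> list[str]:
    """Drop predictors with lower-triangle R2 > r2_max against geography or
    an already-retained predictor; retention order = input order."""
    if not predictors:
        raise ValueError("at least one predictor required")
    g = geo.lower_triangle()
    retained: list[str] = []
    kept_vecs: list[np.ndarray] = []

    def r2(a: np.ndarray, b: np.ndarray) -> float:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return 1.0
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    for name, mat in predictors.items():
        v = mat.align(geo.labels).lower_triangle()
        if r2(v, g) > r2_max:
            continue
        if any(r2(v, w) > r2_max for w in kept_vecs):
            continue
        retained.append(name)
        kept_vecs.append(v)
    return retained


@dataclass
class StepwiseResult:
    stage1: MrdmFit
    stage2_fits: dict[tuple[str, ...], MrdmFit]
    best: tuple[str, ...] | None

    @property
    def best_fit(self) -> MrdmFit | None:
        return self.stage2_fits[self.best] if self.best else None


def stepwise_residual(response: DistanceMatrix, geo: DistanceMatrix,
                      landscape: dict[str, DistanceMatrix],
                      n_permutations: int = 10_000, seed: int = 0,
                      alpha: float = 0.05,
                      max_model_size: int | None = None) -> StepwiseResult:
    """Geography-first stepwise MRDM.

    Stage 1 regresses the response on geographic distance; stage 2 fits
    every non-empty predictor subset (up to `max_model_size`) against the
    reassembled residual matrix.  "No significant model" yields best=None,
    not an error.
    """
    stage1 = mrdm_fit(response, {"geography": geo}, n_permutations, seed)
    residual = stage1.residual_matrix

    names = list(landscape)
    top = max_model_size or len(names)
    fits: dict[tuple[str, ...], MrdmFit] = {}
    for size in range(1, top + 1):
        for subset in combinations(names, size):
            preds = {nm: landscape[nm] for nm in subset}
            fits[subset] = mrdm_fit(residual, preds, n_permutations, seed + 1)

    best, best_r2 = None, -np.inf
    for subset, fit in fits.items():
        if all(p < alpha for p in fit.p_per_predictor.values()):
            if fit.r2 > best_r2:
                best, best_r2 = subset, fit.r2
    return StepwiseResult(stage1, fits, best)


def env_dissimilarity_matrix(pops, column: str,
                             name: str | None = None) -> DistanceMatrix:
    """|pairwise difference| matrix of a per-population environmental value."""
    v = pops[column].to_numpy(float)
    labels = pops["pop"].tolist()
    return DistanceMatrix(labels, np.abs(v[:, None] - v[None, :]),
                          name or f"d_{column}")


def ibe_test(fst_adaptive: DistanceMatrix,
             env_dissimilarity: dict[str, DistanceMatrix],
             n_permutations: int = 10_000, seed: int = 0
             ) -> dict[str, MrdmFit]:
    """Isolation-by-environment: single-predictor MRDM per covariate."""
    return {
        name: mrdm_fit(fst_adaptive, {name: mat}, n_permutations, seed)
        for name, mat in env_dissimilarity.items()
    }
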