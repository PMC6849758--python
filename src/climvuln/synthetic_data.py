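"""Synthetic landscapes, populations and genotypes with planted climate-adaptive loci.

This module emulates the study system the pipeline is designed for: a
low-dispersal vertebrate sampled in ~10 populations across two regions
separated by a sea channel (a large main region holding most populations
and a small second region of two), genotyped at thousands of biallelic
SNPs.  Neutral loci follow the Balding–Nichols island model, hierarchically
(region stratum, then population stratum), so that the neutral null of the
downstream outlier scan is exactly the generating model.  A small set of
adaptive loci receives an additional logistic shift of its population
allele frequencies along one of two climate covariates (maximum
temperature or summer rainfall), which is what the genotype–environment
machinery downstream is meant to recover.

Every draw flows from `SimConfig.seed`; the three generation stages use
independent child seeds so they are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .matrix import MISSING, GenotypeMatrix
from .raster import Grid

MAIN_REGION = "main"
NORTH_REGION = "north"

# niche optimum used for the fabricated suitability surface
_NICHE_T_OPT = 26.0   # degC
_NICHE_T_SD = 7.0
_NICHE_R_OPT = 120.0  # mm, log-scale optimum
_NICHE_R_SD = 0.9     # log-units
SUITABILITY_THRESHOLD = 0.25  # binary suitable/unsuitable cut for synthetic data


@dataclass
class FutureDelta:
    """Change applied to the current climate to obtain the future slice.

    tmax_add : additive change in maximum temperature (degC); scalar or
        a full grid-shaped array.
    rain_mult : multiplicative change in summer rainfall (1.0 = no change).
    """

    tmax_add: float = 6.5
    rain_mult: float = 0.6


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the target system: 10 populations of 9 diploid
    individuals (8 populations in the main region, 2 in the second),
    6000 neutral + 8 adaptive SNPs, within-region differentiation
    F_ST = 0.056, ~8% missing genotypes, and a future climate that is
    6.5 degC hotter and 40% drier.
    """

    n_pops: int = 10
    n_ind_per_pop: int = 9
    n_neutral: int = 6000
    n_adaptive: int = 8
    target_fst: float = 0.056
    region_fst: float = 0.08
    n_second_region_pops: int = 2
    env_effect: float = 2.0
    missing_rate: float = 0.08
    seed: int = 0
    grid_shape: tuple[int, int] = (40, 40)
    future_delta: FutureDelta = field(default_factory=FutureDelta)
    inject_relatives: bool = True

    def __post_init__(self) -> None:
        for name in ("n_pops", "n_ind_per_pop", "n_neutral"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_adaptive < 0:
            raise ValueError("n_adaptive must be >= 0")
        if not 0 < self.target_fst < 1:
            raise ValueError("target_fst must be in (0, 1)")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        if self.n_second_region_pops >= self.n_pops:
            raise ValueError("second region must hold fewer than n_pops populations")
        if min(self.grid_shape) < 2:
            raise ValueError("degenerate grid: every dimension must be >= 2")
        if min(self.grid_shape) < 8:
            raise ValueError("grid_shape must be at least (8, 8)")

    def _stage_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([stage, self.seed])


@dataclass
class Landscape:
    """Stack of aligned raster layers plus the sea mask and region map."""

    layers: dict[str, Grid]
    sea_mask: np.ndarray          # bool, True = sea
    region: np.ndarray            # str array, region label per cell

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    @property
    def shape(self) -> tuple[int, int]:
        return self.sea_mask.shape

    def write_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, grid in self.layers.items():
            grid.write_ascii(outdir / f"{name}.asc")
        sea = Grid(self.sea_mask.astype(float))
        sea.write_ascii(outdir / "sea_mask.asc")


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    noise = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def suitability_from_climate(tmax: np.ndarray, rain: np.ndarray) -> np.ndarray:
    """Fabricated Gaussian-niche suitability in [0, 1].

    The same function is applied to current and future climate, so
    suitable-to-unsuitable transitions arise mechanistically from the
    climate change itself.
    """
    rain = np.maximum(rain, 1.0)
    z_t = (tmax - _NICHE_T_OPT) / _NICHE_T_SD
    z_r = (np.log(rain) - np.log(_NICHE_R_OPT)) / _NICHE_R_SD
    return np.exp(-(z_t**2) - z_r**2)


def generate_landscape(cfg: SimConfig) -> Landscape:
    """Build the aligned raster stack for both time slices.

    Layers: tmax_now, rain_now, tmax_future, rain_future, suitability_now,
    suitability_future, landcover, slope, altitude; plus the sea mask.
    """
    rng = cfg._stage_rng(0)
    nrows, ncols = cfg.grid_shape

    # geometry: 1-cell sea ring; a sea channel splits off a northern island
    sea = np.zeros((nrows, ncols), dtype=bool)
    sea[0, :] = sea[-1, :] = True
    sea[:, 0] = sea[:, -1] = True
    region = np.full((nrows, ncols), MAIN_REGION, dtype=object)
    if cfg.n_second_region_pops > 0:
        ch_lo = max(2, int(round(nrows * 0.22)))
        ch_hi = max(ch_lo + 2, int(round(nrows * 0.28)))
        sea[ch_lo:ch_hi, :] = True
        region[:ch_lo, :] = NORTH_REGION

    lat = np.linspace(0.0, 1.0, nrows)[:, None] * np.ones((1, ncols))  # 0=N, 1=S

    # altitude: a few Gaussian massifs plus smoothed noise, in metres
    rr, cc = np.indices((nrows, ncols))
    alt = np.zeros((nrows, ncols))
    for _ in range(3):
        r0, c0 = rng.uniform(0.2, 0.8) * nrows, rng.uniform(0.2, 0.8) * ncols
        width = rng.uniform(0.1, 0.25) * max(nrows, ncols)
        alt += rng.uniform(400, 1200) * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * width**2)
        )
    alt += 120.0 * _smooth_noise(rng, (nrows, ncols), sigma=2.0)
    alt = np.clip(alt, 0.0, None)

    gy, gx = np.gradient(alt)
    slope = np.degrees(np.arctan(np.hypot(gx, gy) / 1000.0))

    tmax_now = 18.0 + 14.0 * lat - 0.004 * alt + 1.5 * _smooth_noise(
        rng, (nrows, ncols), sigma=3.0
    )
    rain_now = 30.0 + 200.0 * (1.0 - lat) + 0.05 * alt + 15.0 * _smooth_noise(
        rng, (nrows, ncols), sigma=3.0
    )
    rain_now = np.clip(rain_now, 5.0, None)

    delta = cfg.future_delta
    tmax_future = tmax_now + np.asarray(delta.tmax_add, dtype=float)
    rain_future = np.clip(rain_now * delta.rain_mult, 1.0, None)

    suit_now = suitability_from_climate(tmax_now, rain_now)
    suit_future = suitability_from_climate(tmax_future, rain_future)

    # landcover: 3 classes carved from a smooth field (1 forest, 2 open, 3 bare)
    lc_field = _smooth_noise(rng, (nrows, ncols), sigma=2.5)
    q1, q2 = np.quantile(lc_field, [0.4, 0.8])
    landcover = np.where(lc_field < q1, 1.0, np.where(lc_field < q2, 2.0, 3.0))

    def mask(a: np.ndarray) -> np.ndarray:
        out = a.astype(float).copy()
        out[sea] = np.nan
        return out

    layers = {
        "tmax_now": Grid(mask(tmax_now)),
        "rain_now": Grid(mask(rain_now)),
        "tmax_future": Grid(mask(tmax_future)),
        "rain_future": Grid(mask(rain_future)),
        "suitability_now": Grid(mask(suit_now)),
        "suitability_future": Grid(mask(suit_future)),
        "landcover": Grid(mask(landcover)),
        "slope": Grid(mask(slope)),
        "altitude": Grid(mask(alt)),
    }
    region[sea] = "sea"
    return Landscape(layers, sea, region)


def _farthest_point_sample(cells: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy max-min spread over candidate (row, col) cells."""
    chosen = [int(rng.integers(len(cells)))]
    d = np.linalg.norm(cells - cells[chosen[0]], axis=1)
    while len(chosen) < k:
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(cells - cells[nxt], axis=1))
    return cells[chosen]


def generate_populations(cfg: SimConfig, landscape: Landscape) -> pd.DataFrame:
    """Place populations on distinct land cells and read their environments.

    Populations are placed preferentially on currently-suitable cells and
    spread out by farthest-point sampling.  Columns include the per-period
    climate and suitability values sampled at the population cell.
    """
    rng = cfg._stage_rng(1)
    land = ~landscape.sea_mask
    if land.sum() < cfg.n_pops:
        raise ValueError("more populations than available land cells")

    suit = landscape["suitability_now"].data
    per_region = {
        MAIN_REGION: cfg.n_pops - cfg.n_second_region_pops,
        NORTH_REGION: cfg.n_second_region_pops,
    }
    rows: list[dict] = []
    idx = 0
    for reg, k in per_region.items():
        if k == 0:
            continue
        in_reg = land & (landscape.region == reg)
        if in_reg.sum() < k:
            raise ValueError(f"not enough land cells in region '{reg}'")
        cand = in_reg & (suit >= np.nanmedian(suit[in_reg]))
        if cand.sum() < k:
            cand = in_reg
        cells = np.argwhere(cand)
        placed = cells if len(cells) == k else _farthest_point_sample(cells, k, rng)
        for r, c in placed:
            idx += 1
            x, y = landscape["tmax_now"].cell_center(int(r), int(c))
            row = {
                "pop": f"P{idx:02d}",
                "region": reg,
                "row": int(r),
                "col": int(c),
                "x": x,
                "y": y,
            }
            for name in ("tmax_now", "rain_now", "tmax_future", "rain_future",
                         "suitability_now", "suitability_future"):
                row[name] = float(landscape[name].data[r, c])
            row["suitable_now"] = row["suitability_now"] >= SUITABILITY_THRESHOLD
            row["suitable_future"] = row["suitability_future"] >= SUITABILITY_THRESHOLD
            rows.append(row)
    pops = pd.DataFrame(rows)
    # deterministic order: main region first, then north, by placement order
    return pops.reset_index(drop=True)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float,
                     size: tuple[int, ...]) -> np.ndarray:
    """Population frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around p."""
    p = np.clip(p, 1e-4, 1 - 1e-4)
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale, size=size)


_BASES = np.array(list("ACGT"))


def generate_genotypes(cfg: SimConfig, pops: pd.DataFrame
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw diploid genotypes and the ground-truth table of planted loci.

    Neutral loci: ancestral p ~ U(0.05, 0.95), then Balding-Nichols at the
    region stratum (F = region_fst, only if two regions are present) and
    the population stratum (F = target_fst).  Adaptive loci add a logistic
    shift `env_effect * z` (z = covariate standardized across populations)
    on top of the same population-stratum draw, so env_effect = 0 reduces
    exactly to the neutral model.  Genotypes are Binomial(2, p_pop);
    missingness is uniform; one pair of close relatives is injected by
    copying an individual and re-sampling 5% of its genotypes.
    """
    rng = cfg._stage_rng(2)
    n_loci = cfg.n_neutral + cfg.n_adaptive
    if cfg.n_adaptive > n_loci:
        raise ValueError("n_adaptive exceeds total locus count")
    n_pops = len(pops)
    regions = pops["region"].to_numpy()
    uniq_regions = pd.unique(regions)

    p_anc = rng.uniform(0.05, 0.95, size=n_loci)
    # region stratum
    if len(uniq_regions) > 1 and cfg.region_fst > 0:
        p_reg = {
            reg: _balding_nichols(rng, p_anc, cfg.region_fst, (n_loci,))
            for reg in uniq_regions
        }
    else:
        p_reg = {reg: p_anc for reg in uniq_regions}
    # population stratum
    p_pop = np.empty((n_pops, n_loci))
    for k in range(n_pops):
        p_pop[k] = _balding_nichols(rng, p_reg[regions[k]], cfg.target_fst, (n_loci,))

    # plant adaptive loci: logistic shift along a standardized covariate
    adaptive_idx = np.sort(
        rng.choice(n_loci, size=cfg.n_adaptive, replace=False)
    ) if cfg.n_adaptive else np.array([], dtype=int)
    covars = {"temperature": "tmax_now", "rainfall": "rain_now"}
    cov_names = list(covars)
    truth_rows = []
    z_env = {}
    for name, col in covars.items():
        v = pops[col].to_numpy(float)
        sd = v.std(ddof=0)
        z_env[name] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    for j, locus in enumerate(adaptive_idx):
        cov = cov_names[j % len(cov_names)]
        slope = cfg.env_effect * (1.0 if rng.random() < 0.5 else -1.0)
        shifted = expit(logit(np.clip(p_pop[:, locus], 1e-6, 1 - 1e-6))
                        + slope * z_env[cov])
        p_pop[:, locus] = shifted
        truth_rows.append({
            "locus": locus, "is_adaptive": True, "adaptive_covariate": cov,
            # dosage counts A2 copies; positive slope raises A2 with the covariate
            "adaptive_allele": "A2" if slope > 0 else "A1",
            "slope": slope,
        })

    # genotypes
    n_ind = n_pops * cfg.n_ind_per_pop
    geno = np.empty((n_ind, n_loci), dtype=np.int8)
    sample_ids, pop_ids = [], []
    for k in range(n_pops):
        sl = slice(k * cfg.n_ind_per_pop, (k + 1) * cfg.n_ind_per_pop)
        geno[sl] = rng.binomial(2, p_pop[k], size=(cfg.n_ind_per_pop, n_loci))
        pop = pops["pop"].iloc[k]
        for i in range(cfg.n_ind_per_pop):
            sample_ids.append(f"{pop}_I{i + 1}")
            pop_ids.append(pop)

    # inject one close-relative pair in the first population
    if cfg.inject_relatives and cfg.n_ind_per_pop >= 2:
        src, dst = 0, cfg.n_ind_per_pop - 1
        geno[dst] = geno[src]
        resample = rng.random(n_loci) < 0.05
        geno[dst, resample] = rng.binomial(2, p_pop[0, resample])

    # missingness
    if cfg.missing_rate > 0:
        miss = rng.random(geno.shape) < cfg.missing_rate
        geno[miss] = MISSING

    # allele symbols, A1 < A2 alphabetically so PED round-trips are exact
    pairs = np.stack([rng.choice(4, size=n_loci),], axis=1)
    second = (pairs[:, 0] + 1 + rng.integers(0, 3, size=n_loci)) % 4
    alleles = np.sort(np.stack([_BASES[pairs[:, 0]], _BASES[second]], axis=1), axis=1)

    locus_ids = [f"L{j + 1:05d}" for j in range(n_loci)]
    gm = GenotypeMatrix(geno, sample_ids, pop_ids, locus_ids, alleles)

    truth = pd.DataFrame({
        "locus": locus_ids,
        "is_adaptive": False,
        "adaptive_covariate": "",
        "adaptive_allele": "",
        "slope": 0.0,
    })
    for row in truth_rows:
        truth.loc[row["locus"], ["is_adaptive", "adaptive_covariate",
                                 "adaptive_allele", "slope"]] = (
            True, row["adaptive_covariate"], row["adaptive_allele"], row["slope"])
    return gm, truth


@dataclass
class SimResult:
    landscape: Landscape
    pops: pd.DataFrame
    genotypes: GenotypeMatrix
    truth: pd.DataFrame


def generate(cfg: SimConfig) -> SimResult:
    """Run all three stages under one config."""
    landscape = generate_landscape(cfg)
    pops = generate_populations(cfg, landscape)
    gm, truth = generate_genotypes(cfg, pops)
    return SimResult(landscape, pops, gm, truth)


def write_simulation(result: SimResult, outdir) -> None:
    """Serialize a simulation: rasters, population CSV, PED/MAP, truth CSV."""
    from .genotype_qc import write_ped_map

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.landscape.write_dir(outdir / "rasters")
    result.pops.to_csv(outdir / "populations.csv", index=False)
    result.truth.to_csv(outdir / "truth.csv", index=False)
    write_ped_map(result.genotypes, outdir / "genotypes.ped", outdir / "genotypes.map")
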