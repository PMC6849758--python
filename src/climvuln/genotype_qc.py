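"""Genotype input/output and the quality-control filter chain.

The QC chain mirrors conventional plink-style practice for RAD-seq SNP
panels from small population samples:

1. drop individuals with > 50% missing genotypes;
2. drop loci with > 30% missing genotypes;
3. drop loci with minor allele frequency < 0.03 (computed across all
   retained individuals);
4. drop one member of each close-relative pair (method-of-moments
   PI_HAT > 0.5; the member with more missing data is removed, ties by
   sample-id sort order);
5. drop loci out of Hardy-Weinberg equilibrium (exact test, p < 0.01) in
   three or more populations.

The stage order matters and is part of the contract (it is configurable
via `QcThresholds` but the default order above is canonical).  After
filtering, populations with at least 7 individuals are nominated for
population-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import log

from scipy.special import gammaln

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix


# ----------------------------------------------------------------------
# PED/MAP (plink text) I/O
# ----------------------------------------------------------------------

def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read a 6-column PED + MAP pair into a `GenotypeMatrix`.

    Missing genotypes are "0 0"; heterozygotes count as dosage 1 regardless
    of allele order.  Per locus, A1/A2 are the alphabetically first/second
    allele symbols observed, and dosage counts copies of A2.
    """
    locus_ids = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValueError(f"{map_path}:{lineno}: malformed MAP line")
            locus_ids.append(parts[1])
    n_loci = len(locus_ids)

    sample_ids, pop_ids, rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_loci:
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} fields "
                    f"({n_loci} loci), found {len(parts)}"
                )
            pop_ids.append(parts[0])
            sample_ids.append(parts[1])
            alleles = parts[6:]
            for sym in alleles:
                if sym not in ("0", "A", "C", "G", "T"):
                    raise ValueError(
                        f"{ped_path}:{lineno}: unknown allele symbol {sym!r}"
                    )
            rows.append(alleles)

    n_ind = len(rows)
    geno = np.full((n_ind, n_loci), MISSING, dtype=np.int8)
    allele_pairs = np.full((n_loci, 2), "N", dtype="<U1")
    calls = np.array(rows, dtype="<U1").reshape(n_ind, n_loci, 2) if n_ind else \
        np.empty((0, n_loci, 2), dtype="<U1")
    for j in range(n_loci):
        col = calls[:, j, :]
        observed = sorted(set(col.ravel()) - {"0"})
        if len(observed) > 2:
            raise ValueError(
                f"{ped_path}: locus {locus_ids[j]} has >2 alleles: {observed}"
            )
        a1 = observed[0] if observed else "N"
        a2 = observed[1] if len(observed) > 1 else "N"
        allele_pairs[j] = (a1, a2)
        called = ~np.any(col == "0", axis=1)
        if a2 != "N":
            geno[called, j] = (col[called] == a2).sum(axis=1)
        else:
            geno[called, j] = 0
    return GenotypeMatrix(geno, sample_ids, pop_ids, locus_ids, allele_pairs)


def write_ped_map(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write plink text PED (6 leading columns) and MAP files."""
    with open(map_path, "w") as fh:
        for j, locus in enumerate(gm.locus_ids):
            fh.write(f"1 {locus} 0 {j + 1}\n")
    a1 = gm.alleles[:, 0]
    a2 = gm.alleles[:, 1]
    with open(ped_path, "w") as fh:
        for i in range(gm.n_individuals):
            fields = [gm.pop_ids[i], gm.sample_ids[i], "0", "0", "0", "-9"]
            g = gm.genotypes[i]
            for j in range(gm.n_loci):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                elif g[j] == 0:
                    fields += [a1[j], a1[j]]
                elif g[j] == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


# ----------------------------------------------------------------------
# Relatedness: plink-style method-of-moments PI_HAT
# ----------------------------------------------------------------------

def _ibs_expectations(p: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-locus P(IBS=s | IBD=z) for unrelated-pair allele freq p."""
    q = 1.0 - p
    e0_z0 = 2 * p**2 * q**2
    e1_z0 = 4 * p**3 * q + 4 * p * q**3
    e1_z1 = 2 * p**2 * q + 2 * p * q**2
    return e0_z0, e1_z0, e1_z1


def pi_hat(gm: GenotypeMatrix, i: int, j: int,
           freqs: np.ndarray | None = None) -> float:
    """Method-of-moments IBD sharing estimate P(IBD=1)/2 + P(IBD=2).

    Identity-by-state counts across co-genotyped loci are compared with
    their expectations under IBD states 0/1/2 given whole-dataset allele
    frequencies (finite-sample corrections are omitted; with thousands of
    loci they are negligible).  Result clipped to [0, 1].
    """
    gi, gj = gm.genotypes[i], gm.genotypes[j]
    both = (gi != MISSING) & (gj != MISSING)
    if freqs is None:
        freqs = gm.allele_frequencies()
    p = freqs[both]
    informative = (p > 0) & (p < 1)
    gi, gj, p = gi[both][informative], gj[both][informative], p[informative]
    if gi.size == 0:
        raise ValueError(f"no overlapping polymorphic loci for pair ({i}, {j})")

    # IBS2 = identical genotypes, IBS0 = opposite homozygotes, IBS1 = rest
    diff = np.abs(gi.astype(int) - gj.astype(int))
    n0 = float(np.sum(diff == 2))
    n1 = float(np.sum(diff == 1))
    n2 = float(np.sum(diff == 0))

    e0_z0, e1_z0, e1_z1 = _ibs_expectations(p)
    E0 = float(e0_z0.sum())
    E1_0, E1_1 = float(e1_z0.sum()), float(e1_z1.sum())
    L = float(gi.size)

    z0 = n0 / E0 if E0 > 0 else 0.0
    z1 = (n1 - z0 * E1_0) / E1_1 if E1_1 > 0 else 0.0
    e2_z0 = L - E0 - E1_0
    e2_z1 = L - E1_1
    z2 = (n2 - z0 * e2_z0 - z1 * e2_z1) / L
    z = np.clip([z0, z1, z2], 0.0, 1.0)
    if z.sum() > 0:
        z = z / z.sum()
    return float(np.clip(z[1] / 2.0 + z[2], 0.0, 1.0))


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------

@lru_cache(maxsize=100_000)
def hwe_exact(hom1: int, het: int, hom2: int) -> float:
    """Two-sided exact Hardy-Weinberg test (enumeration over heterozygote
    counts conditional on the allele counts).

    Returns the sum of probabilities of all heterozygote counts at most as
    probable as the observed one.  Monomorphic samples return 1 by
    convention.
    """
    if min(hom1, het, hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom1 + het + hom2
    n_a = 2 * hom1 + het
    n_b = 2 * hom2 + het
    if n == 0 or n_a == 0 or n_b == 0:
        return 1.0

    n_minor = min(n_a, n_b)
    parity = n_minor % 2
    hets = np.arange(parity, n_minor + 1, 2)

    haa = (n_a - hets) // 2
    hbb = (n_b - hets) // 2
    lp = (hets * log(2.0) + gammaln(n + 1) - gammaln(haa + 1)
          - gammaln(hets + 1) - gammaln(hbb + 1) + gammaln(n_a + 1)
          + gammaln(n_b + 1) - gammaln(2 * n + 1))
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    obs = probs[hets == het]
    if obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with alleles")
    return float(min(1.0, probs[probs <= obs[0] * (1 + 1e-12)].sum()))


def hwe_pvalues_per_pop(gm: GenotypeMatrix) -> pd.DataFrame:
    """Exact HWE p-values, populations x loci."""
    out = {}
    for pop, idx in gm.pop_indices().items():
        g = gm.genotypes[idx]
        pvals = np.ones(gm.n_loci)
        for j in range(gm.n_loci):
            col = g[:, j]
            col = col[col != MISSING]
            pvals[j] = hwe_exact(int((col == 0).sum()), int((col == 1).sum()),
                                 int((col == 2).sum()))
        out[pop] = pvals
    return pd.DataFrame.from_dict(out, orient="index", columns=gm.locus_ids)


# ----------------------------------------------------------------------
# The filter chain
# ----------------------------------------------------------------------

@dataclass
class QcThresholds:
    ind_missing: float = 0.50
    locus_missing: float = 0.30
    maf: float = 0.03
    pi_hat: float = 0.50
    hwe_p: float = 0.01
    hwe_min_pops: int = 3          # removed if p < hwe_p in >= this many pops
    min_pop_size: int = 7          # populations retained for pop-level stats


@dataclass
class QcReport:
    """Per-stage removal counts; reconciles input and output dimensions."""

    n_ind_in: int
    n_loci_in: int
    removed_ind_missing: list[str] = field(default_factory=list)
    removed_loci_missing: list[str] = field(default_factory=list)
    removed_loci_maf: list[str] = field(default_factory=list)
    removed_ind_related: list[str] = field(default_factory=list)
    removed_loci_hwe: list[str] = field(default_factory=list)
    pops_for_stats: list[str] = field(default_factory=list)
    genotyping_rate: float = float("nan")

    @property
    def n_ind_out(self) -> int:
        return (self.n_ind_in - len(self.removed_ind_missing)
                - len(self.removed_ind_related))

    @property
    def n_loci_out(self) -> int:
        return (self.n_loci_in - len(self.removed_loci_missing)
                - len(self.removed_loci_maf) - len(self.removed_loci_hwe))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("individuals in", self.n_ind_in),
            ("loci in", self.n_loci_in),
            ("individuals removed: missingness", len(self.removed_ind_missing)),
            ("loci removed: missingness", len(self.removed_loci_missing)),
            ("loci removed: MAF", len(self.removed_loci_maf)),
            ("individuals removed: relatedness", len(self.removed_ind_related)),
            ("loci removed: HWE", len(self.removed_loci_hwe)),
            ("individuals out", self.n_ind_out),
            ("loci out", self.n_loci_out),
            ("final genotyping rate", round(self.genotyping_rate, 4)),
        ]
        return pd.DataFrame(rows, columns=["stage", "value"])


def apply_qc(gm: GenotypeMatrix,
             thresholds: QcThresholds | None = None
             ) -> tuple[GenotypeMatrix, QcReport]:
    """Run the canonical filter chain; see module docstring for the order."""
    th = thresholds or QcThresholds()
    if len(set(gm.pop_ids)) < 2:
        raise ValueError("QC requires at least two populations")
    report = QcReport(gm.n_individuals, gm.n_loci)

    # 1. individual missingness
    ind_miss = gm.missing_mask.mean(axis=1)
    keep = np.flatnonzero(ind_miss <= th.ind_missing)
    report.removed_ind_missing = [
        gm.sample_ids[i] for i in np.flatnonzero(ind_miss > th.ind_missing)
    ]
    gm = gm.take_individuals(keep)
    _check_nonempty(gm, "individual missingness")

    # 2. locus missingness
    loc_miss = gm.missing_mask.mean(axis=0)
    drop = loc_miss > th.locus_missing
    report.removed_loci_missing = [l for l, d in zip(gm.locus_ids, drop) if d]
    gm = gm.take_loci(np.flatnonzero(~drop))
    _check_nonempty(gm, "locus missingness")

    # 3. MAF across all retained individuals
    freq = gm.allele_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    drop = ~(maf >= th.maf)  # NaN (all-missing) loci also dropped
    report.removed_loci_maf = [l for l, d in zip(gm.locus_ids, drop) if d]
    gm = gm.take_loci(np.flatnonzero(~drop))
    _check_nonempty(gm, "minor allele frequency")

    # 4. close relatives
    freqs = gm.allele_frequencies()
    miss_by_ind = gm.missing_mask.mean(axis=1)
    to_drop: set[int] = set()
    order = sorted(range(gm.n_individuals), key=lambda i: gm.sample_ids[i])
    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            i, j = order[ai], order[bi]
            if i in to_drop or j in to_drop:
                continue
            if pi_hat(gm, i, j, freqs) > th.pi_hat:
                # drop the member with more missing data; ties -> id order
                if miss_by_ind[i] > miss_by_ind[j]:
                    to_drop.add(i)
                elif miss_by_ind[j] > miss_by_ind[i]:
                    to_drop.add(j)
                else:
                    to_drop.add(max((gm.sample_ids[i], i), (gm.sample_ids[j], j))[1])
    report.removed_ind_related = sorted(gm.sample_ids[i] for i in to_drop)
    gm = gm.take_individuals([i for i in range(gm.n_individuals) if i not in to_drop])
    _check_nonempty(gm, "relatedness")

    # 5. HWE per population
    pvals = hwe_pvalues_per_pop(gm)
    n_violations = (pvals < th.hwe_p).sum(axis=0).to_numpy()
    drop = n_violations >= th.hwe_min_pops
    report.removed_loci_hwe = [l for l, d in zip(gm.locus_ids, drop) if d]
    gm = gm.take_loci(np.flatnonzero(~drop))
    _check_nonempty(gm, "Hardy-Weinberg")

    sizes = pd.Series(gm.pop_ids).value_counts()
    report.pops_for_stats = sorted(sizes[sizes >= th.min_pop_size].index)
    report.genotyping_rate = gm.genotyping_rate()
    return gm, report


def _check_nonempty(gm: GenotypeMatrix, stage: str) -> None:
    if gm.n_individuals == 0 or gm.n_loci == 0:
        raise ValueError(f"all individuals or loci filtered out at stage: {stage}")
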