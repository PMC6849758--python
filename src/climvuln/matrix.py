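"""Core in-memory containers shared across the pipeline.

`GenotypeMatrix` holds diploid biallelic genotypes as dosages of the A2
allele (0/1/2, with -1 for missing), together with sample, population and
locus metadata.  `DistanceMatrix` is a labelled symmetric pairwise matrix
used for genetic, geographic and resistance distances alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotype calls.

    Attributes
    ----------
    genotypes : (n_ind, n_loci) int8 array of A2-allele dosages; -1 = missing.
    sample_ids : per-individual identifiers (unique).
    pop_ids : per-individual population labels.
    locus_ids : per-locus identifiers (unique).
    alleles : (n_loci, 2) array of allele symbols (A1, A2).
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    pop_ids: list[str]
    locus_ids: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_ind, n_loci = self.genotypes.shape
        if len(self.sample_ids) != n_ind or len(self.pop_ids) != n_ind:
            raise ValueError("sample/population id length mismatch with genotype rows")
        if len(self.locus_ids) != n_loci:
            raise ValueError("locus id length mismatch with genotype columns")
        self.alleles = np.asarray(self.alleles)
        if self.alleles.shape != (n_loci, 2):
            raise ValueError("alleles must be (n_loci, 2)")
        bad = ~np.isin(self.genotypes, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    # -- basic shape ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def genotyping_rate(self) -> float:
        """Overall fraction of non-missing calls."""
        return float(1.0 - self.missing_mask.mean())

    # -- frequencies ------------------------------------------------------
    def allele_frequencies(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Per-locus A2 allele frequency over the given individuals.

        Loci with no data return NaN.
        """
        g = self.genotypes if indices is None else self.genotypes[indices]
        called = g != MISSING
        n_alleles = 2.0 * called.sum(axis=0)
        counts = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, counts / n_alleles, np.nan)

    def pop_allele_frequencies(self) -> pd.DataFrame:
        """Population x locus A2 frequencies."""
        rows = {}
        pops = np.asarray(self.pop_ids)
        for pop in pd.unique(pops):
            rows[pop] = self.allele_frequencies(np.flatnonzero(pops == pop))
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.locus_ids)

    # -- subsetting -------------------------------------------------------
    def take_individuals(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        return GenotypeMatrix(
            self.genotypes[idx],
            [self.sample_ids[i] for i in idx],
            [self.pop_ids[i] for i in idx],
            list(self.locus_ids),
            self.alleles.copy(),
        )

    def take_loci(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        return GenotypeMatrix(
            self.genotypes[:, idx],
            list(self.sample_ids),
            list(self.pop_ids),
            [self.locus_ids[i] for i in idx],
            self.alleles[idx],
        )

    def subset_pops(self, pops: Sequence[str]) -> "GenotypeMatrix":
        keep = set(pops)
        idx = [i for i, p in enumerate(self.pop_ids) if p in keep]
        return self.take_individuals(idx)

    def pop_indices(self) -> dict[str, np.ndarray]:
        pops = np.asarray(self.pop_ids)
        return {p: np.flatnonzero(pops == p) for p in pd.unique(pops)}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise matrix keyed by population (or sample) labels."""

    labels: list[str]
    values: np.ndarray
    name: str = "distance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(
            self.values, self.values.T, equal_nan=True, rtol=0, atol=1e-8
        ):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def lower_triangle(self) -> np.ndarray:
        """Strict lower triangle, vectorized in row-major pair order."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def align(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "distance") -> "DistanceMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float), name)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path, name: str = "distance") -> "DistanceMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0), name)
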