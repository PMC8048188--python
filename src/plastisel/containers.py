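"""Core in-memory containers shared across the pipeline.

Genotypes are stored as unordered allele-index pairs so that biallelic SNPs
and multi-allelic microsatellites flow through the same F-statistic code;
biallelic panels additionally expose an alternate-allele dosage view.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x loci genotype calls.

    Parameters
    ----------
    individuals : sample identifiers, length n.
    loci : locus identifiers, length L.
    calls : int array (n, L, 2) of allele indices; both slots ``MISSING``
        for a missing call. Allele order within a call is not meaningful.
    clusters : per-locus transcript-cluster (gene) id, used as the
        "chromosome" unit for LD pruning.
    alleles : per-locus tuple of allele labels (REF first for SNPs).
    qual : per-locus site quality score, optional.
    gq : per-call genotype quality (n, L), optional.
    populations : per-individual population label, optional.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    clusters: np.ndarray | None = None
    alleles: list[tuple[str, ...]] | None = None
    qual: np.ndarray | None = None
    gq: np.ndarray | None = None
    populations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError("calls must have shape (n_individuals, n_loci, 2)")
        n, L, _ = self.calls.shape
        if len(self.individuals) != n or len(self.loci) != L:
            raise ValueError("individual/locus labels do not match call array shape")
        half_missing = (self.calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("half-missing genotype calls are not allowed")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def n_alleles(self) -> np.ndarray:
        """Number of distinct observed (or declared) alleles per locus."""
        if self.alleles is not None:
            return np.array([len(a) for a in self.alleles])
        out = np.empty(self.n_loci, dtype=int)
        for j in range(self.n_loci):
            vals = self.calls[:, j, :]
            vals = vals[vals != MISSING]
            out[j] = len(np.unique(vals)) if vals.size else 0
        return out

    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage view (n, L) in {0,1,2}, MISSING for missing.

        Only meaningful for biallelic loci, where allele index 1 is ALT.
        """
        dos = (self.calls == 1).sum(axis=2).astype(np.int16)
        dos[self.missing_mask] = MISSING
        return dos

    def subset(
        self,
        individual_idx: Sequence[int] | np.ndarray | None = None,
        locus_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        ii = np.arange(self.n_individuals) if individual_idx is None else np.asarray(individual_idx)
        jj = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in ii],
            loci=[self.loci[j] for j in jj],
            calls=self.calls[np.ix_(ii, jj)],
            clusters=None if self.clusters is None else np.asarray(self.clusters)[jj],
            alleles=None if self.alleles is None else [self.alleles[j] for j in jj],
            qual=None if self.qual is None else np.asarray(self.qual)[jj],
            gq=None if self.gq is None else self.gq[np.ix_(ii, jj)],
            populations=None if self.populations is None else np.asarray(self.populations)[ii],
        )

    def with_populations(self, populations: Sequence[str]) -> "GenotypeMatrix":
        if len(populations) != self.n_individuals:
            raise ValueError("population labels must match number of individuals")
        return replace(self, populations=np.asarray(populations, dtype=object))


@dataclass
class CountMatrix:
    """Gene-level integer counts with a population x timepoint sample design."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    design: pd.DataFrame  # index = sample, columns: population, timepoint
    norm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.design.index):
            if set(self.counts.columns) != set(self.design.index):
                raise ValueError("count columns and design rows name different samples")
            self.design = self.design.loc[self.counts.columns]
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_labels(self) -> pd.Series:
        """population:timepoint cell label per sample."""
        d = self.design
        return d["population"].astype(str) + ":" + d["timepoint"].astype(str)


@dataclass
class ExonCountMatrix:
    """Exon-level counts; rows are (gene, exon index) pairs."""

    counts: pd.DataFrame  # MultiIndex (gene, exon) x samples
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.counts.index, pd.MultiIndex):
            raise ValueError("exon counts need a (gene, exon) MultiIndex")
        if not self.counts.columns.equals(self.design.index):
            self.design = self.design.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index.get_level_values(0).unique()


@dataclass
class FilterSpec:
    """Site- and individual-level genotype filter thresholds.

    Quality thresholds are strict (> keeps), allele-frequency and missingness
    thresholds inclusive the way QC pipelines state them: MAF >= min_maf kept,
    missing fraction <= max_site_missing kept.
    """

    min_site_quality: float | None = 30.0
    min_genotype_quality: float | None = 30.0
    biallelic_only: bool = True
    min_maf: float = 0.05
    max_site_missing: float = 0.20
    hwe_p_threshold: float | None = None
    ld_r2_threshold: float | None = None
    max_individual_missing_loci: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0.0 <= self.max_site_missing <= 1.0:
            raise ValueError("max_site_missing must be in [0, 1]")
        if self.hwe_p_threshold is not None and not 0.0 <= self.hwe_p_threshold <= 1.0:
            raise ValueError("hwe_p_threshold must be a probability")
        if self.ld_r2_threshold is not None and not 0.0 < self.ld_r2_threshold <= 1.0:
            raise ValueError("ld_r2_threshold must be in (0, 1]")
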