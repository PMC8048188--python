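"""Site- and individual-level genotype QC: quality masking, biallelic/MAF/
missingness filters, the Hardy-Weinberg exact test, and within-cluster LD
pruning.

Two panels mirror standard mRNA-SNP practice: the "overall" panel keeps
quality/MAF/missingness-clean biallelic SNPs; the "neutral" panel
additionally requires complete data, loci not rejected by the HWE exact
test, and LD pruning within transcript clusters (clusters act as
chromosomes, so loci in different clusters are never compared).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import MISSING, FilterSpec, GenotypeMatrix

log = logging.getLogger(__name__)


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and enumerates every possible
    heterozygote count of the same parity as the minor-allele count; a
    configuration with nAb heterozygotes has weight
    2^nAb * n!/(nAA! nAb! nab!), normalised over configurations. The
    p-value sums the probabilities of all configurations no more probable
    than the observed one. Monomorphic samples return 1.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_a = 2 * n_hom_minor + n_het  # one allele's copy count
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    rare_hom = (n_minor - hets) // 2
    common_hom = n - hets - rare_hom
    logw = hets * np.log(2.0) + gammaln(n + 1) - gammaln(hets + 1) - gammaln(rare_hom + 1) - gammaln(common_hom + 1)
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _mask_low_gq(gm: GenotypeMatrix, min_gq: float | None) -> GenotypeMatrix:
    """Convert calls with genotype quality not exceeding the threshold to missing."""
    if min_gq is None or gm.gq is None:
        return gm
    calls = gm.calls.copy()
    with np.errstate(invalid="ignore"):
        low = np.isfinite(gm.gq) & ~(gm.gq > min_gq)
    calls[low] = MISSING
    out = GenotypeMatrix(
        gm.individuals, gm.loci, calls, gm.clusters, gm.alleles, gm.qual, gm.gq, gm.populations
    )
    return out


def _genotype_counts(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (hom-ref, het, hom-alt) counts from a dosage matrix."""
    present = dos != MISSING
    return (
        ((dos == 0) & present).sum(axis=0),
        (dos == 1).sum(axis=0),
        (dos == 2).sum(axis=0),
    )


def apply_site_filters(gm: GenotypeMatrix, spec: FilterSpec) -> GenotypeMatrix:
    """Quality -> biallelic -> MAF -> missingness -> HWE -> LD cascade.

    Low-GQ calls are masked to missing before allele frequencies and
    missingness are computed. Site quality uses a strictly-greater rule
    (QUAL > threshold kept); MAF is inclusive (>= kept); site missingness
    inclusive (<= kept); HWE keeps loci with exact-test p >= threshold.
    Idempotent and order-preserving.
    """
    if gm.n_loci == 0:
        raise ValueError("empty genotype matrix")
    gm = _mask_low_gq(gm, spec.min_genotype_quality)
    keep = np.ones(gm.n_loci, dtype=bool)

    if spec.min_site_quality is not None and gm.qual is not None:
        with np.errstate(invalid="ignore"):
            keep &= np.where(np.isfinite(gm.qual), gm.qual > spec.min_site_quality, True)

    if spec.biallelic_only:
        keep &= gm.n_alleles() == 2
        max_idx = np.where(gm.calls == MISSING, 0, gm.calls).max(axis=(0, 2))
        keep &= max_idx <= 1

    dos = gm.dosage().astype(float)
    dos[dos == MISSING] = np.nan
    n_called = np.isfinite(dos).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.nansum(dos, axis=0) / (2.0 * n_called)
        maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep &= np.where(n_called > 0, maf >= spec.min_maf, False)

    miss_frac = 1.0 - n_called / gm.n_individuals
    keep &= miss_frac <= spec.max_site_missing

    if spec.hwe_p_threshold is not None:
        dd = gm.dosage()
        n0, n1, n2 = _genotype_counts(dd)
        for j in np.flatnonzero(keep):
            if hwe_exact_test(int(n0[j]), int(n1[j]), int(n2[j])) < spec.hwe_p_threshold:
                keep[j] = False

    out = gm.subset(locus_idx=np.flatnonzero(keep))
    if out.n_loci == 0:
        log.warning("all loci removed by site filters")
    if spec.ld_r2_threshold is not None and out.n_loci:
        out = prune_ld(out, spec.ld_r2_threshold)
    return out


def _pairwise_complete_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        return 0.0  # zero-variance loci never trigger removal
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def prune_ld(gm: GenotypeMatrix, r2_threshold: float) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning within each transcript cluster.

    A locus is dropped when its squared pairwise-complete Pearson
    correlation of dosages with any already-retained locus of the same
    cluster strictly exceeds the threshold; first-kept wins ties, loci in
    different clusters are never compared.
    """
    if gm.clusters is None:
        raise ValueError("LD pruning needs per-locus cluster ids")
    dos = gm.dosage().astype(float)
    dos[dos == MISSING] = np.nan
    clusters = np.asarray(gm.clusters)
    keep = np.ones(gm.n_loci, dtype=bool)
    for cluster in pd.unique(pd.Series(clusters)):
        members = np.flatnonzero(clusters == cluster)
        retained: list[int] = []
        for j in members:
            if any(_pairwise_complete_r2(dos[:, j], dos[:, k]) > r2_threshold for k in retained):
                keep[j] = False
            else:
                retained.append(j)
    return gm.subset(locus_idx=np.flatnonzero(keep))


def filter_individuals(
    gm: GenotypeMatrix,
    max_missing_loci: int | None = None,
    exclusion_list: list[str] | None = None,
) -> GenotypeMatrix:
    """Drop individuals missing at least max_missing_loci loci or listed for
    exclusion (e.g. a pre-computed full-sibling list)."""
    keep = np.ones(gm.n_individuals, dtype=bool)
    if max_missing_loci is not None:
        n_missing = gm.missing_mask.sum(axis=1)
        keep &= n_missing < max_missing_loci
    if exclusion_list:
        excl = set(exclusion_list)
        keep &= np.array([ind not in excl for ind in gm.individuals])
    if not keep.any():
        raise ValueError("all individuals removed by individual filters")
    removed = (~keep).sum()
    if removed:
        log.info("removed %d individuals (missingness/exclusion)", removed)
    return gm.subset(individual_idx=np.flatnonzero(keep))


def overall_panel_spec() -> FilterSpec:
    """Quality/MAF/missingness-only panel (no HWE or LD filtering)."""
    return FilterSpec(
        min_site_quality=30.0,
        min_genotype_quality=30.0,
        biallelic_only=True,
        min_maf=0.05,
        max_site_missing=0.20,
    )


def neutral_panel_spec() -> FilterSpec:
    """Putatively neutral panel: complete data, HWE-consistent, LD-pruned."""
    return FilterSpec(
        min_site_quality=30.0,
        min_genotype_quality=30.0,
        biallelic_only=True,
        min_maf=0.05,
        max_site_missing=0.0,
        hwe_p_threshold=0.005,
        ld_r2_threshold=0.20,
    )


def make_panel(gm: GenotypeMatrix, panel: str) -> GenotypeMatrix:
    if panel == "overall":
        return apply_site_filters(gm, overall_panel_spec())
    if panel == "neutral":
        return apply_site_filters(gm, neutral_panel_spec())
    raise ValueError(f"unknown panel {panel!r}; expected 'overall' or 'neutral'")
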