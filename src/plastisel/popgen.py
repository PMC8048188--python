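"""Population-genetic estimators: Ho/Hs/FIS, Weir-Cockerham pairwise FST,
population-specific (allele-matching) FST, locus bootstrap CIs, PCA and
k-means population reassignment.

Conventions follow the classical estimators: Hs uses Nei's sample-size
corrected gene diversity; multi-locus FST is the ratio of summed
Weir-Cockerham (1984) variance components over alleles and loci, not the
mean of per-locus ratios; the population-specific FST is the Weir-Goudet
allele-matching beta, (M_i - M_B)/(1 - M_B), with matching proportions
averaged over loci before taking the ratio.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# allele bookkeeping


def _pop_partition(gm: GenotypeMatrix, pops=None) -> tuple[list[str], list[np.ndarray]]:
    """Population names and per-population individual index arrays."""
    labels = np.asarray(pops if pops is not None else gm.populations)
    if labels is None or len(labels) != gm.n_individuals:
        raise ValueError("population labels required, one per individual")
    names = list(pd.unique(pd.Series(labels)))
    return names, [np.flatnonzero(labels == name) for name in names]


def _allele_summaries(gm: GenotypeMatrix, idx_by_pop: list[np.ndarray]):
    """Per (pop, locus): sample size, allele counts and heterozygote-carrier counts.

    Returns n (P, L) diploid sample sizes, counts (P, L, A) allele-copy
    counts, hets (P, L, A) counts of heterozygous individuals carrying each
    allele.
    """
    calls = gm.calls
    A = int(max(calls.max() + 1, 2))
    P, L = len(idx_by_pop), gm.n_loci
    n = np.zeros((P, L))
    counts = np.zeros((P, L, A))
    hets = np.zeros((P, L, A))
    for p, idx in enumerate(idx_by_pop):
        sub = calls[idx]  # (n_p, L, 2)
        non_missing = sub[:, :, 0] != MISSING
        n[p] = non_missing.sum(axis=0)
        het = (sub[:, :, 0] != sub[:, :, 1]) & non_missing
        for a in range(A):
            carry = (sub[:, :, 0] == a).astype(np.int64) + (sub[:, :, 1] == a)
            counts[p, :, a] = carry.sum(axis=0)
            hets[p, :, a] = ((carry > 0) & het).sum(axis=0)
    return n, counts, hets


# ---------------------------------------------------------------------------
# basic statistics (Ho, Hs, FIS)


@dataclass
class BasicStats:
    """Per-population multi-locus Ho, Hs and FIS with per-locus components."""

    populations: list[str]
    ho: np.ndarray  # (P,) multi-locus means
    hs: np.ndarray
    fis: np.ndarray
    ho_by_locus: np.ndarray  # (P, L), NaN where undefined
    hs_by_locus: np.ndarray


def basic_stats(gm: GenotypeMatrix, pops=None) -> BasicStats:
    """Observed heterozygosity, Nei gene diversity and FIS per population.

    Per locus: Ho is the heterozygote fraction among genotyped individuals;
    Hs = n/(n-1) * (1 - sum p^2 - Ho/(2n)). FIS = 1 - sum(Ho)/sum(Hs) over
    loci with Hs > 0 (ratio of sums, so monomorphic loci contribute nothing).
    """
    names, idx_by_pop = _pop_partition(gm, pops)
    for name, idx in zip(names, idx_by_pop):
        if len(idx) < 2:
            raise ValueError(f"population {name!r} has fewer than 2 individuals; Hs undefined")
    n, counts, hets = _allele_summaries(gm, idx_by_pop)
    with np.errstate(divide="ignore", invalid="ignore"):
        het_ind = hets.sum(axis=2) / 2.0  # each het individual counted for 2 alleles
        ho = np.where(n > 0, het_ind / n, np.nan)
        freqs = counts / np.where(n[:, :, None] > 0, 2.0 * n[:, :, None], np.nan)
        sum_p2 = (freqs**2).sum(axis=2)
        hs = np.where(n > 1, n / (n - 1.0) * (1.0 - sum_p2 - ho / (2.0 * n)), np.nan)
    defined = np.isfinite(hs)
    ho_mean = np.array([np.nanmean(np.where(defined[p], ho[p], np.nan)) for p in range(len(names))])
    hs_mean = np.array([np.nanmean(np.where(defined[p], hs[p], np.nan)) for p in range(len(names))])
    fis = np.empty(len(names))
    for p in range(len(names)):
        poly = defined[p] & (hs[p] > 0)
        fis[p] = 1.0 - ho[p][poly].sum() / hs[p][poly].sum() if poly.any() else np.nan
    return BasicStats(names, ho_mean, hs_mean, fis, ho, hs)


# ---------------------------------------------------------------------------
# Weir-Cockerham pairwise FST


@dataclass
class WcFstResult:
    theta: float
    a_by_locus: np.ndarray  # (L,) summed over alleles
    abc_by_locus: np.ndarray
    populations: tuple[str, str]

    def theta_by_locus(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.a_by_locus / self.abc_by_locus


def _wc_components(n: np.ndarray, counts: np.ndarray, hets: np.ndarray):
    """Weir-Cockerham (1984) variance components per locus, summed over alleles.

    n: (P, L); counts, hets: (P, L, A). Loci where any population has no
    genotyped individual get NaN components.
    """
    P, L, A = counts.shape
    r = float(P)
    valid = (n > 0).all(axis=0) & (n.sum(axis=0) > r)  # need nbar > 1
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = n.sum(axis=0) / r  # (L,)
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        p_i = counts / (2.0 * n[:, :, None])  # (P, L, A)
        h_i = hets / n[:, :, None]
        pbar = (n[:, :, None] * p_i).sum(axis=0) / (r * nbar[:, None])  # (L, A)
        s2 = (n[:, :, None] * (p_i - pbar[None]) ** 2).sum(axis=0) / ((r - 1.0) * nbar[:, None])
        hbar = (n[:, :, None] * h_i).sum(axis=0) / (r * nbar[:, None])
        pq = pbar * (1.0 - pbar)
        inner = pq - (r - 1.0) / r * s2 - hbar / 4.0
        a = nbar[:, None] / nc[:, None] * (s2 - inner / (nbar[:, None] - 1.0))
        b = nbar[:, None] / (nbar[:, None] - 1.0) * (
            pq - (r - 1.0) / r * s2 - (2.0 * nbar[:, None] - 1.0) / (4.0 * nbar[:, None]) * hbar
        )
        c = hbar / 2.0
    a_sum = np.where(valid, np.nansum(a, axis=1), np.nan)
    abc_sum = np.where(valid, np.nansum(a + b + c, axis=1), np.nan)
    return a_sum, abc_sum


def wc_pairwise_fst(gm: GenotypeMatrix, pops=None) -> WcFstResult:
    """Multi-locus Weir-Cockerham theta-hat between exactly two populations.

    Ratio of sums of the a (among-population) component over a+b+c across
    all alleles and loci; per-locus components are retained for
    bootstrapping and permutation scans.
    """
    names, idx_by_pop = _pop_partition(gm, pops)
    if len(names) != 2:
        raise ValueError(f"pairwise FST needs exactly 2 populations, got {len(names)}")
    for name, idx in zip(names, idx_by_pop):
        if len(idx) < 2:
            raise ValueError(f"population {name!r} has fewer than 2 individuals")
    n, counts, hets = _allele_summaries(gm, idx_by_pop)
    a_sum, abc_sum = _wc_components(n, counts, hets)
    denom = np.nansum(abc_sum)
    if denom == 0 or not np.isfinite(denom):
        raise ValueError("FST undefined: total variance components are zero (monomorphic data?)")
    theta = float(np.nansum(a_sum) / denom)
    return WcFstResult(theta, a_sum, abc_sum, (names[0], names[1]))


# ---------------------------------------------------------------------------
# population-specific FST (allele-matching betas)


@dataclass
class BetaFstResult:
    populations: list[str]
    beta: np.ndarray  # (P,)
    overall: float
    m_within_by_locus: np.ndarray  # (P, L)
    m_between_by_locus: np.ndarray  # (L,)


def population_specific_fst(gm: GenotypeMatrix, pops=None) -> BetaFstResult:
    """Weir-Goudet population-specific FST from allele-matching proportions.

    M_i: probability two distinct allele copies drawn within population i
    match (sample-size corrected); M_B: mean matching probability between
    population pairs. beta_i = (mean_l M_i - mean_l M_B)/(1 - mean_l M_B).
    """
    names, idx_by_pop = _pop_partition(gm, pops)
    if len(names) < 2:
        raise ValueError("population-specific FST needs >= 2 populations")
    n, counts, hets = _allele_summaries(gm, idx_by_pop)
    P, L, A = counts.shape
    m = 2.0 * n  # allele copies
    with np.errstate(divide="ignore", invalid="ignore"):
        m_within = (counts * (counts - 1.0)).sum(axis=2) / (m * (m - 1.0))  # (P, L)
        freqs = counts / m[:, :, None]
    pair_match = np.zeros(L)
    n_pairs = 0
    for i in range(P):
        for j in range(i + 1, P):
            pair_match += np.nansum(freqs[i] * freqs[j], axis=1)
            n_pairs += 1
    m_between = pair_match / n_pairs
    valid = np.isfinite(m_within).all(axis=0) & np.isfinite(m_between)
    mb = float(np.mean(m_between[valid]))
    if mb >= 1.0:
        raise ValueError("between-population matching is 1 everywhere; beta undefined")
    beta = np.array([(np.mean(m_within[p, valid]) - mb) / (1.0 - mb) for p in range(P)])
    return BetaFstResult(names, beta, float(beta.mean()), m_within, m_between)


# ---------------------------------------------------------------------------
# bootstrap over loci


@dataclass
class BootstrapCI:
    lower: float
    upper: float
    level: float
    n_boot: int
    seed: int
    n_skipped: int = 0


def bootstrap_ci(statistic, n_loci: int, n_boot: int = 1000, level: float = 0.95, seed: int = 0) -> BootstrapCI:
    """Percentile bootstrap CI, resampling loci with replacement.

    statistic maps an index array of resampled loci to a scalar; replicates
    where it is undefined (NaN or raising) are skipped and counted, with
    more than 10% skips treated as an error.
    """
    if n_loci < 2:
        raise ValueError("bootstrap needs at least 2 loci")
    rng = np.random.default_rng(seed)
    vals = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n_loci, size=n_loci)
        try:
            v = statistic(idx)
        except (ValueError, ZeroDivisionError, FloatingPointError):
            v = np.nan
        if np.isfinite(v):
            vals.append(v)
        else:
            skipped += 1
    if skipped > 0.10 * n_boot:
        raise ValueError(f"statistic undefined on {skipped}/{n_boot} bootstrap resamples")
    lo, hi = np.quantile(vals, [(1 - level) / 2.0, 1 - (1 - level) / 2.0])
    return BootstrapCI(float(lo), float(hi), level, n_boot, seed, skipped)


def fst_bootstrap_statistic(res: WcFstResult):
    """Re-aggregate stored per-locus WC components on a locus resample."""

    def stat(idx: np.ndarray) -> float:
        denom = np.nansum(res.abc_by_locus[idx])
        if denom == 0:
            return np.nan
        return float(np.nansum(res.a_by_locus[idx]) / denom)

    return stat


# ---------------------------------------------------------------------------
# PCA and cluster reassignment


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, K)
    variance_explained: np.ndarray
    loadings: np.ndarray  # (L, K)


def pca_genotypes(gm: GenotypeMatrix) -> PcaResult:
    """PCA of the dosage matrix: mean-imputed, column-centred, not scaled."""
    if gm.n_individuals < 2 or gm.n_loci < 2:
        raise ValueError("PCA needs at least 2 individuals and 2 loci")
    dos = gm.dosage().astype(float)
    dos[dos == MISSING] = np.nan
    col_mean = np.nanmean(dos, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    inds = np.where(np.isnan(dos))
    dos[inds] = np.take(col_mean, inds[1])
    X = dos - dos.mean(axis=0)
    total_var = (X**2).sum()
    if total_var == 0:
        raise ValueError("genotype matrix has zero variance")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    scores = u * s
    return PcaResult(scores, s**2 / total_var, vt.T)


def assign_clusters(pca: PcaResult, k: int = 2, n_pcs: int = 75, seed: int = 0) -> np.ndarray:
    """K-means on the leading PC scores; 1-based labels, 1 = largest cluster."""
    avail = pca.scores.shape[1]
    if n_pcs > avail:
        n_pcs = avail  # clamp; upstream logs
    if k > pca.scores.shape[0]:
        raise ValueError("more clusters than individuals")
    if k == 1:
        return np.ones(pca.scores.shape[0], dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pca.scores[:, :n_pcs])
    sizes = np.bincount(km.labels_, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return relabel[km.labels_]


# ---------------------------------------------------------------------------
# full report


def popgen_report(gm: GenotypeMatrix, pops=None, n_boot: int = 1000, level: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """Per-population Ho/Hs/FIS/beta and pairwise FST with bootstrap CIs.

    Tab-separated-friendly long table: statistic, population, estimate,
    ci_low, ci_high.
    """
    names, _ = _pop_partition(gm, pops)
    bs = basic_stats(gm, pops)
    betas = population_specific_fst(gm, pops)
    rows = []
    L = gm.n_loci
    for p, name in enumerate(names):
        ho_l, hs_l = bs.ho_by_locus[p], bs.hs_by_locus[p]

        def fis_stat(idx, ho_l=ho_l, hs_l=hs_l):
            ho_s, hs_s = ho_l[idx], hs_l[idx]
            keep = np.isfinite(hs_s) & (hs_s > 0)
            if not keep.any():
                return np.nan
            return 1.0 - ho_s[keep].sum() / hs_s[keep].sum()

        ci_ho = bootstrap_ci(lambda idx, x=ho_l: np.nanmean(x[idx]), L, n_boot, level, seed)
        ci_hs = bootstrap_ci(lambda idx, x=hs_l: np.nanmean(x[idx]), L, n_boot, level, seed)
        ci_fis = bootstrap_ci(fis_stat, L, n_boot, level, seed)
        mwl = betas.m_within_by_locus[p]
        mbl = betas.m_between_by_locus

        def beta_stat(idx, mwl=mwl, mbl=mbl):
            keep = np.isfinite(mwl[idx]) & np.isfinite(mbl[idx])
            mb = np.mean(mbl[idx][keep])
            if mb >= 1.0:
                return np.nan
            return (np.mean(mwl[idx][keep]) - mb) / (1.0 - mb)

        ci_beta = bootstrap_ci(beta_stat, L, n_boot, level, seed)
        rows += [
            ("Ho", name, bs.ho[p], ci_ho.lower, ci_ho.upper),
            ("Hs", name, bs.hs[p], ci_hs.lower, ci_hs.upper),
            ("FIS", name, bs.fis[p], ci_fis.lower, ci_fis.upper),
            ("beta_fst", name, betas.beta[p], ci_beta.lower, ci_beta.upper),
        ]
    if len(names) == 2:
        wc = wc_pairwise_fst(gm, pops)
        ci = bootstrap_ci(fst_bootstrap_statistic(wc), L, n_boot, level, seed)
        rows.append(("pairwise_fst", f"{names[0]}-{names[1]}", wc.theta, ci.lower, ci.upper))
    return pd.DataFrame(rows, columns=["statistic", "population", "estimate", "ci_low", "ci_high"])
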