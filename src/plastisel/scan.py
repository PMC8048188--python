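"""Outlier-SNP scans for signatures of selection.

Two independent detectors whose intersection defines joint outliers:

* a PC-based scan: each SNP's dosage is regressed on the leading K
  principal-component scores, the K z-statistics are combined into a
  Mahalanobis distance under a robustly estimated covariance, the
  distances are rescaled by the genomic inflation factor and referred to a
  chi-square(K); SNPs are flagged when q < alpha AND their largest squared
  z lies on PC1;
* a label-permutation scan of the per-locus Weir-Cockerham theta with the
  (1+b)/(1+n) empirical p-value convention.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet

from .containers import MISSING, GenotypeMatrix
from .popgen import _allele_summaries, _pop_partition, _wc_components

log = logging.getLogger(__name__)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class OutlierScanResult:
    """Per-SNP scan output; `table` columns: locus, stat, p, q, component
    (PC scan only), flagged."""

    table: pd.DataFrame
    method: str
    inflation: float | None = None


def pc_outlier_scan(gm: GenotypeMatrix, K: int = 2, alpha: float = 0.05, seed: int = 0) -> OutlierScanResult:
    """PC-regression outlier scan with robust Mahalanobis distances.

    Dosages are centred and scaled by the binomial standard deviation
    sqrt(2 p (1-p)); missing entries are mean-imputed. Zero-variance SNPs
    get p = 1.
    """
    n, L = gm.n_individuals, gm.n_loci
    if K >= n:
        raise ValueError("K must be smaller than the number of individuals")
    dos = gm.dosage().astype(float)
    dos[dos == MISSING] = np.nan
    p_hat = np.nanmean(dos, axis=0) / 2.0
    col_mean = 2.0 * p_hat
    inds = np.where(np.isnan(dos))
    dos[inds] = np.take(np.where(np.isfinite(col_mean), col_mean, 0.0), inds[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    degenerate = ~np.isfinite(sd) | (sd == 0) | (np.nanvar(dos, axis=0) == 0)
    sd_safe = np.where(degenerate, 1.0, sd)
    X = (dos - np.where(np.isfinite(col_mean), col_mean, 0.0)) / sd_safe
    X[:, degenerate] = 0.0

    u, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = u[:, :K]  # orthonormal regressors
    beta = scores.T @ X  # (K, L)
    rss = np.maximum((X**2).sum(axis=0) - (beta**2).sum(axis=0), 0.0)
    df = n - K
    sigma = np.sqrt(rss / df)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / sigma
    z = np.where(np.isfinite(z), z, 0.0).T  # (L, K)

    informative = ~degenerate
    z_fit = z[informative]
    if z_fit.shape[0] >= max(50, 5 * K):
        try:
            cov = MinCovDet(random_state=seed).fit(z_fit)
            d2_fit = cov.mahalanobis(z_fit)
        except Exception:  # degenerate covariance; plain fallback
            d2_fit = _plain_mahalanobis(z_fit)
    else:
        d2_fit = _plain_mahalanobis(z_fit)
    d2 = np.zeros(L)
    d2[informative] = d2_fit

    lam = float(np.median(d2_fit) / stats.chi2.ppf(0.5, K)) if informative.any() else 1.0
    if lam <= 0 or not np.isfinite(lam):
        lam = 1.0
    p = stats.chi2.sf(d2 / lam, K)
    p[degenerate] = 1.0
    q = bh_fdr(p)
    component = np.argmax(z**2, axis=1) + 1
    component[degenerate] = 0
    flagged = (q < alpha) & (component == 1)
    table = pd.DataFrame(
        {
            "locus": gm.loci,
            "cluster": gm.clusters if gm.clusters is not None else [""] * L,
            "stat": d2,
            "p": p,
            "q": q,
            "component": component,
            "flagged": flagged,
        }
    )
    return OutlierScanResult(table, method="pc_mahalanobis", inflation=lam)


def _plain_mahalanobis(z: np.ndarray) -> np.ndarray:
    center = z.mean(axis=0)
    cov = np.cov(z, rowvar=False)
    cov = np.atleast_2d(cov) + 1e-10 * np.eye(z.shape[1])
    prec = np.linalg.inv(cov)
    d = z - center
    return np.einsum("ij,jk,ik->i", d, prec, d)


def fst_permutation_scan(
    gm: GenotypeMatrix, pops=None, n_perm: int = 999, alpha: float = 0.05, seed: int = 0
) -> OutlierScanResult:
    """Per-locus WC theta against a population-label permutation null.

    Empirical p = (1 + #{permuted theta >= observed}) / (n_perm + 1), BH q.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    names, idx_by_pop = _pop_partition(gm, pops)
    if len(names) != 2:
        raise ValueError("permutation FST scan needs exactly 2 populations")
    labels = np.asarray(pops if pops is not None else gm.populations)

    def per_locus_theta(lbls: np.ndarray) -> np.ndarray:
        parts = [np.flatnonzero(lbls == name) for name in names]
        n, counts, hets = _allele_summaries(gm, parts)
        a, abc = _wc_components(n, counts, hets)
        with np.errstate(divide="ignore", invalid="ignore"):
            return a / abc

    observed = per_locus_theta(labels)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(gm.n_loci)
    valid_perm = np.zeros(gm.n_loci)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        th = per_locus_theta(perm)
        ok = np.isfinite(th) & np.isfinite(observed)
        exceed[ok] += th[ok] >= observed[ok]
        valid_perm[ok] += 1
    with np.errstate(invalid="ignore"):
        p = (1.0 + exceed) / (1.0 + valid_perm)
    p = np.where(np.isfinite(observed) & (valid_perm > 0), p, 1.0)
    q = bh_fdr(p)
    table = pd.DataFrame(
        {
            "locus": gm.loci,
            "cluster": gm.clusters if gm.clusters is not None else [""] * gm.n_loci,
            "stat": observed,
            "p": p,
            "q": q,
            "component": 0,
            "flagged": q < alpha,
        }
    )
    return OutlierScanResult(table, method="fst_permutation")


def intersect_to_genes(
    scan_a: OutlierScanResult,
    scan_b: OutlierScanResult,
    locus_to_gene: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Joint outliers (significant and flagged in BOTH scans) mapped to genes.

    A gene is selection-flagged when it carries at least one joint-outlier
    SNP; its retained value is the minimum -log10 q among the significant
    q-values of its joint outliers across both methods (the least
    significant of the significant). Columns: gene, n_joint_snps,
    neg_log10_q.
    """
    a = scan_a.table.set_index("locus")
    b = scan_b.table.set_index("locus")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("scans share no loci")
    joint = common[(a.loc[common, "flagged"].to_numpy()) & (b.loc[common, "flagged"].to_numpy())]
    records: dict[str, list[float]] = {}
    dropped = 0
    for locus in joint:
        gene = locus_to_gene.get(locus)
        if gene is None:
            dropped += 1
            continue
        vals = []
        for tab in (a, b):
            qv = tab.loc[locus, "q"]
            if qv < alpha:
                vals.append(-np.log10(max(qv, 1e-300)))
        records.setdefault(gene, []).extend(vals)
    if dropped:
        log.info("%d joint-outlier loci had no gene mapping and were excluded", dropped)
    rows = [
        (gene, sum(1 for l in joint if locus_to_gene.get(l) == gene), min(vals))
        for gene, vals in records.items()
    ]
    return pd.DataFrame(rows, columns=["gene", "n_joint_snps", "neg_log10_q"])
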