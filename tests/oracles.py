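"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the defining formulas with plain loops and, where
possible, exact arithmetic, deliberately avoiding the vectorised code paths
in the package.
"""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hwe_exact_enumeration(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact conditional HWE p-value by full enumeration, rational arithmetic."""
    n = n_aa + n_ab + n_bb
    nb = 2 * n_bb + n_ab
    n_minor = min(nb, 2 * n - nb)
    if n_minor == 0:
        return Fraction(1)
    weights: dict[int, int] = {}
    for het in range(n_minor % 2, n_minor + 1, 2):
        rare = (n_minor - het) // 2
        common = n - het - rare
        if common < 0:
            continue
        weights[het] = (
            2**het * math.factorial(n)
            // (math.factorial(common) * math.factorial(het) * math.factorial(rare))
        )
    total = sum(weights.values())
    observed = weights[n_ab]
    return Fraction(sum(w for w in weights.values() if w <= observed), total)


def bh_stepup(p: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, literal step-up definition."""
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        q[i] = min(val, 1.0)
        prev = q[i]
    return q


def chisq_expected_counts(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square as sum over cells of (O-E)^2/E."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (table[i, j] - e) ** 2 / e
    return stat


def nei_stats_one_pop(genotypes: list[tuple[int, int]]):
    """Ho, Hs for one population at one locus, direct formulas.

    genotypes: allele-index pairs for genotyped individuals only.
    """
    n = len(genotypes)
    ho = sum(1 for a, b in genotypes if a != b) / n
    alleles = [a for g in genotypes for a in g]
    freqs = {}
    for a in alleles:
        freqs[a] = freqs.get(a, 0) + 1
    sum_p2 = sum((c / (2 * n)) ** 2 for c in freqs.values())
    hs = n / (n - 1) * (1 - sum_p2 - ho / (2 * n))
    return ho, hs


def wc84_components(pop_genotypes: list[list[tuple[int, int]]]):
    """Weir-Cockerham (1984) variance components for one locus, summed over
    alleles; loop-based transcription of the published estimator.

    pop_genotypes: one genotype list (allele pairs, genotyped only) per
    population. Returns (a, b, c) summed over alleles.
    """
    r = len(pop_genotypes)
    n_i = [len(g) for g in pop_genotypes]
    nbar = sum(n_i) / r
    nc = (r * nbar - sum(n * n for n in n_i) / (r * nbar)) / (r - 1)
    alleles = sorted({a for pop in pop_genotypes for g in pop for a in g})
    a_sum = b_sum = c_sum = 0.0
    for al in alleles:
        p_i = [sum((g[0] == al) + (g[1] == al) for g in pop) / (2 * n) for pop, n in zip(pop_genotypes, n_i)]
        h_i = [sum(1 for g in pop if g[0] != g[1] and al in g) / n for pop, n in zip(pop_genotypes, n_i)]
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def matching_beta(pop_genotypes_by_locus: list[list[list[tuple[int, int]]]]):
    """Allele-matching population-specific FST, loop transcription.

    pop_genotypes_by_locus[l][p] = genotype list for population p, locus l.
    Returns per-population betas.
    """
    n_pops = len(pop_genotypes_by_locus[0])
    m_within = [[] for _ in range(n_pops)]
    m_between = []
    for locus in pop_genotypes_by_locus:
        freqs = []
        for p, pop in enumerate(locus):
            alleles = [a for g in pop for a in g]
            m = len(alleles)
            counts: dict[int, int] = {}
            for a in alleles:
                counts[a] = counts.get(a, 0) + 1
            m_within[p].append(sum(c * (c - 1) for c in counts.values()) / (m * (m - 1)))
            freqs.append({a: c / m for a, c in counts.items()})
        pair_vals = []
        for i in range(n_pops):
            for j in range(i + 1, n_pops):
                shared = set(freqs[i]) | set(freqs[j])
                pair_vals.append(sum(freqs[i].get(a, 0) * freqs[j].get(a, 0) for a in shared))
        m_between.append(sum(pair_vals) / len(pair_vals))
    mb = sum(m_between) / len(m_between)
    return [
        (sum(mw) / len(mw) - mb) / (1 - mb) for mw in m_within
    ]


def simes_combination(pvals: list[float]) -> float:
    ps = sorted(pvals)
    k = len(ps)
    return min(min(k * p / (i + 1) for i, p in enumerate(ps)), 1.0)
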