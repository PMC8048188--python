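"""Synthetic genotype and expression data with known truth.

The genotype simulators use the Balding-Nichols model: population allele
frequencies are Beta (biallelic) or Dirichlet (multi-allelic) distributed
around an ancestral frequency with variance controlled by a per-locus
divergence parameter theta, which is the quantity the Weir-Cockerham FST
estimator targets. Within-population inbreeding F deflates the heterozygote
probability at genotype draw. The expression simulator draws negative
binomial gene counts with sample-specific library-size factors and splits
them into exon counts by a per-gene multinomial, so differential exon usage
can be planted independently of differential gene expression.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, CountMatrix, ExonCountMatrix, GenotypeMatrix

# substream labels so stages can be re-run independently from one global seed
_STREAM = {"snp": 1, "msat": 2, "expr": 3}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[stage]])


@dataclass
class GenotypeSimConfig:
    """Two-or-more population genotype simulation settings.

    theta_background may be a scalar (shared divergence) or one value per
    population (population-specific drift); theta 0 means the population
    frequency equals the ancestral frequency exactly.
    """

    n_pops: int = 2
    n_per_pop: int | Sequence[int] = 16
    n_loci: int = 5000
    theta_background: float | Sequence[float] = 0.023
    theta_selected: float = 0.4
    n_selected: int = 0
    f_is: float = 0.0
    ancestral_maf_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.0
    cluster_size: int = 5
    seed: int = 0

    def pop_sizes(self) -> np.ndarray:
        n = self.n_per_pop
        sizes = np.full(self.n_pops, n) if np.isscalar(n) else np.asarray(n)
        if len(sizes) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        return sizes.astype(int)

    def thetas(self) -> np.ndarray:
        th = self.theta_background
        thetas = np.full(self.n_pops, th) if np.isscalar(th) else np.asarray(th, dtype=float)
        if len(thetas) != self.n_pops:
            raise ValueError("theta_background length must equal n_pops")
        return thetas

    def __post_init__(self) -> None:
        thetas = self.thetas()
        if ((thetas < 0) | (thetas >= 1)).any() or not 0 <= self.theta_selected < 1:
            raise ValueError("divergence parameters must lie in [0, 1)")
        if self.n_selected and self.theta_selected < thetas.max():
            raise ValueError("theta_selected must be >= theta_background")
        if self.n_selected > self.n_loci:
            raise ValueError("n_selected cannot exceed n_loci")
        if not -1 < self.f_is < 1:
            raise ValueError("f_is must lie in (-1, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo < hi < 1):
            raise ValueError("ancestral_maf_range bounds must be ordered within (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if (self.pop_sizes() < 1).any():
            raise ValueError("every population needs at least one individual")
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be positive")


def _bn_pop_freqs(p: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols draw of one population's per-locus allele frequencies."""
    if theta == 0:
        return p.copy()
    scale = (1.0 - theta) / theta
    return rng.beta(p * scale, (1.0 - p) * scale)


def _draw_biallelic_genotypes(
    pk: np.ndarray, n_ind: int, f: float, rng: np.random.Generator
) -> np.ndarray:
    """Genotype dosages (n_ind, L) with HWE distorted by inbreeding f."""
    q = 1.0 - pk
    p_hom_alt = pk * pk + f * pk * q
    p_het = 2.0 * pk * q * (1.0 - f)
    u = rng.random((n_ind, pk.size))
    return (u < p_hom_alt).astype(np.int16) + (u < p_hom_alt + p_het).astype(np.int16)


def _dosage_to_calls(dos: np.ndarray) -> np.ndarray:
    """{0,1,2,MISSING} dosage -> allele-pair calls."""
    calls = np.empty(dos.shape + (2,), dtype=np.int16)
    calls[:, :, 0] = (dos == 2).astype(np.int16)
    calls[:, :, 1] = (dos >= 1).astype(np.int16)
    calls[dos == MISSING] = MISSING
    return calls


def sim_snp_genotypes(cfg: GenotypeSimConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate a biallelic SNP panel under the Balding-Nichols model.

    Returns the genotype matrix (with cluster ids, site/genotype qualities
    and population labels) and a truth table with one row per locus giving
    its class (neutral/selected) and the divergence used.
    """
    rng = _rng(cfg.seed, "snp")
    L = cfg.n_loci
    sizes = cfg.pop_sizes()
    thetas = cfg.thetas()

    lo, hi = cfg.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=L)

    selected = np.zeros(L, dtype=bool)
    if cfg.n_selected:
        selected[rng.choice(L, size=cfg.n_selected, replace=False)] = True

    dosage_blocks = []
    for k in range(cfg.n_pops):
        theta_loc = np.where(selected, cfg.theta_selected, thetas[k])
        # per-locus theta: draw via Beta with locus-wise parameters
        scale = np.where(theta_loc > 0, (1.0 - theta_loc) / np.where(theta_loc > 0, theta_loc, 1.0), np.inf)
        pk = np.where(
            theta_loc > 0,
            rng.beta(np.where(theta_loc > 0, p_anc * scale, 1.0), np.where(theta_loc > 0, (1 - p_anc) * scale, 1.0)),
            p_anc,
        )
        dosage_blocks.append(_draw_biallelic_genotypes(pk, sizes[k], cfg.f_is, rng))
    dos = np.vstack(dosage_blocks)

    if cfg.missing_rate > 0:
        dos[rng.random(dos.shape) < cfg.missing_rate] = MISSING

    loci = [f"L{j}" for j in range(L)]
    clusters = np.array([f"cluster{j // cfg.cluster_size}" for j in range(L)], dtype=object)
    pops = np.concatenate([[f"pop{k+1}"] * sizes[k] for k in range(cfg.n_pops)])
    gm = GenotypeMatrix(
        individuals=[f"ind{i}" for i in range(dos.shape[0])],
        loci=loci,
        calls=_dosage_to_calls(dos),
        clusters=clusters,
        alleles=[("A", "G")] * L,
        qual=np.full(L, 60.0),
        gq=np.full(dos.shape, 99.0),
        populations=pops,
    )
    truth = pd.DataFrame(
        {
            "locus": loci,
            "cluster": clusters,
            "truth_class": np.where(selected, "selected", "neutral"),
            "theta": np.where(selected, cfg.theta_selected, thetas.mean()),
            "ancestral_freq": p_anc,
        }
    )
    return gm, truth


def sim_microsat_genotypes(
    cfg: GenotypeSimConfig, n_alleles: int = 8
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate a multi-allelic microsatellite panel.

    Ancestral allele frequencies are symmetric-Dirichlet; population
    frequencies follow the multi-allelic Balding-Nichols model
    Dirichlet(ancestral * (1-theta)/theta). Genotypes are unordered allele
    pairs; inbreeding makes the two allele draws identical with
    probability f_is.
    """
    if n_alleles < 2:
        raise ValueError("n_alleles must be >= 2")
    rng = _rng(cfg.seed, "msat")
    L = cfg.n_loci
    sizes = cfg.pop_sizes()
    thetas = cfg.thetas()

    anc = rng.dirichlet(np.ones(n_alleles), size=L)  # (L, A)
    selected = np.zeros(L, dtype=bool)
    if cfg.n_selected:
        selected[rng.choice(L, size=cfg.n_selected, replace=False)] = True

    call_blocks = []
    for k in range(cfg.n_pops):
        freqs = np.empty_like(anc)
        for j in range(L):
            theta_loc = cfg.theta_selected if selected[j] else thetas[k]
            if theta_loc == 0:
                freqs[j] = anc[j]
            else:
                freqs[j] = rng.dirichlet(anc[j] * (1.0 - theta_loc) / theta_loc)
        n_ind = sizes[k]
        calls_k = np.empty((n_ind, L, 2), dtype=np.int16)
        for j in range(L):
            a1 = rng.choice(n_alleles, size=n_ind, p=freqs[j])
            a2 = rng.choice(n_alleles, size=n_ind, p=freqs[j])
            ibd = rng.random(n_ind) < cfg.f_is
            a2 = np.where(ibd, a1, a2)
            calls_k[:, j, 0] = a1
            calls_k[:, j, 1] = a2
        call_blocks.append(calls_k)
    calls = np.vstack(call_blocks)

    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape[:2]) < cfg.missing_rate
        calls[miss] = MISSING

    loci = [f"M{j}" for j in range(L)]
    pops = np.concatenate([[f"pop{k+1}"] * sizes[k] for k in range(cfg.n_pops)])
    gm = GenotypeMatrix(
        individuals=[f"ind{i}" for i in range(calls.shape[0])],
        loci=loci,
        calls=calls,
        alleles=[tuple(str(100 + 2 * a) for a in range(n_alleles))] * L,
        populations=pops,
    )
    truth = pd.DataFrame(
        {
            "locus": loci,
            "truth_class": np.where(selected, "selected", "neutral"),
            "theta": np.where(selected, cfg.theta_selected, thetas.mean()),
        }
    )
    return gm, truth


@dataclass
class PlantedEffect:
    """One planted expression effect.

    cells: the population x timepoint cells the effect applies to.
    For DGE, value is the log2 fold change added in those cells; for GEV,
    value is the dispersion ratio applied there; for DEU, exon and the
    usage proportions of that exon inside (usage_alt) and outside
    (usage_base) the affected cells.
    """

    gene: int
    cells: tuple[tuple[str, int], ...]
    value: float = 0.0
    exon: int | None = None
    usage_base: float = 0.5
    usage_alt: float = 0.1


def _default_groups() -> tuple[tuple[str, int, int], ...]:
    # two populations, three timepoints; 16 fish per population split 6/5/5
    return (
        ("CV", 0, 6), ("CV", 72, 5), ("CV", 168, 5),
        ("SP", 0, 6), ("SP", 72, 5), ("SP", 168, 5),
    )


@dataclass
class ExpressionSimConfig:
    """Negative-binomial expression simulation settings.

    groups is a tuple of (population, timepoint, n_samples) cells. Baseline
    log-mean counts are Normal(loc, scale) on the natural-log scale; library
    size factors are uniform on lib_size_range and multiply every gene's
    mean in that sample.
    """

    n_genes: int = 2000
    groups: tuple[tuple[str, int, int], ...] = field(default_factory=_default_groups)
    baseline_logmean: tuple[float, float] = (4.0, 1.5)
    dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    planted_dge: tuple[PlantedEffect, ...] = ()
    planted_deu: tuple[PlantedEffect, ...] = ()
    planted_gev: tuple[PlantedEffect, ...] = ()
    exons_per_gene: int | tuple[int, int] = (2, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.lib_size_range[0] <= 0:
            raise ValueError("library size factors must be positive")
        for effects in (self.planted_dge, self.planted_deu, self.planted_gev):
            genes = [e.gene for e in effects]
            if len(genes) != len(set(genes)):
                raise ValueError("planted effects must be disjoint by gene within a type")
        for e in self.planted_dge:
            if not np.isfinite(e.value):
                raise ValueError("log2 fold changes must be finite")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB draws parameterised by mean mu and dispersion alpha (var = mu + alpha mu^2)."""
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = alpha <= 1e-12
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / alpha[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def sim_expression(cfg: ExpressionSimConfig) -> tuple[CountMatrix, ExonCountMatrix, pd.DataFrame]:
    """Simulate gene- and exon-level counts with planted DGE/DEU/GEV effects."""
    rng = _rng(cfg.seed, "expr")
    samples, pops, tps = [], [], []
    for pop, tp, n in cfg.groups:
        for i in range(n):
            samples.append(f"{pop}_{tp}h_{i+1}")
            pops.append(pop)
            tps.append(tp)
    n_samp = len(samples)
    design = pd.DataFrame({"population": pops, "timepoint": tps}, index=pd.Index(samples, name="sample"))
    cell = list(zip(pops, tps))

    G = cfg.n_genes
    loc, scale = cfg.baseline_logmean
    base_logmu = rng.normal(loc, scale, size=G)
    lib = rng.uniform(*cfg.lib_size_range, size=n_samp)

    log_mu = base_logmu[:, None] + np.log(lib)[None, :]
    alpha = np.full((G, n_samp), cfg.dispersion)

    for e in cfg.planted_dge:
        affected = np.array([c in e.cells for c in cell])
        log_mu[e.gene, affected] += e.value * np.log(2.0)
    for e in cfg.planted_gev:
        affected = np.array([c in e.cells for c in cell])
        alpha[e.gene, affected] *= e.value

    gene_counts = _nb_draw(rng, np.exp(log_mu), alpha)
    counts = pd.DataFrame(gene_counts, index=[f"gene{g}" for g in range(G)], columns=samples)

    # exon structure: fixed per-gene usage proportions, multinomial split
    if np.isscalar(cfg.exons_per_gene):
        n_exons = np.full(G, int(cfg.exons_per_gene))
    else:
        lo_e, hi_e = cfg.exons_per_gene
        n_exons = rng.integers(lo_e, hi_e + 1, size=G)
    deu_by_gene = {e.gene: e for e in cfg.planted_deu}

    exon_rows, exon_data = [], []
    for g in range(G):
        E = int(n_exons[g])
        props = rng.dirichlet(np.full(E, 5.0))
        props_by_sample = np.tile(props, (n_samp, 1))
        eff = deu_by_gene.get(g)
        if eff is not None and E >= 2:
            exon_idx = int(eff.exon or 0)
            affected = np.array([c in eff.cells for c in cell])
            for s in range(n_samp):
                target = eff.usage_alt if affected[s] else eff.usage_base
                rest = props.copy()
                rest[exon_idx] = 0.0
                rest = rest / rest.sum() * (1.0 - target)
                rest[exon_idx] = target
                props_by_sample[s] = rest
        ex = np.empty((E, n_samp), dtype=np.int64)
        for s in range(n_samp):
            ex[:, s] = rng.multinomial(gene_counts[g, s], props_by_sample[s])
        for e_i in range(E):
            exon_rows.append((f"gene{g}", e_i))
            exon_data.append(ex[e_i])
    exon_counts = pd.DataFrame(
        np.asarray(exon_data),
        index=pd.MultiIndex.from_tuples(exon_rows, names=["gene", "exon"]),
        columns=samples,
    )

    truth_class = np.array(["null"] * G, dtype=object)
    truth_value = np.full(G, np.nan)
    for e in cfg.planted_dge:
        truth_class[e.gene] = "dge"
        truth_value[e.gene] = e.value
    for e in cfg.planted_deu:
        truth_class[e.gene] = "deu" if truth_class[e.gene] == "null" else truth_class[e.gene] + "+deu"
        truth_value[e.gene] = e.usage_alt - e.usage_base
    for e in cfg.planted_gev:
        truth_class[e.gene] = "gev" if truth_class[e.gene] == "null" else truth_class[e.gene] + "+gev"
        truth_value[e.gene] = e.value
    truth = pd.DataFrame(
        {"gene": [f"gene{g}" for g in range(G)], "truth_class": truth_class, "param": truth_value}
    )
    return CountMatrix(counts, design), ExonCountMatrix(exon_counts, design), truth
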