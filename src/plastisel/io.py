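"""Readers and writers for the pipeline's on-disk formats.

VCF v4.2 carries the SNP panels (GT and GQ per genotype, QUAL per site,
transcript-cluster id in the CHROM column so clusters act as chromosomes for
LD pruning). Count matrices, design tables and truth tables are plain TSV.
Microsatellite genotypes use the classic two-columns-per-locus layout: id,
site, then two integer allele columns per locus, with 0/0 or NA meaning
missing.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, CountMatrix, ExonCountMatrix, GenotypeMatrix


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a biallelic genotype matrix as VCF v4.2 text."""
    if gm.clusters is None:
        raise ValueError("VCF writing needs per-locus cluster ids for CHROM")
    calls = gm.calls
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for c in pd.unique(pd.Series(gm.clusters)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.individuals) + "\n")
        pos_in_cluster: dict[str, int] = {}
        for j, locus in enumerate(gm.loci):
            chrom = str(gm.clusters[j])
            pos = pos_in_cluster.get(chrom, 0) + 100
            pos_in_cluster[chrom] = pos
            ref, alt = (gm.alleles[j][:2] if gm.alleles is not None else ("A", "G"))
            qual = f"{gm.qual[j]:g}" if gm.qual is not None else "."
            fields = [chrom, str(pos), locus, ref, alt, qual, ".", ".", "GT:GQ"]
            for i in range(gm.n_individuals):
                a, b = calls[i, j]
                if a == MISSING:
                    fields.append("./.:.")
                else:
                    gq = f"{int(gm.gq[i, j])}" if gm.gq is not None else "99"
                    fields.append(f"{min(a, b)}/{max(a, b)}:{gq}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | os.PathLike, cluster_map: dict[str, str] | None = None) -> GenotypeMatrix:
    """Load a biallelic-SNP VCF into a GenotypeMatrix.

    CHROM is used as the transcript-cluster id unless cluster_map maps locus
    ids to clusters. Genotype-quality values are stored but low-GQ masking
    happens at filter time, not here.
    """
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    loci, clusters, alleles, quals = [], [], [], []
    call_rows, gq_rows = [], []
    for k, rec in enumerate(vcf):
        gts = rec.genotype.array()
        if gts.shape[1] > 3:
            raise ValueError(f"non-diploid genotype at record {k+1} ({rec.CHROM}:{rec.POS})")
        locus = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        loci.append(locus)
        clusters.append(cluster_map.get(locus, rec.CHROM) if cluster_map else rec.CHROM)
        alleles.append(tuple([rec.REF] + list(rec.ALT)))
        quals.append(rec.QUAL if rec.QUAL is not None else np.nan)
        pair = gts[:, :2].astype(np.int16)
        missing = (pair < 0).any(axis=1)
        pair[missing] = MISSING
        call_rows.append(pair)
        try:
            gq = rec.format("GQ")
            gq = np.full(len(individuals), np.nan) if gq is None else gq.astype(float).ravel()
        except Exception:
            gq = np.full(len(individuals), np.nan)
        gq_rows.append(gq)
    if not loci:
        raise ValueError(f"no records parsed from {path}")
    calls = np.stack(call_rows, axis=1)  # (n, L, 2)
    gq_arr = np.stack(gq_rows, axis=1)
    return GenotypeMatrix(
        individuals=individuals,
        loci=loci,
        calls=calls,
        clusters=np.asarray(clusters, dtype=object),
        alleles=alleles,
        qual=np.asarray(quals, dtype=float),
        gq=gq_arr,
    )


def write_microsat_table(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Two-columns-per-locus microsatellite table; 0 0 codes a missing call."""
    if gm.alleles is None:
        raise ValueError("microsatellite writing needs allele labels")
    cols = ["id", "site"]
    for locus in gm.loci:
        cols += [f"{locus}_1", f"{locus}_2"]
    rows = []
    pops = gm.populations if gm.populations is not None else ["NA"] * gm.n_individuals
    for i, ind in enumerate(gm.individuals):
        row = [ind, str(pops[i])]
        for j in range(gm.n_loci):
            a, b = gm.calls[i, j]
            if a == MISSING:
                row += ["0", "0"]
            else:
                row += [gm.alleles[j][a], gm.alleles[j][b]]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_microsat_table(path: str | os.PathLike) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    ids = df.iloc[:, 0].tolist()
    sites = df.iloc[:, 1].to_numpy(dtype=object)
    allele_cols = df.columns[2:]
    if len(allele_cols) % 2:
        raise ValueError("microsatellite table must have two allele columns per locus")
    loci = [c[:-2] for c in allele_cols[::2]]
    n, L = len(ids), len(loci)
    calls = np.full((n, L, 2), MISSING, dtype=np.int16)
    alleles: list[tuple[str, ...]] = []
    for j in range(L):
        a1 = df.iloc[:, 2 + 2 * j].to_numpy(dtype=object)
        a2 = df.iloc[:, 3 + 2 * j].to_numpy(dtype=object)
        missing = np.array(
            [(x in ("0", "NA", None) or y in ("0", "NA", None) or pd.isna(x) or pd.isna(y)) for x, y in zip(a1, a2)]
        )
        labels = sorted({str(x) for x in np.concatenate([a1[~missing], a2[~missing]])}, key=lambda s: (len(s), s))
        index = {lab: k for k, lab in enumerate(labels)}
        alleles.append(tuple(labels))
        for i in range(n):
            if not missing[i]:
                calls[i, j, 0] = index[str(a1[i])]
                calls[i, j, 1] = index[str(a2[i])]
    return GenotypeMatrix(
        individuals=ids, loci=loci, calls=calls, alleles=alleles, populations=sites
    )


def write_counts(cm: CountMatrix | ExonCountMatrix, path: str | os.PathLike) -> None:
    df = cm.counts.copy()
    if isinstance(cm, ExonCountMatrix):
        df.index = [f"{g}:{e}" for g, e in df.index]
        df.index.name = "exon_id"
    else:
        df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_design(cm: CountMatrix | ExonCountMatrix, path: str | os.PathLike) -> None:
    cm.design.to_csv(path, sep="\t")


def read_counts(path: str | os.PathLike, design_path: str | os.PathLike, exon: bool = False):
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if exon:
        pairs = [tuple(i.rsplit(":", 1)) for i in df.index]
        df.index = pd.MultiIndex.from_tuples(
            [(g, int(e)) for g, e in pairs], names=["gene", "exon"]
        )
        return ExonCountMatrix(df, design)
    return CountMatrix(df, design)


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)
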