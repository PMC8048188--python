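"""Combine per-gene selection and plasticity evidence.

Each gene in the universe is flagged plastic if any DGE/DEU/GEV contrast
reaches q < alpha, and selection-flagged if it carries a joint-outlier SNP.
The retained value on each axis is the LOWEST -log10 q among that gene's
significant results (the least significant of the significant). The four
resulting categories feed a 2x2 chi-square test of independence.
"""
from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ContingencySummary:
    both: int
    selection_only: int
    plasticity_only: int
    neither: int
    total: int
    chi2: float
    df: int
    p_value: float
    yates: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def classify_genes(
    plasticity: pd.DataFrame,
    selection: pd.DataFrame,
    gene_universe,
    alpha: float = 0.05,
    retain: str = "least_significant",
) -> pd.DataFrame:
    """Per-gene evidence table over a fixed gene universe.

    plasticity: long table with columns gene, test, contrast, q;
    selection: table with columns gene, neg_log10_q (from joint outliers).
    retain: 'least_significant' keeps the lowest -log10 q among the
    significant plasticity results (default); 'most_significant' keeps the
    highest, for sensitivity analysis.
    """
    if retain not in ("least_significant", "most_significant"):
        raise ValueError("retain must be 'least_significant' or 'most_significant'")
    universe = pd.Index(pd.unique(pd.Series(list(gene_universe))))
    known = set(universe)
    for df, src in ((plasticity, "plasticity"), (selection, "selection")):
        extra = set(df["gene"]) - known
        if extra:
            raise ValueError(f"{src} results contain genes outside the universe, e.g. {sorted(extra)[:3]}")

    sig = plasticity.loc[plasticity["q"].notna() & (plasticity["q"] < alpha)].copy()
    sig["neg_log10_q"] = -np.log10(np.maximum(sig["q"].to_numpy(dtype=float), 1e-300))
    agg = "min" if retain == "least_significant" else "max"
    plastic_val = sig.groupby("gene")["neg_log10_q"].agg(agg)
    sel_val = selection.set_index("gene")["neg_log10_q"] if len(selection) else pd.Series(dtype=float)

    out = pd.DataFrame(index=universe)
    out.index.name = "gene"
    out["plastic"] = out.index.isin(plastic_val.index)
    out["selected"] = out.index.isin(sel_val.index)
    out["plasticity_neg_log10_q"] = plastic_val.reindex(out.index)
    out["selection_neg_log10_q"] = sel_val.reindex(out.index)
    tests = sig.groupby("gene")["test"].agg(lambda s: ",".join(sorted(set(s))))
    out["plasticity_tests"] = tests.reindex(out.index).fillna("")
    return out.reset_index()


def contingency_counts(evidence: pd.DataFrame) -> tuple[int, int, int, int]:
    """(both, selection-only, plasticity-only, neither) over the universe."""
    sel = evidence["selected"].to_numpy(bool)
    pla = evidence["plastic"].to_numpy(bool)
    return (
        int((sel & pla).sum()),
        int((sel & ~pla).sum()),
        int((~sel & pla).sum()),
        int((~sel & ~pla).sum()),
    )


def chisq_independence(
    both: int, selection_only: int, plasticity_only: int, neither: int, yates: bool = False
) -> ContingencySummary:
    """2x2 chi-square test of independence, closed form.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the Yates variant
    subtracts N/2 from |ad - bc|. Any zero margin makes the test undefined.
    """
    a, b, c, d = both, selection_only, plasticity_only, neither
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("test undefined: zero row or column margin")
    delta = abs(a * d - b * c)
    if yates:
        delta = max(0.0, delta - n / 2.0)
    chi2 = n * delta**2 / np.prod([float(m) for m in margins])
    p = float(stats.chi2.sf(chi2, 1))
    return ContingencySummary(a, b, c, d, n, float(chi2), 1, p, yates)


# ---------------------------------------------------------------------------
# pipeline orchestration


def run_pipeline(config: dict, outdir: str | os.PathLike) -> dict:
    """Simulate, filter, scan, test, classify; write every table and a
    selection-vs-plasticity scatter. Returns the run summary dict.

    config keys (all optional): seed, genotype (GenotypeSimConfig kwargs),
    expression (ExpressionSimConfig kwargs), alpha, n_perm, n_boot, yates.
    """
    from . import io as pio
    from .expression import deu_fit_test, dge_fit_test, gev_fit_test, filter_expressed, tmm_factors
    from .filters import make_panel
    from .popgen import popgen_report
    from .scan import fst_permutation_scan, intersect_to_genes, pc_outlier_scan
    from .simulate import ExpressionSimConfig, GenotypeSimConfig, sim_expression, sim_snp_genotypes

    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    n_perm = int(config.get("n_perm", 199))
    n_boot = int(config.get("n_boot", 200))
    summary: dict = {"seed": seed, "alpha": alpha, "stages": {}}

    try:
        g_cfg = GenotypeSimConfig(**{"seed": seed, **config.get("genotype", {})})
        gm, g_truth = sim_snp_genotypes(g_cfg)
        pio.write_truth(g_truth, os.path.join(outdir, "genotype_truth.tsv"))
        summary["stages"]["simulate_genotypes"] = {"n_individuals": gm.n_individuals, "n_loci": gm.n_loci}
    except Exception as e:
        raise RuntimeError(f"stage simulate_genotypes failed: {e}") from e

    try:
        overall = make_panel(gm, "overall")
        summary["stages"]["filter"] = {"overall_loci": overall.n_loci}
    except Exception as e:
        raise RuntimeError(f"stage filter failed: {e}") from e

    try:
        report = popgen_report(overall, n_boot=n_boot, seed=seed)
        report.to_csv(os.path.join(outdir, "popgen_report.tsv"), sep="\t", index=False)
        summary["stages"]["popgen"] = {"n_statistics": len(report)}
    except Exception as e:
        raise RuntimeError(f"stage popgen failed: {e}") from e

    try:
        scan_a = pc_outlier_scan(overall, K=2, alpha=alpha, seed=seed)
        scan_b = fst_permutation_scan(overall, n_perm=n_perm, alpha=alpha, seed=seed)
        scan_a.table.to_csv(os.path.join(outdir, "scan_pc.tsv"), sep="\t", index=False)
        scan_b.table.to_csv(os.path.join(outdir, "scan_fstperm.tsv"), sep="\t", index=False)
        locus_to_gene = dict(zip(overall.loci, np.asarray(overall.clusters)))
        sel_genes = intersect_to_genes(scan_a, scan_b, locus_to_gene, alpha=alpha)
        sel_genes.to_csv(os.path.join(outdir, "selection_genes.tsv"), sep="\t", index=False)
        summary["stages"]["scan"] = {
            "pc_flagged": int(scan_a.table["flagged"].sum()),
            "fstperm_flagged": int(scan_b.table["flagged"].sum()),
            "joint_genes": len(sel_genes),
            "inflation": scan_a.inflation,
        }
    except Exception as e:
        raise RuntimeError(f"stage scan failed: {e}") from e

    try:
        e_cfg = ExpressionSimConfig(**{"seed": seed, **config.get("expression", {})})
        cm, ecm, e_truth = sim_expression(e_cfg)
        pio.write_truth(e_truth, os.path.join(outdir, "expression_truth.tsv"))
        cm = filter_expressed(cm)
        cm.norm_factors = tmm_factors(cm)
        dge = dge_fit_test(cm)
        deu = deu_fit_test(ecm)
        gev = gev_fit_test(cm, cm.design["population"], contrast_label="population")
        plasticity = pd.concat(
            [dge, deu, gev[["gene", "test", "contrast", "log2fc", "stat", "p", "q"]]], ignore_index=True
        )
        plasticity.to_csv(os.path.join(outdir, "plasticity_results.tsv"), sep="\t", index=False)
        summary["stages"]["plasticity"] = {
            "dge_sig": int((dge["q"] < alpha).sum()),
            "deu_sig": int((deu["q"] < alpha).sum()),
            "gev_sig": int((gev["q"] < alpha).sum()),
        }
    except Exception as e:
        raise RuntimeError(f"stage plasticity failed: {e}") from e

    try:
        universe = sorted(
            set(e_truth["gene"]) | set(np.asarray(overall.clusters)) | set(plasticity["gene"])
        )
        evidence = classify_genes(plasticity, sel_genes, universe, alpha=alpha)
        evidence.to_csv(os.path.join(outdir, "gene_evidence.tsv"), sep="\t", index=False)
        counts = contingency_counts(evidence)
        try:
            cont = chisq_independence(*counts, yates=bool(config.get("yates", False)))
            with open(os.path.join(outdir, "contingency.json"), "w") as fh:
                fh.write(cont.to_json())
            summary["stages"]["integration"] = asdict(cont)
        except ValueError as err:  # zero margin: counts still reported
            summary["stages"]["integration"] = {
                "both": counts[0],
                "selection_only": counts[1],
                "plasticity_only": counts[2],
                "neither": counts[3],
                "chi2": None,
                "note": str(err),
            }
        plot_selection_plasticity(evidence, os.path.join(outdir, "selection_vs_plasticity.png"))
    except Exception as e:
        raise RuntimeError(f"stage integration failed: {e}") from e

    with open(os.path.join(outdir, "run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary


def plot_selection_plasticity(evidence: pd.DataFrame, path: str | os.PathLike) -> None:
    """Scatter of retained selection vs plasticity -log10 q per gene."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    x = evidence["selection_neg_log10_q"].fillna(0.0)
    y = evidence["plasticity_neg_log10_q"].fillna(0.0)
    shown = evidence["plastic"] | evidence["selected"]
    ax.scatter(x[shown], y[shown], s=8, alpha=0.6, edgecolors="none")
    ax.set_xlabel(r"selection $-\log_{10} q$")
    ax.set_ylabel(r"plasticity $-\log_{10} q$")
    ax.set_title("Per-gene selection vs plasticity evidence")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
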