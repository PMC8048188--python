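"""Normalization, expression filtering, and the DGE/DEU/GEV tests:
calibration under the null, power on planted effects, and independent
cross-checks of the fold-change and normalization code."""
import numpy as np
import pandas as pd
import pytest

from oracles import simes_combination
from plastisel import (
    CountMatrix,
    ExpressionSimConfig,
    PlantedEffect,
    deu_fit_test,
    dge_fit_test,
    filter_expressed,
    gev_fit_test,
    sim_expression,
    standard_contrasts,
    tmm_factors,
)
from plastisel.expression import _simes


def _design(n_per_cell=4, samples=None):
    rows = []
    for pop in ("CV", "SP"):
        for tp in (0, 72, 168):
            for i in range(n_per_cell):
                rows.append((f"{pop}_{tp}_{i}", pop, tp))
    df = pd.DataFrame(rows, columns=["sample", "population", "timepoint"]).set_index("sample")
    if samples is not None:
        df.index = pd.Index(samples, name="sample")
    return df


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(50, size=500)
        counts = pd.DataFrame({f"s{i}": col for i in range(6)})
        cm = CountMatrix(counts, _design(1, samples=counts.columns))
        assert tmm_factors(cm).to_numpy() == pytest.approx(np.ones(6), abs=1e-9)

    def test_doubled_column_is_compensated(self):
        rng = np.random.default_rng(2)
        col = rng.poisson(100, size=2000).astype(float)
        counts = pd.DataFrame({"a": col, "b": 2 * col, "c": col, "d": col, "e": col, "f": col})
        cm = CountMatrix(counts, _design(1, samples=counts.columns))
        f = tmm_factors(cm)
        # library size already captures the doubling; factors stay ~1
        assert f.to_numpy() == pytest.approx(np.ones(6), abs=0.02)
        # composition bias: a quarter of the genes inflated in one sample only;
        # TMM follows the unchanged majority and scales that sample down
        biased = counts.copy()
        biased.iloc[:500, 0] = biased.iloc[:500, 0] * 4
        cmb = CountMatrix(biased, _design(1, samples=counts.columns))
        fb = tmm_factors(cmb)
        assert fb["a"] < 0.8

    def test_geometric_mean_one_and_zero_sample_error(self):
        cm, _, _ = sim_expression(ExpressionSimConfig(n_genes=300, seed=5))
        f = tmm_factors(cm)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-12)
        bad = cm.counts.copy()
        bad.iloc[:, 0] = 0
        with pytest.raises(ValueError):
            tmm_factors(CountMatrix(bad, cm.design))

    def test_matches_edger_reference_on_small_matrix(self, tmp_path):
        """Independent cross-check against edgeR's calcNormFactors."""
        import subprocess

        cm, _, _ = sim_expression(ExpressionSimConfig(n_genes=400, lib_size_range=(0.5, 2.0), seed=9))
        path = tmp_path / "counts.tsv"
        cm.counts.to_csv(path, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"x <- as.matrix(read.delim('{path}', row.names=1))\n"
            "cat(calcNormFactors(DGEList(counts=x))$samples$norm.factors, sep='\\n')\n"
        )
        try:
            out = subprocess.run(
                ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300, check=True
            )
        except (FileNotFoundError, subprocess.CalledProcessError, subprocess.TimeoutExpired):
            pytest.skip("Rscript/edgeR unavailable for the cross-check")
        ref = np.array([float(v) for v in out.stdout.split()])
        mine = tmm_factors(cm).to_numpy()
        assert mine == pytest.approx(ref, abs=0.05)


class TestFilterExpressed:
    def test_rule_on_constructed_cases(self):
        design = _design(2)
        samples = design.index
        counts = pd.DataFrame(1, index=["complete_group", "hole_everywhere", "all_zero"], columns=samples)
        counts.loc["complete_group"] = 0
        counts.loc["complete_group", ["CV_0_0", "CV_0_1"]] = 5  # full in cell CV:0
        for g in design.groupby(["population", "timepoint"]).groups.values():
            counts.loc["hole_everywhere", g[0]] = 0  # one zero in every cell
        counts.loc["all_zero"] = 0
        cm = CountMatrix(counts, design)
        kept = filter_expressed(cm).counts.index
        assert list(kept) == ["complete_group"]


class TestDge:
    def test_null_type_i_error_calibrated(self, null_expression):
        cm, _, _ = null_expression
        cmf = filter_expressed(cm)
        cmf.norm_factors = tmm_factors(cmf)
        res = dge_fit_test(cmf)
        rate = (res.p < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_power_and_fold_change_recovery(self):
        eff = tuple(PlantedEffect(gene=g, cells=(("SP", 168),), value=2.0) for g in range(40))
        cm, _, _ = sim_expression(ExpressionSimConfig(n_genes=600, planted_dge=eff, seed=303))
        cmf = filter_expressed(cm)
        cmf.norm_factors = tmm_factors(cmf)
        res = dge_fit_test(cmf)
        sub = res[res.contrast == "SP_vs_CV@168h"].set_index("gene")
        planted = [f"gene{g}" for g in range(40) if f"gene{g}" in sub.index]
        assert (sub.loc[planted].q < 0.05).mean() > 0.8
        assert sub.loc[planted].log2fc.mean() == pytest.approx(2.0, abs=0.25)

    def test_contrast_antisymmetry(self, null_expression):
        cm, _, _ = null_expression
        cmf = filter_expressed(cm)
        cmf.norm_factors = tmm_factors(cmf)
        fwd = dge_fit_test(cmf, contrasts={"f": (("SP", 168), ("CV", 168))})
        rev = dge_fit_test(cmf, contrasts={"r": (("CV", 168), ("SP", 168))})
        assert fwd.log2fc.to_numpy() == pytest.approx(-rev.log2fc.to_numpy(), abs=1e-9)
        assert fwd.p.to_numpy() == pytest.approx(rev.p.to_numpy(), abs=1e-12)

    def test_log2fc_matches_independent_poisson_glm_at_high_counts(self):
        """At high counts the NB fold change agrees with a statsmodels Poisson
        GLM fitted per gene (dispersion barely matters there)."""
        import statsmodels.api as sm

        eff = tuple(PlantedEffect(gene=g, cells=(("SP", 168),), value=1.0) for g in range(5))
        # equal library sizes: the NB and Poisson means-model MLEs coincide
        cm, _, _ = sim_expression(
            ExpressionSimConfig(n_genes=40, baseline_logmean=(7.0, 0.3), dispersion=0.05,
                                lib_size_range=(1.0, 1.0), planted_dge=eff, seed=17)
        )
        cm.norm_factors = tmm_factors(cm)
        res = dge_fit_test(cm, contrasts={"c": (("SP", 168), ("CV", 168))}).set_index("gene")
        d = cm.design
        cells = d.population.astype(str) + ":" + d.timepoint.astype(str)
        X = pd.get_dummies(cells, dtype=float)
        offset = np.log(cm.lib_sizes.to_numpy() * cm.norm_factors.to_numpy())
        for g in ["gene0", "gene1", "gene2"]:
            y = cm.counts.loc[g].to_numpy(dtype=float)
            fit = sm.GLM(y, X.to_numpy(), family=sm.families.Poisson(), offset=offset).fit()
            lfc_ref = (fit.params[list(X.columns).index("SP:168")] - fit.params[list(X.columns).index("CV:168")]) / np.log(2)
            assert res.loc[g, "log2fc"] == pytest.approx(lfc_ref, abs=0.05)

    def test_missing_cell_contrast_errors(self, null_expression):
        cm, _, _ = null_expression
        with pytest.raises(ValueError):
            dge_fit_test(cm, contrasts={"bad": (("XX", 0), ("CV", 0))})


class TestDeu:
    def test_simes_rule(self):
        assert _simes(pd.Series([0.01, 0.04])) == pytest.approx(0.02)
        assert _simes(pd.Series([0.5])) == 0.5
        for pv in ([0.2, 0.9, 0.04], [0.5, 0.5, 0.5, 0.01]):
            assert _simes(pd.Series(pv)) == pytest.approx(simes_combination(pv))

    def test_pure_dge_gene_shows_no_deu_signal(self):
        eff = tuple(PlantedEffect(gene=g, cells=(("SP", 168),), value=3.0) for g in range(30))
        _, ecm, _ = sim_expression(ExpressionSimConfig(n_genes=200, planted_dge=eff, seed=55))
        res = deu_fit_test(ecm)
        sub = res[res.contrast == "SP_vs_CV@168h"].set_index("gene")
        dge_genes = [f"gene{g}" for g in range(30) if f"gene{g}" in sub.index]
        assert (sub.loc[dge_genes].q < 0.05).mean() < 0.1

    def test_planted_usage_switch_detected(self):
        eff = tuple(
            PlantedEffect(gene=g, cells=(("SP", 168),), exon=0, usage_base=0.5, usage_alt=0.1) for g in range(40)
        )
        _, ecm, _ = sim_expression(ExpressionSimConfig(n_genes=400, planted_deu=eff, seed=56))
        res = deu_fit_test(ecm)
        sub = res[res.contrast == "SP_vs_CV@168h"].set_index("gene")
        planted = [f"gene{g}" for g in range(40) if f"gene{g}" in sub.index]
        assert (sub.loc[planted].q < 0.05).mean() > 0.7
        null = sub.drop(index=planted)
        assert (null.q < 0.05).mean() < 0.05

    def test_single_exon_genes_excluded(self):
        _, ecm, _ = sim_expression(ExpressionSimConfig(n_genes=50, exons_per_gene=(1, 3), seed=57))
        res = deu_fit_test(ecm)
        sizes = ecm.counts.groupby(level=0).size()
        single = set(sizes.index[sizes == 1])
        assert single and not (set(res.gene) & single)

    def test_row_and_sample_order_invariance(self):
        _, ecm, _ = sim_expression(ExpressionSimConfig(n_genes=60, seed=58))
        res = deu_fit_test(ecm).sort_values(["contrast", "gene"]).reset_index(drop=True)
        rng = np.random.default_rng(0)
        perm_rows = rng.permutation(len(ecm.counts))
        perm_cols = rng.permutation(ecm.counts.columns)
        shuffled = type(ecm)(ecm.counts.iloc[perm_rows][perm_cols], ecm.design.loc[perm_cols])
        res2 = deu_fit_test(shuffled).sort_values(["contrast", "gene"]).reset_index(drop=True)
        assert res.p.to_numpy() == pytest.approx(res2.p.to_numpy(), abs=1e-9)


class TestGev:
    def test_null_type_i_error_calibrated(self, null_expression):
        cm, _, _ = null_expression
        cm2 = CountMatrix(cm.counts, cm.design, tmm_factors(cm))
        res = gev_fit_test(cm2, cm2.design["population"])
        tested = res[res.included]
        rate = (tested.p < 0.05).mean()
        assert 0.03 <= rate <= 0.08

    def test_dispersion_shift_detected_at_high_expression(self):
        eff = tuple(
            PlantedEffect(gene=g, cells=(("SP", 0), ("SP", 72), ("SP", 168)), value=6.0) for g in range(40)
        )
        cm, _, _ = sim_expression(
            ExpressionSimConfig(n_genes=300, baseline_logmean=(6.0, 1.0), planted_gev=eff, seed=61)
        )
        cm.norm_factors = tmm_factors(cm)
        res = gev_fit_test(cm, cm.design["population"]).set_index("gene")
        planted = [f"gene{g}" for g in range(40) if f"gene{g}" in res.index and res.loc[f"gene{g}", "included"]]
        assert (res.loc[planted].q < 0.05).mean() > 0.6

    def test_cv_filter_removes_extreme_genes(self, null_expression):
        cm, _, _ = null_expression
        cm2 = CountMatrix(cm.counts, cm.design, tmm_factors(cm))
        res = gev_fit_test(cm2, cm2.design["population"], cv_range=(1e-3, 0.4))
        dropped = res[~res.included]
        assert (dropped.cv >= 0.4).any()
        assert res.loc[res.included, "cv"].between(1e-3, 0.4).all()
        assert res.loc[~res.included, "q"].isna().all()

    def test_single_group_rejected(self, null_expression):
        cm, _, _ = null_expression
        ones = pd.Series("g", index=cm.samples)
        with pytest.raises(ValueError):
            gev_fit_test(cm, ones)


def test_standard_contrasts_enumerate_nine_comparisons(null_expression):
    cm, _, _ = null_expression
    cons = standard_contrasts(cm.design)
    assert len(cons) == 9
    between = [c for c in cons.values() if c[0][1] == c[1][1]]
    within = [c for c in cons.values() if c[0][0] == c[1][0]]
    assert len(between) == 3 and len(within) == 6
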