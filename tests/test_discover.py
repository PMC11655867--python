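import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import immunocarto as ic
from immunocarto.discover import Contrast, ModuleSet, build_module_set, squeeze_variances
from immunocarto.exceptions import ConfigurationError, DataError, StatisticsError


def _labels(n_a, n_b, a="A", b="B"):
    idx = [f"s{i}" for i in range(n_a + n_b)]
    return pd.Series([a] * n_a + [b] * n_b, index=idx), idx


class TestDifferentialExpression:
    def test_constant_matrix_gives_zero_fc_p_one(self):
        labels, idx = _labels(4, 4)
        mat = pd.DataFrame(5.0, index=idx, columns=["g1", "g2"])
        de = ic.differential_expression(mat, labels, "A")
        assert (de["log2fc"] == 0).all()
        assert (de["pvalue"] == 1).all()
        assert ic.select_module_genes(de) == []

    def test_planted_shift_recovered_with_significance(self):
        """Gene with true log2 shift 3, tiny noise, n=10 vs 40; Welch oracle."""
        rng = np.random.default_rng(0)
        labels, idx = _labels(10, 40)
        noise = rng.normal(0, 0.1, size=(50, 30))
        mat = pd.DataFrame(noise + 5.0, index=idx, columns=[f"g{i}" for i in range(30)])
        mat.iloc[:10, 0] += 3.0
        de = ic.differential_expression(mat, labels, "A")
        assert de.iloc[0]["log2fc"] == pytest.approx(3.0, abs=0.2)
        assert de.iloc[0]["padj"] < 0.01
        # Welch oracle agrees on the planted gene's extremity
        t, p = stats.ttest_ind(mat.iloc[:10, 0], mat.iloc[10:, 0], equal_var=False)
        assert p < 1e-6

    def test_bh_adjustment_matches_stepup_bruteforce(self):
        """BH on (0.001, 0.01, 0.03, 0.04): step-up by hand gives
        (0.004, 0.02, 0.04, 0.04)."""
        labels, idx = _labels(3, 3)
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(6, 4)), index=idx,
                           columns=["a", "b", "c", "d"])
        de = ic.differential_expression(mat, labels, "A", method="welch")
        raw = np.array([0.001, 0.01, 0.03, 0.04])
        # independent brute-force step-up
        m = len(raw)
        order = np.argsort(raw)
        adj = raw[order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(adj, 1)
        assert np.allclose(expected, [0.004, 0.02, 0.04, 0.04])
        from statsmodels.stats.multitest import multipletests
        assert np.allclose(multipletests(raw, method="fdr_bh")[1], expected)
        # and the DE table's padj is BH of its own pvalues
        assert np.allclose(
            de["padj"], multipletests(de["pvalue"], method="fdr_bh")[1]
        )

    def test_swapping_groups_negates_fc(self):
        rng = np.random.default_rng(2)
        labels, idx = _labels(5, 7)
        mat = pd.DataFrame(rng.normal(size=(12, 20)), index=idx,
                           columns=[f"g{i}" for i in range(20)])
        de_a = ic.differential_expression(mat, labels, "A", ["B"])
        de_b = ic.differential_expression(mat, labels, "B", ["A"])
        assert np.allclose(de_a["log2fc"], -de_b["log2fc"])

    def test_small_group_rejected(self):
        labels, idx = _labels(1, 5)
        mat = pd.DataFrame(np.ones((6, 3)), index=idx, columns=list("abc"))
        with pytest.raises(StatisticsError):
            ic.differential_expression(mat, labels, "A")

    def test_moderated_p_monotone_in_signal(self):
        rng = np.random.default_rng(3)
        labels, idx = _labels(6, 6)
        mat = pd.DataFrame(rng.normal(0, 0.3, size=(12, 3)), index=idx,
                           columns=["null", "weak", "strong"])
        mat.loc[labels == "A", "weak"] += 0.8
        mat.loc[labels == "A", "strong"] += 3.0
        de = ic.differential_expression(mat, labels, "A")
        assert de.loc["strong", "pvalue"] < de.loc["weak", "pvalue"] < de.loc["null", "pvalue"]


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_moderated_t_agrees_with_limma_oracle(tmp_path):
    """Independent cross-check of the empirical-Bayes moderated t against
    the reference linear-model implementation on a small fixture."""
    rng = np.random.default_rng(7)
    n1, n2, g = 5, 6, 40
    mat = rng.normal(6, 1, size=(n1 + n2, g))
    mat[:n1, :5] += 2.0
    idx = [f"s{i}" for i in range(n1 + n2)]
    cols = [f"g{i}" for i in range(g)]
    df = pd.DataFrame(mat, index=idx, columns=cols)
    labels = pd.Series(["T"] * n1 + ["C"] * n2, index=idx)
    df.T.to_csv(tmp_path / "expr.csv")
    script = textwrap.dedent(f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.csv("{tmp_path}/expr.csv", row.names=1, check.names=FALSE))
        design <- cbind(Intercept=1, T=c(rep(1,{n1}), rep(0,{n2})))
        fit <- eBayes(lmFit(x, design))
        tab <- topTable(fit, coef="T", number=Inf, sort.by="none")
        write.csv(tab[, c("logFC","P.Value")], "{tmp_path}/limma.csv")
    """)
    (tmp_path / "run.R").write_text(script)
    subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                   capture_output=True, timeout=300)
    ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)
    de = ic.differential_expression(df, labels, "T", method="moderated")
    assert np.allclose(de["log2fc"], ref["logFC"], atol=1e-8)
    assert np.allclose(de["pvalue"], ref["P.Value"], rtol=1e-4)


class TestSqueezeVariances:
    def test_shrinks_toward_prior(self):
        rng = np.random.default_rng(0)
        true_var = 1.0
        s2 = true_var * rng.chisquare(4, size=500) / 4
        post, d0, s02 = squeeze_variances(s2, 4)
        assert d0 > 0
        # posterior variances are less dispersed than the raw ones
        assert post.std() < s2.std()
        assert s02 == pytest.approx(true_var, rel=0.3)


class TestSelectModuleGenes:
    def test_threshold_gates(self):
        de = pd.DataFrame(
            {"log2fc": [1.5, 0.9, -2.0], "pvalue": [1e-4, 1e-7, 1e-9],
             "padj": [0.005, 1e-6, 1e-8]},
            index=["pass", "fc_fail", "down"],
        )
        assert ic.select_module_genes(de) == ["pass"]

    def test_empty_table(self):
        de = pd.DataFrame(columns=["log2fc", "pvalue", "padj"])
        assert ic.select_module_genes(de) == []


class TestBuildModuleSet:
    def test_gene_assigned_to_largest_fc_contrast(self):
        """A gene passing two contrasts lands in the higher-FC one (brute
        force over both assignments confirms the winner)."""
        rng = np.random.default_rng(4)
        idx = [f"s{i}" for i in range(18)]
        labels = pd.Series(["A"] * 6 + ["B"] * 6 + ["C"] * 6, index=idx)
        mat = pd.DataFrame(rng.normal(5, 0.1, size=(18, 5)), index=idx,
                           columns=[f"g{i}" for i in range(5)])
        # g0 up in A (+2.1 vs C) and in B (+1.4 vs C)
        mat.loc[labels == "A", "g0"] += 2.1
        mat.loc[labels == "B", "g0"] += 1.4
        contrasts = [Contrast("modA", "A", ("C",)), Contrast("modB", "B", ("C",))]
        ms = build_module_set(mat, labels, contrasts)
        de_a = ic.differential_expression(mat, labels, "A", ("C",))
        de_b = ic.differential_expression(mat, labels, "B", ("C",))
        assert de_a.loc["g0", "log2fc"] > de_b.loc["g0", "log2fc"]
        assert "g0" in ms["modA"] and "g0" not in ms["modB"]

    def test_unknown_contrast_group_rejected(self):
        labels, idx = _labels(5, 5)
        mat = pd.DataFrame(np.ones((10, 2)), index=idx, columns=["a", "b"])
        with pytest.raises(ConfigurationError):
            build_module_set(mat, labels, [Contrast("m", "Nope", ("B",))])

    def test_exclusion_list_removes_genes(self):
        rng = np.random.default_rng(5)
        labels, idx = _labels(6, 6)
        mat = pd.DataFrame(rng.normal(5, 0.1, size=(12, 4)), index=idx,
                           columns=list("wxyz"))
        mat.loc[labels == "A", ["w", "x"]] += 3.0
        ms = build_module_set(mat, labels, [Contrast("m", "A", ("B",))],
                              exclusion_list=["x"])
        assert "w" in ms["m"] and "x" not in ms["m"]

    def test_module_set_disjointness_enforced(self):
        with pytest.raises(DataError):
            ModuleSet({"m1": ["g1", "g2"], "m2": ["g2"]})

    def test_module_set_json_roundtrip(self, tmp_path):
        ms = ModuleSet({"m1": ["a", "b"], "m2": ["c"]}, {"note": 1})
        ms.save_json(tmp_path / "m.json")
        back = ModuleSet.load_json(tmp_path / "m.json")
        assert back.modules == ms.modules
        assert back.provenance == ms.provenance


class TestPlantedModuleRecovery:
    def test_recovery_on_default_synthetic_cohort(self):
        """On the canonical extended cohort (n=10 per disease, seed 0) every
        planted module is recovered with Jaccard >= 0.9 and almost no
        background genes are admitted."""
        panel = [
            ic.DiseaseProfile(p.name, 10, p.dominant, p.subdominant)
            for p in ic.extended_panel()
        ]
        cfg = ic.SimulationConfig(diseases=tuple(panel), seed=0)
        raw, truth = ic.generate_cohort(cfg)
        norm = ic.normalize_counts(raw)
        ms = build_module_set(norm.data, truth.disease)
        assert set(ms.modules) == set(ic.MODULES)
        n_planted = sum(len(v) for v in truth.module_genes.values())
        n_recovered = 0
        for m in ms.modules:
            planted, got = set(truth.module_genes[m]), set(ms[m])
            jaccard = len(planted & got) / len(planted | got)
            assert jaccard >= 0.9, (m, jaccard)
            n_recovered += len(planted & got)
        assert n_recovered / n_planted >= 0.9
        background = [g for g in ms.all_genes if g.startswith("BG_")]
        assert len(background) / 480 <= 0.05
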