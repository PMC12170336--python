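import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoforms.matrix import IntensityMatrix, SampleDesign
from glycoforms.quant import (
    benjamini_hochberg,
    correct_by_ratio,
    correct_by_regression,
    differential,
    normalize,
    squeeze_variances,
)
from conftest import two_group_matrix


def _raw_matrix(values, channels=None):
    values = np.asarray(values, dtype=float)
    channels = channels or [f"c{i}" for i in range(values.shape[1])]
    design = SampleDesign(
        pd.DataFrame({"condition": ["x"] * len(channels)}, index=pd.Index(channels, name="channel"))
    )
    frame = pd.DataFrame(values, columns=channels, index=[f"f{i}" for i in range(len(values))])
    return IntensityMatrix(frame, design, scale="raw")


class TestNormalize:
    def test_median_removes_scalar_factor(self):
        rng = np.random.default_rng(0)
        col = rng.uniform(10, 1000, 50)
        m = _raw_matrix(np.column_stack([col, 3.7 * col]))
        out = normalize(m, "median")
        np.testing.assert_allclose(out.values["c0"], out.values["c1"], rtol=1e-12)

    def test_quantile_equalizes_distributions(self):
        rng = np.random.default_rng(1)
        m = _raw_matrix(rng.lognormal(10, 2, size=(100, 4)))
        out = normalize(m, "quantile")
        sorted_cols = np.sort(out.values.to_numpy(), axis=0)
        for j in range(1, 4):
            np.testing.assert_allclose(sorted_cols[:, 0], sorted_cols[:, j])

    def test_vsn_like_monotone_per_sample(self):
        rng = np.random.default_rng(2)
        m = _raw_matrix(rng.lognormal(10, 1, size=(60, 3)))
        out = normalize(m, "vsn_like")
        assert out.scale == "normalized"
        for col in m.values.columns:
            order_in = np.argsort(m.values[col].to_numpy())
            order_out = np.argsort(out.values[col].to_numpy())
            np.testing.assert_array_equal(order_in, order_out)

    def test_vsn_like_log2_units_for_large_intensities(self):
        # doubling a large intensity adds ~1 on the transformed scale
        m = _raw_matrix(np.array([[1e6], [2e6], [4e6], [8e6]]).reshape(1, 4).T.reshape(4, 1))
        h = np.arcsinh(m.values.to_numpy()) / np.log(2)
        np.testing.assert_allclose(np.diff(h[:, 0]), 1.0, atol=1e-6)

    def test_vsn_like_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            normalize(_raw_matrix([[1.0, -2.0]]), "vsn_like")


class TestRegressionCorrection:
    def _pair(self, g_values, p_values, channels=("c0", "c1", "c2", "c3")):
        g = _raw_matrix(g_values, list(channels))
        p = IntensityMatrix(
            pd.DataFrame(np.atleast_2d(p_values), columns=list(channels), index=["prot"]),
            g.design,
            scale="log2",
        )
        g = g.with_values(g.values, scale="log2")
        return g, p, pd.Series({f"f{i}": "prot" for i in range(len(np.atleast_2d(g_values)))})

    def test_perfect_fit_gives_constant(self):
        prot = np.array([1.0, 2.0, 3.0, 4.0])
        g, p, mapping = self._pair([2 * prot + 1], prot)
        out, flags = correct_by_regression(g, p, mapping)
        np.testing.assert_allclose(out.values.iloc[0], np.mean(2 * prot + 1), atol=1e-12)
        assert flags.iloc[0] == "corrected"

    def test_constant_protein_passes_through(self):
        g, p, mapping = self._pair([[5.0, 6.0, 7.0, 8.0]], [3.0, 3.0, 3.0, 3.0])
        out, flags = correct_by_regression(g, p, mapping)
        np.testing.assert_allclose(out.values.iloc[0], [5.0, 6.0, 7.0, 8.0])
        assert flags.iloc[0] == "zero_variance_protein"

    def test_recovers_independent_effect(self):
        # enough samples that the per-feature slope is estimated well; the
        # independent effect acts as regression noise, so recovery fidelity
        # scales with the sample count
        rng = np.random.default_rng(3)
        n_feat, n_samp = 100, 100
        prot = rng.normal(20, 1, (1, n_samp))
        effect = rng.normal(0, 1, (n_feat, n_samp))
        g_vals = prot + effect + rng.normal(0, 0.05, (n_feat, n_samp))
        channels = [f"c{i}" for i in range(n_samp)]
        design = SampleDesign(
            pd.DataFrame({"condition": ["x"] * n_samp}, index=pd.Index(channels, name="channel"))
        )
        g = IntensityMatrix(
            pd.DataFrame(g_vals, columns=channels, index=[f"f{i}" for i in range(n_feat)]),
            design,
            scale="log2",
        )
        p = IntensityMatrix(pd.DataFrame(prot, columns=channels, index=["prot"]), design, scale="log2")
        mapping = pd.Series("prot", index=g.values.index)
        out, _ = correct_by_regression(g, p, mapping)
        centered_out = out.values.to_numpy() - out.values.to_numpy().mean(axis=1, keepdims=True)
        centered_eff = effect - effect.mean(axis=1, keepdims=True)
        r = np.corrcoef(centered_out.ravel(), centered_eff.ravel())[0, 1]
        assert r > 0.99


class TestRatioCorrection:
    def _setup(self, seed=4, n_feat=40, n_samp=5):
        rng = np.random.default_rng(seed)
        channels = [f"c{i}" for i in range(n_samp)]
        design = SampleDesign(
            pd.DataFrame({"condition": ["x"] * n_samp}, index=pd.Index(channels, name="channel"))
        )
        proteins = [f"prot{i}" for i in range(10)]
        g = IntensityMatrix(
            pd.DataFrame(
                rng.lognormal(13, 1, (n_feat, n_samp)),
                columns=channels,
                index=[f"f{i}" for i in range(n_feat)],
            ),
            design,
            scale="raw",
        )
        p = IntensityMatrix(
            pd.DataFrame(rng.lognormal(15, 1, (10, n_samp)), columns=channels, index=proteins),
            design,
            scale="raw",
        )
        mapping = pd.Series([proteins[i % 10] for i in range(n_feat)], index=g.values.index)
        return g, p, mapping

    def test_hand_evaluated_formula(self):
        channels = ["c0"]
        design = SampleDesign(pd.DataFrame({"condition": ["x"]}, index=pd.Index(channels, name="channel")))
        # three features so the medians are what the hand calculation assumes
        g = IntensityMatrix(
            pd.DataFrame([[2e6], [1e6], [0.5e6]], columns=channels, index=["a", "b", "c"]),
            design, scale="raw",
        )
        p = IntensityMatrix(
            pd.DataFrame([[4e6], [2e6], [1e6]], columns=channels, index=["pa", "pb", "pc"]),
            design, scale="raw",
        )
        mapping = pd.Series({"a": "pa", "b": "pb", "c": "pc"})
        out = correct_by_ratio(g, p, mapping)
        # median_g = 1e6, median_p = 2e6; for a: ((2e6/4e6)/(1e6/2e6))*1e6 = 1e6
        assert out.values.loc["a", "c0"] == pytest.approx(1e6)
        # fixed point: g = median_g, p = median_p -> corrected = median_g
        assert out.values.loc["b", "c0"] == pytest.approx(1e6)

    @pytest.mark.parametrize("c", [0.1, 7.0, 1000.0])
    def test_invariant_to_protein_scaling(self, c):
        g, p, mapping = self._setup()
        base = correct_by_ratio(g, p, mapping)
        scaled = correct_by_ratio(g, p.with_values(p.values * c), mapping)
        np.testing.assert_allclose(
            base.values.to_numpy(), scaled.values.to_numpy(), rtol=1e-9
        )

    def test_zero_protein_becomes_missing(self):
        g, p, mapping = self._setup()
        pv = p.values.copy()
        pv.iloc[0, 0] = 0.0
        out = correct_by_ratio(g, p.with_values(pv), mapping)
        fid = mapping[mapping == pv.index[0]].index[0]
        assert np.isnan(out.values.loc[fid].iloc[0])


class TestBenjaminiHochberg:
    def test_hand_stepped_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_bounds(self):
        assert benjamini_hochberg([1.0]) == pytest.approx([1.0])
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_adjusted_at_least_raw(self, ps):
        adj = benjamini_hochberg(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_agrees_with_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(500):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            mine = benjamini_hochberg(p)
            # brute-force step-up definition
            m = len(p)
            order = np.argsort(p)
            brute = np.empty(m)
            running = np.inf
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                brute[i] = min(running, 1.0)
            np.testing.assert_allclose(mine, brute, atol=1e-12)
            np.testing.assert_allclose(mine, multipletests(p, method="fdr_bh")[1], atol=1e-12)


class TestDifferential:
    def test_null_calibration(self):
        fracs = []
        for seed in range(10):
            m = two_group_matrix(seed, n_features=1000)
            res = differential(m, [("treatment", "control")])
            fracs.append(res.table["significant"].mean())
        mc_se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert np.mean(fracs) <= 0.05 + 3 * mc_se

    def test_power_on_spiked_features(self):
        m = two_group_matrix(100, n_features=500, n_spiked=50, log2fc=2.0, noise_sd=0.1)
        res = differential(m, [("treatment", "control")])
        tab = res.for_contrast("treatment_vs_control")
        spiked = [f"f{i}" for i in range(50)]
        assert tab.loc[spiked, "significant"].mean() >= 0.95

    def test_fold_change_rule(self):
        # tiny but highly reproducible shift: below the effect-size cutoff
        m = two_group_matrix(7, n_features=300, n_spiked=40, log2fc=0.5, noise_sd=0.02)
        res = differential(m, [("treatment", "control")])
        tab = res.for_contrast("treatment_vs_control")
        small = tab[(tab["p_adj"] < 1e-4) & (tab["log2_fc"].abs() < np.log2(1.5))]
        assert len(small) > 0
        assert not small["significant"].any()

    def test_unknown_contrast_level(self):
        m = two_group_matrix(8)
        with pytest.raises(ValueError, match="absent"):
            differential(m, [("treatment", "vehicle")])

    def test_moderated_t_converges_to_ordinary_t(self):
        # heteroscedastic features: with growing per-group sample size the
        # data term dominates the squeezed variance and the moderated t
        # approaches the ordinary t
        rng = np.random.default_rng(9)
        n_feat, n_rep = 300, 200
        channels = [f"ctl_r{i}" for i in range(n_rep)] + [f"trt_r{i}" for i in range(n_rep)]
        design = SampleDesign(
            pd.DataFrame(
                {"condition": ["control"] * n_rep + ["treatment"] * n_rep},
                index=pd.Index(channels, name="channel"),
            )
        )
        sds = rng.uniform(0.05, 1.0, (n_feat, 1))
        values = rng.normal(10, 1.5, (n_feat, 1)) + rng.normal(0, sds, (n_feat, 2 * n_rep))
        m = IntensityMatrix(
            pd.DataFrame(values, columns=channels, index=[f"f{i}" for i in range(n_feat)]),
            design,
            scale="log2",
        )
        res = differential(m, [("treatment", "control")], covariates=())
        tab = res.for_contrast("treatment_vs_control")
        a, b = values[:, n_rep:], values[:, :n_rep]
        pooled = ((a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2)
        ordinary_t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(pooled * 2 / n_rep)
        rel = np.abs(tab["t"].to_numpy() - ordinary_t) / np.abs(ordinary_t)
        assert np.median(rel) < 0.01

    def test_replicate_covariate_absorbs_batch(self):
        m = two_group_matrix(11, n_features=200, noise_sd=0.1)
        v = m.values.copy()
        # replicate r2 channels get a +3 batch shift in both groups
        v[["ctl_r2", "trt_r2"]] += 3.0
        res = differential(m.with_values(v), [("treatment", "control")])
        assert res.table["significant"].mean() < 0.02


class TestSqueezeVariances:
    def test_posterior_between_prior_and_observed(self):
        rng = np.random.default_rng(12)
        df = 4
        s2 = rng.chisquare(df, 500) / df * 0.25
        post, df_prior, s2_prior = squeeze_variances(s2, df)
        assert df_prior > 0 and s2_prior > 0
        lo = np.minimum(s2, s2_prior) - 1e-12
        hi = np.maximum(s2, s2_prior) + 1e-12
        assert np.all((post >= lo) & (post <= hi))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_moderated_statistics_match_limma(tmp_path):
    """Independent oracle: Bioconductor limma on the same matrix."""
    rng = np.random.default_rng(42)
    n_feat, n_rep = 80, 3
    base = rng.normal(8, 1, (n_feat, 1))
    sds = rng.uniform(0.05, 0.5, (n_feat, 1))
    Y = base + rng.normal(0, sds, (n_feat, 2 * n_rep))
    Y[:10, n_rep:] += 1.0
    mat_path = tmp_path / "mat.tsv"
    pd.DataFrame(Y).to_csv(mat_path, sep="\t", index=False)
    out_path = tmp_path / "limma_out.tsv"
    r_code = textwrap.dedent(
        f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.delim("{mat_path}"))
        design <- model.matrix(~0 + factor(c("a","a","a","b","b","b")))
        colnames(design) <- c("a","b")
        fit <- lmFit(m, design)
        fit <- contrasts.fit(fit, makeContrasts(b-a, levels=design))
        fit <- eBayes(fit)
        out <- data.frame(lfc=fit$coefficients[,1], t=fit$t[,1], p=fit$p.value[,1])
        write.table(out, "{out_path}", sep="\\t", row.names=FALSE)
        """
    )
    script = tmp_path / "limma.R"
    script.write_text(r_code)
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    ref = pd.read_csv(out_path, sep="\t")
    channels = [f"c{i}" for i in range(2 * n_rep)]
    design = SampleDesign(
        pd.DataFrame({"condition": ["a"] * n_rep + ["b"] * n_rep}, index=pd.Index(channels, name="channel"))
    )
    m = IntensityMatrix(
        pd.DataFrame(Y, columns=channels, index=[f"f{i}" for i in range(n_feat)]),
        design,
        scale="log2",
    )
    res = differential(m, [("b", "a")], covariates=())
    tab = res.for_contrast("b_vs_a")
    np.testing.assert_allclose(tab["log2_fc"].to_numpy(), ref["lfc"].to_numpy(), atol=1e-9)
    np.testing.assert_allclose(tab["t"].to_numpy(), ref["t"].to_numpy(), rtol=0.02)
    np.testing.assert_allclose(tab["p_raw"].to_numpy(), ref["p"].to_numpy(), atol=0.01)
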