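import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_design, make_matrix
from ncpanel.panel_io import CountMatrix, GeneSet
from ncpanel.scoring import (
    celltype_qc,
    celltype_score,
    covariate_t,
    directed_gss,
    gss_table,
    pathway_score,
    score_pathways,
    undirected_gss,
)


class TestPathwayScore:
    def test_rank_one_set_aligns_with_expression(self):
        v = np.array([1.0, -1.0, 3.0, 0.0, 2.0, -5.0])
        m = make_matrix({f"g{i}": 10 + (i + 1) * v for i in range(4)})
        res = pathway_score(m, GeneSet("s", [f"g{i}" for i in range(4)]))
        centered = v - v.mean()
        corr = np.corrcoef(res.scores, centered)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-10)
        assert res.pc1_var_frac == pytest.approx(1.0, abs=1e-12)

    def test_scores_average_to_zero(self, rng):
        for _ in range(5):
            m = make_matrix({f"g{i}": rng.normal(5, 2, size=12) for i in range(6)})
            res = pathway_score(m, GeneSet("s", [f"g{i}" for i in range(6)]))
            assert abs(res.scores.sum()) < 1e-10

    def test_matches_pca_oracle_up_to_sign(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        m = make_matrix({f"g{i}": rng.normal(size=12) for i in range(6)})
        res = pathway_score(m, GeneSet("s", [f"g{i}" for i in range(6)]))
        x = m.values.to_numpy().T
        ref = SkPCA(n_components=1).fit_transform(x - x.mean(axis=0)).ravel()
        dev = min(np.abs(res.scores.to_numpy() - ref).max(),
                  np.abs(res.scores.to_numpy() + ref).max())
        assert dev < 1e-8

    def test_invariant_under_reordering_and_constant_shift(self, rng):
        data = {f"g{i}": rng.normal(size=8) for i in range(5)}
        m1 = make_matrix(data)
        shuffled = {k: data[k] for k in reversed(list(data))}
        shuffled["g0"] = shuffled["g0"] + 7.5  # constant per-gene shift
        m2 = make_matrix(shuffled)
        s1 = pathway_score(m1, GeneSet("s", list(data)))
        s2 = pathway_score(m2, GeneSet("s", list(data)))
        np.testing.assert_allclose(s1.scores, s2.scores, atol=1e-10)

    def test_raising_one_sample_raises_its_score(self, rng):
        base = {f"g{i}": rng.normal(8, 1, size=10) for i in range(6)}
        m1 = make_matrix(base)
        bumped = {g: v.copy() for g, v in base.items()}
        for g in bumped:
            bumped[g][3] += 0.8
        m2 = make_matrix(bumped)
        gs = GeneSet("s", list(base))
        s1 = pathway_score(m1, gs).scores.iloc[3]
        s2 = pathway_score(m2, gs).scores.iloc[3]
        assert s2 > s1

    def test_too_few_measured_genes_skipped_with_report(self, rng):
        m = make_matrix({f"g{i}": rng.normal(size=6) for i in range(6)})
        sets = [GeneSet("big", [f"g{i}" for i in range(6)]),
                GeneSet("small", ["g0", "g1", "missing1", "missing2"])]
        res = score_pathways(m, sets, min_genes=5)
        assert list(res.scores.index) == ["big"]
        assert "small" in res.skipped


class TestCovariateT:
    def test_pure_shift_gives_huge_positive_t(self):
        design = make_design()
        values = {s: [3.0 + (1.0 if design.group_key(s)[0] == "APP" else 0.0)
                      + 0.001 * i]
                  for i, s in enumerate(design.samples)}
        m = CountMatrix(pd.DataFrame(values, index=["g"]), scale="log2")
        t = covariate_t(m, design, "APP")
        assert t["g"] > 100

    def test_matches_ols_oracle(self, rng):
        import statsmodels.api as sm

        design = make_design()
        data = rng.normal(size=(15, 12))
        m = CountMatrix(pd.DataFrame(data, index=[f"g{i}" for i in range(15)],
                                     columns=design.samples), scale="log2")
        t_app = covariate_t(m, design, "APP")
        t_arg = covariate_t(m, design, "Arg1")
        X = sm.add_constant(np.column_stack([
            design.indicator("APP").to_numpy(),
            design.indicator("Arg1").to_numpy(),
        ]))
        for i, g in enumerate(m.genes):
            fit = sm.OLS(data[i], X).fit()
            assert t_app[g] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert t_arg[g] == pytest.approx(fit.tvalues[2], abs=1e-8)

    def test_null_t_centered_at_zero(self):
        design = make_design()
        rng = np.random.default_rng(123)
        data = rng.normal(size=(1000, 12))
        m = CountMatrix(pd.DataFrame(data, index=[f"g{i}" for i in range(1000)],
                                     columns=design.samples), scale="log2")
        t = covariate_t(m, design, "APP")
        assert abs(t.mean()) < 0.1

    def test_confounded_design_rejected(self):
        df = pd.DataFrame(
            {"APP": ["nTg", "nTg", "APP", "APP"],
             "Arg1": ["Arg1_suff", "Arg1_suff", "Arg1_insuff", "Arg1_insuff"]},
            index=[f"s{i}" for i in range(4)],
        )
        from ncpanel.panel_io import DesignTable

        design = DesignTable(df, ("APP", "Arg1"),
                             {"APP": ("nTg", "APP"),
                              "Arg1": ("Arg1_suff", "Arg1_insuff")})
        m = CountMatrix(pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)),
                                     index=["g1", "g2", "g3"],
                                     columns=df.index), scale="log2")
        with pytest.raises(ValueError, match="aliased|single level"):
            covariate_t(m, design, "APP")


class TestGss:
    def test_single_zero_t(self):
        gs = GeneSet("s", ["g1"])
        assert directed_gss({"g1": 0.0}, gs) == 0.0

    def test_signed_mean_square_example(self):
        gs = GeneSet("s", ["g1", "g2"])
        t = {"g1": 3.0, "g2": -1.0}
        assert directed_gss(t, gs) == pytest.approx(2.0)
        assert undirected_gss(t, gs) == pytest.approx(np.sqrt(5))

    def test_antisymmetric_pair_cancels(self):
        gs = GeneSet("s", ["g1", "g2"])
        assert directed_gss({"g1": 2.0, "g2": -2.0}, gs) == 0.0

    def test_single_negative_t_magnitude(self):
        gs = GeneSet("s", ["g1"])
        assert undirected_gss({"g1": -4.0}, gs) == 4.0

    def test_no_measured_genes_rejected(self):
        with pytest.raises(ValueError):
            directed_gss({"other": 1.0}, GeneSet("s", ["g1"]))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=20))
    def test_directed_bounded_by_undirected(self, tvals):
        gs = GeneSet("s", [f"g{i}" for i in range(len(tvals))])
        t = {f"g{i}": v for i, v in enumerate(tvals)}
        assert abs(directed_gss(t, gs)) <= undirected_gss(t, gs) + 1e-9

    def test_equality_iff_one_sign(self):
        gs = GeneSet("s", ["g1", "g2"])
        same = {"g1": 2.0, "g2": 3.0}
        mixed = {"g1": 2.0, "g2": -3.0}
        assert directed_gss(same, gs) == pytest.approx(undirected_gss(same, gs))
        assert abs(directed_gss(mixed, gs)) < undirected_gss(mixed, gs)


class TestGssTable:
    def test_flags_consistent_with_cutoff(self, sim_default):
        from ncpanel import panel, qc_normalize as qcn

        matrix, design, _ = sim_default
        gn = qcn.genorm_select(matrix.of_class("Housekeeping"), 6)
        log2m = qcn.normalize(matrix, gn)
        table = gss_table(log2m, design, panel.default_pathways())
        for _, row in table.iterrows():
            d = row["directed_gss"]
            expected = "up" if d >= 1.3 else ("down" if d <= -1.3 else "")
            assert row["flag"] == expected
            assert abs(d) <= row["undirected_gss"] + 1e-9

    def test_spiked_sets_flagged_up_for_their_factor(self, sim_default):
        from ncpanel import panel, qc_normalize as qcn

        matrix, design, truth = sim_default
        gn = qcn.genorm_select(matrix.of_class("Housekeeping"), 6)
        log2m = qcn.normalize(matrix, gn)
        table = gss_table(log2m, design, panel.default_pathways())
        app = table[table["covariate"] == "APP"].set_index("gene_set")
        for name in truth.spiked_sets["APP"]:
            assert app.loc[name, "flag"] == "up"


class TestCellTypes:
    def test_score_is_marker_mean(self):
        m = make_matrix({"a": [4.0, 8.0], "b": [6.0, 2.0], "c": [0.0, 0.0]})
        s = celltype_score(m, GeneSet("ct", ["a", "b"]))
        np.testing.assert_allclose(s, [5.0, 5.0])

    def test_single_marker_score_is_that_gene(self):
        m = make_matrix({"a": [4.0, 8.0], "b": [6.0, 2.0]})
        s = celltype_score(m, GeneSet("ct", ["a"]))
        np.testing.assert_allclose(s, [4.0, 8.0])

    def test_mean_oracle_on_random_markers(self, rng):
        data = {f"g{i}": rng.normal(size=6) for i in range(10)}
        m = make_matrix(data)
        markers = [f"g{i}" for i in range(7)]
        s = celltype_score(m, GeneSet("ct", markers))
        ref = np.mean([data[g] for g in markers], axis=0)
        np.testing.assert_allclose(s, ref, atol=1e-12)

    def test_perfectly_correlated_markers_get_minimal_p(self, rng):
        profile = rng.normal(size=10)
        data = {f"m{i}": profile + 0.01 * rng.normal(size=10) for i in range(5)}
        data.update({f"bg{i}": rng.normal(size=10) for i in range(40)})
        m = make_matrix(data)
        prof = celltype_qc(m, GeneSet("ct", [f"m{i}" for i in range(5)]),
                           n_random=999, seed=1)
        assert prof.qc_p == pytest.approx(1 / 1000)
        assert prof.mean_marker_corr > 0.99

    def test_single_marker_flagged_undefined(self, rng):
        m = make_matrix({f"g{i}": rng.normal(size=6) for i in range(5)})
        prof = celltype_qc(m, GeneSet("ct", ["g0"]))
        assert prof.qc_p == 1.0
        assert prof.qc_flag

    def test_null_markers_give_calibrated_p(self):
        # markers drawn from the same distribution as background: p ~ uniform
        rng = np.random.default_rng(2024)
        n_rep = 500
        ps = []
        for _ in range(n_rep):
            data = {f"g{i}": rng.normal(size=8) for i in range(24)}
            m = make_matrix(data)
            prof = celltype_qc(m, GeneSet("ct", [f"g{i}" for i in range(4)]),
                               n_random=99, seed=rng)
            ps.append(prof.qc_p)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.05)
        # validity at the 5% level, allowing 3σ binomial fluctuation
        bound = 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert np.mean(np.asarray(ps) <= 0.05) <= bound


class TestUnivariateCovariateT:
    def test_univariate_t_equals_two_group_pooled_t(self, rng):
        from scipy import stats as sps

        design = make_design()
        data = rng.normal(size=(8, 12))
        m = CountMatrix(pd.DataFrame(data, index=[f"g{i}" for i in range(8)],
                                     columns=design.samples), scale="log2")
        t = covariate_t(m, design, "APP", adjust=False)
        app = [s for s in design.samples if design.group_key(s)[0] == "APP"]
        ntg = [s for s in design.samples if design.group_key(s)[0] == "nTg"]
        for g in m.genes:
            t_ref, _ = sps.ttest_ind(m.values.loc[g, app], m.values.loc[g, ntg],
                                     equal_var=True)
            assert t[g] == pytest.approx(t_ref, abs=1e-10)
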