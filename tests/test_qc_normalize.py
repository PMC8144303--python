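import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from ncpanel.panel_io import CountMatrix, SampleLane
from ncpanel.qc_normalize import (
    QCThresholds,
    background_threshold,
    filter_background,
    genorm_select,
    lane_qc,
    normalize,
    pos_control_r2,
)

POS_TITRATION = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


def make_lane(fov=100.0, bd=1.0, pos_counts=None, neg_counts=None, sample_id="L1"):
    pos_counts = pos_counts or {c: 40 * c for c in POS_TITRATION}
    neg_counts = neg_counts if neg_counts is not None else [5] * 8
    counts, classes = {}, {}
    for i, (c, v) in enumerate(pos_counts.items()):
        name = f"POS_{chr(65+i)}({c:g})"
        counts[name] = int(v)
        classes[name] = "Positive"
    for i, v in enumerate(neg_counts):
        name = f"NEG_{chr(65+i)}"
        counts[name] = int(v)
        classes[name] = "Negative"
    counts["G1"] = 100
    classes["G1"] = "Endogenous"
    return SampleLane(sample_id, counts, fov, bd, classes)


class TestPosControlR2:
    def test_exact_power_law_gives_one(self):
        counts = {c: 10 * c for c in POS_TITRATION}
        assert pos_control_r2(counts) == pytest.approx(1.0, abs=1e-12)

    def test_flat_response_gives_zero(self):
        assert pos_control_r2({c: 50 for c in POS_TITRATION}) == 0.0

    def test_matches_least_squares_oracle(self):
        counts = {128: 1200, 32: 300, 8: 80, 2: 22, 0.5: 6, 0.125: 2}
        x = np.log2(np.array(list(counts), dtype=float))
        y = np.log2(np.array(list(counts.values()), dtype=float))
        r_oracle = np.corrcoef(x, y)[0, 1] ** 2
        assert pos_control_r2(counts) == pytest.approx(r_oracle, abs=1e-10)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            counts = dict(zip(POS_TITRATION, rng.integers(0, 5000, size=6)))
            assert 0.0 <= pos_control_r2(counts) <= 1.0

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            pos_control_r2({1.0: 5, 2.0: 10})


class TestLaneQC:
    def test_clean_lane_passes_everything(self):
        report = lane_qc([make_lane(fov=100, bd=1.0)])
        row = report.table.iloc[0]
        assert row[["fov_pass", "bd_pass", "poslin_pass", "lod_pass"]].all()
        assert row["overall_pass"]

    def test_binding_density_above_range_fails(self):
        report = lane_qc([make_lane(bd=2.5)])
        row = report.table.iloc[0]
        assert not row["bd_pass"] and not row["overall_pass"]

    def test_binding_density_bounds_inclusive(self):
        for bd in (0.1, 2.25):
            assert lane_qc([make_lane(bd=bd)]).table.iloc[0]["bd_pass"]

    def test_fov_rule_strict_at_threshold(self):
        assert not lane_qc([make_lane(fov=75.0)]).table.iloc[0]["fov_pass"]

    def test_lod_needs_strict_exceedance(self):
        pos = {c: 40 * c for c in POS_TITRATION}
        pos[0.5] = 4
        report = lane_qc([make_lane(pos_counts=pos, neg_counts=[4] * 8)])
        row = report.table.iloc[0]
        assert not row["lod_pass"]  # 4 is not > mean 4 + 2·SD 0

    def test_lane_without_controls_rejected(self):
        lane = SampleLane("L1", {"G1": 5}, 100, 1.0, {"G1": "Endogenous"})
        with pytest.raises(ValueError):
            lane_qc([lane])


class TestBackgroundThreshold:
    def test_zero_spread_returns_mean(self):
        assert background_threshold([5] * 8) == 5.0

    def test_sample_sd_convention(self):
        # mean 5, sample SD sqrt(20/3) = 2.581989
        assert background_threshold([2, 4, 6, 8]) == pytest.approx(10.163978, abs=1e-5)

    def test_all_zero_controls(self):
        assert background_threshold([0, 0]) == 0.0

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            background_threshold([5])


class TestFilterBackground:
    def make(self, rows):
        return make_matrix(rows, scale="raw")

    def test_gene_below_in_three_quarters_removed(self):
        m = self.make({"g": [3, 3, 3, 12]})
        assert filter_background(m, 10).removed == ["g"]

    def test_half_is_kept_boundary(self):
        m = self.make({"g": [3, 3, 12, 12]})
        bf = filter_background(m, 10)
        assert bf.kept == ["g"] and bf.removed == []

    def test_zero_threshold_keeps_all(self, sim_default):
        matrix, _, _ = sim_default
        bf = filter_background(matrix, 0)
        assert bf.removed == []

    def test_controls_never_filtered(self, sim_default):
        matrix, _, _ = sim_default
        bf = filter_background(matrix, 1e9)
        classes = matrix.code_classes.loc[bf.removed]
        assert set(classes) <= {"Endogenous", "Housekeeping"}
        assert sorted(bf.kept + bf.removed) == sorted(
            matrix.of_class("Endogenous", "Housekeeping").genes)

    def test_raising_threshold_never_grows_kept_set(self, rng):
        m = self.make({f"g{i}": rng.integers(0, 30, size=6) for i in range(40)})
        previous = None
        for thr in (0, 5, 10, 20, 40):
            kept = set(filter_background(m, thr).kept)
            if previous is not None:
                assert kept <= previous
            previous = kept


class TestGeNorm:
    def test_noisy_candidate_removed_first(self):
        # A and B are exact scalar multiples: their pairwise ratio SD is 0
        m = make_matrix(
            {"A": [10, 20, 40], "B": [20, 40, 80], "C": [10, 50, 11]}, scale="raw"
        )
        res = genorm_select(m, n_select=2)
        assert res.removal_order == ["C"]
        assert res.stability["A"] == pytest.approx(res.stability["B"], abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        counts = rng.integers(10, 1000, size=(4, 5))
        genes = [f"hk{i}" for i in range(4)]
        m = CountMatrix(pd.DataFrame(counts, index=genes,
                                     columns=[f"s{j}" for j in range(5)]), scale="raw")
        res = genorm_select(m, n_select=4)

        logs = np.log2(counts.astype(float))
        for j, g in enumerate(genes):
            vs = [np.std(logs[j] - logs[k], ddof=1) for k in range(4) if k != j]
            assert res.stability[g] == pytest.approx(np.mean(vs), abs=1e-10)

    def test_select_all_removes_nothing(self):
        m = make_matrix({"A": [10, 20], "B": [20, 41], "C": [5, 9]}, scale="raw")
        res = genorm_select(m, n_select=3)
        assert sorted(res.selected) == ["A", "B", "C"]
        assert res.removal_order == []

    def test_sample_permutation_invariance(self, rng):
        counts = rng.integers(10, 1000, size=(5, 6))
        genes = [f"hk{i}" for i in range(5)]
        cols = [f"s{j}" for j in range(6)]
        m1 = CountMatrix(pd.DataFrame(counts, index=genes, columns=cols), scale="raw")
        perm = rng.permutation(6)
        m2 = CountMatrix(pd.DataFrame(counts[:, perm], index=genes,
                                      columns=[cols[j] for j in perm]), scale="raw")
        r1, r2 = genorm_select(m1, 3), genorm_select(m2, 3)
        for g in genes:
            assert r1.stability[g] == pytest.approx(r2.stability[g], abs=1e-12)
        assert r1.selected == r2.selected

    def test_too_few_candidates_rejected(self):
        m = make_matrix({"A": [1, 2], "B": [2, 3]}, scale="raw")
        with pytest.raises(ValueError):
            genorm_select(m, n_select=3)


def hk_result(selected):
    from ncpanel.qc_normalize import GeNormResult

    return GeNormResult(stability={}, selected=selected, removal_order=[])


class TestNormalize:
    def base_matrix(self, col_a, col_b=None):
        cols = {"s1": col_a, "s2": col_b if col_b is not None else col_a}
        genes = ["g1", "g2", "hk1", "hk2", "POS_A(128)", "POS_B(32)", "NEG_A"]
        classes = dict(zip(genes, ["Endogenous"] * 2 + ["Housekeeping"] * 2
                           + ["Positive"] * 2 + ["Negative"]))
        df = pd.DataFrame(cols, index=genes)
        return CountMatrix(df, scale="raw", code_classes=pd.Series(classes))

    def test_identical_lanes_stay_identical(self):
        m = self.base_matrix([100, 50, 200, 300, 1000, 400, 5])
        out = normalize(m, hk_result(["hk1", "hk2"]))
        assert out.scale == "log2"
        np.testing.assert_allclose(out.values["s1"], out.values["s2"])
        assert set(out.code_classes) <= {"Endogenous", "Housekeeping"}

    def test_doubled_lane_normalizes_back(self):
        a = [100, 50, 200, 300, 1000, 400, 5]
        m = self.base_matrix(a, [2 * v for v in a])
        out = normalize(m, hk_result(["hk1", "hk2"]))
        np.testing.assert_allclose(out.values["s1"], out.values["s2"], rtol=1e-12)

    def test_all_ones_give_log2_of_offset_plus_one(self):
        m = self.base_matrix([1] * 7)
        out = normalize(m, hk_result(["hk1", "hk2"]), pos_norm=False)
        np.testing.assert_allclose(out.values.to_numpy(), np.log2(1.5))

    def test_zero_housekeeping_without_offset_rejected(self):
        m = self.base_matrix([100, 50, 0, 300, 1000, 400, 5])
        with pytest.raises(ValueError):
            normalize(m, hk_result(["hk1", "hk2"]), offset=0.0)

    def test_per_lane_scalar_invariance(self, sim_default):
        matrix, _, _ = sim_default
        sub = matrix.values.iloc[:, :4].copy()
        scaled = (sub * pd.Series([1, 2, 4, 8], index=sub.columns)).astype(int)
        m1 = CountMatrix(sub, "raw", matrix.code_classes)
        m2 = CountMatrix(scaled, "raw", matrix.code_classes)
        hk = hk_result(["Aars", "Lars"])
        out1 = normalize(m1, hk, pos_norm=False)
        out2 = normalize(m2, hk, pos_norm=False)
        # lane scaling is absorbed up to one global log2 shift (offset aside)
        diff = (out2.values - out1.values).to_numpy()
        keep = out1.values.to_numpy() > 5  # offset negligible above ~32 counts
        assert np.ptp(diff[keep]) < 0.02


def test_qc_thresholds_validated():
    with pytest.raises(ValueError):
        QCThresholds(bd_min=3.0, bd_max=2.0)
    with pytest.raises(ValueError):
        QCThresholds(poslin_r2_min=0.0)


def test_per_lane_background_thresholds(sim_default):
    from ncpanel.qc_normalize import background_thresholds_per_lane

    matrix, _, _ = sim_default
    per_lane = background_thresholds_per_lane(matrix)
    neg = matrix.of_class("Negative").values
    for s in matrix.samples:
        ref = neg[s].mean() + 2 * neg[s].std(ddof=1)
        assert per_lane[s] == pytest.approx(ref, abs=1e-10)
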