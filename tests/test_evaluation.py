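import numpy as np
import pandas as pd
import pytest

from netblocks.diffusion import TransientEstimate
from netblocks.errors import EvaluationError, GraphDomainError
from netblocks.evaluation import (
    EvalReport,
    RegressionConfig,
    build_feature_table,
    evaluate_prediction,
    feature_vector,
    motif_mse,
    rank_and_select,
)
from netblocks.motifs import FrequencyVariant, build_census
from netblocks.samplers import SamplerSpec, draw_sample

from conftest import connected_er_graph


class TestMotifMse:
    def test_identical_vectors(self):
        v = np.array([0.2, 0.8])
        assert motif_mse(v, v).raw == 0.0

    def test_orthogonal_unit_vectors(self):
        d = motif_mse(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert d.raw == 2.0 and d.mean == 1.0

    def test_hand_arithmetic(self):
        d = motif_mse(np.array([0.7, 0.3]), np.array([0.5, 0.5]))
        assert d.raw == pytest.approx(0.08)
        assert d.mean == pytest.approx(0.04)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.random(6), rng.random(6)
            assert motif_mse(a, b).raw == pytest.approx(motif_mse(b, a).raw)
            assert motif_mse(a, b).raw >= 0.0

    def test_zero_iff_equal(self):
        a = np.array([0.5, 0.5])
        b = np.array([0.5, 0.5 + 1e-9])
        assert motif_mse(a, b).raw > 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(GraphDomainError):
            motif_mse(np.ones(2), np.ones(3))


def make_rows(n_hosts, reps, feature_fn, tau_fn, seed=0, k=4):
    """Feature table built through the real sample/census path."""
    samples, censuses, taus = [], {}, {}
    rng = np.random.default_rng(seed)
    for h in range(n_hosts):
        host_id = f"h{h:02d}"
        g = connected_er_graph(60, 0.1, seed=200 + h)
        taus[host_id] = TransientEstimate(tau_fn(h), 0.0, 1, 0)
        for _ in range(reps):
            s = draw_sample(g, SamplerSpec(method="RN", target_size=20,
                                           rng_seed=int(rng.integers(2**31))),
                            host_id=host_id)
            censuses[len(samples)] = build_census(s.subgraph, k)
            samples.append(s)
    return build_feature_table(samples, censuses, taus)


class TestFeatureTable:
    def test_feature_vector_length_k4(self):
        g = connected_er_graph(30, 0.2, seed=1)
        vec = feature_vector(build_census(g, 4), FrequencyVariant.JOINT_RATIO)
        assert len(vec) == 7  # 6 classes + disjoint-total scalar

    def test_row_count(self):
        rows = make_rows(2, 1, None, lambda h: 5.0 + h)
        assert len(rows) == 2
        assert set(rows["host_id"]) == {"h00", "h01"}

    def test_all_zero_sample_flagged(self):
        import networkx as nx

        from netblocks.samplers import SampleResult

        sparse = nx.Graph()
        sparse.add_nodes_from("abcd")
        spec = SamplerSpec(method="RN", target_size=4)
        sample = SampleResult(subgraph=sparse, spec=spec, actual_size=4,
                              host_id="h")
        table = build_feature_table(
            [sample], {0: build_census(sparse, 4)},
            {"h": TransientEstimate(3.0, 0.0, 1, 0)},
        )
        assert bool(table["all_zero"].iloc[0])

    def test_missing_tau_named_in_error(self):
        g = connected_er_graph(30, 0.2, seed=2)
        s = draw_sample(g, SamplerSpec(method="RN", target_size=10), host_id="orphan")
        with pytest.raises(EvaluationError, match="orphan"):
            build_feature_table([s], {0: build_census(s.subgraph, 4)}, {})


class TestEvaluatePrediction:
    def test_leaked_target_is_recovered(self):
        # enough rows that boosted trees can resolve the leaked feature
        rows = make_rows(60, 5, None, lambda h: float(h))
        rows = rows.copy()
        rows["f0"] = rows["target_tau"]  # leak the target into a feature
        r2 = evaluate_prediction(rows, RegressionConfig(model_seed=0))
        assert r2 >= 0.99

    def test_permuted_targets_have_no_skill(self):
        rows = make_rows(10, 3, None, lambda h: float(h))
        rng = np.random.default_rng(1)
        scores = []
        for _ in range(10):
            shuffled = rows.copy()
            shuffled["target_tau"] = rng.permutation(shuffled["target_tau"].to_numpy())
            scores.append(evaluate_prediction(shuffled, RegressionConfig(model_seed=0)))
        assert np.mean(scores) <= 0.1

    def test_constant_target_rejected(self):
        rows = make_rows(10, 2, None, lambda h: 7.0)
        with pytest.raises(EvaluationError):
            evaluate_prediction(rows, RegressionConfig())

    def test_too_few_rows_rejected(self):
        rows = make_rows(3, 1, None, lambda h: float(h))
        with pytest.raises(EvaluationError):
            evaluate_prediction(rows, RegressionConfig())

    def test_reproducible_under_seed(self):
        rows = make_rows(8, 3, None, lambda h: float(h) ** 1.5)
        cfg = RegressionConfig(model_seed=11)
        assert evaluate_prediction(rows, cfg) == evaluate_prediction(rows, cfg)

    def test_linear_baseline_runs(self):
        rows = make_rows(8, 3, None, lambda h: float(h))
        cfg = RegressionConfig(model="linear")
        assert evaluate_prediction(rows, cfg) <= 1.0


def build_report(mse, r2):
    report = EvalReport()
    report.mse_table = mse
    report.r2_table = r2
    return report


class TestRankAndSelect:
    sizes = [10, 20, 30, 40, 50]

    def test_dominant_method_selected(self):
        mse, r2 = {}, {}
        for s in self.sizes:
            mse[("A", s, "JOINT_RATIO")] = 0.01
            r2[("A", s, "JOINT_RATIO")] = 0.9
            mse[("B", s, "JOINT_RATIO")] = 0.05
            r2[("B", s, "JOINT_RATIO")] = 0.2
        method, _ = rank_and_select(build_report(mse, r2), self.sizes)
        assert method == "A"

    def test_plateau_after_thirty(self):
        mse, r2 = {}, {}
        mse_curve = {10: 0.10, 20: 0.05, 30: 0.02, 40: 0.019, 50: 0.0185}
        r2_curve = {10: 0.10, 20: 0.40, 30: 0.70, 40: 0.71, 50: 0.72}
        for s in self.sizes:
            mse[("A", s, "JOINT_RATIO")] = mse_curve[s]
            r2[("A", s, "JOINT_RATIO")] = r2_curve[s]
        method, size = rank_and_select(build_report(mse, r2), self.sizes)
        assert (method, size) == ("A", 30)

    def test_disjoint_top_lists_fall_back_to_best_r2(self, caplog):
        # 10 methods with exactly opposite orderings: top-5 lists disjoint
        mse, r2 = {}, {}
        for i in range(10):
            name = f"M{i}"
            mse[(name, 10, "V")] = float(i)        # best delta: M0..M4
            r2[(name, 10, "V")] = float(i) / 10.0  # best R2: M9..M5
        with caplog.at_level("WARNING"):
            method, _ = rank_and_select(build_report(mse, r2), [10])
        assert method == "M9"
        assert any("disjoint" in r.message for r in caplog.records)

    def test_empty_report_rejected(self):
        with pytest.raises(EvaluationError):
            rank_and_select(EvalReport(), [10])

    def test_first_common_method_wins(self):
        # C is ranked 2nd by delta and 2nd by R2; A and B split the firsts
        mse = {("A", 10, "V"): 0.01, ("C", 10, "V"): 0.02, ("B", 10, "V"): 0.03}
        r2 = {("B", 10, "V"): 0.9, ("C", 10, "V"): 0.8, ("A", 10, "V"): 0.1}
        method, _ = rank_and_select(build_report(mse, r2), [10])
        assert method == "C"
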