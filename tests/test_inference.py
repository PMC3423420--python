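import numpy as np
import pytest

from temponet import (
    InferenceConfig,
    SmoothnessIndicator,
    TransitionNetworkModel,
    TransitionSeries,
    WindowWeighting,
    export_network,
    fit_bcd,
    fit_qp_oracle,
    lambda_max,
    objective,
    window_weight,
)
from conftest import random_instance


def brute_force_objective(series, data, cfg):
    """Independent triple-loop evaluation of the combined objective."""
    mats = series.matrices
    n_tr = len(mats)
    loss = 0.0
    for v in data:
        for s in range(n_tr):
            for t in range(s, min(s + cfg.window.delta, n_tr - 1) + 1):
                w = window_weight(t, s, cfg.window)
                resid = v[:, t + 1] - mats[s] @ v[:, t]
                loss += w * float(resid @ resid)
    loss /= len(data)
    m = cfg.indicator.matrix(n_tr)
    smooth = 0.0
    for a in range(n_tr):
        for b in range(a + 1, n_tr):
            smooth += m[a, b] * float(np.sum((mats[a] - mats[b]) ** 2))
    l1 = sum(float(np.abs(w).sum()) for w in mats)
    return loss, smooth, l1, loss + cfg.lambda1 * smooth + cfg.lambda2 * l1


class TestWindowWeight:
    def test_center_weight_is_one(self):
        assert window_weight(3, 3, WindowWeighting(delta=2)) == 1.0

    def test_gaussian_unit_offset(self):
        w = window_weight(4, 3, WindowWeighting(delta=2, sigma=1.0))
        assert w == pytest.approx(np.exp(-0.5))

    def test_window_covers_offsets_zero_to_delta(self):
        win = WindowWeighting(delta=2)
        weights = [window_weight(3 + d, 3, win) for d in range(-1, 4)]
        assert weights[0] == 0.0  # backward frames excluded
        assert all(w > 0 for w in weights[1:4])
        assert weights[4] == 0.0  # beyond delta

    def test_weights_non_increasing_within_window(self):
        win = WindowWeighting(delta=3, sigma=0.8)
        ws = [window_weight(d, 0, win) for d in range(4)]
        assert all(a >= b for a, b in zip(ws, ws[1:]))


class TestObjective:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            data = random_instance(rng)
            cfg = InferenceConfig(
                lambda1=float(rng.uniform(0, 1)),
                lambda2=float(rng.uniform(0, 1)),
                window=WindowWeighting(delta=int(rng.integers(0, 3))),
            )
            series = TransitionSeries([rng.standard_normal((3, 3)) for _ in range(3)])
            terms = objective(series, data, cfg)
            loss, smooth, l1, total = brute_force_objective(series, data, cfg)
            assert terms.loss == pytest.approx(loss, rel=1e-10)
            assert terms.smoothness == pytest.approx(smooth, rel=1e-10)
            assert terms.sparsity == pytest.approx(l1, rel=1e-10)
            assert terms.total == pytest.approx(total, rel=1e-10)

    def test_zero_series_loss_is_weighted_signal_energy(self):
        rng = np.random.default_rng(1)
        data = random_instance(rng, n_templates=2, n_times=3, n_samples=3)
        cfg = InferenceConfig(window=WindowWeighting(delta=1))
        series = TransitionSeries.zeros(2, 2)
        terms = objective(series, data, cfg)
        expected = brute_force_objective(series, data, cfg)[0]
        assert terms.loss == pytest.approx(expected)
        assert terms.smoothness == 0.0
        assert terms.sparsity == 0.0

    def test_exact_model_noiseless_zero_loss(self):
        rng = np.random.default_rng(2)
        mats = [rng.standard_normal((3, 3)) * 0.5 for _ in range(2)]
        data = []
        for _ in range(4):
            v = np.empty((3, 3))
            v[:, 0] = rng.standard_normal(3)
            for t in range(2):
                v[:, t + 1] = mats[t] @ v[:, t]
            data.append(v)
        cfg = InferenceConfig(window=WindowWeighting(delta=0))
        terms = objective(TransitionSeries(mats), data, cfg)
        # evaluated through sufficient statistics, so zero only up to
        # floating-point cancellation of O(1) quantities
        assert terms.total == pytest.approx(0.0, abs=1e-10)

    def test_sparsity_contribution_arithmetic(self):
        series = TransitionSeries([np.array([[1.5, 0.0], [0.0, -2.0]])])
        data = [np.zeros((2, 2))]
        cfg = InferenceConfig(lambda2=2.0)
        terms = objective(series, data, cfg)
        assert terms.sparsity == pytest.approx(3.5)
        assert cfg.lambda2 * terms.sparsity == pytest.approx(7.0)


class TestFitBCD:
    def test_noiseless_recovery_matches_per_transition_least_squares(self):
        """At lambda1=0, tiny lambda2 and delta=0 the fit reduces to OLS."""
        rng = np.random.default_rng(3)
        k, t, n = 2, 3, 8
        mats = [rng.standard_normal((k, k)) for _ in range(t - 1)]
        mats = [np.where(np.abs(m) > 0.8, m, 0.0) for m in mats]
        data = []
        for _ in range(n):
            v = np.empty((k, t))
            v[:, 0] = rng.standard_normal(k)
            for s in range(t - 1):
                v[:, s + 1] = mats[s] @ v[:, s]
            data.append(v)
        cfg = InferenceConfig(
            lambda1=0.0, lambda2=1e-4, window=WindowWeighting(delta=0),
            tol_outer=1e-12, tol_inner=1e-13, max_cycles=2000,
        )
        res = fit_bcd(data, cfg)
        # independent closed-form oracle: normal equations per transition
        arr = np.stack(data)
        for s in range(t - 1):
            x = arr[:, :, s]
            y = arr[:, :, s + 1]
            ols = np.linalg.lstsq(x, y, rcond=None)[0].T
            assert np.linalg.norm(res.series.matrices[s] - ols) < 1e-2

    def test_lambda_max_forces_exact_zero(self):
        rng = np.random.default_rng(4)
        data = random_instance(rng)
        cfg = InferenceConfig(lambda1=0.1)
        lmax = lambda_max(data, cfg)
        res = fit_bcd(data, InferenceConfig(lambda1=0.1, lambda2=lmax))
        assert res.series.l1_norm() == 0.0
        # just below lambda_max the solution is no longer identically zero
        res2 = fit_bcd(data, InferenceConfig(lambda1=0.1, lambda2=0.99 * lmax))
        assert res2.series.l1_norm() > 0.0

    def test_huge_smoothness_equalizes_blocks(self):
        rng = np.random.default_rng(5)
        data = random_instance(rng, n_templates=2, n_times=4, n_samples=6)
        # warm start along the path: with strong coupling the consensus mode
        # moves O(1/lambda1) per cold-started cycle
        start = None
        for lam1 in (1.0, 1e2, 1e4, 1e6):
            cfg = InferenceConfig(
                lambda1=lam1, lambda2=0.0, tol_outer=1e-12, tol_inner=1e-13,
                max_cycles=5000,
            )
            model = TransitionNetworkModel(data, cfg)
            res = model.fit(start=start)
            start = res.series
        w = res.params
        scale = max(np.linalg.norm(w[s]) for s in range(w.shape[0]))
        for a in range(w.shape[0]):
            for b in range(a + 1, w.shape[0]):
                assert np.linalg.norm(w[a] - w[b]) <= 1e-4 * max(scale, 1e-12)

    def test_objective_history_monotone_non_increasing(self):
        rng = np.random.default_rng(6)
        data = random_instance(rng, n_templates=4, n_times=4, n_samples=5)
        cfg = InferenceConfig(lambda1=0.3, lambda2=0.2)
        res = fit_bcd(data, cfg)
        hist = np.array(res.objective_history)
        assert np.all(np.diff(hist) <= 1e-10 * (1 + np.abs(hist[:-1])))

    def test_l1_norm_non_increasing_in_lambda2(self):
        rng = np.random.default_rng(7)
        data = random_instance(rng, n_templates=3, n_times=4, n_samples=6)
        norms = []
        for lam2 in [0.0, 0.01, 0.1, 0.5, 1.0, 2.0]:
            res = fit_bcd(data, InferenceConfig(
                lambda1=0.1, lambda2=lam2, tol_outer=1e-10, tol_inner=1e-12))
            norms.append(res.series.l1_norm())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        data = random_instance(rng, n_templates=4, n_times=4, n_samples=6)
        cfg = InferenceConfig(lambda1=0.2, lambda2=0.1,
                              tol_outer=1e-12, tol_inner=1e-13, max_cycles=3000)
        perm = np.array([2, 0, 3, 1])
        res = fit_bcd(data, cfg)
        res_p = fit_bcd([d[perm] for d in data], cfg)
        for w, wp in zip(res.series.matrices, res_p.series.matrices):
            np.testing.assert_allclose(wp, w[np.ix_(perm, perm)], atol=1e-6)

    def test_non_convergence_is_flagged_not_raised(self):
        rng = np.random.default_rng(9)
        data = random_instance(rng)
        cfg = InferenceConfig(lambda1=10.0, lambda2=0.01,
                              tol_outer=1e-15, max_cycles=1)
        res = fit_bcd(data, cfg)
        assert res.converged is False


class TestOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_bcd_matches_joint_oracle(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        t = int(rng.integers(3, 5))
        n = int(rng.integers(2, 9))
        data = [rng.standard_normal((k, t)) for _ in range(n)]
        cfg = InferenceConfig(
            lambda1=float(10 ** rng.uniform(-2, 0)),
            lambda2=float(10 ** rng.uniform(-2, 0)),
            tol_outer=1e-12, tol_inner=1e-13, max_cycles=5000,
        )
        rb = fit_bcd(data, cfg)
        ro = fit_qp_oracle(data, cfg)
        gap = abs(rb.objective.total - ro.objective.total)
        assert gap <= 1e-6 * (1 + abs(ro.objective.total))

    def test_unregularized_oracle_matches_normal_equations(self):
        rng = np.random.default_rng(20)
        k, t, n = 3, 3, 6
        data = [rng.standard_normal((k, t)) for _ in range(n)]
        cfg = InferenceConfig(lambda1=0.0, lambda2=0.0,
                              window=WindowWeighting(delta=0))
        ro = fit_qp_oracle(data, cfg)
        arr = np.stack(data)
        for s in range(t - 1):
            ols = np.linalg.lstsq(arr[:, :, s], arr[:, :, s + 1], rcond=None)[0].T
            np.testing.assert_allclose(ro.series.matrices[s], ols, atol=1e-6)

    def test_zero_data_zero_solution(self):
        data = [np.zeros((2, 3)) for _ in range(3)]
        ro = fit_qp_oracle(data, InferenceConfig(lambda1=0.1, lambda2=0.1))
        assert ro.series.l1_norm() == 0.0

    def test_size_limit(self):
        rng = np.random.default_rng(21)
        data = [rng.standard_normal((30, 4))]
        with pytest.raises(ValueError, match="oracle"):
            fit_qp_oracle(data, InferenceConfig())


class TestSmoothnessIndicator:
    def test_hard_indicator_structure(self):
        m = SmoothnessIndicator(kind="hard", radius=1).matrix(4)
        expected = np.array(
            [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]], float
        )
        np.testing.assert_array_equal(m, expected)

    def test_soft_indicator_decays_with_distance(self):
        m = SmoothnessIndicator(kind="soft", tau=1.0).matrix(4)
        assert np.all(np.diag(m) == 0)
        assert m[0, 1] == pytest.approx(np.exp(-1.0))
        assert m[0, 2] == pytest.approx(np.exp(-4.0))
        np.testing.assert_array_equal(m, m.T)


class TestExport:
    def test_zero_series_empty_edges(self, tmp_path):
        rng = np.random.default_rng(22)
        data = random_instance(rng)
        res = fit_bcd(data, InferenceConfig(lambda2=100.0))
        assert res.series.l1_norm() == 0.0
        path = export_network(res, tmp_path / "edges.tsv")
        assert len(path.read_text().strip().splitlines()) == 1  # header only

    def test_single_edge_attributes(self):
        rng = np.random.default_rng(23)
        data = random_instance(rng, n_templates=4)
        res = fit_bcd(data, InferenceConfig(lambda2=100.0))
        res.series.matrices[0][1, 2] = 0.8  # template3 -> template2 at t=1
        edges = res.to_edge_frame(1e-3)
        assert len(edges) == 1
        row = edges.iloc[0]
        assert (row.source, row.target, row.transition) == ("template_3", "template_2", 1)
        assert row.weight == pytest.approx(0.8)
        assert row.sign == "+"

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(24)
        data = random_instance(rng)
        res = fit_bcd(data, InferenceConfig(lambda2=0.05))
        strict = res.to_edge_frame(1e-3)
        loose = res.to_edge_frame(0.0)
        key = ["source", "target", "transition"]
        strict_set = set(map(tuple, strict[key].itertuples(index=False)))
        loose_set = set(map(tuple, loose[key].itertuples(index=False)))
        assert strict_set <= loose_set

    def test_formats_roundtrip(self, tmp_path):
        import networkx as nx

        rng = np.random.default_rng(25)
        data = random_instance(rng)
        res = fit_bcd(data, InferenceConfig(lambda2=0.05))
        n_edges = len(res.to_edge_frame(1e-3))
        sif = export_network(res, tmp_path / "net.sif", fmt="sif")
        assert len(sif.read_text().strip().splitlines()) == n_edges
        gml = export_network(res, tmp_path / "net.graphml", fmt="graphml")
        g = nx.read_graphml(gml)
        assert g.number_of_edges() == n_edges

    def test_unknown_format_rejected(self, tmp_path):
        rng = np.random.default_rng(26)
        res = fit_bcd(random_instance(rng), InferenceConfig())
        with pytest.raises(ValueError, match="format"):
            export_network(res, tmp_path / "x", fmt="dot")
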