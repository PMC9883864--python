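import numpy as np
import pytest

from lncloc import model_meta as mm
from lncloc.graph import build_similarity_graph, extract_local_graphs

from conftest import random_local_graphs


class QuarticToy:
    """L(theta) = 0.5 theta'A theta + b.theta + (c/4) sum(theta^4).

    Non-constant Hessian for c > 0, so curvature products are exercised
    beyond the quadratic case.  A batch is the tuple (A, b, c).
    """

    def loss_and_grad(self, params, batch):
        a, b, c = batch
        th = params[0]
        loss = 0.5 * th @ a @ th + b @ th + 0.25 * c * np.sum(th**4)
        grad = a @ th + b + c * th**3
        return float(loss), [grad]


def _toy_task(seed=0, c=1.0):
    rng = np.random.default_rng(seed)
    def spd():
        m = rng.normal(size=(2, 2))
        return m @ m.T + np.eye(2)
    support = (spd(), rng.normal(size=2), c)
    query = (spd(), rng.normal(size=2), c)
    return mm.Task(np.array([0]), np.array([1])), support, query


class _TaskToy(QuarticToy):
    """QuarticToy with batches looked up by index so Task machinery applies."""

    def __init__(self, batches):
        self.batches = batches

    def loss_and_grad(self, params, batch):
        key = int(np.asarray(batch).ravel()[0])
        return super().loss_and_grad(params, self.batches[key])


class TestNormalizeAdjacency:
    def test_isolated_node(self):
        _, locals_ = random_local_graphs(np.random.default_rng(0), n_nodes=3, tau=0.999)
        iso = [lg for lg in locals_ if lg.n_nodes == 1]
        if not iso:  # force an isolated ego by taking any single-node slice
            pytest.skip("no isolated node at this threshold")
        assert np.allclose(mm.normalize_adjacency(iso[0]), [[1.0]])

    def test_two_connected_nodes(self):
        g, locals_ = random_local_graphs(np.random.default_rng(1), n_nodes=2, tau=-1.0)
        a_hat = mm.normalize_adjacency(locals_[0])
        assert np.allclose(a_hat, 0.5)

    def test_regular_graph_row_sums(self):
        # ring (degree 2 everywhere): with self-loops every row sums to 1
        from lncloc.graph import LocalGraph

        g, locals_ = random_local_graphs(np.random.default_rng(2), n_nodes=6, tau=-1.0)
        n = 6
        ring_edges = np.array([[i, (i + 1) % n] for i in range(n)])
        ring = LocalGraph(center=int(locals_[0].members[0]),
                          members=locals_[0].members[:n],
                          edges=ring_edges, graph=g)
        a_hat = mm.normalize_adjacency(ring)
        assert np.allclose(a_hat.sum(axis=1), 1.0)


class TestGcnForward:
    def test_matches_dense_matrix_oracle(self):
        """Spec propagation rule recomputed independently on random graphs."""
        rng = np.random.default_rng(3)
        for trial in range(50):
            n = int(rng.integers(2, 9))
            g, locals_ = random_local_graphs(rng, n_nodes=n, dim=5,
                                             tau=float(rng.uniform(0.2, 0.9)))
            config = mm.GcnConfig(layer_dims=(5, 4, 3))
            params = mm.init_gcn_params(config, rng)
            lg = locals_[int(rng.integers(0, n))]
            out = mm.gcn_forward(lg, params, config)
            # independent recomputation of sigma(D'^-1/2 A' D'^-1/2 X W)
            m = lg.n_nodes
            a = np.zeros((m, m))
            for u, v in lg.edges:
                a[u, v] = a[v, u] = 1.0
            a += np.eye(m)
            d = np.diag(1.0 / np.sqrt(a.sum(axis=1)))
            a_hat = d @ a @ d
            h = np.maximum(a_hat @ lg.X @ params[0], 0.0)
            z = a_hat @ h @ params[1]
            e = np.exp(z - z.max(axis=1, keepdims=True))
            expected = e / e.sum(axis=1, keepdims=True)
            assert np.allclose(out, expected, atol=1e-6)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        g, locals_ = random_local_graphs(rng, n_nodes=6, dim=5, tau=0.3)
        config = mm.GcnConfig(layer_dims=(5, 4, 3))
        out = mm.gcn_forward(locals_[0], mm.init_gcn_params(config, rng), config)
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_shape_mismatch_errors(self):
        rng = np.random.default_rng(5)
        g, locals_ = random_local_graphs(rng, n_nodes=4, dim=5, tau=0.3)
        config = mm.GcnConfig(layer_dims=(9, 4, 3))
        with pytest.raises(ValueError, match="dimension"):
            mm.gcn_forward(locals_[0], mm.init_gcn_params(config, rng), config)


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(6)
    g, locals_ = random_local_graphs(rng, n_nodes=15, dim=6, tau=0.5)
    config = mm.GcnConfig(layer_dims=(6, 5, 3))
    model = mm.GcnEpisodeModel(
        locals_, config, class_names=["0", "1", "2"], normalize_features=False
    )
    params = mm.init_gcn_params(config, rng)
    return model, locals_, config, params


class TestGcnEpisodeModel:
    def test_batched_path_matches_reference_forward(self, setup):
        model, locals_, config, params = setup
        probs = model.predict_proba(params, np.arange(len(locals_)))
        for i, lg in enumerate(locals_):
            ref = mm.gcn_forward(lg, params, config)[0]
            assert np.allclose(probs[i], ref, atol=1e-10)

    def test_analytic_gradient_matches_finite_differences(self, setup):
        model, locals_, _config, params = setup
        batch = np.arange(8)
        _, grads = model.loss_and_grad(params, batch)
        rng = np.random.default_rng(7)
        eps = 1e-6
        for layer in range(2):
            for _ in range(6):
                i = int(rng.integers(params[layer].shape[0]))
                j = int(rng.integers(params[layer].shape[1]))
                p_hi = [w.copy() for w in params]
                p_lo = [w.copy() for w in params]
                p_hi[layer][i, j] += eps
                p_lo[layer][i, j] -= eps
                hi, _ = model.loss_and_grad(p_hi, batch)
                lo, _ = model.loss_and_grad(p_lo, batch)
                fd = (hi - lo) / (2 * eps)
                assert grads[layer][i, j] == pytest.approx(fd, abs=1e-5)

    def test_loss_matches_center_cross_entropy(self, setup):
        model, locals_, config, params = setup
        batch = np.arange(5)
        loss, _ = model.loss_and_grad(params, batch)
        ce = 0.0
        for i in batch:
            probs = mm.gcn_forward(locals_[i], params, config)[0]
            ce -= np.log(probs[model.y[i]])
        assert loss == pytest.approx(ce / len(batch), abs=1e-10)

    def test_dropout_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        g, locals_ = random_local_graphs(rng, n_nodes=10, dim=6, tau=0.4)
        config = mm.GcnConfig(layer_dims=(6, 5, 3), dropout=0.4)
        model = mm.GcnEpisodeModel(locals_, config, class_names=["0", "1", "2"])
        params = mm.init_gcn_params(config, rng)
        l1, _ = model.loss_and_grad(params, np.arange(6), dropout_seed=11)
        l2, _ = model.loss_and_grad(params, np.arange(6), dropout_seed=11)
        l3, _ = model.loss_and_grad(params, np.arange(6), dropout_seed=12)
        assert l1 == l2 and l1 != l3


class TestSampleTasks:
    def _labels(self, counts):
        labels = []
        for c, n in counts.items():
            labels.extend([c] * n)
        return np.array(labels, dtype=object)

    def test_task_sizes_five_way_one_shot(self):
        labels = self._labels({c: 10 for c in "ABCDE"})
        tasks = mm.sample_tasks(labels, mm.EpisodeConfig(m=3, k_support=1, k_query=1), 0)
        assert len(tasks) == 3
        for t in tasks:
            assert len(t.support) + len(t.query) == 10
            assert len(t.support) == 5 and len(t.query) == 5

    def test_task_sizes_three_support_two_query(self):
        labels = self._labels({c: 10 for c in "ABCDE"})
        (task,) = mm.sample_tasks(labels, mm.EpisodeConfig(m=1, k_support=3, k_query=2), 1)
        assert len(task.support) == 15 and len(task.query) == 10

    def test_support_query_disjoint_and_stratified(self):
        labels = self._labels({"A": 8, "B": 8})
        (task,) = mm.sample_tasks(labels, mm.EpisodeConfig(m=1, k_support=2, k_query=3), 2)
        assert not set(task.support) & set(task.query)
        for part, per_class in ((task.support, 2), (task.query, 3)):
            counts = {c: sum(labels[i] == c for i in part) for c in "AB"}
            assert counts == {"A": per_class, "B": per_class}

    def test_insufficient_class_errors_with_name(self):
        labels = self._labels({"A": 5, "Tiny": 1})
        with pytest.raises(ValueError, match="Tiny"):
            mm.sample_tasks(labels, mm.EpisodeConfig(m=1, k_support=1, k_query=1), 0)

    def test_deterministic_under_seed(self):
        labels = self._labels({"A": 9, "B": 9})
        cfg = mm.EpisodeConfig(m=4, k_support=2, k_query=2)
        t1 = mm.sample_tasks(labels, cfg, 5)
        t2 = mm.sample_tasks(labels, cfg, 5)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.support, b.support)
            assert np.array_equal(a.query, b.query)


class TestInnerAdapt:
    def test_zero_steps_returns_input(self):
        toy = QuarticToy()
        _, support, _ = _toy_task(0)
        params = [np.array([1.0, -2.0])]
        meta = mm.MetaConfig(inner_lr=0.1, outer_lr=0.1, inner_steps=0,
                             meta_iterations=1)
        adapted = mm.inner_adapt(toy, params, support, meta)
        assert np.array_equal(adapted[0], params[0])
        params[0][0] = 99.0  # adapted must be a copy
        assert adapted[0][0] != 99.0

    def test_single_step_closed_form_on_quadratic(self):
        """L = 0.5||theta - t||^2 gives theta + lr (t - theta) after one step."""
        target = np.array([3.0, -1.0])
        toy = QuarticToy()
        batch = (np.eye(2), -target, 0.0)  # grad = theta - target
        params = [np.array([0.5, 0.5])]
        meta = mm.MetaConfig(inner_lr=0.2, outer_lr=0.1, inner_steps=1,
                             meta_iterations=1)
        adapted = mm.inner_adapt(toy, params, batch, meta)
        expected = params[0] + 0.2 * (target - params[0])
        assert np.allclose(adapted[0], expected)

    def test_descent_on_support_loss(self):
        toy = QuarticToy()
        meta = mm.MetaConfig(inner_lr=0.05, outer_lr=0.1, inner_steps=5,
                             meta_iterations=1)
        for seed in range(20):
            _, support, _ = _toy_task(seed)
            params = [np.random.default_rng(seed).normal(size=2)]
            before, _ = toy.loss_and_grad(params, support)
            after, _ = toy.loss_and_grad(mm.inner_adapt(toy, params, support, meta),
                                         support)
            assert after <= before + 1e-12


class TestMetaGradient:
    def test_zero_inner_steps_degenerates_to_query_gradient(self):
        toy = QuarticToy()
        task, support, query = _toy_task(1)
        model = _TaskToy({0: support, 1: query})
        params = [np.array([0.7, -0.3])]
        meta = mm.MetaConfig(inner_lr=0.1, outer_lr=0.1, inner_steps=0,
                             meta_iterations=1, order="second")
        loss, grads = mm.meta_gradient(model, params, task, meta)
        plain_loss, plain_grads = model.loss_and_grad(params, np.array([1]))
        assert loss == pytest.approx(plain_loss)
        assert np.allclose(grads[0], plain_grads[0], atol=1e-5)

    @pytest.mark.parametrize("inner_steps", [1, 3])
    @pytest.mark.parametrize("c", [0.0, 1.0])
    def test_second_order_matches_central_finite_differences(self, inner_steps, c):
        """Outer gradient vs finite differences of the composite objective
        F(theta) = L_query(theta after inner adaptation)."""
        toy = QuarticToy()
        task, support, query = _toy_task(2, c=c)
        model = _TaskToy({0: support, 1: query})
        params = [np.array([0.4, -0.8])]
        meta = mm.MetaConfig(inner_lr=0.07, outer_lr=0.1, inner_steps=inner_steps,
                             meta_iterations=1, order="second")
        _, grads = mm.meta_gradient(model, params, task, meta)

        def objective(theta_vec):
            adapted = mm.inner_adapt(model, [theta_vec], np.array([0]), meta)
            loss, _ = model.loss_and_grad(adapted, np.array([1]))
            return loss

        eps = 1e-6
        for i in range(2):
            hi = params[0].copy(); hi[i] += eps
            lo = params[0].copy(); lo[i] -= eps
            fd = (objective(hi) - objective(lo)) / (2 * eps)
            assert grads[0][i] == pytest.approx(fd, abs=1e-4)

    def test_first_order_drops_curvature_terms(self):
        toy = QuarticToy()
        task, support, query = _toy_task(3, c=1.0)
        model = _TaskToy({0: support, 1: query})
        params = [np.array([0.4, -0.8])]
        second = mm.MetaConfig(inner_lr=0.1, outer_lr=0.1, inner_steps=2,
                               meta_iterations=1, order="second")
        first = mm.MetaConfig(inner_lr=0.1, outer_lr=0.1, inner_steps=2,
                              meta_iterations=1, order="first")
        _, g2 = mm.meta_gradient(model, params, task, second)
        _, g1 = mm.meta_gradient(model, params, task, first)
        assert not np.allclose(g1[0], g2[0])


class TestMetaTrain:
    def _episodes(self, n_tasks=2, seed=4):
        batches, tasks = {}, []
        for t in range(n_tasks):
            _, support, query = _toy_task(seed + t, c=0.0)
            batches[2 * t] = support
            batches[2 * t + 1] = query
            tasks.append(mm.Task(np.array([2 * t]), np.array([2 * t + 1])))
        return _TaskToy(batches), tasks

    def test_zero_inner_steps_equals_plain_gradient_descent(self):
        model, tasks = self._episodes(1)
        meta = mm.MetaConfig(inner_lr=0.1, outer_lr=0.05, inner_steps=0,
                             meta_iterations=10, seed=0)
        theta, log = mm.meta_train(model, lambda rng: tasks[:1],
                                   [np.array([1.0, 1.0])], meta)
        # plain gradient descent on the query loss
        ref = np.array([1.0, 1.0])
        for _ in range(10):
            _, g = model.loss_and_grad([ref], tasks[0].query)
            ref = ref - 0.05 * g[0]
        assert np.allclose(theta[0], ref, atol=1e-12)

    def test_query_loss_decreases_on_quadratic_episodes(self):
        model, tasks = self._episodes(2)
        meta = mm.MetaConfig(inner_lr=0.05, outer_lr=0.02, inner_steps=2,
                             meta_iterations=10, seed=1)
        _, log = mm.meta_train(model, lambda rng: tasks,
                               [np.array([2.0, -2.0])], meta)
        losses = [entry["query_loss"] for entry in log]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_seeded_repetition_is_bit_identical(self):
        model, tasks = self._episodes(2)
        meta = mm.MetaConfig(inner_lr=0.05, outer_lr=0.02, inner_steps=1,
                             meta_iterations=5, seed=7)
        run = lambda: mm.meta_train(model, lambda rng: tasks,
                                    [np.array([1.0, 0.5])], meta)
        t1, l1 = run()
        t2, l2 = run()
        assert np.array_equal(t1[0], t2[0])
        assert l1 == l2

    def test_divergence_raises(self):
        model, tasks = self._episodes(1)
        meta = mm.MetaConfig(inner_lr=0.01, outer_lr=1e4, inner_steps=0,
                             meta_iterations=500, seed=0)
        with pytest.raises(mm.MetaDivergenceError):
            mm.meta_train(model, lambda rng: tasks[:1], [np.array([1.0, 1.0])], meta)


class TestSplitDataset:
    def _labels(self):
        return np.array(["A"] * 50 + ["B"] * 30 + ["C"] * 20, dtype=object)

    def test_fractions_disjoint_exhaustive(self):
        labels = self._labels()
        train, val, test = mm.split_dataset(labels, (0.8, 0.1, 0.1), seed=0)
        assert len(train) == 80 and len(val) == 10 and len(test) == 10
        union = np.concatenate([train, val, test])
        assert len(set(union)) == 100

    def test_stratification_within_one_sample(self):
        labels = self._labels()
        train, val, test = mm.split_dataset(labels, (0.6, 0.2, 0.2), seed=1)
        for part, frac in ((train, 0.6), (val, 0.2), (test, 0.2)):
            for c, n_c in (("A", 50), ("B", 30), ("C", 20)):
                got = sum(labels[i] == c for i in part)
                assert abs(got - frac * n_c) < 1.0 + 1e-9

    def test_fold_mode(self):
        labels = self._labels()
        train, val, test = mm.split_dataset(labels, seed=2, folds=10, fold_index=3)
        assert len(test) == 10
        assert not set(test) & (set(train) | set(val))
        assert len(train) + len(val) + len(test) == 100

    def test_deterministic(self):
        labels = self._labels()
        s1 = mm.split_dataset(labels, seed=5)
        s2 = mm.split_dataset(labels, seed=5)
        for a, b in zip(s1, s2):
            assert np.array_equal(a, b)

    def test_empty_split_errors(self):
        labels = np.array(["A"] * 5 + ["B"] * 5, dtype=object)
        with pytest.raises(ValueError, match="empty"):
            mm.split_dataset(labels, (0.98, 0.01, 0.01), seed=0)


@pytest.fixture(scope="module")
def separable_model():
    """Two orthogonal-feature classes: ego graphs are class-pure cliques."""
    rng = np.random.default_rng(9)
    n_per = 12
    feats = np.vstack([
        np.tile([1.0, 0.0], (n_per, 1)) + rng.normal(0, 0.02, (n_per, 2)),
        np.tile([0.0, 1.0], (n_per, 1)) + rng.normal(0, 0.02, (n_per, 2)),
    ])
    labels = ["up"] * n_per + ["down"] * n_per
    g = build_similarity_graph(feats, labels, tau=0.9)
    return mm.GcnEpisodeModel(extract_local_graphs(g),
                              mm.GcnConfig(layer_dims=(2, 4, 2)))


class TestFineTuneAndEvaluate:
    def test_memorization_on_separable_data(self, separable_model):
        model = separable_model
        task = mm.Task(np.arange(0, 24, 2), np.arange(1, 24, 2))
        meta = mm.MetaConfig(inner_lr=1.0, outer_lr=0.1, inner_steps=0,
                             meta_iterations=1, fine_tune_steps=60, seed=0)
        init = model.init_params(np.random.default_rng(3))
        report = mm.fine_tune_and_evaluate(model, task, init, meta)
        assert report.accuracy == 1.0

    def test_zero_fine_tune_steps_uses_theta_directly(self, separable_model):
        model = separable_model
        task = mm.Task(np.arange(0, 24, 2), np.arange(1, 24, 2))
        meta = mm.MetaConfig(inner_lr=1.0, outer_lr=0.1, inner_steps=3,
                             meta_iterations=1, fine_tune_steps=0, seed=0)
        theta = model.init_params(np.random.default_rng(4))
        report = mm.fine_tune_and_evaluate(model, task, theta, meta)
        direct = model.predict(theta, task.query)
        expected_acc = float(np.mean(direct == model.true_labels(task.query)))
        assert report.accuracy == pytest.approx(expected_acc)

    def test_query_mask_restricts_scoring(self, separable_model):
        model = separable_model
        task = mm.Task(np.arange(0, 24, 2), np.arange(1, 24, 2))
        meta = mm.MetaConfig(inner_lr=1.0, outer_lr=0.1, inner_steps=0,
                             meta_iterations=1, fine_tune_steps=60, seed=0)
        init = model.init_params(np.random.default_rng(3))
        mask = np.zeros(len(task.query), dtype=bool)
        mask[:4] = True
        report = mm.fine_tune_and_evaluate(model, task, init, meta, query_mask=mask)
        assert report.accuracy == 1.0  # still perfect on the restricted set


class TestWarmStartAdvantage:
    def test_meta_initialization_reaches_target_loss_in_fewer_steps(
        self, tiny_labeled_features
    ):
        """Fine-tuning from theta' should need no more gradient steps than
        training from a random initialization to hit the same loss."""
        X, labels = tiny_labeled_features
        g = build_similarity_graph(X, labels, tau=0.5)
        model = mm.GcnEpisodeModel(extract_local_graphs(g))
        y = np.array(labels, dtype=object)
        episode = mm.EpisodeConfig(m=2, k_support=2, k_query=2)
        meta = mm.MetaConfig(inner_lr=0.5, outer_lr=0.05, inner_steps=1,
                             meta_iterations=15, seed=0)
        rng = np.random.default_rng(0)
        sampler = lambda r: mm.sample_tasks(y, episode, rng)
        init = model.init_params(np.random.default_rng(1))
        theta, _ = mm.meta_train(model, sampler, init, meta)
        batch = mm.sample_tasks(y, mm.EpisodeConfig(m=1, k_support=4, k_query=4),
                                99)[0].support
        target = 0.9  # below ln(3) chance loss

        def steps_to_target(params):
            curve = mm.adaptation_curve(model, params, batch, lr=0.5, steps=50)
            hits = [i for i, l in enumerate(curve) if l <= target]
            return hits[0] if hits else len(curve)

        warm = steps_to_target(theta)
        cold = np.mean([
            steps_to_target(model.init_params(np.random.default_rng(s)))
            for s in range(2, 7)
        ])
        assert warm <= cold
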