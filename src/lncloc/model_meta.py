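"""Graph-convolutional classifier trained with model-agnostic meta-learning.

The classifier is a two-layer GCN over each sample's ego graph with a
center-node readout: layer l computes sigma(A_hat H W_l) with
A_hat = D'^(-1/2) A' D'^(-1/2), A' = A + I, and the center row of the final
softmax is the sample's class distribution.  Forward and backward passes are
written directly in numpy; per-sample ego graphs share one global feature
matrix, so a batch costs two large matrix products (X W1 and X^T dP) plus
cheap sparse propagation per graph.

Meta-learning follows the MAML regime: a task is a support/query split of
sampled ego graphs; the inner loop adapts parameters on the support set by
plain gradient descent; the outer loop updates the shared initialization
from the summed post-adaptation query losses.  The second-order meta-gradient
back-propagates through the inner updates using Hessian-vector products
evaluated by central finite differences of the analytic gradient; a
first-order switch drops those curvature terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import scipy.sparse as sp

from .graph import LocalGraph

__all__ = [
    "GcnConfig",
    "MetaConfig",
    "EpisodeConfig",
    "Task",
    "MetaDivergenceError",
    "normalize_adjacency",
    "gcn_forward",
    "init_gcn_params",
    "GcnEpisodeModel",
    "hvp_fd",
    "inner_adapt",
    "meta_gradient",
    "meta_train",
    "fine_tune_and_evaluate",
    "adaptation_curve",
    "sample_tasks",
    "split_dataset",
]

Params = list[np.ndarray]


class MetaDivergenceError(RuntimeError):
    """Raised when training produces a non-finite loss."""


# --------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class GcnConfig:
    """Layer widths and nonlinearity of the GCN.

    ``layer_dims`` runs input -> hidden(s) -> number of classes.  The episode
    trainer supports the two-layer form (one hidden layer, default width 64);
    :func:`gcn_forward` accepts any depth.
    """

    layer_dims: tuple[int, ...]
    activation: str = "relu"
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if len(self.layer_dims) < 2:
            raise ValueError("layer_dims needs at least input and output")
        if any(d <= 0 for d in self.layer_dims):
            raise ValueError("layer_dims must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class MetaConfig:
    """Inner/outer loop hyperparameters.

    Defaults are conventional few-shot settings, not values tuned to any
    particular dataset; expect to adjust the learning rates and iteration
    count to the task at hand.  ``inner_steps = 0`` degenerates meta-training
    to plain gradient descent on the query loss.  ``order`` selects the full
    second-order meta-gradient or its first-order approximation.
    """

    inner_lr: float = 0.01
    outer_lr: float = 0.001
    inner_steps: int = 5
    meta_iterations: int = 1000
    order: str = "second"
    seed: int = 0
    fine_tune_steps: int | None = None  # defaults to inner_steps

    def __post_init__(self) -> None:
        if self.inner_lr <= 0 or self.outer_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.inner_steps < 0:
            raise ValueError("inner_steps must be non-negative")
        if self.meta_iterations <= 0:
            raise ValueError("meta_iterations must be positive")
        if self.order not in ("first", "second"):
            raise ValueError("order must be 'first' or 'second'")


@dataclass(frozen=True)
class EpisodeConfig:
    """Task shape: m tasks per meta-batch, k_support/k_query shots per class."""

    m: int = 8
    k_support: int = 5
    k_query: int = 5

    def __post_init__(self) -> None:
        if min(self.m, self.k_support, self.k_query) < 1:
            raise ValueError("m, k_support and k_query must be >= 1")

    def task_size(self, num_classes: int) -> int:
        return num_classes * (self.k_support + self.k_query)


@dataclass(frozen=True)
class Task:
    """Support/query split of pool indices; disjoint within the task."""

    support: np.ndarray
    query: np.ndarray

    def __post_init__(self) -> None:
        if set(map(int, self.support)) & set(map(int, self.query)):
            raise ValueError("support and query sets must be disjoint")


# --------------------------------------------------------------------------
# GCN forward (reference, per-graph dense)

_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


def normalize_adjacency(local: LocalGraph) -> np.ndarray:
    """Symmetrically normalized self-looped adjacency D'^(-1/2) A' D'^(-1/2)."""
    n = local.n_nodes
    a = np.zeros((n, n))
    for u, v in local.edges:
        a[u, v] = 1.0
        a[v, u] = 1.0
    a_prime = a + np.eye(n)
    inv_sqrt = 1.0 / np.sqrt(a_prime.sum(axis=1))
    return a_prime * inv_sqrt[:, None] * inv_sqrt[None, :]


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def gcn_forward(
    local: LocalGraph, params: Params, config: GcnConfig
) -> np.ndarray:
    """Per-node class probabilities for one ego graph (rows sum to 1).

    Reference implementation: explicit dense propagation through every layer.
    Row 0 (the center) is the sample's prediction.
    """
    if local.X.shape[1] != config.layer_dims[0]:
        raise ValueError(
            f"feature dimension {local.X.shape[1]} != layer_dims[0] "
            f"{config.layer_dims[0]}"
        )
    act, _ = _ACTIVATIONS[config.activation]
    a_hat = normalize_adjacency(local)
    h = local.X
    for w in params[:-1]:
        h = act(a_hat @ h @ w)
    return _softmax_rows(a_hat @ h @ params[-1])


def init_gcn_params(config: GcnConfig, rng: np.random.Generator) -> Params:
    """Glorot-uniform weight matrices chained along layer_dims."""
    params = []
    dims = config.layer_dims
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        bound = np.sqrt(6.0 / (d_in + d_out))
        params.append(rng.uniform(-bound, bound, size=(d_in, d_out)))
    return params


# --------------------------------------------------------------------------
# episodic GCN model (fast batched path over shared features)


class EpisodeModel(Protocol):
    """Anything MAML can train: a differentiable loss over index batches."""

    def loss_and_grad(self, params: Params, batch) -> tuple[float, Params]: ...


class GcnEpisodeModel:
    """Two-layer GCN over a pool of ego graphs sharing one feature matrix.

    The sample loss is the cross-entropy of the center node's softmax row
    against the center's compartment label; a batch averages over its
    samples.  Row-normalizing the global feature matrix (on by default) puts
    k-mer frequency vectors on the unit sphere, which keeps pre-activation
    scales independent of sequence length and feature dimension.
    """

    def __init__(
        self,
        local_graphs: Sequence[LocalGraph],
        config: GcnConfig | None = None,
        class_names: Sequence[str] | None = None,
        normalize_features: bool = True,
    ):
        if not local_graphs:
            raise ValueError("need at least one local graph")
        parent = local_graphs[0].graph
        self.local_graphs = list(local_graphs)
        self.features = np.array(parent.features, dtype=float)
        if normalize_features:
            norms = np.linalg.norm(self.features, axis=1, keepdims=True)
            norms[norms == 0.0] = 1.0
            self.features = self.features / norms
        labels = [lg.label for lg in local_graphs]
        if class_names is None:
            class_names = sorted(set(labels))
        self.class_names = list(class_names)
        index = {c: i for i, c in enumerate(self.class_names)}
        self.y = np.array([index[l] for l in labels], dtype=int)
        if config is None:
            config = GcnConfig(
                layer_dims=(self.features.shape[1], 64, len(self.class_names))
            )
        if len(config.layer_dims) != 3:
            raise ValueError("GcnEpisodeModel supports exactly two layers")
        if config.layer_dims[0] != self.features.shape[1]:
            raise ValueError("layer_dims[0] must equal the feature dimension")
        if config.layer_dims[-1] != len(self.class_names):
            raise ValueError("layer_dims[-1] must equal the number of classes")
        self.config = config
        self._act, self._act_grad = _ACTIVATIONS[config.activation]
        # Precompute each ego graph's normalized adjacency once (sparse).
        self._members: list[np.ndarray] = []
        self._a_hat: list[sp.csr_matrix] = []
        for lg in local_graphs:
            n = lg.n_nodes
            if len(lg.edges):
                u, v = lg.edges[:, 0], lg.edges[:, 1]
                rows = np.concatenate([u, v, np.arange(n)])
                cols = np.concatenate([v, u, np.arange(n)])
            else:
                rows = cols = np.arange(n)
            a = sp.csr_matrix(
                (np.ones(len(rows)), (rows, cols)), shape=(n, n)
            )
            inv_sqrt = 1.0 / np.sqrt(np.asarray(a.sum(axis=1)).ravel())
            d = sp.diags(inv_sqrt)
            self._a_hat.append((d @ a @ d).tocsr())
            self._members.append(np.asarray(lg.members, dtype=int))

    def init_params(self, rng: np.random.Generator) -> Params:
        return init_gcn_params(self.config, rng)

    def _union(self, batch: np.ndarray) -> np.ndarray:
        return np.unique(np.concatenate([self._members[int(i)] for i in batch]))

    def loss_and_grad(
        self, params: Params, batch, dropout_seed: int | None = None
    ) -> tuple[float, Params]:
        """Mean center-node cross-entropy and its gradient over a batch.

        ``dropout_seed`` fixes the dropout masks so repeated evaluations at
        nearby parameters (as in finite-difference curvature products) see
        the same stochastic network.
        """
        batch = np.asarray(batch, dtype=int)
        w1, w2 = params
        rate = self.config.dropout
        rng = np.random.default_rng(dropout_seed) if rate > 0.0 else None
        union = self._union(batch)
        xu = self.features[union]
        pu = xu @ w1
        dpu = np.zeros_like(pu)
        g_w2 = np.zeros_like(w2)
        total = 0.0
        for gi in batch:
            gi = int(gi)
            members = self._members[gi]
            pos = np.searchsorted(union, members)
            a_hat = self._a_hat[gi]
            z1 = a_hat @ pu[pos]
            h1 = self._act(z1)
            if rng is not None:
                mask = (rng.uniform(size=h1.shape) >= rate) / (1.0 - rate)
                h1 = h1 * mask
            a_c = np.asarray(a_hat.getrow(0).todense()).ravel()
            h2 = a_c @ h1
            z2 = h2 @ w2
            p = _softmax_rows(z2)
            y = self.y[gi]
            total -= np.log(max(p[y], 1e-300))
            d2 = p.copy()
            d2[y] -= 1.0
            g_w2 += np.outer(h2, d2)
            dh1 = np.outer(a_c, d2 @ w2.T)
            if rng is not None:
                dh1 = dh1 * mask
            dz1 = dh1 * self._act_grad(z1)
            dpu[pos] += a_hat.T @ dz1
        b = len(batch)
        g_w1 = xu.T @ dpu / b
        return total / b, [g_w1, g_w2 / b]

    def predict_proba(self, params: Params, batch) -> np.ndarray:
        """Center-node class probabilities for each sample in the batch."""
        batch = np.asarray(batch, dtype=int)
        w1, w2 = params
        union = self._union(batch)
        pu = self.features[union] @ w1
        out = np.empty((len(batch), w2.shape[1]))
        for row, gi in enumerate(batch):
            gi = int(gi)
            pos = np.searchsorted(union, self._members[gi])
            a_hat = self._a_hat[gi]
            h1 = self._act(a_hat @ pu[pos])
            a_c = np.asarray(a_hat.getrow(0).todense()).ravel()
            out[row] = _softmax_rows((a_c @ h1) @ w2)
        return out

    def predict(self, params: Params, batch) -> np.ndarray:
        return np.argmax(self.predict_proba(params, batch), axis=1)

    def true_labels(self, batch) -> np.ndarray:
        return self.y[np.asarray(batch, dtype=int)]


# --------------------------------------------------------------------------
# MAML machinery (model-agnostic: works for any EpisodeModel)


def _flat_norm(vs: Params) -> float:
    return float(np.sqrt(sum(float(np.sum(v * v)) for v in vs)))


def hvp_fd(
    model: EpisodeModel,
    params: Params,
    batch,
    vector: Params,
    eps: float | None = None,
) -> Params:
    """Hessian-vector product H(params) @ vector by central differences.

    Evaluates the analytic gradient at params +/- eps*vector; exact for
    quadratic losses, O(eps^2) otherwise with eps at the cube root of machine
    precision scaled by parameter and vector norms.
    """
    v_norm = _flat_norm(vector)
    if v_norm == 0.0:
        return [np.zeros_like(p) for p in params]
    if eps is None:
        eps = (np.finfo(float).eps ** (1.0 / 3.0)) * (1.0 + _flat_norm(params)) / v_norm
    plus = [p + eps * v for p, v in zip(params, vector)]
    minus = [p - eps * v for p, v in zip(params, vector)]
    _, g_plus = model.loss_and_grad(plus, batch)
    _, g_minus = model.loss_and_grad(minus, batch)
    return [(gp - gm) / (2.0 * eps) for gp, gm in zip(g_plus, g_minus)]


def inner_adapt(
    model: EpisodeModel,
    params: Params,
    support,
    meta: MetaConfig,
    return_trajectory: bool = False,
):
    """``inner_steps`` gradient-descent steps on the support loss.

    The input parameters are never modified; with zero steps the result
    equals the input.  With ``return_trajectory`` the full parameter path
    theta_0 .. theta_k is returned for back-propagation through adaptation.
    """
    theta = [p.copy() for p in params]
    trajectory = [theta]
    for _ in range(meta.inner_steps):
        _, grads = model.loss_and_grad(theta, support)
        theta = [p - meta.inner_lr * g for p, g in zip(theta, grads)]
        trajectory.append(theta)
    if return_trajectory:
        return theta, trajectory
    return theta


def meta_gradient(
    model: EpisodeModel, params: Params, task: Task, meta: MetaConfig
) -> tuple[float, Params]:
    """Post-adaptation query loss and its gradient w.r.t. the initialization.

    Second order: the query gradient at the adapted parameters is pulled
    back through each inner update via (I - inner_lr * H_support); first
    order returns the query gradient unmodified.
    """
    theta_k, trajectory = inner_adapt(
        model, params, task.support, meta, return_trajectory=True
    )
    loss_q, grad_q = model.loss_and_grad(theta_k, task.query)
    if meta.order == "first" or meta.inner_steps == 0:
        return loss_q, grad_q
    v = grad_q
    for theta_i in reversed(trajectory[:-1]):
        hv = hvp_fd(model, theta_i, task.support, v)
        v = [vi - meta.inner_lr * hi for vi, hi in zip(v, hv)]
    return loss_q, v


def meta_train(
    model: EpisodeModel,
    task_sampler: Callable[[np.random.Generator], Sequence[Task]],
    init_params: Params,
    meta: MetaConfig,
) -> tuple[Params, list[dict]]:
    """MAML outer loop: returns the meta-parameters theta' and a loss log.

    Each iteration draws a meta-batch of tasks, adapts per task on support,
    sums the post-adaptation query losses and gradients over the batch, and
    takes one outer gradient step.  Deterministic under ``meta.seed``; a
    non-finite loss aborts with :class:`MetaDivergenceError`.
    """
    rng = np.random.default_rng(meta.seed)
    theta = [p.copy() for p in init_params]
    log: list[dict] = []
    for iteration in range(meta.meta_iterations):
        tasks = task_sampler(rng)
        total_loss = 0.0
        total_grad = [np.zeros_like(p) for p in theta]
        for task in tasks:
            loss_q, grads = meta_gradient(model, theta, task, meta)
            total_loss += loss_q
            for acc, g in zip(total_grad, grads):
                acc += g
        if not np.isfinite(total_loss):
            raise MetaDivergenceError(
                f"non-finite query loss at meta-iteration {iteration}"
            )
        theta = [p - meta.outer_lr * g for p, g in zip(theta, total_grad)]
        log.append({"iteration": iteration, "query_loss": float(total_loss)})
    return theta, log


def fine_tune_and_evaluate(
    model: GcnEpisodeModel,
    test_task: Task,
    meta_params: Params,
    meta: MetaConfig,
    query_mask: np.ndarray | None = None,
):
    """Adapt theta' on the test support set and score the query set.

    ``query_mask`` (boolean, aligned to ``test_task.query``) restricts the
    scored samples — e.g. to real-provenance sequences only.  Returns a
    :class:`lncloc.evaluation.MetricsReport`; theta' is not modified.
    """
    from .evaluation import confusion_counts, compute_metrics

    steps = meta.fine_tune_steps if meta.fine_tune_steps is not None else meta.inner_steps
    ft_meta = MetaConfig(
        inner_lr=meta.inner_lr,
        outer_lr=meta.outer_lr,
        inner_steps=steps,
        meta_iterations=max(meta.meta_iterations, 1),
        order=meta.order,
        seed=meta.seed,
    )
    adapted = inner_adapt(model, meta_params, test_task.support, ft_meta)
    query = np.asarray(test_task.query, dtype=int)
    if query_mask is not None:
        query = query[np.asarray(query_mask, dtype=bool)]
    if len(query) == 0:
        raise ValueError("query set is empty after masking")
    y_true = model.true_labels(query)
    y_pred = model.predict(adapted, query)
    counts = confusion_counts(y_true, y_pred, len(model.class_names))
    return compute_metrics(counts, class_names=model.class_names)


def adaptation_curve(
    model: EpisodeModel, params: Params, batch, lr: float, steps: int
) -> list[float]:
    """Loss after each of ``steps`` gradient steps on ``batch`` (index 0 =
    starting loss); handy for comparing warm and cold starts."""
    theta = [p.copy() for p in params]
    losses = []
    for _ in range(steps + 1):
        loss, grads = model.loss_and_grad(theta, batch)
        losses.append(float(loss))
        theta = [p - lr * g for p, g in zip(theta, grads)]
    return losses


# --------------------------------------------------------------------------
# episode sampling and dataset splitting


def sample_tasks(
    labels: Sequence[str] | np.ndarray,
    episode: EpisodeConfig,
    seed: int | np.random.Generator,
    pool_indices: Sequence[int] | None = None,
) -> list[Task]:
    """Draw ``episode.m`` N-way tasks from a labeled pool.

    Within a task each class contributes exactly k_support + k_query samples
    drawn without replacement (support first); different tasks resample the
    pool independently.  A class with fewer members than k_support + k_query
    raises, naming the class.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=object)
    pool = (
        np.arange(len(labels))
        if pool_indices is None
        else np.asarray(pool_indices, dtype=int)
    )
    by_class: dict[str, np.ndarray] = {}
    for c in sorted(set(str(labels[i]) for i in pool)):
        by_class[c] = pool[np.array([str(labels[i]) == c for i in pool])]
    need = episode.k_support + episode.k_query
    for c, members in by_class.items():
        if len(members) < need:
            raise ValueError(
                f"class {c!r} has {len(members)} pool members; "
                f"needs k_support + k_query = {need}"
            )
    tasks = []
    for _ in range(episode.m):
        support, query = [], []
        for c in sorted(by_class):
            chosen = rng.choice(by_class[c], size=need, replace=False)
            support.extend(chosen[: episode.k_support])
            query.extend(chosen[episode.k_support :])
        tasks.append(Task(np.array(support, dtype=int), np.array(query, dtype=int)))
    return tasks


def _stratified_fractions(
    labels: np.ndarray, fractions: Sequence[float], rng: np.random.Generator
) -> list[np.ndarray]:
    """Largest-remainder stratified allocation; per-class split sizes are
    within one sample of exact proportionality."""
    splits: list[list[int]] = [[] for _ in fractions]
    for c in sorted(set(map(str, labels))):
        members = np.flatnonzero(np.array([str(l) == c for l in labels]))
        members = rng.permutation(members)
        exact = np.array(fractions) * len(members)
        alloc = np.floor(exact).astype(int)
        remainder = len(members) - alloc.sum()
        order = np.argsort(-(exact - alloc), kind="stable")
        for slot in order[:remainder]:
            alloc[slot] += 1
        start = 0
        for s, size in enumerate(alloc):
            splits[s].extend(members[start : start + size])
            start += size
    return [np.array(sorted(s), dtype=int) for s in splits]


def split_dataset(
    labels: Sequence[str] | np.ndarray,
    fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    folds: int | None = None,
    fold_index: int | None = None,
    val_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, label-stratified (train, val, test) indices.

    Either fractional mode (three fractions summing to 1) or fold mode
    (``folds``/``fold_index``: test = the given fold, val carved out of the
    remainder at ``val_fraction``).  Deterministic under ``seed``.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        raise ValueError("empty pool")
    rng = np.random.default_rng(seed)
    if folds is not None:
        if fold_index is None or not 0 <= fold_index < folds:
            raise ValueError("fold_index must lie in [0, folds)")
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        y = np.array([str(l) for l in labels])
        rest, test = list(skf.split(np.zeros(len(y)), y))[fold_index]
        if val_fraction > 0:
            sub_train, sub_val = _stratified_fractions(
                labels[rest], (1.0 - val_fraction, val_fraction), rng
            )
            train, val = rest[sub_train], rest[sub_val]
        else:
            train, val = rest, np.array([], dtype=int)
        result = (np.sort(train), np.sort(val), np.sort(test))
    else:
        fractions = tuple(fractions)
        if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("need three fractions summing to 1")
        result = tuple(_stratified_fractions(labels, fractions, rng))
    expected = (1.0, val_fraction, 1.0) if folds is not None else fractions
    for frac, part in zip(expected, result):
        if frac and len(part) == 0:
            raise ValueError("a requested split came out empty")
    return result  # type: ignore[return-value]
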