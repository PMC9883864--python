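"""SMOTE oversampling in feature space.

Minority classes are raised to the majority count by interpolating between a
class member and one of its same-class nearest neighbors (Euclidean metric):
each synthetic point is x_c + u * (x_n - x_c) with u ~ U[0, 1].  Originals
are kept unchanged and flagged "real"; synthetics are appended after them and
flagged "synthetic", with full parentage recorded so the convex-combination
geometry can be audited.

Two neighbor policies are provided.  ``standard`` is classic SMOTE: centers
drawn across the class, each interpolated toward one of its k nearest
neighbors (default 5), repeating until the deficit is filled.  ``single_center``
follows a single-center variant: one random center per round donates one
synthetic toward each of its deficit-many nearest neighbors.  ``standard``
is the default; the single-center variant is an opt-in reproduction mode.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ClassDistribution",
    "SmoteConfig",
    "SmoteError",
    "SyntheticParentage",
    "SmoteResult",
    "class_distribution",
    "smote_balance",
]


class SmoteError(ValueError):
    """Raised when oversampling is impossible (e.g. a one-member class)."""


@dataclass(frozen=True)
class ClassDistribution:
    """Multiset of compartment labels."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def majority_count(self) -> int:
        return max(self.counts.values()) if self.counts else 0

    def imbalance_ratio(self) -> float:
        """max/min class count; inf if any class is empty."""
        if not self.counts:
            return float("nan")
        low = min(self.counts.values())
        return float("inf") if low == 0 else self.majority_count / low


def class_distribution(labels: Sequence[str]) -> ClassDistribution:
    return ClassDistribution(dict(Counter(labels)))


@dataclass(frozen=True)
class SmoteConfig:
    """Neighbor policy and seed for oversampling.

    ``neighbor_count`` is the k of the k-nearest-neighbor pool in standard
    mode (clipped to class size - 1); ignored in single_center mode, where the
    neighbor pool per round is the deficit itself.
    """

    neighbor_count: int = 5
    seed: int = 0
    mode: str = "standard"

    def __post_init__(self) -> None:
        if self.mode not in ("standard", "single_center"):
            raise ValueError(f"unknown SMOTE mode {self.mode!r}")
        if self.neighbor_count < 1:
            raise ValueError("neighbor_count must be >= 1")


@dataclass(frozen=True)
class SyntheticParentage:
    """Provenance of one synthetic row: global parent indices and the mix u."""

    center_index: int
    neighbor_index: int
    u: float


@dataclass
class SmoteResult:
    vectors: np.ndarray
    labels: list[str]
    provenance: list[str]  # "real" | "synthetic", aligned to vectors
    parentage: list[SyntheticParentage] = field(default_factory=list)
    #: row index in ``vectors`` of each synthetic, aligned to ``parentage``
    synthetic_rows: list[int] = field(default_factory=list)

    @property
    def n_synthetic(self) -> int:
        return len(self.parentage)

    def distribution(self) -> ClassDistribution:
        return class_distribution(self.labels)


def _class_indices(labels: Sequence[str]) -> dict[str, np.ndarray]:
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    return {lab: np.array(idx) for lab, idx in by_class.items()}


def smote_balance(
    vectors: np.ndarray,
    labels: Sequence[str],
    config: SmoteConfig = SmoteConfig(),
) -> SmoteResult:
    """Raise every class to the majority count with interpolated synthetics.

    Output order is all originals (unchanged, in input order) followed by
    synthetics grouped by class.  Deterministic under ``config.seed``.  A
    class that needs synthetics but has fewer than two members raises
    :class:`SmoteError` (no line segment exists).
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise SmoteError("vectors must be a 2-D array")
    if vectors.shape[0] != len(labels):
        raise SmoteError("vectors and labels must be aligned")
    labels = list(labels)
    rng = np.random.default_rng(config.seed)
    by_class = _class_indices(labels)
    target = max((len(v) for v in by_class.values()), default=0)

    new_rows: list[np.ndarray] = []
    new_labels: list[str] = []
    parentage: list[SyntheticParentage] = []

    for lab in sorted(by_class):  # sorted for seed-stable iteration order
        members = by_class[lab]
        deficit = target - len(members)
        if deficit == 0:
            continue
        if len(members) < 2:
            raise SmoteError(
                f"class {lab!r} has {len(members)} sample(s); "
                "at least 2 are required to interpolate"
            )
        class_vecs = vectors[members]
        if config.mode == "standard":
            k = min(config.neighbor_count, len(members) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(class_vecs)
            # column 0 is the point itself
            neigh = nn.kneighbors(class_vecs, return_distance=False)[:, 1:]
            centers = rng.integers(0, len(members), size=deficit)
            picks = rng.integers(0, k, size=deficit)
            for c_local, pick in zip(centers, picks):
                n_local = int(neigh[c_local, pick])
                u = float(rng.uniform())
                new_rows.append(
                    class_vecs[c_local] + u * (class_vecs[n_local] - class_vecs[c_local])
                )
                new_labels.append(lab)
                parentage.append(
                    SyntheticParentage(int(members[c_local]), int(members[n_local]), u)
                )
        else:  # single_center: one center per round serves its nearest neighbors
            nn = NearestNeighbors(n_neighbors=len(members)).fit(class_vecs)
            remaining = deficit
            while remaining > 0:
                c_local = int(rng.integers(0, len(members)))
                order = nn.kneighbors(
                    class_vecs[c_local : c_local + 1], return_distance=False
                )[0]
                order = order[order != c_local]  # drop the center itself
                take = order[: min(remaining, len(order))]
                for n_local in take:
                    u = float(rng.uniform())
                    new_rows.append(
                        class_vecs[c_local]
                        + u * (class_vecs[n_local] - class_vecs[c_local])
                    )
                    new_labels.append(lab)
                    parentage.append(
                        SyntheticParentage(
                            int(members[c_local]), int(members[n_local]), u
                        )
                    )
                remaining -= len(take)

    if new_rows:
        out_vectors = np.vstack([vectors, np.array(new_rows)])
    else:
        out_vectors = vectors.copy()
    out_labels = labels + new_labels
    provenance = ["real"] * len(labels) + ["synthetic"] * len(new_labels)
    synthetic_rows = list(range(len(labels), len(out_labels)))
    return SmoteResult(out_vectors, out_labels, provenance, parentage, synthetic_rows)
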