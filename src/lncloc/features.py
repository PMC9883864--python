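"""Low-level sequence features: k-mer, reverse-complement k-mer, PseDNC.

These are the per-sequence vectors used both as node features and for the
cosine-similarity graph.  Sequences are canonicalized U->T before counting so
RNA and DNA spellings map to identical k-mers.

k-mer indexing is lexicographic over A < C < G < T and fixed across runs so
feature matrices are comparable and serializable.  Counts are normalized by
the number of sliding windows (L - k + 1), making vectors length-invariant —
the property that lets cosine similarity compare sequences of different
lengths on composition alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from ._dinuc_properties import standardized_property_matrix
from .sequence_io import SequenceRecord

__all__ = [
    "FeatureConfig",
    "FeatureError",
    "canonicalize",
    "kmer_frequencies",
    "kmer_labels",
    "revkmer_frequencies",
    "revkmer_classes",
    "revkmer_labels",
    "psednc_features",
    "pca_reduce",
    "featurize_dataset",
    "feature_labels",
    "write_feature_table",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class FeatureError(ValueError):
    """Raised when a sequence cannot be featurized as requested."""


def canonicalize(sequence: str) -> str:
    """Uppercase and map U->T; reject characters outside {A,C,G,T,U}."""
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - set(_BASES)
    if bad:
        raise FeatureError(f"sequence contains unsupported characters {sorted(bad)}")
    return seq


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int64, count=len(seq))


@lru_cache(maxsize=None)
def kmer_labels(k: int) -> tuple[str, ...]:
    """The 4^k k-mers in lexicographic order (A < C < G < T)."""
    return tuple("".join(p) for p in product(_BASES, repeat=k))


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of every length-k window, lexicographic base-4 encoding."""
    if k < 1:
        raise FeatureError("k must be >= 1")
    if len(seq) < k:
        raise FeatureError(f"sequence of length {len(seq)} is shorter than k={k}")
    enc = _encode(seq)
    codes = np.zeros(len(seq) - k + 1, dtype=np.int64)
    for offset in range(k):
        codes = codes * 4 + enc[offset : offset + len(codes)]
    return codes


def kmer_frequencies(sequence: str, k: int) -> np.ndarray:
    """Sliding-window k-mer frequency vector of dimension 4^k.

    Entry i counts occurrences of the i-th lexicographic k-mer over the
    L - k + 1 windows, divided by the window count, so entries are
    non-negative and sum to one.
    """
    seq = canonicalize(sequence)
    codes = _kmer_codes(seq, k)
    counts = np.bincount(codes, minlength=4**k).astype(float)
    return counts / len(codes)


@lru_cache(maxsize=None)
def revkmer_classes(k: int) -> tuple[tuple[str, ...], np.ndarray]:
    """Reverse-complement equivalence classes of the 4^k k-mers.

    Returns (class representatives in lexicographic order, mapping array of
    length 4^k sending each k-mer index to its class index).  Each class is
    keyed by its lexicographically smaller member; palindromic k-mers form
    singleton classes.
    """
    mers = kmer_labels(k)
    reps: list[str] = []
    rep_index: dict[str, int] = {}
    mapping = np.empty(len(mers), dtype=np.int64)
    for i, mer in enumerate(mers):
        rc = "".join(_COMPLEMENT[b] for b in reversed(mer))
        rep = min(mer, rc)
        if rep not in rep_index:
            rep_index[rep] = len(reps)
            reps.append(rep)
        mapping[i] = rep_index[rep]
    return tuple(reps), mapping


def revkmer_labels(k: int) -> tuple[str, ...]:
    return revkmer_classes(k)[0]


def revkmer_frequencies(sequence: str, k: int) -> np.ndarray:
    """k-mer frequencies pooled over reverse-complement pairs.

    Dimension is the number of reverse-complement classes; each entry is the
    sum of the plain k-mer frequencies of the class members, so the vector
    still sums to one and is invariant under reverse-complementing the input.
    """
    reps, mapping = revkmer_classes(k)
    plain = kmer_frequencies(sequence, k)
    pooled = np.zeros(len(reps))
    np.add.at(pooled, mapping, plain)
    return pooled


def psednc_features(sequence: str, lam: int = 150, weight: float = 0.3) -> np.ndarray:
    """Pseudo dinucleotide composition of dimension 16 + lam.

    The leading 16 entries are normalized dinucleotide frequencies; the tail
    holds lam sequence-order correlation factors theta_j, each the average
    squared property distance between dinucleotides j steps apart, computed
    on the standardized six-property step-parameter table.  With weight w,

        d_u = f_u / (1 + w * sum(theta))            u <= 16
        d_u = w * theta_(u-16) / (1 + w * sum(theta))  u > 16

    so the vector is non-negative and sums to one.  At w = 0 the tail
    vanishes and the head reduces to plain dinucleotide frequencies.
    """
    if lam < 0:
        raise FeatureError("lambda must be non-negative")
    if not 0.0 <= weight <= 1.0:
        raise FeatureError("weight must lie in [0, 1]")
    seq = canonicalize(sequence)
    if len(seq) < lam + 2:
        raise FeatureError(
            f"sequence of length {len(seq)} too short for lambda={lam} "
            f"(needs >= lambda + 2)"
        )
    codes = _kmer_codes(seq, 2)
    freqs = np.bincount(codes, minlength=16).astype(float)
    freqs /= len(codes)

    props = standardized_property_matrix()  # 16 x 6
    step_props = props[codes]  # (L-1) x 6
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diff = step_props[:-j] - step_props[j:]
        thetas[j - 1] = np.mean(np.sum(diff * diff, axis=1) / props.shape[1])
    denom = 1.0 + weight * thetas.sum()
    return np.concatenate([freqs / denom, weight * thetas / denom])


def pca_reduce(
    vectors: np.ndarray,
    target_dims: int,
    fit_indices: Sequence[int] | None = None,
) -> np.ndarray:
    """Project feature vectors to ``target_dims`` principal components.

    The projection is fitted only on ``fit_indices`` (all rows if None) and
    then applied to every row, so held-out samples never influence the axes.
    """
    vectors = np.asarray(vectors, dtype=float)
    fit = vectors if fit_indices is None else vectors[np.asarray(fit_indices)]
    if target_dims > min(vectors.shape[1], fit.shape[0]):
        raise FeatureError(
            f"target_dims={target_dims} exceeds min(dimension={vectors.shape[1]}, "
            f"fitting samples={fit.shape[0]})"
        )
    pca = PCA(n_components=target_dims, svd_solver="full")
    pca.fit(fit)
    return pca.transform(vectors)


@dataclass(frozen=True)
class FeatureConfig:
    """Which low-level encoding to use and its parameters.

    k defaults to 7 (the strongest k-mer setting on the benchmark task;
    smaller k is much cheaper and adequate for well-separated data).  PCA is
    off by default — on this task reduction tends to discard discriminative
    composition signal.
    """

    method: str = "kmer"
    k: int = 7
    lam: int = 150
    weight: float = 0.3
    pca_dims: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("kmer", "revkmer", "psednc"):
            raise ValueError(f"unknown feature method {self.method!r}")
        if not 1 <= self.k <= 7:
            raise ValueError("k must lie in [1, 7]")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")
        if self.pca_dims is not None and self.pca_dims <= 0:
            raise ValueError("pca_dims must be positive")

    def featurize_one(self, sequence: str) -> np.ndarray:
        if self.method == "kmer":
            return kmer_frequencies(sequence, self.k)
        if self.method == "revkmer":
            return revkmer_frequencies(sequence, self.k)
        return psednc_features(sequence, self.lam, self.weight)


def feature_labels(config: FeatureConfig) -> tuple[str, ...]:
    """Column names for a feature matrix produced under ``config``."""
    if config.pca_dims is not None:
        return tuple(f"PC{i + 1}" for i in range(config.pca_dims))
    if config.method == "kmer":
        return kmer_labels(config.k)
    if config.method == "revkmer":
        return revkmer_labels(config.k)
    return tuple(
        [f"dinuc_{d}" for d in kmer_labels(2)]
        + [f"theta_{j + 1}" for j in range(config.lam)]
    )


def featurize_dataset(
    records: Sequence[SequenceRecord],
    config: FeatureConfig,
    pca_fit_indices: Sequence[int] | None = None,
) -> np.ndarray:
    """One feature vector per record, same order, shared dimension.

    Any per-sequence failure aborts with the offending record ID.  If
    ``config.pca_dims`` is set, PCA is fitted on ``pca_fit_indices`` (all
    rows when None) and applied to the whole matrix afterwards.
    """
    rows = []
    for rec in records:
        try:
            rows.append(config.featurize_one(rec.sequence))
        except FeatureError as err:
            raise FeatureError(f"record {rec.id!r}: {err}") from err
    matrix = np.array(rows) if rows else np.empty((0, len(feature_labels(config))))
    if config.pca_dims is not None and len(rows):
        matrix = pca_reduce(matrix, config.pca_dims, pca_fit_indices)
    return matrix


def write_feature_table(
    matrix: np.ndarray,
    ids: Sequence[str],
    columns: Sequence[str],
    path: str | Path,
) -> None:
    """Serialize a feature matrix as TSV with sequence IDs as the index."""
    frame = pd.DataFrame(matrix, index=list(ids), columns=list(columns))
    frame.to_csv(path, sep="\t", index_label="id")
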