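"""Model similarity matrices and second-order (matrix-level) comparisons.

Builds labeled, symmetric similarity matrices from concept-feature weights,
phonetic transcriptions, stimulus family labels, and per-layer feature
vectors of an external encoder, and compares any two such matrices with a
rank correlation over the strictly-upper triangle plus a label-permutation
test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np

from .permutation import (
    PermutationResult,
    make_result,
    random_permutations,
    spearman_permutation_nulls,
    spearman_upper,
)

__all__ = [
    "SimilarityMatrix",
    "ConceptFeatureMatrix",
    "FeatureLayerSet",
    "cosine_similarity_matrix",
    "semantic_similarity_matrix",
    "phonological_similarity_matrix",
    "family_similarity_matrix",
    "layer_similarity_matrices",
    "matrix_correlation",
    "matrix_permutation_test",
    "levenshtein",
]

_SYMMETRY_TOL = 1e-10


def _check_labels(labels: Sequence[str]) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate labels: {dupes}")
    return labels


@dataclass
class SimilarityMatrix:
    """Labeled square symmetric matrix of pairwise similarities.

    Invariants checked on construction: unique labels, symmetry within
    1e-10, and all values in [-1, 1].
    """

    labels: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity values must be finite")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > _SYMMETRY_TOL:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:.3e})")
        if np.any(self.values < -1 - 1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("similarity values outside [-1, 1]")
        self.values = np.clip((self.values + self.values.T) / 2.0, -1.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_cells(self) -> np.ndarray:
        """Strictly-upper-triangle values in row-major order."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "SimilarityMatrix":
        """Return a copy with rows/columns rearranged into the given label order."""
        labels = list(labels)
        if sorted(labels) != sorted(self.labels):
            raise ValueError("reorder labels must be a permutation of existing labels")
        idx = [self.labels.index(l) for l in labels]
        return SimilarityMatrix(labels, self.values[np.ix_(idx, idx)], dict(self.meta))

    def restrict(self, labels: Sequence[str]) -> "SimilarityMatrix":
        """Submatrix for a subset of labels, in the given order."""
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise ValueError(f"labels not present: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return SimilarityMatrix(list(labels), self.values[np.ix_(idx, idx)], dict(self.meta))


@dataclass
class ConceptFeatureMatrix:
    """Entity-by-feature applicability weights (binary in the source norms)."""

    entity_labels: list[str]
    feature_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.entity_labels = _check_labels(self.entity_labels)
        self.feature_labels = _check_labels(self.feature_labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_labels), len(self.feature_labels)):
            raise ValueError("values shape does not match labels")
        if np.any(self.values < 0):
            raise ValueError("feature weights must be non-negative")
        zero = np.flatnonzero(~self.values.any(axis=1))
        if zero.size:
            bad = [self.entity_labels[i] for i in zero]
            raise ValueError(f"entities with no nonzero feature: {bad}")


@dataclass
class FeatureLayerSet:
    """Ordered per-layer feature vectors for a fixed stimulus set."""

    stimulus_labels: list[str]
    layers: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        self.stimulus_labels = _check_labels(self.stimulus_labels)
        checked = []
        for name, mat in self.layers:
            mat = np.asarray(mat, dtype=float)
            if mat.shape[0] != len(self.stimulus_labels):
                raise ValueError(
                    f"layer {name!r} has {mat.shape[0]} rows for "
                    f"{len(self.stimulus_labels)} stimuli"
                )
            zero = np.flatnonzero(~mat.any(axis=1))
            if zero.size:
                bad = [self.stimulus_labels[i] for i in zero]
                raise ValueError(f"layer {name!r} has all-zero rows for {bad}")
            checked.append((str(name), mat))
        self.layers = checked


def cosine_similarity_matrix(
    vectors: Mapping[str, Sequence[float]],
    meta: dict | None = None,
) -> SimilarityMatrix:
    """Pairwise cosine similarity between labeled vectors.

    Raises if any vector has zero norm (cosine undefined) or if lengths differ.
    """
    labels = _check_labels(list(vectors.keys()))
    rows = [np.asarray(vectors[l], dtype=float).ravel() for l in labels]
    lengths = {r.size for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"vectors have differing lengths: {sorted(lengths)}")
    mat = np.vstack(rows)
    norms = np.linalg.norm(mat, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"zero-norm vector for label {labels[zero[0]]!r}")
    unit = mat / norms[:, None]
    values = unit @ unit.T
    np.fill_diagonal(values, 1.0)
    m = {"source": "cosine"}
    m.update(meta or {})
    return SimilarityMatrix(labels, np.clip((values + values.T) / 2, -1, 1), m)


def semantic_similarity_matrix(cfm: ConceptFeatureMatrix) -> SimilarityMatrix:
    """Row-wise cosine similarity of a concept-feature matrix."""
    vectors = dict(zip(cfm.entity_labels, cfm.values))
    return cosine_similarity_matrix(vectors, meta={"source": "concept_features"})


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance over symbols (one symbol per code point)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def phonological_similarity_matrix(
    transcriptions: Mapping[str, str],
) -> SimilarityMatrix:
    """Length-normalized edit similarity: 1 - L(s_i, s_j) / max(|s_i|, |s_j|)."""
    labels = _check_labels(list(transcriptions.keys()))
    strings = [str(transcriptions[l]) for l in labels]
    for lab, s in zip(labels, strings):
        if len(s) == 0:
            raise ValueError(f"empty transcription for label {lab!r}")
    n = len(labels)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = levenshtein(strings[i], strings[j])
            sim = 1.0 - d / max(len(strings[i]), len(strings[j]))
            values[i, j] = values[j, i] = sim
    return SimilarityMatrix(labels, values, {"source": "phonological"})


def family_similarity_matrix(
    family_labels: Mapping[str, Hashable],
) -> SimilarityMatrix:
    """Binary block matrix: 1 for same-family stimulus pairs, 0 otherwise."""
    labels = _check_labels(list(family_labels.keys()))
    if not labels:
        raise ValueError("at least one stimulus required")
    fams = np.asarray([family_labels[l] for l in labels], dtype=object)
    values = (fams[:, None] == fams[None, :]).astype(float)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(labels, values, {"source": "family"})


def layer_similarity_matrices(fls: FeatureLayerSet) -> list[SimilarityMatrix]:
    """One cosine similarity matrix per encoder layer, in layer order."""
    out = []
    for name, mat in fls.layers:
        vectors = dict(zip(fls.stimulus_labels, mat))
        try:
            sm = cosine_similarity_matrix(
                vectors, meta={"source": "feature_layer", "layer": name}
            )
        except ValueError as exc:
            raise ValueError(f"layer {name!r}: {exc}") from exc
        out.append(sm)
    return out


def _check_same_labels(a: SimilarityMatrix, b: SimilarityMatrix) -> None:
    if a.labels != b.labels:
        diff = [
            (la, lb) for la, lb in zip(a.labels, b.labels) if la != lb
        ] or [("length", f"{a.n} vs {b.n}")]
        raise ValueError(f"label order mismatch between matrices: {diff}")


def matrix_correlation(a: SimilarityMatrix, b: SimilarityMatrix) -> float:
    """Spearman rank correlation over strictly-upper-triangle cells only.

    Midranks are used for ties; diagonal and lower triangle never enter.
    """
    _check_same_labels(a, b)
    if a.n < 3:
        raise ValueError("need at least 3 labels for a matrix correlation")
    return spearman_upper(a.values, b.values)


def matrix_permutation_test(
    a: SimilarityMatrix,
    b: SimilarityMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
    n_comparisons: int = 1,
) -> PermutationResult:
    """Label-permutation test of the second-order Spearman correlation.

    The null jointly permutes the row+column labels of ``b`` (entity
    relabeling); the one-tailed upper p includes the observed statistic in the
    count.  ``n_comparisons`` only annotates the Bonferroni-corrected alpha.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = matrix_correlation(a, b)
    rng = np.random.default_rng(seed)
    perms = random_permutations(rng, a.n, n_perm)
    null = spearman_permutation_nulls(a.values, b.values, perms)
    return make_result(
        "matrix_spearman",
        observed,
        null,
        seed,
        alpha_corrected=0.05 / n_comparisons,
        n_comparisons=n_comparisons,
    )
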