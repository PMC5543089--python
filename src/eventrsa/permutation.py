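"""Permutation-null machinery shared by model-matrix and pattern statistics.

All label-permutation nulls in the package flow through the helpers here so
that the p-value convention — ``p = (1 + #{null >= observed}) / (n_perm + 1)``
for the upper tail — is defined in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationResult",
    "p_value",
    "random_permutations",
    "spearman_upper",
    "upper_rank_matrix",
    "spearman_permutation_nulls",
]


def p_value(observed: float, null: np.ndarray, tail: str = "greater") -> float:
    """Permutation p-value including the observed statistic in the count.

    Guarantees ``0 < p <= 1`` at any finite number of permutations.
    """
    null = np.asarray(null, dtype=float)
    if null.ndim != 1 or null.size < 1:
        raise ValueError("null must be a non-empty 1-D sample vector")
    if tail == "greater":
        count = int(np.sum(null >= observed))
    elif tail == "less":
        count = int(np.sum(null <= observed))
    else:
        raise ValueError(f"unknown tail {tail!r}; expected 'greater' or 'less'")
    return (1 + count) / (null.size + 1)


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the resulting p-value."""

    statistic: str
    observed: float
    null: np.ndarray
    p: float
    n_perm: int
    seed: int | None
    tail: str = "greater"
    meta: dict = field(default_factory=dict)
    per_subject_observed: np.ndarray | None = None
    per_subject_null: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.null = np.asarray(self.null, dtype=float)
        if self.null.size != self.n_perm:
            raise ValueError("null sample length must equal n_perm")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"invalid p-value {self.p}")

    def rejects(self, alpha: float = 0.05) -> bool:
        return self.p <= alpha

    def to_dict(self) -> dict:
        """JSON-serializable summary (null samples excluded)."""
        out = {
            "statistic": self.statistic,
            "observed": float(self.observed),
            "p": float(self.p),
            "n_perm": int(self.n_perm),
            "seed": self.seed,
            "tail": self.tail,
        }
        out.update({k: v for k, v in self.meta.items() if _jsonable(v)})
        return out


def _jsonable(v) -> bool:
    return isinstance(v, (int, float, str, bool, type(None), list, dict))


def make_result(
    statistic: str,
    observed: float,
    null: np.ndarray,
    seed: int | None,
    tail: str = "greater",
    **meta,
) -> PermutationResult:
    null = np.asarray(null, dtype=float)
    return PermutationResult(
        statistic=statistic,
        observed=float(observed),
        null=null,
        p=p_value(observed, null, tail=tail),
        n_perm=null.size,
        seed=seed,
        tail=tail,
        meta=meta,
    )


def random_permutations(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    """``n_perm`` independent uniform permutations of ``range(n)``, one per row."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    base = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(base, axis=1)


def spearman_upper(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation over the strictly-upper-triangle cells."""
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    rho = sps.spearmanr(a[iu], b[iu]).statistic
    return float(rho)


def upper_rank_matrix(values: np.ndarray) -> np.ndarray:
    """Midrank matrix of the strictly-upper-triangle cells, symmetrized.

    Because a joint row+column relabeling maps the set of unordered label
    pairs onto itself, the multiset of off-diagonal cell values — and hence
    their midranks — is invariant under any such relabeling.  Ranking once and
    gathering under each permutation therefore reproduces rank-then-Pearson
    exactly, at a fraction of the cost.
    """
    n = values.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = sps.rankdata(values[iu])
    out = np.zeros((n, n), dtype=float)
    out[iu] = ranks
    return out + out.T


def spearman_permutation_nulls(
    a: np.ndarray,
    b: np.ndarray,
    perms: np.ndarray,
    chunk: int = 2048,
) -> np.ndarray:
    """Spearman correlation of ``a`` with label-permuted ``b``, per permutation.

    ``perms`` has one permutation of ``range(n)`` per row; ``b`` is permuted
    jointly on rows and columns.
    """
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    ra = sps.rankdata(a[iu])
    ra = ra - ra.mean()
    norm_a = np.linalg.norm(ra)
    if norm_a == 0:
        raise ValueError("matrix 'a' has constant upper-triangle cells")
    rb_mat = upper_rank_matrix(b)
    null = np.empty(perms.shape[0], dtype=float)
    for start in range(0, perms.shape[0], chunk):
        p = perms[start : start + chunk]
        sub = rb_mat[p[:, :, None], p[:, None, :]]
        cells = sub[:, iu[0], iu[1]]
        cells -= cells.mean(axis=1, keepdims=True)
        norm_b = np.linalg.norm(cells, axis=1)
        if np.any(norm_b == 0):
            raise ValueError("matrix 'b' has constant upper-triangle cells")
        null[start : start + p.shape[0]] = (cells @ ra) / (norm_a * norm_b)
    return null
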