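"""Pattern similarity statistics with pair exclusion and permutation inference.

Three statistics, sharing one engine:

* semantic RSA — entity-by-entity cosine similarity matrix over trial pairs
  presented at *different* locations, averaged over subjects and rank-
  correlated with a model matrix; null = joint label permutation of the model;
* object identity — mean cosine over same-entity trial pairs at different
  locations, averaged over entities, subjects; null = entity labels permuted
  across trials within each run of each subject (locations fixed), with each
  permuted block inheriting the observed block's exclusion mask so that all
  null samples average the same number of pairs as the observed statistic;
* location — mean cosine over same-location trial pairs of different
  entities; null = location labels permuted within runs (entities fixed),
  with the same-entity exclusion recomputed under the permuted labels.

Group nulls draw one independent permutation per subject per iteration and
average across subjects; per-subject null distributions are retained for the
rank-based secondary comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrices import SimilarityMatrix, _check_same_labels
from .permutation import (
    PermutationResult,
    make_result,
    random_permutations,
    spearman_permutation_nulls,
    spearman_upper,
)
from .response import ResponsePatternSet, TrialTable

__all__ = [
    "SubjectRank",
    "fmri_similarity_matrix",
    "entity_average_similarity_matrix",
    "group_average_matrix",
    "rsa_test",
    "rsa_subject_tests",
    "identity_statistic",
    "location_statistic",
    "subject_rank",
    "compare_conditions",
    "subjectwise_diagnostics",
]


@dataclass
class SubjectRank:
    """Percentile of a subject's observed statistic within their own null."""

    subject: object
    percentile: float

    def __post_init__(self) -> None:
        if not (0.0 < self.percentile <= 1.0):
            raise ValueError(f"percentile {self.percentile} outside (0, 1]")


# ---------------------------------------------------------------------------
# similarity matrices from trial patterns


def _unit_rows(values: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(values, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"trial {zero[0]} has a zero-norm pattern vector")
    return values / norms[:, None]


def _codes(series: pd.Series) -> tuple[np.ndarray, list]:
    cats = pd.Categorical(series)
    order = sorted(cats.categories)
    mapping = {c: i for i, c in enumerate(order)}
    return series.map(mapping).to_numpy(), order


def fmri_similarity_matrix(
    rps: ResponsePatternSet,
    trials: TrialTable,
    exclude_same_location: bool = True,
) -> SimilarityMatrix:
    """Entity-by-entity mean trial-pair cosine similarity with pair exclusion.

    Cell (i, j), i != j, averages the cosine over all trial pairs
    (a in trials of i, b in trials of j) whose stimulus locations differ.
    The diagonal is set to 1 by convention and never used in inference.
    Per-cell admissible pair counts are reported in ``meta['pair_counts']``.
    """
    df = trials.data
    if len(df) != rps.n_trials:
        raise ValueError("pattern set and trial table are misaligned")
    ent, ent_labels = _codes(df["entity"])
    if len(ent_labels) < 2:
        raise ValueError("need at least 2 entities")
    loc = df["location"].to_numpy()
    unit = _unit_rows(rps.values)
    cos = unit @ unit.T
    adm = loc[:, None] != loc[None, :] if exclude_same_location else ~np.eye(len(df), dtype=bool)
    one_hot = np.zeros((len(df), len(ent_labels)))
    one_hot[np.arange(len(df)), ent] = 1.0
    sums = one_hot.T @ (cos * adm) @ one_hot
    counts = one_hot.T @ adm.astype(float) @ one_hot
    off = ~np.eye(len(ent_labels), dtype=bool)
    empty = off & (counts == 0)
    if empty.any():
        i, j = np.argwhere(empty)[0]
        raise ValueError(
            f"no admissible trial pair for entities "
            f"{ent_labels[i]!r} / {ent_labels[j]!r}"
        )
    values = np.ones_like(sums)
    values[off] = sums[off] / counts[off]
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(
        [str(l) for l in ent_labels],
        values,
        {"source": "fmri_trial_pairs", "pair_counts": counts.astype(int)},
    )


def entity_average_similarity_matrix(
    rps: ResponsePatternSet, trials: TrialTable
) -> SimilarityMatrix:
    """Sensitivity variant: cosine between per-entity average patterns.

    The same-location pair exclusion is not expressible here; the trial-pair
    matrix is the primary definition.
    """
    df = trials.data
    ent, ent_labels = _codes(df["entity"])
    means = np.vstack(
        [rps.values[ent == k].mean(axis=0) for k in range(len(ent_labels))]
    )
    unit = _unit_rows(means)
    values = np.clip(unit @ unit.T, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        [str(l) for l in ent_labels], values, {"source": "fmri_entity_average"}
    )


def group_average_matrix(matrices: Sequence[SimilarityMatrix]) -> SimilarityMatrix:
    """Element-wise mean of per-subject similarity matrices."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        _check_same_labels(first, m)
    values = np.mean([m.values for m in matrices], axis=0)
    return SimilarityMatrix(
        list(first.labels), values, {"source": "group_average", "n_subjects": len(matrices)}
    )


# ---------------------------------------------------------------------------
# semantic RSA


def rsa_test(
    group_matrix: SimilarityMatrix,
    model: SimilarityMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
) -> PermutationResult:
    """Second-order Spearman correlation with a model-relabeling null.

    Upper-triangle cells only; one-tailed (greater) p.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_same_labels(group_matrix, model)
    observed = spearman_upper(group_matrix.values, model.values)
    rng = np.random.default_rng(seed)
    perms = random_permutations(rng, model.n, n_perm)
    null = spearman_permutation_nulls(group_matrix.values, model.values, perms)
    return make_result("rsa_spearman", observed, null, seed)


def rsa_subject_tests(
    subject_matrices: Sequence[SimilarityMatrix],
    model: SimilarityMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
    restrict_labels: Sequence[str] | None = None,
) -> list[PermutationResult]:
    """Per-subject RSA with independent model-relabeling nulls.

    With ``restrict_labels`` the correlation is computed on the submatrix for
    those labels while the null still permutes the full label set, mirroring
    a category-confined analysis ranked against permutations over all stimuli.
    """
    seeds = np.random.SeedSequence(seed).spawn(len(subject_matrices))
    results = []
    for mat, ss in zip(subject_matrices, seeds):
        _check_same_labels(mat, model)
        rng = np.random.default_rng(ss)
        perms = random_permutations(rng, model.n, n_perm)
        if restrict_labels is None:
            observed = spearman_upper(mat.values, model.values)
            null = spearman_permutation_nulls(mat.values, model.values, perms)
        else:
            keep = np.asarray([model.labels.index(l) for l in restrict_labels])
            iu = np.triu_indices(keep.size, 1)
            data_cells = mat.values[np.ix_(keep, keep)][iu]
            observed = float(sps.spearmanr(data_cells, model.values[np.ix_(keep, keep)][iu]).statistic)
            null = np.empty(n_perm)
            for k in range(n_perm):
                pm = model.values[np.ix_(perms[k], perms[k])]
                null[k] = sps.spearmanr(data_cells, pm[np.ix_(keep, keep)][iu]).statistic
        results.append(make_result("rsa_spearman_subject", observed, null, seed))
    return results


# ---------------------------------------------------------------------------
# identity / location pair statistics


def _pair_mean(
    cos: np.ndarray,
    blocks: list[np.ndarray],
    other: np.ndarray,
    perms: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-over-blocks of mean admissible within-block pair similarity.

    For each permutation row p (trial relabeling), block b with fixed trial
    index set I contributes mean of cos[p[a], p[b']] over a, b' in I with
    other[p[a]] != other[p[b']].  Blocks with no admissible pair under a given
    permutation are dropped from that permutation's average.
    """
    n_perm = perms.shape[0]
    block_means = np.full((n_perm, len(blocks)), np.nan)
    for bi, idx_set in enumerate(blocks):
        idx = perms[:, idx_set]
        sub = cos[idx[:, :, None], idx[:, None, :]]
        oth = other[idx]
        adm = oth[:, :, None] != oth[:, None, :]
        cnt = adm.sum(axis=(1, 2))
        ok = cnt > 0
        if ok.any():
            block_means[ok, bi] = (sub * adm).sum(axis=(1, 2))[ok] / cnt[ok]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled upstream
        stat = np.nanmean(block_means, axis=1)
    return stat, block_means


def _pair_mean_fixed_mask(
    cos: np.ndarray,
    blocks: list[np.ndarray],
    masks: list[np.ndarray],
    perms: np.ndarray,
) -> np.ndarray:
    """Mean-over-blocks of masked within-block pair similarity.

    Unlike :func:`_pair_mean`, the admissible-pair mask of each block is fixed
    (inherited from the observed labeling), so every permutation averages
    exactly as many pairs as the observed statistic.  Under the null the
    identity of the masked pairs is immaterial, and matching the pair count
    keeps the null variance equal to the observed statistic's variance —
    without this, the location counterbalancing of real designs makes the
    test conservative.
    """
    n_perm = perms.shape[0]
    block_means = np.empty((n_perm, len(blocks)))
    for bi, (idx_set, mask) in enumerate(zip(blocks, masks)):
        idx = perms[:, idx_set]
        sub = cos[idx[:, :, None], idx[:, None, :]]
        block_means[:, bi] = (sub * mask).sum(axis=(1, 2)) / mask.sum()
    return block_means.mean(axis=1)


def _within_run_permutations(
    rng: np.random.Generator, runs: np.ndarray, n_perm: int
) -> np.ndarray:
    """Trial relabelings that shuffle labels independently within each run.

    Respects the event design (each entity occurs once per run, locations are
    balanced within runs), so permuted label blocks have the same cross-run
    structure as the observed ones.  A permutation spanning runs would pair
    temporally adjacent trials, whose overlapping responses are correlated
    even under the null, and would bias it.
    """
    perms = np.tile(np.arange(runs.size), (n_perm, 1))
    for r in pd.unique(runs):
        idx = np.flatnonzero(runs == r)
        perms[:, idx] = rng.permuted(np.tile(idx, (n_perm, 1)), axis=1)
    return perms


def _pair_counts(blocks: list[np.ndarray], other: np.ndarray) -> list[int]:
    out = []
    for idx in blocks:
        oth = other[idx]
        out.append(int((oth[:, None] != oth[None, :]).sum() // 2))
    return out


def _pair_statistic(
    subject_data: Sequence[tuple[ResponsePatternSet, TrialTable]],
    block_field: str,
    other_field: str,
    statistic_name: str,
    n_perm: int,
    seed: int | None,
    restrict_to_category=None,
    exclude: bool = True,
    null_mask: str = "inherited",
) -> PermutationResult:
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not subject_data:
        raise ValueError("no subject data")
    seeds = np.random.SeedSequence(seed).spawn(len(subject_data))
    per_obs = np.empty(len(subject_data))
    per_null = np.empty((len(subject_data), n_perm))
    counts_meta = []
    for si, ((rps, trials), ss) in enumerate(zip(subject_data, seeds)):
        df = trials.data
        if len(df) != rps.n_trials:
            raise ValueError(f"subject {si}: pattern set and trial table misaligned")
        block_vals = df[block_field].to_numpy()
        if exclude:
            other = df[other_field].to_numpy()
        else:
            other = np.arange(len(df))  # all distinct: every pair admissible
        levels = sorted(pd.unique(block_vals))
        if restrict_to_category is not None:
            in_cat = df["category"] == restrict_to_category
            kept = sorted(pd.unique(df.loc[in_cat, block_field]))
            if not kept:
                raise ValueError(f"no {block_field} in category {restrict_to_category!r}")
            levels = kept
        blocks = [np.flatnonzero(block_vals == lv) for lv in levels]
        for lv, idx in zip(levels, blocks):
            if idx.size < 2:
                raise ValueError(f"{block_field} {lv!r} has fewer than 2 trials")
        counts = _pair_counts(blocks, other)
        for lv, c in zip(levels, counts):
            if c == 0:
                raise ValueError(
                    f"{block_field} {lv!r} has no admissible trial pair"
                )
        counts_meta.append(dict(zip(map(str, levels), counts)))
        cos = _unit_rows(rps.values) @ _unit_rows(rps.values).T
        identity = np.arange(len(df))[None, :]
        rng = np.random.default_rng(ss)
        runs = df["run"].to_numpy()
        perms = _within_run_permutations(rng, runs, n_perm)
        if null_mask == "inherited":
            masks = [other[I][:, None] != other[I][None, :] for I in blocks]
            per_obs[si] = _pair_mean_fixed_mask(cos, blocks, masks, identity)[0]
            per_null[si] = _pair_mean_fixed_mask(cos, blocks, masks, perms)
        else:
            per_obs[si] = _pair_mean(cos, blocks, other, identity)[0][0]
            null_s, _ = _pair_mean(cos, blocks, other, perms)
            # a permutation can (rarely, on tiny designs) leave every block
            # without an admissible pair; redraw those permutations
            bad = np.flatnonzero(np.isnan(null_s))
            while bad.size:
                redraw = _within_run_permutations(rng, runs, bad.size)
                null_s[bad], _ = _pair_mean(cos, blocks, other, redraw)
                bad = np.flatnonzero(np.isnan(null_s))
            per_null[si] = null_s
    observed = float(per_obs.mean())
    null = per_null.mean(axis=0)
    result = make_result(
        statistic_name,
        observed,
        null,
        seed,
        n_subjects=len(subject_data),
        admissible_pairs=counts_meta,
    )
    result.per_subject_observed = per_obs
    result.per_subject_null = per_null
    return result


def identity_statistic(
    subject_data: Sequence[tuple[ResponsePatternSet, TrialTable]],
    n_perm: int = 10000,
    seed: int | None = None,
    restrict_to_category=None,
    exclude_same_location: bool = True,
) -> PermutationResult:
    """Mean cosine over same-entity trial pairs presented at different locations.

    Averaged over entities per subject, then over subjects.  The null permutes
    entity labels across trials within each run (locations fixed), with an
    independent permutation per subject per iteration; permuted blocks reuse
    the observed blocks' exclusion masks, keeping pair counts identical.
    ``exclude_same_location=False`` is a test-only switch that drops the
    exclusion to pin its effect.
    """
    return _pair_statistic(
        subject_data,
        block_field="entity",
        other_field="location",
        statistic_name="identity_cosine",
        n_perm=n_perm,
        seed=seed,
        restrict_to_category=restrict_to_category,
        exclude=exclude_same_location,
        null_mask="inherited",
    )


def location_statistic(
    subject_data: Sequence[tuple[ResponsePatternSet, TrialTable]],
    n_perm: int = 10000,
    seed: int | None = None,
    exclude_same_entity: bool = True,
) -> PermutationResult:
    """Mean cosine over same-location trial pairs of different entities.

    Mirror of :func:`identity_statistic` with the entity and location roles
    swapped; the same-entity exclusion applies to observed and null alike.
    """
    return _pair_statistic(
        subject_data,
        block_field="location",
        other_field="entity",
        statistic_name="location_cosine",
        n_perm=n_perm,
        seed=seed,
        exclude=exclude_same_entity,
        null_mask="permuted",
    )


# ---------------------------------------------------------------------------
# rank-based secondary comparisons


def subject_rank(
    observed: Sequence[float],
    nulls: np.ndarray,
    subjects: Sequence | None = None,
) -> list[SubjectRank]:
    """Percentile of each subject's statistic within their own null samples."""
    observed = np.asarray(observed, dtype=float)
    nulls = np.asarray(nulls, dtype=float)
    if nulls.ndim != 2 or nulls.shape[0] != observed.size:
        raise ValueError("nulls must be an (n_subjects, n_perm) matrix")
    if nulls.shape[1] < 100:
        raise ValueError("subject ranks require at least 100 null samples")
    if subjects is None:
        subjects = list(range(observed.size))
    n_perm = nulls.shape[1]
    return [
        SubjectRank(s, (1 + int(np.sum(nulls[i] <= observed[i]))) / (n_perm + 1))
        for i, s in enumerate(subjects)
    ]


def _rank_values(ranks) -> np.ndarray:
    vals = [r.percentile if isinstance(r, SubjectRank) else float(r) for r in ranks]
    return np.asarray(vals, dtype=float)


def compare_conditions(
    ranks_a,
    ranks_b,
    paired: bool = True,
    tail: str = "two",
) -> float:
    """Rank-based comparison of two conditions' subject percentiles.

    Paired: Wilcoxon signed-rank on within-subject differences (zeros dropped,
    midranks for ties; exact null for n <= 25 without ties, normal
    approximation with continuity correction otherwise).  Unpaired:
    Mann-Whitney U, two-tailed.  ``tail='one'`` tests a > b.
    """
    a = _rank_values(ranks_a)
    b = _rank_values(ranks_b)
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    alternative = "greater" if tail == "one" else "two-sided"
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal-length rank lists")
        diffs = a - b
        nz = diffs[diffs != 0]
        if nz.size == 0:
            return 1.0  # no information: identical paired ranks
        method = "exact" if nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size else "approx"
        res = sps.wilcoxon(
            nz, alternative=alternative, method=method, correction=(method == "approx")
        )
        return float(res.pvalue)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", use_continuity=True)
    return float(res.pvalue)


def subjectwise_diagnostics(
    per_subject_rho: Sequence[float],
    per_subject_p: Sequence[float],
) -> dict:
    """Normality and location diagnostics of per-subject correlations.

    Shapiro-Wilk on the correlations; one-sample (one-tailed, greater) t-test
    against zero; the per-subject p-values are mapped to Z = Phi^-1(1 - p) and
    the same two tests are run on the Z scores.
    """
    rho = np.asarray(per_subject_rho, dtype=float)
    pvals = np.asarray(per_subject_p, dtype=float)
    if rho.size < 3 or pvals.size != rho.size:
        raise ValueError("need >= 3 subjects with matching rho and p vectors")
    if np.ptp(rho) == 0:
        raise ValueError("per-subject correlations are constant; tests degenerate")
    z = sps.norm.isf(pvals)
    out = {
        "n_subjects": int(rho.size),
        "rho_mean": float(rho.mean()),
        "shapiro_rho_p": float(sps.shapiro(rho).pvalue),
        "ttest_rho_p": float(sps.ttest_1samp(rho, 0.0, alternative="greater").pvalue),
        "z_scores": z,
        "z_mean": float(z.mean()),
    }
    if np.ptp(z) == 0:
        raise ValueError("per-subject Z scores are constant; tests degenerate")
    out["shapiro_z_p"] = float(sps.shapiro(z).pvalue)
    out["ttest_z_p"] = float(sps.ttest_1samp(z, 0.0, alternative="greater").pvalue)
    return out
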