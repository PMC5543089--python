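"""Trial-level response extraction from event-related voxel time series.

The per-trial, per-voxel response measure is the area under the curve of the
BOLD signal in a post-stimulus window (default 2-8 s), computed by linear
interpolation of the frame-sampled signal onto a fine peristimulus grid and
trapezoidal integration.  Nuisance regression (motion + discrete-cosine
drift) runs per voxel via ordinary least squares, per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "TrialTable",
    "VoxelTimeSeries",
    "ResponsePatternSet",
    "dct_drift_basis",
    "nuisance_regress",
    "bold_integral",
    "extract_patterns",
    "average_patterns",
]

TRIAL_COLUMNS = (
    "subject",
    "run",
    "onset",
    "entity",
    "category",
    "location",
    "size",
    "mirrored",
)


@dataclass
class TrialTable:
    """One record per stimulus presentation, with all design labels.

    Invariants: onsets strictly increasing within each (subject, run); each
    (subject, run, entity) appears at most once; locations drawn from the
    declared set.
    """

    data: pd.DataFrame
    locations: tuple = (1, 2, 3, 4)

    def __post_init__(self) -> None:
        missing = [c for c in TRIAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"events table missing columns: {missing}")
        df = self.data.reset_index(drop=True)
        bad_loc = ~df["location"].isin(self.locations)
        if bad_loc.any():
            rows = df.index[bad_loc].tolist()[:5]
            raise ValueError(
                f"locations outside declared set {self.locations} at rows {rows}"
            )
        for (sub, run), grp in df.groupby(["subject", "run"], sort=False):
            onsets = grp["onset"].to_numpy(dtype=float)
            if np.any(np.diff(onsets) <= 0):
                raise ValueError(
                    f"onsets not strictly increasing in subject {sub!r} run {run!r}"
                )
            if grp["entity"].duplicated().any():
                dup = grp.loc[grp["entity"].duplicated(), "entity"].iloc[0]
                raise ValueError(
                    f"entity {dup!r} repeated within subject {sub!r} run {run!r}"
                )
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.data["subject"]))

    @property
    def entities(self) -> list:
        return sorted(pd.unique(self.data["entity"]))

    def for_subject(self, subject) -> "TrialTable":
        sub = self.data[self.data["subject"] == subject]
        if sub.empty:
            raise ValueError(f"no trials for subject {subject!r}")
        return TrialTable(sub.reset_index(drop=True), self.locations)


@dataclass
class VoxelTimeSeries:
    """Frame-sampled signal for one run: time x voxel, sampling interval TR."""

    run: object
    tr: float
    values: np.ndarray
    voxel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("values must be a time x voxel matrix with >= 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.tr


@dataclass
class ResponsePatternSet:
    """Per-trial voxel vectors of BOLD integrals (units: signal x seconds)."""

    values: np.ndarray
    window: tuple[float, float]
    trial_ids: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be trial x voxel")
        if not self.window[0] < self.window[1]:
            raise ValueError("window start must precede window end")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def dct_drift_basis(n_frames: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete cosine drift regressors for periods longer than ``cutoff`` seconds.

    Returns ``n_frames x k`` with k = floor(2 * n_frames * tr / cutoff); the
    constant term is excluded (the regression adds its own intercept).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    k = int(np.floor(2.0 * n_frames * tr / cutoff))
    t = np.arange(n_frames)
    cols = [
        np.sqrt(2.0 / n_frames) * np.cos(np.pi * (2 * t + 1) * j / (2 * n_frames))
        for j in range(1, k + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_frames, 0))


def nuisance_regress(
    ts: VoxelTimeSeries,
    regressors: np.ndarray | None = None,
    highpass_cutoff: float = 128.0,
) -> VoxelTimeSeries:
    """OLS residuals against [intercept | nuisance regressors | cosine drift].

    Residuals are orthogonal to every design column.  A rank-deficient design
    raises, naming the collinear columns.
    """
    if highpass_cutoff <= 2 * ts.tr:
        raise ValueError("highpass_cutoff must exceed twice the TR")
    n = ts.n_frames
    parts = [np.ones((n, 1))]
    names = ["intercept"]
    if regressors is not None:
        reg = np.asarray(regressors, dtype=float)
        if reg.ndim == 1:
            reg = reg[:, None]
        if reg.shape[0] != n:
            raise ValueError(
                f"regressors have {reg.shape[0]} rows for {n} frames"
            )
        parts.append(reg)
        names += [f"regressor_{i}" for i in range(reg.shape[1])]
    drift = dct_drift_basis(n, ts.tr, highpass_cutoff)
    parts.append(drift)
    names += [f"drift_{i}" for i in range(drift.shape[1])]
    design = np.hstack(parts)
    # pivoted QR exposes which columns are linearly dependent
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag[0] * max(design.shape) * np.finfo(float).eps
    dead = diag < tol
    if dead.any():
        bad = [names[piv[i]] for i in np.flatnonzero(dead)]
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    resid = ts.values - design @ beta
    return VoxelTimeSeries(ts.run, ts.tr, resid, ts.voxel_ids)


def _integration_weights(
    onsets: np.ndarray,
    n_frames: int,
    tr: float,
    window: tuple[float, float],
    substep: float,
) -> np.ndarray:
    """Trials x frames matrix Q such that integrals = Q @ values.

    Encodes linear interpolation onto the peristimulus grid followed by the
    trapezoidal rule, so the whole extraction is one matrix product.
    """
    start, end = window
    n_steps = int(round((end - start) / substep))
    grid = start + np.arange(n_steps + 1) * substep
    trapz = np.full(n_steps + 1, substep)
    trapz[0] = trapz[-1] = substep / 2.0
    q = np.zeros((onsets.size, n_frames))
    for t, onset in enumerate(onsets):
        times = onset + grid
        pos = times / tr
        k = np.floor(pos).astype(int)
        k = np.minimum(k, n_frames - 2)
        frac = pos - k
        np.add.at(q[t], k, trapz * (1.0 - frac))
        np.add.at(q[t], k + 1, trapz * frac)
    return q


def bold_integral(
    ts: VoxelTimeSeries,
    onsets: Sequence[float],
    window: tuple[float, float] = (2.0, 8.0),
    substep: float = 0.1,
) -> ResponsePatternSet:
    """Area under the BOLD curve in a post-stimulus window, per trial and voxel.

    The frame-sampled signal is linearly interpolated onto a peristimulus grid
    from ``window[0]`` to ``window[1]`` at ``substep`` resolution and
    integrated with the trapezoidal rule.  No baseline is subtracted.
    """
    onsets = np.asarray(onsets, dtype=float)
    if substep <= 0 or substep > ts.tr:
        raise ValueError("substep must be in (0, TR]")
    if not window[0] < window[1]:
        raise ValueError("window start must precede window end")
    late = np.flatnonzero(onsets + window[1] > ts.duration + 1e-9)
    if late.size:
        raise ValueError(
            f"trial {late[0]} (onset {onsets[late[0]]:.2f}s) extends past the end "
            f"of run {ts.run!r} ({ts.duration:.2f}s)"
        )
    if np.any(onsets + window[0] < 0):
        raise ValueError("window starts before the run for some trial")
    q = _integration_weights(onsets, ts.n_frames, ts.tr, window, substep)
    return ResponsePatternSet(q @ ts.values, window)


def extract_patterns(
    run_series: Mapping[object, VoxelTimeSeries],
    trials: TrialTable,
    window: tuple[float, float] = (2.0, 8.0),
    substep: float = 0.1,
) -> ResponsePatternSet:
    """BOLD integrals for every trial of one subject, aligned to table rows."""
    df = trials.data
    if df["subject"].nunique() > 1:
        raise ValueError("extract_patterns expects a single subject's trials")
    n_vox = {ts.n_voxels for ts in run_series.values()}
    if len(n_vox) != 1:
        raise ValueError("runs have differing voxel counts")
    out = np.empty((len(df), n_vox.pop()))
    for run, grp in df.groupby("run", sort=False):
        if run not in run_series:
            raise ValueError(f"no time series supplied for run {run!r}")
        rps = bold_integral(
            run_series[run], grp["onset"].to_numpy(), window, substep
        )
        out[grp.index.to_numpy()] = rps.values
    return ResponsePatternSet(out, window, trial_ids=df.index.to_numpy())


def average_patterns(
    rps: ResponsePatternSet,
    trials: TrialTable,
    group_by: str = "entity",
) -> tuple[dict, dict]:
    """Mean trial vector per level of a design factor, plus group sizes."""
    df = trials.data
    if group_by not in df.columns:
        raise ValueError(f"unknown design field {group_by!r}")
    if len(df) != rps.n_trials:
        raise ValueError(
            f"pattern set has {rps.n_trials} trials but table has {len(df)}"
        )
    means, counts = {}, {}
    for label, grp in df.groupby(group_by, sort=True):
        idx = grp.index.to_numpy()
        if idx.size == 0:
            raise ValueError(f"empty group {label!r}")
        means[label] = rps.values[idx].mean(axis=0)
        counts[label] = int(idx.size)
    return means, counts
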