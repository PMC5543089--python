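"""File readers and writers for every pipeline data type.

Conventions: events are BIDS-style TSV with onsets in seconds from run start;
similarity matrices are CSV with labels as both header and first column,
written with 10 significant digits; volumes are NIfTI-1; masks additionally
round-trip through a plain-text index list carrying the grid geometry.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .masks import Grid, VoiMask
from .matrices import ConceptFeatureMatrix, FeatureLayerSet, SimilarityMatrix
from .permutation import PermutationResult
from .response import TRIAL_COLUMNS, TrialTable, VoxelTimeSeries

__all__ = [
    "read_events", "write_events",
    "read_matrix", "write_matrix",
    "read_concept_features", "read_transcriptions", "read_feature_layers",
    "read_mask_nifti", "write_mask_nifti", "read_mask_tsv", "write_mask_tsv",
    "read_volume_timeseries", "write_volume_timeseries", "timeseries_from_volume",
    "write_permutation_result",
    "write_dataset", "read_dataset",
]

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# events


def write_events(trials: TrialTable, path) -> None:
    trials.data.to_csv(path, sep="\t", index=False)


def read_events(path, locations: tuple = (1, 2, 3, 4)) -> TrialTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col, kind in (("onset", float), ("location", int)):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise ValueError(f"{path}: malformed {col!r} value at line {line}")
        df[col] = coerced.astype(kind)
    df["mirrored"] = df["mirrored"].astype(bool)
    return TrialTable(df, locations)


# ---------------------------------------------------------------------------
# similarity and feature matrices


def write_matrix(sm: SimilarityMatrix, path) -> None:
    pd.DataFrame(sm.values, index=sm.labels, columns=sm.labels).to_csv(
        path, float_format=_FLOAT_FMT
    )


def read_matrix(path) -> SimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    return SimilarityMatrix(labels, df.to_numpy(dtype=float), {"source": str(path)})


def read_concept_features(path) -> ConceptFeatureMatrix:
    """CSV: first column entity label, header row feature labels, numeric cells."""
    df = pd.read_csv(path, index_col=0)
    return ConceptFeatureMatrix(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(dtype=float),
    )


def read_transcriptions(path) -> dict[str, str]:
    """2-column TSV (label, transcription), one symbol per code point."""
    df = pd.read_csv(path, sep="\t", header=None, names=["label", "transcription"],
                     dtype=str, keep_default_na=False)
    out = {}
    for i, row in df.iterrows():
        if not row["transcription"]:
            raise ValueError(f"{path}: empty transcription at line {i + 1}")
        out[row["label"]] = row["transcription"]
    return out


def read_feature_layers(manifest_path) -> FeatureLayerSet:
    """Ordered manifest: one ``layer_name<TAB>csv_path`` per line.

    Each CSV has the stimulus label in the first column; paths are resolved
    relative to the manifest.
    """
    manifest = Path(manifest_path)
    layers = []
    stim_labels = None
    for raw in manifest.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        name, rel = line.split("\t")
        df = pd.read_csv(manifest.parent / rel, index_col=0)
        labels = [str(i) for i in df.index]
        if stim_labels is None:
            stim_labels = labels
        elif labels != stim_labels:
            raise ValueError(f"layer {name!r}: stimulus labels differ from first layer")
        layers.append((name, df.to_numpy(dtype=float)))
    if stim_labels is None:
        raise ValueError(f"{manifest}: no layers listed")
    return FeatureLayerSet(stim_labels, layers)


# ---------------------------------------------------------------------------
# volumes and masks


def write_mask_nifti(mask: VoiMask, path) -> None:
    img = nib.Nifti1Image(mask.to_volume().astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def read_mask_nifti(path, name: str | None = None) -> VoiMask:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    return VoiMask(
        Grid(vol.shape, img.affine),
        np.argwhere(vol > 0),
        name or Path(path).stem,
        {"kind": "file", "path": str(path)},
    )


def write_mask_tsv(mask: VoiMask, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name: {mask.name}\n")
        fh.write(f"# shape: {' '.join(map(str, mask.grid.shape))}\n")
        fh.write("# affine: " + " ".join(_FLOAT_FMT % v for v in mask.grid.affine.ravel()) + "\n")
        fh.write("# provenance: " + json.dumps(mask.provenance, default=str) + "\n")
        fh.write("i\tj\tk\n")
        for i, j, k in mask.indices:
            fh.write(f"{i}\t{j}\t{k}\n")


def read_mask_tsv(path) -> VoiMask:
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                header[key.strip()] = val.strip()
            elif line.strip() and not line.startswith("i\t"):
                rows.append([int(x) for x in line.split()])
    shape = tuple(int(x) for x in header["shape"].split())
    affine = np.array([float(x) for x in header["affine"].split()]).reshape(4, 4)
    return VoiMask(
        Grid(shape, affine),
        np.asarray(rows, dtype=int),
        header.get("name", Path(path).stem),
        json.loads(header.get("provenance", "{}")),
    )


def write_volume_timeseries(
    ts: VoxelTimeSeries, mask: VoiMask, path
) -> None:
    """Embed a time x voxel matrix into a 4D NIfTI through a mask."""
    if ts.n_voxels != mask.size:
        raise ValueError(
            f"time series has {ts.n_voxels} voxels but mask has {mask.size}"
        )
    vol = np.zeros(mask.grid.shape + (ts.n_frames,), dtype=np.float64)
    vol[tuple(mask.indices.T)] = ts.values.T
    img = nib.Nifti1Image(vol, mask.grid.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (ts.tr,))
    nib.save(img, str(path))


def read_volume_timeseries(path, mask: VoiMask, run=None) -> VoxelTimeSeries:
    img = nib.load(str(path))
    return timeseries_from_volume(img, mask, run=run)


def timeseries_from_volume(img, mask: VoiMask, run=None) -> VoxelTimeSeries:
    """Sample a 4D image at a mask's voxels; checks the affine matches."""
    if not np.allclose(img.affine, mask.grid.affine, atol=1e-6):
        raise ValueError("image affine does not match mask grid")
    if img.shape[:3] != mask.grid.shape:
        raise ValueError(
            f"image shape {img.shape[:3]} does not match mask grid {mask.grid.shape}"
        )
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr <= 0:
        raise ValueError("image header does not carry a positive TR")
    data = np.asarray(img.dataobj)
    values = data[tuple(mask.indices.T)].T
    return VoxelTimeSeries(run, tr, values)


# ---------------------------------------------------------------------------
# permutation results


def write_permutation_result(
    result: PermutationResult, path, null_path=None
) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")
    if null_path is not None:
        np.savetxt(null_path, result.null, fmt=_FLOAT_FMT, header="null_sample")


# ---------------------------------------------------------------------------
# whole synthetic datasets


def _cube_grid(n_voxels: int, voxel_mm: float = 3.0) -> tuple[Grid, VoiMask]:
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    shape = (side, side, side)
    while int(np.prod(shape)) < n_voxels:
        shape = (shape[0] + 1, shape[1], shape[2])
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * np.asarray(shape) / 2.0
    grid = Grid(shape, affine)
    idx = grid.all_indices()[:n_voxels]
    return grid, VoiMask(grid, idx, "simulated", {"kind": "simulated"})


def write_dataset(
    subjects: Sequence[Mapping[object, VoxelTimeSeries]],
    trials: TrialTable,
    out_dir,
    model: SimilarityMatrix | None = None,
    ground_truth=None,
) -> VoiMask:
    """Write a generated dataset as NIfTI volumes + events TSV (+ model CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_voxels = next(iter(subjects[0].values())).n_voxels
    _, mask = _cube_grid(n_voxels)
    write_mask_nifti(mask, out / "mask.nii")
    write_mask_tsv(mask, out / "mask.tsv")
    write_events(trials, out / "events.tsv")
    if model is not None:
        write_matrix(model, out / "model.csv")
    sub_ids = trials.subjects
    if len(sub_ids) != len(subjects):
        raise ValueError("subject count mismatch between runs and events")
    for sub_id, runs in zip(sub_ids, subjects):
        for run_id, ts in runs.items():
            path = out / f"{sub_id}_run-{int(run_id):02d}_bold.nii"
            write_volume_timeseries(ts, mask, path)
    if ground_truth is not None:
        for sub_id, gt in zip(sub_ids, ground_truth):
            np.savetxt(out / f"{sub_id}_entity_patterns.csv",
                       gt.entity_patterns, delimiter=",", fmt=_FLOAT_FMT)
            np.savetxt(out / f"{sub_id}_location_patterns.csv",
                       gt.location_patterns, delimiter=",", fmt=_FLOAT_FMT)
            write_matrix(gt.realized, out / f"{sub_id}_realized.csv")
    return mask


_BOLD_RE = re.compile(r"(?P<sub>sub-\d+)_run-(?P<run>\d+)_bold\.nii$")


def read_dataset(
    data_dir, mask: VoiMask | None = None
) -> tuple[list[dict], TrialTable, SimilarityMatrix | None, VoiMask]:
    """Load a dataset directory written by :func:`write_dataset`."""
    data = Path(data_dir)
    if mask is None:
        mask = read_mask_tsv(data / "mask.tsv")
    trials = read_events(data / "events.tsv")
    model = None
    if (data / "model.csv").exists():
        model = read_matrix(data / "model.csv")
    subjects = []
    for sub_id in trials.subjects:
        runs = {}
        for path in sorted(data.glob(f"{sub_id}_run-*_bold.nii")):
            m = _BOLD_RE.search(path.name)
            run_id = int(m.group("run"))
            runs[run_id] = read_volume_timeseries(path, mask, run=run_id)
        if not runs:
            raise ValueError(f"no time series found for subject {sub_id!r}")
        subjects.append(runs)
    return subjects, trials, model, mask
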