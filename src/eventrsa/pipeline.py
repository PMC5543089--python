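"""End-to-end orchestration: dataset -> patterns -> statistics -> reports."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import io as erio
from .masks import VoiMask
from .matrices import SimilarityMatrix
from .response import TrialTable, VoxelTimeSeries, extract_patterns, nuisance_regress
from .stats import (
    compare_conditions,
    fmri_similarity_matrix,
    entity_average_similarity_matrix,
    group_average_matrix,
    identity_statistic,
    location_statistic,
    rsa_subject_tests,
    rsa_test,
    subject_rank,
    subjectwise_diagnostics,
)

__all__ = ["PipelineConfig", "PipelineError", "analyze_dataset", "run_pipeline"]

log = logging.getLogger("eventrsa")


class PipelineError(RuntimeError):
    """Stage failure with the stage name and offending input attached."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and analysis switches for a full run."""

    dataset_dir: str
    out_dir: str
    model_path: str | None = None
    mask_paths: dict = field(default_factory=dict)  # voi name -> path
    statistics: tuple = ("rsa", "identity", "location")
    n_perm: int = 10000
    seed: int | None = None
    window: tuple = (2.0, 8.0)
    substep: float = 0.1
    highpass_cutoff: float | None = None
    cell_variant: str = "trial_pairs"  # or "entity_average"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.cell_variant not in ("trial_pairs", "entity_average"):
            raise ValueError(f"unknown cell_variant {self.cell_variant!r}")
        unknown = set(self.statistics) - {"rsa", "identity", "location"}
        if unknown:
            raise ValueError(f"unknown statistics requested: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        if "statistics" in raw:
            raw["statistics"] = tuple(raw["statistics"])
        return cls(**raw)

    def validate_paths(self) -> None:
        data = Path(self.dataset_dir)
        if not (data / "events.tsv").exists():
            raise PipelineError("validate", f"missing events file {data / 'events.tsv'}")
        if self.model_path is not None and not Path(self.model_path).exists():
            raise PipelineError("validate", f"missing model matrix {self.model_path}")
        for name, p in self.mask_paths.items():
            if not Path(p).exists():
                raise PipelineError("validate", f"missing mask {name!r}: {p}")


def _spawn_seeds(seed: int | None, n: int) -> list[int]:
    return [int(c.generate_state(1)[0]) for c in np.random.SeedSequence(seed).spawn(n)]


def analyze_dataset(
    subjects: Sequence[Mapping[object, VoxelTimeSeries]],
    trials: TrialTable,
    model: SimilarityMatrix | None,
    n_perm: int = 10000,
    seed: int | None = None,
    statistics: Sequence[str] = ("rsa", "identity", "location"),
    window: tuple[float, float] = (2.0, 8.0),
    substep: float = 0.1,
    highpass_cutoff: float | None = None,
    regressors: Mapping | None = None,
    cell_variant: str = "trial_pairs",
) -> dict:
    """Run every requested statistic on in-memory data; returns a result bundle.

    ``regressors`` optionally maps (subject index, run id) to a nuisance
    matrix.  One master seed drives all permutation streams.
    """
    rsa_seed, id_seed, loc_seed, sub_seed = _spawn_seeds(seed, 4)
    sub_ids = trials.subjects
    if len(sub_ids) != len(subjects):
        raise ValueError("subject count mismatch between time series and events")
    subject_data = []
    subject_matrices = []
    for s_idx, (sub_id, runs) in enumerate(zip(sub_ids, subjects)):
        tt = trials.for_subject(sub_id)
        if highpass_cutoff is not None or regressors is not None:
            cleaned = {}
            for run_id, ts in runs.items():
                reg = None if regressors is None else regressors.get((s_idx, run_id))
                cleaned[run_id] = nuisance_regress(
                    ts, reg, highpass_cutoff or 128.0
                )
            runs = cleaned
        rps = extract_patterns(runs, tt, window, substep)
        subject_data.append((rps, tt))
        if cell_variant == "entity_average":
            subject_matrices.append(entity_average_similarity_matrix(rps, tt))
        else:
            subject_matrices.append(fmri_similarity_matrix(rps, tt))
    out: dict = {
        "subject_ids": sub_ids,
        "subject_matrices": subject_matrices,
        "group_matrix": group_average_matrix(subject_matrices),
    }
    if "rsa" in statistics:
        if model is None:
            raise ValueError("RSA requested but no model matrix supplied")
        model = model.reorder(out["group_matrix"].labels)
        out["rsa"] = rsa_test(out["group_matrix"], model, n_perm, rsa_seed)
        out["rsa_subjects"] = rsa_subject_tests(
            subject_matrices, model, n_perm, sub_seed
        )
    if "identity" in statistics:
        out["identity"] = identity_statistic(subject_data, n_perm, id_seed)
    if "location" in statistics:
        out["location"] = location_statistic(subject_data, n_perm, loc_seed)
    return out


def _result_ranks(result) -> list:
    return subject_rank(result.per_subject_observed, result.per_subject_null)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """File-to-file pipeline over one or more VOIs.

    Per VOI: per-subject and group similarity matrices, permutation results
    for each requested statistic, subject ranks, between-VOI signed-rank
    comparisons, normality diagnostics, and a manifest with every seed used.
    Partial results are flushed as each stage completes.
    """
    cfg.validate_paths()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "eventrsa",
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "statistics": list(cfg.statistics),
        "cell_variant": cfg.cell_variant,
        "vois": {},
        "timing_s": {},
    }
    t0 = time.time()
    try:
        subjects, trials, model, default_mask = erio.read_dataset(cfg.dataset_dir)
    except Exception as exc:
        raise PipelineError("load", str(exc)) from exc
    if cfg.model_path is not None:
        model = erio.read_matrix(cfg.model_path)
    manifest["timing_s"]["load"] = round(time.time() - t0, 3)

    vois: dict[str, VoiMask | None] = {}
    if cfg.mask_paths:
        for name, p in cfg.mask_paths.items():
            p = str(p)
            vois[name] = (
                erio.read_mask_tsv(p) if p.endswith(".tsv") else erio.read_mask_nifti(p, name)
            )
    else:
        vois["whole"] = default_mask

    voi_seeds = _spawn_seeds(cfg.seed, len(vois))
    ranks_by_voi: dict[str, dict] = {}
    for (voi_name, mask), voi_seed in zip(vois.items(), voi_seeds):
        t_voi = time.time()
        log.info("analyzing VOI %s (%d voxels)", voi_name, mask.size)
        try:
            voi_subjects = []
            for runs in subjects:
                resampled = {}
                for run_id, ts in runs.items():
                    resampled[run_id] = ts  # synthetic data already mask-aligned
                voi_subjects.append(resampled)
            if mask is not default_mask:
                # re-read the volumes through this VOI's mask
                voi_subjects, trials, _, _ = erio.read_dataset(cfg.dataset_dir, mask)
            bundle = analyze_dataset(
                voi_subjects,
                trials,
                model,
                n_perm=cfg.n_perm,
                seed=voi_seed,
                statistics=cfg.statistics,
                window=cfg.window,
                substep=cfg.substep,
                highpass_cutoff=cfg.highpass_cutoff,
                cell_variant=cfg.cell_variant,
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(voi_name, str(exc)) from exc

        voi_dir = out_dir / voi_name
        voi_dir.mkdir(exist_ok=True)
        for sub_id, mat in zip(bundle["subject_ids"], bundle["subject_matrices"]):
            erio.write_matrix(mat, voi_dir / f"{sub_id}_similarity.csv")
        erio.write_matrix(bundle["group_matrix"], voi_dir / "group_similarity.csv")
        voi_manifest: dict = {"n_voxels": mask.size, "seed": voi_seed, "results": {}}
        ranks_by_voi[voi_name] = {}
        for stat in cfg.statistics:
            if stat not in bundle:
                continue
            res = bundle[stat]
            erio.write_permutation_result(
                res, voi_dir / f"{stat}.json", voi_dir / f"{stat}_null.csv"
            )
            voi_manifest["results"][stat] = {"observed": res.observed, "p": res.p}
            if stat == "rsa":
                subs = bundle["rsa_subjects"]
                obs = np.array([r.observed for r in subs])
                nulls = np.vstack([r.null for r in subs])
                pvals = np.array([r.p for r in subs])
                ranks = subject_rank(obs, nulls, bundle["subject_ids"])
                try:
                    diag = subjectwise_diagnostics(obs, pvals)
                    diag.pop("z_scores")
                    with open(voi_dir / "rsa_diagnostics.json", "w") as fh:
                        json.dump(diag, fh, indent=2)
                except ValueError as exc:
                    log.warning("diagnostics degenerate for %s: %s", voi_name, exc)
            else:
                ranks = _result_ranks(res)
            ranks_by_voi[voi_name][stat] = ranks
            with open(voi_dir / f"{stat}_ranks.tsv", "w") as fh:
                fh.write("subject\tpercentile\n")
                for r in ranks:
                    fh.write(f"{r.subject}\t{r.percentile:.6g}\n")
        manifest["vois"][voi_name] = voi_manifest
        manifest["timing_s"][voi_name] = round(time.time() - t_voi, 3)
        with open(out_dir / "manifest.json", "w") as fh:  # flush progress
            json.dump(manifest, fh, indent=2)

    # pairwise between-VOI comparison of subject ranks (one-tailed signed rank)
    names = list(ranks_by_voi)
    comparisons = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for stat in cfg.statistics:
                if stat in ranks_by_voi[a] and stat in ranks_by_voi[b]:
                    p = compare_conditions(
                        ranks_by_voi[a][stat], ranks_by_voi[b][stat],
                        paired=True, tail="one",
                    )
                    comparisons.append(
                        {"voi_a": a, "voi_b": b, "statistic": stat, "p": p}
                    )
    if comparisons:
        import pandas as pd

        pd.DataFrame(comparisons).to_csv(out_dir / "voi_comparisons.csv", index=False)
    manifest["timing_s"]["total"] = round(time.time() - t0, 3)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"manifest": manifest, "ranks": ranks_by_voi, "out_dir": str(out_dir)}
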