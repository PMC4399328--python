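"""End-to-end orchestration: simulate → glm → decode → aggregate → report.

Every stage reads its inputs from and writes its outputs to the working
directory, so chained CLI subcommands and the one-shot ``run_pipeline``
produce identical artifacts.  All randomness descends from one master
seed through named substreams.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from soundmvpa import __version__
from soundmvpa.aggregation import (
    DEFAULT_MIN_FOLDS,
    DEFAULT_MIN_SUBJECTS,
    binomial_tail,
    effective_voxels,
    recovery_scores,
    significant_effective_voxels,
)
from soundmvpa.decoding import group_accuracy_test, loro_cv_with_selections
from soundmvpa.geometry import CONDITIONS, build_speaker_array, condition_labels
from soundmvpa.glm import ResponseImage, build_design_matrix, fit_run_glm
from soundmvpa.rng import substream
from soundmvpa.selection import SelectionResult
from soundmvpa.synth import (
    PatternSpec,
    make_pattern_spec,
    read_dataset,
    simulate_subject,
    write_dataset,
)

logger = logging.getLogger("soundmvpa")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults mirror the experiment."""

    seed: int = 0
    n_subjects: int = 8
    synth: dict = field(default_factory=dict)
    conditions: tuple[str, ...] = CONDITIONS
    n_perm: int = 2000
    alpha: float = 0.05
    min_folds: int = DEFAULT_MIN_FOLDS
    min_subjects: int = DEFAULT_MIN_SUBJECTS
    svm_c: float = 1.0
    standardize: bool = True
    output_dir: str = "soundmvpa_out"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        payload = json.loads(path.read_text())
        allowed = set(cls.__dataclass_fields__)
        unknown = set(payload) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in payload:
            payload["conditions"] = tuple(payload["conditions"])
        return cls(**payload)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        return d


def _subject_ids(cfg: PipelineConfig) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(cfg.n_subjects)]


def _subject_seed(cfg: PipelineConfig, index: int) -> int:
    return int(substream(cfg.seed, "subject", index).integers(2**31))


def stage_simulate(cfg: PipelineConfig) -> None:
    """Simulate all subjects from a shared pattern spec and persist them."""
    t0 = time.monotonic()
    out = Path(cfg.output_dir)
    spec = make_pattern_spec(cfg.synth, seed=cfg.seed)
    for i, sid in enumerate(_subject_ids(cfg)):
        ds = simulate_subject(spec, seed=_subject_seed(cfg, i), subject_id=sid)
        write_dataset(ds, out / "subjects" / sid)
    logger.info("simulate: %d subjects in %.1fs", cfg.n_subjects, time.monotonic() - t0)


def _load_subjects(cfg: PipelineConfig):
    out = Path(cfg.output_dir)
    for sid in _subject_ids(cfg):
        yield sid, read_dataset(out / "subjects" / sid)


def stage_glm(cfg: PipelineConfig) -> None:
    """Fit the per-run beta-series GLM on the raw (unsmoothed) data."""
    t0 = time.monotonic()
    out = Path(cfg.output_dir)
    for sid, ds in _load_subjects(cfg):
        bdir = out / "betas" / sid
        bdir.mkdir(parents=True, exist_ok=True)
        for r, (design, vol) in enumerate(ds.runs):
            dm = build_design_matrix(design, acquisition_times=vol.acquisition_times_s)
            resp = fit_run_glm(vol, dm, run_id=r)
            affine = np.diag(list(vol.voxel_size_mm) + [1.0])
            data = np.moveaxis(resp.betas, 0, -1)  # (x, y, z, location)
            nib.save(nib.Nifti1Image(data, affine), bdir / f"run-{r:02d}_betas.nii.gz")
            nib.save(
                nib.Nifti1Image(resp.residual_variance, affine),
                bdir / f"run-{r:02d}_resvar.nii.gz",
            )
            sidecar = {
                "run_id": r,
                "location_ids": list(range(resp.n_beta_maps)),
                "smoothed": False,
            }
            (bdir / f"run-{r:02d}_betas.json").write_text(json.dumps(sidecar))
    logger.info("glm: done in %.1fs", time.monotonic() - t0)


def _load_responses(cfg: PipelineConfig, sid: str) -> list[ResponseImage]:
    bdir = Path(cfg.output_dir) / "betas" / sid
    responses = []
    for path in sorted(bdir.glob("run-*_betas.nii.gz")):
        sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
        if sidecar.get("smoothed"):
            raise ValueError(f"{path} was smoothed; the decoding path requires raw betas")
        data = np.asarray(nib.load(path).dataobj, dtype=np.float64)
        resvar = np.asarray(
            nib.load(path.parent / path.name.replace("_betas", "_resvar")).dataobj,
            dtype=np.float64,
        )
        responses.append(
            ResponseImage(
                run_id=int(sidecar["run_id"]),
                betas=np.moveaxis(data, -1, 0),
                residual_variance=resvar,
            )
        )
    if not responses:
        raise FileNotFoundError(f"no beta maps found under {bdir}")
    return responses


def _load_spec(cfg: PipelineConfig) -> PatternSpec:
    meta = json.loads(
        (Path(cfg.output_dir) / "subjects" / _subject_ids(cfg)[0] / "dataset.json").read_text()
    )
    return PatternSpec.from_json_dict(meta["pattern_spec"])


def stage_decode(cfg: PipelineConfig) -> None:
    """Leave-one-run-out decoding per subject and condition."""
    t0 = time.monotonic()
    out = Path(cfg.output_dir)
    spec = _load_spec(cfg)
    array = build_speaker_array()
    (out / "decoding").mkdir(parents=True, exist_ok=True)
    (out / "selections").mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(_subject_ids(cfg)):
        responses = _load_responses(cfg, sid)
        for cond in cfg.conditions:
            labeling = condition_labels(array, cond)
            result, selections = loro_cv_with_selections(
                responses,
                labeling,
                spec.roi_mask,
                n_perm=cfg.n_perm,
                alpha=cfg.alpha,
                C=cfg.svm_c,
                standardize=cfg.standardize,
                seed=int(substream(cfg.seed, "decode", i, cond).integers(2**31)),
                subject_id=sid,
            )
            (out / "decoding" / f"{sid}_{cond}.json").write_text(
                json.dumps(result.to_json_dict())
            )
            for sel in selections:
                sel.to_json(
                    out / "selections" / f"{sid}_{cond}_fold-{sel.fold_id}.json",
                    include_pvalues=False,
                )
    logger.info("decode: done in %.1fs", time.monotonic() - t0)


def stage_aggregate(cfg: PipelineConfig) -> None:
    """EV per subject, SEV across subjects, recovery vs planted truth."""
    t0 = time.monotonic()
    out = Path(cfg.output_dir)
    spec = _load_spec(cfg)
    grid_shape = tuple(spec.grid_shape)
    (out / "aggregate").mkdir(parents=True, exist_ok=True)
    for cond in cfg.conditions:
        ev_masks = []
        for sid in _subject_ids(cfg):
            sels = [
                SelectionResult.from_json(out / "selections" / f"{sid}_{cond}_fold-{f}.json")
                for f in range(8)
            ]
            ev_masks.append(
                effective_voxels(sels, grid_shape, min_folds=cfg.min_folds, subject_id=sid)
            )
        if len(ev_masks) >= cfg.min_subjects:
            sev = significant_effective_voxels(ev_masks, min_subjects=cfg.min_subjects)
            sev.to_json(out / "aggregate" / f"{cond}_sev.json")
            truth = spec.condition_patterns[cond].voxels
            recovery = recovery_scores(sev.mask, truth) if truth else None
        else:
            sev, recovery = None, None
        summary = {
            "condition": cond,
            "ev_counts": {m.subject_id: m.n_effective for m in ev_masks},
            "n_sev": sev.n_significant if sev else None,
            "binomial_tail_bound": (
                binomial_tail(cfg.n_subjects, cfg.alpha, cfg.min_subjects)
                if cfg.min_subjects <= cfg.n_subjects
                else None
            ),
            "recovery": recovery,
        }
        (out / "aggregate" / f"{cond}_summary.json").write_text(json.dumps(summary))
    logger.info("aggregate: done in %.1fs", time.monotonic() - t0)


def stage_report(cfg: PipelineConfig) -> dict:
    """Assemble the final JSON report from persisted stage outputs."""
    out = Path(cfg.output_dir)
    report: dict = {
        "software_version": __version__,
        "config": cfg.to_json_dict(),
        "subjects": {},
        "group": {},
        "aggregate": {},
    }
    for sid in _subject_ids(cfg):
        report["subjects"][sid] = {}
        for cond in cfg.conditions:
            payload = json.loads((out / "decoding" / f"{sid}_{cond}.json").read_text())
            report["subjects"][sid][cond] = payload
    for cond in cfg.conditions:
        accs = [report["subjects"][sid][cond]["mean_accuracy"] for sid in _subject_ids(cfg)]
        if len(accs) >= 2:
            group = group_accuracy_test(accs, condition=cond)
            report["group"][cond] = group.to_json_dict()
        summary_path = out / "aggregate" / f"{cond}_summary.json"
        if summary_path.exists():
            report["aggregate"][cond] = json.loads(summary_path.read_text())
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    lines = [f"soundmvpa {__version__} — seed {cfg.seed}, {cfg.n_subjects} subjects"]
    for cond in cfg.conditions:
        if cond in report["group"]:
            g = report["group"][cond]
            lines.append(
                f"{cond}: mean accuracy {g['group_mean']:.3f} "
                f"(chance {g['chance']}, p = {g['p_value']:.4g})"
            )
        agg = report["aggregate"].get(cond)
        if agg and agg.get("n_sev") is not None:
            lines.append(f"{cond}: {agg['n_sev']} significant effective voxels")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return report


_STAGES = {
    "simulate": stage_simulate,
    "glm": stage_glm,
    "decode": stage_decode,
    "aggregate": stage_aggregate,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and return the final report."""
    Path(cfg.output_dir).mkdir(parents=True, exist_ok=True)
    report = None
    for name, stage in _STAGES.items():
        try:
            result = stage(cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if name == "report":
            report = result
    return report
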