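"""Design generation and synthetic sparse-sampling datasets.

Emulates the scanning protocol: 8 runs of 76 trials at TR = 5.5 s, each
trial opening with a 2 s acquisition window; 64 stimulus trials per run
(4 per each of the 16 locations) and 12 silent trials in random order, the
550 ms stimulus jittered uniformly within the 2.5 s after acquisition.

Synthetic voxel time series are built from the same convolved regressors
the GLM uses: every ROI voxel carries a common baseline auditory response,
condition-informative voxels additionally carry a class-antisymmetric
location effect, and AR(1) noise plus a linear drift are added before
sampling one volume per trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from soundmvpa.geometry import CONDITIONS, build_speaker_array, condition_labels
from soundmvpa.hrf import sample_event_regressor
from soundmvpa.rng import substream

__all__ = [
    "TR_S",
    "N_TRIALS",
    "N_STIMULUS_TRIALS",
    "N_SILENT_TRIALS",
    "N_LOCATIONS",
    "TRIALS_PER_LOCATION",
    "N_RUNS",
    "STIM_DURATION_S",
    "ACQUISITION_DURATION_S",
    "JITTER_WINDOW_S",
    "Trial",
    "RunDesign",
    "ConditionPattern",
    "PatternSpec",
    "VolumeSeries",
    "SubjectDataset",
    "make_run_design",
    "make_pattern_spec",
    "default_roi_mask",
    "simulate_subject",
    "write_dataset",
    "read_dataset",
]

TR_S = 5.5
N_TRIALS = 76
N_STIMULUS_TRIALS = 64
N_SILENT_TRIALS = 12
N_LOCATIONS = 16
TRIALS_PER_LOCATION = 4
N_RUNS = 8
STIM_DURATION_S = 0.55
ACQUISITION_DURATION_S = 2.0
JITTER_WINDOW_S = 2.5


@dataclass(frozen=True)
class Trial:
    """One trial slot: acquisition burst followed by an optional stimulus."""

    index: int
    trial_type: str  # "stimulus" | "silent"
    location_id: int | None
    stim_onset_s: float | None
    stim_duration_s: float = STIM_DURATION_S

    def __post_init__(self) -> None:
        if self.trial_type not in ("stimulus", "silent"):
            raise ValueError(f"bad trial_type {self.trial_type!r}")
        if self.trial_type == "stimulus":
            if self.location_id is None or self.stim_onset_s is None:
                raise ValueError("stimulus trials need location_id and stim_onset_s")
            lo = self.trial_onset_s + ACQUISITION_DURATION_S
            if not (lo <= self.stim_onset_s <= lo + JITTER_WINDOW_S):
                raise ValueError(
                    f"stim_onset_s {self.stim_onset_s} outside the jitter window of trial {self.index}"
                )
        elif self.location_id is not None or self.stim_onset_s is not None:
            raise ValueError("silent trials carry no location or stimulus onset")

    @property
    def trial_onset_s(self) -> float:
        return self.index * TR_S

    @property
    def acquisition_onset_s(self) -> float:
        return self.trial_onset_s


@dataclass(frozen=True)
class RunDesign:
    """Ordered trial list for one functional run."""

    trials: tuple[Trial, ...]
    tr_s: float = TR_S

    def __post_init__(self) -> None:
        if len(self.trials) != N_TRIALS:
            raise ValueError(f"a run has {N_TRIALS} trials, got {len(self.trials)}")
        counts: dict[int, int] = {}
        n_silent = 0
        for i, tr in enumerate(self.trials):
            if tr.index != i:
                raise ValueError("trial indices must be 0..75 in order")
            if tr.trial_type == "silent":
                n_silent += 1
            else:
                counts[tr.location_id] = counts.get(tr.location_id, 0) + 1
        if n_silent != N_SILENT_TRIALS or any(
            counts.get(l, 0) != TRIALS_PER_LOCATION for l in range(N_LOCATIONS)
        ):
            raise ValueError("run must hold 12 silent trials and 4 stimulus trials per location")

    @property
    def run_duration_s(self) -> float:
        return len(self.trials) * self.tr_s

    @property
    def acquisition_times_s(self) -> np.ndarray:
        return np.array([t.acquisition_onset_s for t in self.trials])

    def stimulus_trials(self, location_id: int | None = None) -> list[Trial]:
        return [
            t
            for t in self.trials
            if t.trial_type == "stimulus"
            and (location_id is None or t.location_id == location_id)
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "onset": t.stim_onset_s if t.trial_type == "stimulus" else t.trial_onset_s,
                    "duration": t.stim_duration_s if t.trial_type == "stimulus" else 0.0,
                    "trial_type": t.trial_type,
                    "location_id": t.location_id if t.location_id is not None else "n/a",
                    "trial_index": t.index,
                }
            )
        return pd.DataFrame(rows)

    def to_events_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_events_tsv(cls, path: str | Path) -> "RunDesign":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"events file not found: {path}")
        df = pd.read_csv(path, sep="\t", dtype={"location_id": str})
        required = {"onset", "duration", "trial_type", "location_id", "trial_index"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"events table {path} missing columns: {sorted(missing)}")
        trials = []
        for r in df.sort_values("trial_index").itertuples():
            if r.trial_type == "silent":
                trials.append(Trial(index=int(r.trial_index), trial_type="silent", location_id=None, stim_onset_s=None))
            else:
                trials.append(
                    Trial(
                        index=int(r.trial_index),
                        trial_type="stimulus",
                        location_id=int(r.location_id),
                        stim_onset_s=float(r.onset),
                        stim_duration_s=float(r.duration),
                    )
                )
        return cls(tuple(trials))


def make_run_design(seed: int | np.random.Generator) -> RunDesign:
    """Randomly ordered run: 64 stimulus trials (4/location) + 12 silent."""
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "design")
    slots: list[int | None] = [l for l in range(N_LOCATIONS) for _ in range(TRIALS_PER_LOCATION)]
    slots += [None] * N_SILENT_TRIALS
    order = rng.permutation(len(slots))
    jitter = rng.uniform(0.0, JITTER_WINDOW_S, size=len(slots))
    trials = []
    for i, k in enumerate(order):
        loc = slots[k]
        if loc is None:
            trials.append(Trial(index=i, trial_type="silent", location_id=None, stim_onset_s=None))
        else:
            onset = i * TR_S + ACQUISITION_DURATION_S + jitter[i]
            trials.append(Trial(index=i, trial_type="stimulus", location_id=loc, stim_onset_s=onset))
    return RunDesign(tuple(trials))


@dataclass(frozen=True)
class ConditionPattern:
    """Ground truth for one condition: which voxels respond, how strongly."""

    voxels: tuple[int, ...]  # flat indices into the grid
    effects: tuple[float, ...]  # per-location amplitude, length 16

    def __post_init__(self) -> None:
        if len(self.effects) != N_LOCATIONS:
            raise ValueError("effects must have one entry per location")


@dataclass(frozen=True)
class PatternSpec:
    """Full generative specification for one synthetic subject."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    roi_mask: np.ndarray  # boolean, grid_shape
    baseline_amplitude: float
    condition_patterns: dict[str, ConditionPattern]
    noise_sd: float
    ar1_coeff: float
    drift_slope: float
    mean_intensity: float = 100.0
    acquisition_lag_s: float = 0.0

    def __post_init__(self) -> None:
        if self.roi_mask.shape != tuple(self.grid_shape):
            raise ValueError("roi_mask shape must match grid_shape")
        if not (0.0 <= self.ar1_coeff < 1.0):
            raise ValueError("ar1_coeff must lie in [0, 1)")
        roi_flat = set(np.flatnonzero(self.roi_mask.ravel()).tolist())
        for cond, pat in self.condition_patterns.items():
            if not set(pat.voxels) <= roi_flat:
                raise ValueError(f"informative voxels of {cond} stray outside the ROI")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    def amplitude_map(self) -> np.ndarray:
        """Per-voxel, per-location response amplitude, shape (n_voxels, 16)."""
        amp = np.zeros((self.n_voxels, N_LOCATIONS))
        amp[self.roi_mask.ravel(), :] = self.baseline_amplitude
        for pat in self.condition_patterns.values():
            idx = np.asarray(pat.voxels, dtype=int)
            if idx.size:
                amp[idx, :] += np.asarray(pat.effects)[None, :]
        return amp

    def to_json_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": list(self.voxel_size_mm),
            "roi_voxels": np.flatnonzero(self.roi_mask.ravel()).tolist(),
            "baseline_amplitude": self.baseline_amplitude,
            "condition_patterns": {
                c: {"voxels": list(p.voxels), "effects": list(p.effects)}
                for c, p in self.condition_patterns.items()
            },
            "noise_sd": self.noise_sd,
            "ar1_coeff": self.ar1_coeff,
            "drift_slope": self.drift_slope,
            "mean_intensity": self.mean_intensity,
            "acquisition_lag_s": self.acquisition_lag_s,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PatternSpec":
        grid_shape = tuple(d["grid_shape"])
        roi = np.zeros(int(np.prod(grid_shape)), dtype=bool)
        roi[np.asarray(d["roi_voxels"], dtype=int)] = True
        return cls(
            grid_shape=grid_shape,
            voxel_size_mm=tuple(d["voxel_size_mm"]),
            roi_mask=roi.reshape(grid_shape),
            baseline_amplitude=float(d["baseline_amplitude"]),
            condition_patterns={
                c: ConditionPattern(tuple(p["voxels"]), tuple(p["effects"]))
                for c, p in d["condition_patterns"].items()
            },
            noise_sd=float(d["noise_sd"]),
            ar1_coeff=float(d["ar1_coeff"]),
            drift_slope=float(d["drift_slope"]),
            mean_intensity=float(d.get("mean_intensity", 100.0)),
            acquisition_lag_s=float(d.get("acquisition_lag_s", 0.0)),
        )

    def __eq__(self, other) -> bool:  # ndarray field breaks the generated __eq__
        if not isinstance(other, PatternSpec):
            return NotImplemented
        return self.to_json_dict() == other.to_json_dict()


@dataclass(frozen=True)
class VolumeSeries:
    """Sparse-sampled 4D data: one volume per trial."""

    data: np.ndarray  # (x, y, z, n_volumes)
    acquisition_times_s: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")
        if self.data.shape[3] != len(self.acquisition_times_s):
            raise ValueError("one acquisition time per volume required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass(frozen=True)
class SubjectDataset:
    subject_id: str
    runs: tuple[tuple[RunDesign, VolumeSeries], ...]
    pattern_spec: PatternSpec
    seed: int

    def __post_init__(self) -> None:
        if len(self.runs) != N_RUNS:
            raise ValueError(f"a subject has {N_RUNS} runs, got {len(self.runs)}")


def default_roi_mask(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Bilateral ellipsoidal 'temporal lobe' ROI: two blobs, one per hemisphere."""
    nx, ny, nz = grid_shape
    x, y, z = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    mask = np.zeros(grid_shape, dtype=bool)
    for cx in (nx * 0.25, nx * 0.75):
        d = (
            ((x - cx) / (nx * 0.16)) ** 2
            + ((y - ny * 0.5) / (ny * 0.28)) ** 2
            + ((z - nz * 0.4) / (nz * 0.3)) ** 2
        )
        mask |= d <= 1.0
    return mask


_DEFAULT_CONFIG = {
    "grid_shape": (24, 24, 12),
    "voxel_size_mm": (3.0, 3.0, 3.0),
    "roi_mask": None,  # default bilateral ellipsoids
    "baseline_amplitude": 1.0,
    "amplitudes": {c: 0.5 for c in CONDITIONS},
    "n_informative": 30,
    "overlap_fraction": 0.0,
    "noise_sd": 0.5,
    "ar1_coeff": 0.3,
    "drift_slope": 0.01,
    "mean_intensity": 100.0,
    "acquisition_lag_s": 0.0,
}


def make_pattern_spec(config: dict | None = None, seed: int = 0) -> PatternSpec:
    """Draw the ground-truth pattern layout for one synthetic subject.

    ``config`` overrides entries of the default: grid/ROI geometry, the
    per-condition planted amplitude ``amplitudes``, the informative voxel
    count per condition and their allowed ``overlap_fraction``, and the
    noise/drift parameters.  Informative voxel sets are disjoint across
    conditions unless overlap is requested.
    """
    cfg = dict(_DEFAULT_CONFIG)
    cfg.update(config or {})
    grid_shape = tuple(cfg["grid_shape"])
    roi = cfg["roi_mask"]
    if roi is None:
        roi = default_roi_mask(grid_shape)
    roi = np.asarray(roi, dtype=bool)

    rng = substream(seed, "patterns")
    roi_flat = np.flatnonzero(roi.ravel())
    n_inf = int(cfg["n_informative"])
    overlap = float(cfg["overlap_fraction"])
    n_shared = int(round(n_inf * overlap))
    n_fresh = n_inf - n_shared
    if n_fresh * len(CONDITIONS) + n_shared > roi_flat.size:
        raise ValueError(
            f"requested {n_inf} informative voxels per condition exceed ROI size {roi_flat.size}"
        )

    array = build_speaker_array()
    available = rng.permutation(roi_flat)
    shared = available[:n_shared]
    cursor = n_shared
    patterns: dict[str, ConditionPattern] = {}
    for cond in CONDITIONS:
        amp = float(cfg["amplitudes"].get(cond, 0.0))
        fresh = available[cursor : cursor + n_fresh]
        cursor += n_fresh
        voxels = np.sort(np.concatenate([shared, fresh])).astype(int)
        labeling = condition_labels(array, cond)
        effects = np.zeros(N_LOCATIONS)
        for lid in labeling.class_a:
            effects[lid] = +amp
        for lid in labeling.class_b:
            effects[lid] = -amp
        if amp == 0.0:
            voxels = np.array([], dtype=int)
        patterns[cond] = ConditionPattern(tuple(voxels.tolist()), tuple(effects.tolist()))

    return PatternSpec(
        grid_shape=grid_shape,
        voxel_size_mm=tuple(cfg["voxel_size_mm"]),
        roi_mask=roi,
        baseline_amplitude=float(cfg["baseline_amplitude"]),
        condition_patterns=patterns,
        noise_sd=float(cfg["noise_sd"]),
        ar1_coeff=float(cfg["ar1_coeff"]),
        drift_slope=float(cfg["drift_slope"]),
        mean_intensity=float(cfg["mean_intensity"]),
        acquisition_lag_s=float(cfg["acquisition_lag_s"]),
    )


def _ar1_noise(rng: np.random.Generator, n_t: int, n_v: int, sd: float, phi: float) -> np.ndarray:
    """AR(1) innovations scaled so the stationary sd equals ``sd``."""
    if sd == 0.0:
        return np.zeros((n_t, n_v))
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=(n_t, n_v))
    noise = np.empty_like(eps)
    noise[0] = rng.normal(0.0, sd, size=n_v)
    for t in range(1, n_t):
        noise[t] = phi * noise[t - 1] + eps[t]
    return noise


def simulate_run(
    spec: PatternSpec, design: RunDesign, rng: np.random.Generator
) -> VolumeSeries:
    """Generate one run's sparse-sampled volumes from the generative spec."""
    sample_times = design.acquisition_times_s + spec.acquisition_lag_s
    n_t = len(design.trials)

    regressors = np.zeros((n_t, N_LOCATIONS))
    for lid in range(N_LOCATIONS):
        trials = design.stimulus_trials(lid)
        regressors[:, lid] = sample_event_regressor(
            np.array([t.stim_onset_s for t in trials]),
            np.array([t.stim_duration_s for t in trials]),
            sample_times,
        )

    amp = spec.amplitude_map()  # (n_voxels, 16)
    signal = regressors @ amp.T  # (n_t, n_voxels)

    trial_idx = np.arange(n_t, dtype=float)
    drift = spec.drift_slope * (trial_idx - trial_idx.mean())
    series = (
        spec.mean_intensity
        + signal
        + drift[:, None]
        + _ar1_noise(rng, n_t, spec.n_voxels, spec.noise_sd, spec.ar1_coeff)
    )
    data = np.ascontiguousarray(series.T.reshape(*spec.grid_shape, n_t))
    return VolumeSeries(
        data=data, acquisition_times_s=sample_times, voxel_size_mm=spec.voxel_size_mm
    )


def simulate_subject(
    spec: PatternSpec, seed: int, subject_id: str = "sub-01"
) -> SubjectDataset:
    """Simulate all 8 runs of one subject from a single master seed."""
    runs = []
    for r in range(N_RUNS):
        design = make_run_design(substream(seed, "design", r))
        vol = simulate_run(spec, design, substream(seed, "noise", r))
        runs.append((design, vol))
    return SubjectDataset(
        subject_id=subject_id, runs=tuple(runs), pattern_spec=spec, seed=seed
    )


def write_dataset(ds: SubjectDataset, path: str | Path) -> None:
    """Persist a subject: NIfTI volumes, events TSVs, spec/seed JSON."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for r, (design, vol) in enumerate(ds.runs, start=1):
        affine = np.diag(list(vol.voxel_size_mm) + [1.0])
        img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
        nib.save(img, root / f"run-{r:02d}_bold.nii.gz")
        design.to_events_tsv(root / f"run-{r:02d}_events.tsv")
        np.savetxt(root / f"run-{r:02d}_acqtimes.tsv", vol.acquisition_times_s, fmt="%.6f")
    meta = {
        "subject_id": ds.subject_id,
        "seed": ds.seed,
        "n_runs": len(ds.runs),
        "pattern_spec": ds.pattern_spec.to_json_dict(),
    }
    (root / "dataset.json").write_text(json.dumps(meta, indent=2))


def read_dataset(path: str | Path) -> SubjectDataset:
    root = Path(path)
    meta_path = root / "dataset.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"dataset metadata not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    spec = PatternSpec.from_json_dict(meta["pattern_spec"])
    runs = []
    for r in range(1, meta["n_runs"] + 1):
        bold_path = root / f"run-{r:02d}_bold.nii.gz"
        events_path = root / f"run-{r:02d}_events.tsv"
        if not bold_path.exists():
            raise FileNotFoundError(f"missing BOLD file for run {r}: {bold_path}")
        if not events_path.exists():
            raise FileNotFoundError(f"missing events file for run {r}: {events_path}")
        design = RunDesign.from_events_tsv(events_path)
        data = np.asarray(nib.load(bold_path).dataobj, dtype=np.float64)
        acq = np.loadtxt(root / f"run-{r:02d}_acqtimes.tsv")
        vol = VolumeSeries(
            data=data, acquisition_times_s=acq, voxel_size_mm=spec.voxel_size_mm
        )
        runs.append((design, vol))
    return SubjectDataset(
        subject_id=meta["subject_id"],
        runs=tuple(runs),
        pattern_spec=spec,
        seed=int(meta["seed"]),
    )
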