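"""Frame schedules, time-activity curves, regional extraction, and file I/O.

Conventions
-----------
* Frame start/duration times are stored in **seconds** from injection;
  mid-times exposed to kinetic code are in **minutes**.
* Activity concentration is in kBq/mL, decay-corrected to injection time.
  No SUV normalization is applied: every downstream quantity (SUVR, DVR)
  is a ratio in which injected dose and body weight cancel.
* Time integrals use the rectangular (frame-duration weighted) rule
  because frame values are already time-averages of the underlying
  continuous curve.
* A frame belongs to a window or integral iff its mid-time lies in the
  closed interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "RegionSet",
    "DEFAULT_REGIONS",
    "default_schedule",
    "extract_tacs",
    "integrate_tac",
    "load_dynamic_nifti",
    "load_label_nifti",
    "read_schedule_json",
    "write_schedule_json",
    "read_tac_csv",
    "write_tac_csv",
    "write_results_csv",
]

#: canonical region labels: cortex, hippocampus, striatum, midbrain,
#: cerebellum (reference)
DEFAULT_REGIONS = ("CX", "HIP", "STR", "MB", "CB")

#: integer label -> region for packaged phantoms (0 = background)
DEFAULT_LABEL_MAP = {1: "CX", 2: "HIP", 3: "STR", 4: "MB", 5: "CB"}

TAC_CSV_COLUMNS = ["region", "frame_index", "mid_time_min", "value_kBq_per_mL"]


class FrameMismatchError(ValueError):
    """Raised when image, mask, or schedule dimensions disagree."""


class MissingLabelError(ValueError):
    """Raised when a mapped label has no voxels in the label volume."""


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous acquisition frames.

    Parameters
    ----------
    frame_durations_s
        Duration of each frame in seconds; frames are contiguous and the
        first frame starts at injection (t = 0).
    """

    frame_durations_s: tuple[float, ...]

    def __post_init__(self):
        d = np.asarray(self.frame_durations_s, dtype=float)
        if d.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(d <= 0):
            raise ValueError("all frame durations must be positive")
        object.__setattr__(self, "frame_durations_s", tuple(float(x) for x in d))

    @property
    def n_frames(self) -> int:
        return len(self.frame_durations_s)

    @property
    def durations_s(self) -> np.ndarray:
        return np.asarray(self.frame_durations_s, dtype=float)

    @property
    def starts_s(self) -> np.ndarray:
        d = self.durations_s
        return np.concatenate([[0.0], np.cumsum(d)[:-1]])

    @property
    def total_duration_s(self) -> float:
        return float(np.sum(self.durations_s))

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations_s / 60.0

    @property
    def end_min(self) -> float:
        return self.total_duration_s / 60.0

    def mid_times_min(self) -> np.ndarray:
        """Frame mid-times in minutes: (start + duration/2) / 60."""
        return (self.starts_s + self.durations_s / 2.0) / 60.0


def default_schedule() -> FrameSchedule:
    """The 90-min dynamic acquisition: 18x10 s, 4x30 s, 5x60 s, 10x300 s,
    3x600 s (40 frames, 5400 s total)."""
    durations = [10.0] * 18 + [30.0] * 4 + [60.0] * 5 + [300.0] * 10 + [600.0] * 3
    return FrameSchedule(tuple(durations))


def frame_midtimes(schedule: FrameSchedule) -> np.ndarray:
    """Frame mid-times in minutes (strictly increasing, one per frame)."""
    return schedule.mid_times_min()


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-region mean activity concentration per frame.

    ``values`` are kBq/mL, decay-corrected to injection time;
    ``mid_times`` are minutes post-injection.
    """

    region: str
    mid_times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        t = np.asarray(self.mid_times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise ValueError(
                f"mid_times ({t.size}) and values ({v.size}) differ in length"
            )
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("mid_times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("activity values must be non-negative")
        object.__setattr__(self, "mid_times", tuple(float(x) for x in t))
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.mid_times, dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def with_values(self, values: np.ndarray) -> "TimeActivityCurve":
        return TimeActivityCurve(self.region, self.mid_times, tuple(float(x) for x in values))


@dataclass(frozen=True)
class RegionSet:
    """Integer label volume plus label -> region mapping (0 = background)."""

    label_volume: np.ndarray
    label_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_MAP))
    voxel_size_mm: float = 1.0

    def __post_init__(self):
        vol = np.asarray(self.label_volume)
        if vol.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {vol.shape}")
        if not np.issubdtype(vol.dtype, np.integer):
            raise ValueError("label volume must be an integer grid")
        present = set(np.unique(vol).tolist())
        missing = [lab for lab in self.label_map if lab not in present]
        if missing:
            raise MissingLabelError(
                "labels mapped but absent from volume: "
                + ", ".join(f"{lab} ({self.label_map[lab]})" for lab in sorted(missing))
            )
        object.__setattr__(self, "label_volume", vol)

    @property
    def regions(self) -> list[str]:
        return [self.label_map[k] for k in sorted(self.label_map)]


def extract_tacs(
    image: np.ndarray, regions: RegionSet, schedule: FrameSchedule
) -> dict[str, TimeActivityCurve]:
    """Extract one TAC per mapped region from a 4D activity grid.

    ``image`` has shape (nx, ny, nz, n_frames); each regional value is the
    unweighted mean of the voxel activities carrying that label in that
    frame. Images must already be aligned to the label grid.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 4:
        raise FrameMismatchError(f"dynamic image must be 4D, got shape {img.shape}")
    if img.shape[:3] != regions.label_volume.shape:
        raise FrameMismatchError(
            f"image grid {img.shape[:3]} does not match label volume "
            f"{regions.label_volume.shape}"
        )
    if img.shape[3] != schedule.n_frames:
        raise FrameMismatchError(
            f"image has {img.shape[3]} frames but schedule has {schedule.n_frames}"
        )
    mids = schedule.mid_times_min()
    out: dict[str, TimeActivityCurve] = {}
    for lab in sorted(regions.label_map):
        name = regions.label_map[lab]
        mask = regions.label_volume == lab
        if not mask.any():
            raise MissingLabelError(f"label {lab} ({name}) has no voxels")
        vals = img[mask, :].mean(axis=0)
        out[name] = TimeActivityCurve(name, tuple(mids), tuple(vals))
    return out


def integrate_tac(
    tac: TimeActivityCurve, schedule: FrameSchedule, upto: float
) -> float:
    """Duration-weighted rectangular integral of the TAC in kBq.min/mL.

    Sums value[i] * duration_min[i] over frames whose mid-time is <= ``upto``
    (minutes). Returns 0 for ``upto`` before the first mid-time.
    """
    if upto < 0:
        raise ValueError(f"integration limit must be non-negative, got {upto}")
    if upto > schedule.end_min + 1e-9:
        raise ValueError(
            f"integration limit {upto} min exceeds scan end {schedule.end_min} min"
        )
    mids = schedule.mid_times_min()
    if len(mids) != len(tac.values):
        raise FrameMismatchError(
            f"TAC has {len(tac.values)} frames but schedule has {len(mids)}"
        )
    sel = mids <= upto + 1e-12
    return float(np.sum(tac.y[sel] * schedule.durations_min[sel]))


def cumulative_integral(tac: TimeActivityCurve, schedule: FrameSchedule) -> np.ndarray:
    """Running rectangular integral evaluated at each frame mid-time.

    Element i is the integral up to and including frame i, i.e.
    ``integrate_tac(tac, schedule, mid_time[i])`` for every frame at once.
    """
    return np.cumsum(tac.y * schedule.durations_min)


# ---------------------------------------------------------------------------
# File I/O

def load_dynamic_nifti(path, schedule: FrameSchedule) -> np.ndarray:
    """Load a 4D dynamic volume and check its frame count against the schedule."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FrameMismatchError(f"{path}: expected 4D image, got shape {data.shape}")
    if data.shape[3] != schedule.n_frames:
        raise FrameMismatchError(
            f"{path}: image has {data.shape[3]} frames but schedule has "
            f"{schedule.n_frames}"
        )
    return data


def load_label_nifti(path, label_map: dict[int, str] | None = None) -> RegionSet:
    """Load a 3D integer label volume as a :class:`RegionSet`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.rint(data).astype(np.int32)
    zooms = img.header.get_zooms()[:3]
    return RegionSet(
        label_volume=data,
        label_map=dict(label_map) if label_map else dict(DEFAULT_LABEL_MAP),
        voxel_size_mm=float(zooms[0]) if zooms else 1.0,
    )


def save_nifti(path, data: np.ndarray, voxel_size_mm: float = 1.0) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_schedule_json(path) -> FrameSchedule:
    """Read a frame schedule from JSON: {"frame_durations_s": [...]}."""
    with open(path) as fh:
        obj = json.load(fh)
    if "frame_durations_s" not in obj:
        raise KeyError(f"{path}: missing 'frame_durations_s'")
    return FrameSchedule(tuple(float(x) for x in obj["frame_durations_s"]))


def write_schedule_json(path, schedule: FrameSchedule) -> None:
    with open(path, "w") as fh:
        json.dump({"frame_durations_s": list(schedule.frame_durations_s)}, fh, indent=1)
        fh.write("\n")


def write_tac_csv(path, tacs: dict[str, TimeActivityCurve]) -> None:
    """Write TACs in the fixed dialect (comma, header, '.' decimal).

    Columns: region, frame_index, mid_time_min, value_kBq_per_mL. Values are
    written with repr precision so that write -> read is an identity.
    """
    rows = []
    for name in sorted(tacs):
        tac = tacs[name]
        for i, (t, v) in enumerate(zip(tac.mid_times, tac.values)):
            rows.append((name, i, t, v))
    df = pd.DataFrame(rows, columns=TAC_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_tac_csv(path) -> dict[str, TimeActivityCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TAC_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing TAC CSV columns {missing}")
    out: dict[str, TimeActivityCurve] = {}
    for name, grp in df.groupby("region", sort=True):
        grp = grp.sort_values("frame_index")
        out[str(name)] = TimeActivityCurve(
            str(name),
            tuple(grp["mid_time_min"].to_numpy(dtype=float)),
            tuple(grp["value_kBq_per_mL"].to_numpy(dtype=float)),
        )
    return out


def write_results_csv(path, df: pd.DataFrame) -> None:
    """Write an analysis results table (plain CSV, '.' decimal, header)."""
    df.to_csv(path, index=False, float_format="%.10g")
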