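"""Frame schedules, time-activity curves, decay correction and SUV.

The temporal backbone of a dynamic PET study is the frame schedule: an
ordered, contiguous list of acquisition frames (start, duration) in
seconds from injection.  A :class:`TimeActivityCurve` (TAC) holds one
activity-concentration sample per frame for a single region -- the tissue
curves and the image-derived left-ventricular input function are both
TACs on the same schedule.

Activity concentrations are kBq/mL; SUV conversion normalises by injected
activity per gram of body weight (tissue density 1 g/mL).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .units import HALF_LIVES_MIN, minutes_to_seconds

__all__ = [
    "FrameSchedule",
    "TracerInfo",
    "InjectionRecord",
    "TimeActivityCurve",
    "DynamicVolume",
    "make_frame_schedule",
    "truncate_schedule",
    "decay_correct",
    "compute_suv",
    "suv_to_concentration",
    "extract_roi_tac",
    "read_tac_csv",
    "write_tac_csv",
    "read_injection_json",
    "write_injection_json",
    "load_dynamic_volume",
    "load_mask",
]

_CONTIGUITY_TOL = 1e-9


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping dynamic-scan frames (seconds)."""

    frame_starts: np.ndarray
    frame_durations: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.frame_starts, dtype=float)
        durs = np.asarray(self.frame_durations, dtype=float)
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_durations", durs)
        if starts.ndim != 1 or durs.shape != starts.shape or starts.size == 0:
            raise ValueError("frame_starts and frame_durations must be equal-length 1-D arrays")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        if starts[0] < 0:
            raise ValueError("first frame start must be >= 0")
        expected = starts[:-1] + durs[:-1]
        if not np.allclose(starts[1:], expected, rtol=0, atol=_CONTIGUITY_TOL):
            raise ValueError("frames must be contiguous: start[i+1] == start[i] + duration[i]")

    @classmethod
    def from_spec(cls, spec: Iterable[tuple[int, float]]) -> "FrameSchedule":
        return make_frame_schedule(spec)

    @property
    def n_frames(self) -> int:
        return self.frame_starts.size

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations

    @property
    def frame_mids(self) -> np.ndarray:
        return self.frame_starts + 0.5 * self.frame_durations

    @property
    def total_duration(self) -> float:
        return float(self.frame_ends[-1] - self.frame_starts[0])

    def truncate(self, t_end: float) -> tuple["FrameSchedule", np.ndarray]:
        return truncate_schedule(self, t_end)


@dataclass(frozen=True)
class TracerInfo:
    """Radiotracer label and physical half-life (minutes)."""

    name: str
    half_life_min: float

    def __post_init__(self):
        if self.half_life_min <= 0:
            raise ValueError("half_life_min must be positive")

    @classmethod
    def from_registry(cls, nuclide: str, name: str | None = None) -> "TracerInfo":
        return cls(name=name or nuclide, half_life_min=HALF_LIVES_MIN[nuclide])


@dataclass(frozen=True)
class InjectionRecord:
    """Injected activity (MBq, at injection time) and body weight (g)."""

    injected_activity_mbq: float
    body_weight_g: float

    def __post_init__(self):
        if self.injected_activity_mbq <= 0:
            raise ValueError("injected_activity_mbq must be positive")
        if self.body_weight_g <= 0:
            raise ValueError("body_weight_g must be positive")


@dataclass(frozen=True)
class TimeActivityCurve:
    """One activity-concentration value per frame for a single region.

    Values are kBq/mL (or SUV after :func:`compute_suv`; see ``units``).
    Noisy values may dip below zero and are preserved as-is: truncating
    them would bias downstream model fits.
    """

    schedule: FrameSchedule
    values: np.ndarray
    region_label: str = ""
    tracer: TracerInfo | None = None
    decay_corrected: bool = True
    units: str = "kBq/mL"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"expected {self.schedule.n_frames} values (one per frame), got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC values must be finite")


@dataclass(frozen=True)
class DynamicVolume:
    """4-D dynamic image (x, y, z, frame) in kBq/mL with a frame schedule."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 4:
            raise ValueError("dynamic volume must be 4-D (x, y, z, frame)")
        if data.shape[3] != self.schedule.n_frames:
            raise ValueError("4th axis must match the number of frames")


def make_frame_schedule(spec: Iterable[tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule from (count, duration-seconds) pairs.

    Example: ``[(30, 3), (9, 10), (4, 30), (5, 60), (4, 300)]`` is a
    52-frame, 30-minute dynamic cardiac protocol.
    """
    durations: list[float] = []
    for count, dur in spec:
        if count < 1 or int(count) != count:
            raise ValueError(f"frame count must be a positive integer, got {count}")
        if dur <= 0:
            raise ValueError(f"frame duration must be positive, got {dur}")
        durations.extend([float(dur)] * int(count))
    if not durations:
        raise ValueError("schedule spec is empty")
    durs = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
    return FrameSchedule(starts, durs)


def truncate_schedule(schedule: FrameSchedule, t_end: float) -> tuple[FrameSchedule, np.ndarray]:
    """Keep the frames wholly before ``t_end`` (seconds).

    ``t_end`` must coincide with a frame boundary -- partial frames are
    not meaningful.  Returns the truncated schedule and the index map
    into the original frame list.
    """
    ends = schedule.frame_ends
    if not np.any(np.isclose(ends, t_end, rtol=0, atol=_CONTIGUITY_TOL)):
        raise ValueError(f"t_end={t_end} s does not fall on a frame boundary")
    keep = np.flatnonzero(ends <= t_end + _CONTIGUITY_TOL)
    return (
        FrameSchedule(schedule.frame_starts[keep], schedule.frame_durations[keep]),
        keep,
    )


def decay_correct(tac: TimeActivityCurve, reference_time_s: float = 0.0) -> TimeActivityCurve:
    """Correct a TAC for physical decay to ``reference_time_s``.

    Each frame value is scaled by ``2**((t_mid - t_ref)/T_half)`` using the
    frame midpoint; the tracer half-life comes from ``tac.tracer``.
    """
    if tac.decay_corrected:
        raise ValueError("TAC is already decay-corrected")
    if tac.tracer is None:
        raise ValueError("decay correction requires tracer half-life metadata")
    half_life_s = minutes_to_seconds(tac.tracer.half_life_min)
    factor = 2.0 ** ((tac.schedule.frame_mids - reference_time_s) / half_life_s)
    return replace(tac, values=tac.values * factor, decay_corrected=True)


def _suv_denominator(injection: InjectionRecord) -> float:
    # injected activity per gram of body weight, in kBq/g; with tissue
    # density 1 g/mL this is the concentration of a uniform distribution.
    return injection.injected_activity_mbq * 1000.0 / injection.body_weight_g


def compute_suv(tac: TimeActivityCurve, injection: InjectionRecord) -> TimeActivityCurve:
    """Convert a decay-corrected kBq/mL TAC to standardized uptake values."""
    if tac.units != "kBq/mL":
        raise ValueError(f"expected a TAC in kBq/mL, got units={tac.units!r}")
    if not tac.decay_corrected:
        raise ValueError("SUV requires a decay-corrected TAC")
    return replace(tac, values=tac.values / _suv_denominator(injection), units="SUV")


def suv_to_concentration(tac: TimeActivityCurve, injection: InjectionRecord) -> TimeActivityCurve:
    """Inverse of :func:`compute_suv`."""
    if tac.units != "SUV":
        raise ValueError(f"expected a TAC in SUV, got units={tac.units!r}")
    return replace(tac, values=tac.values * _suv_denominator(injection), units="kBq/mL")


def extract_roi_tac(
    volume: DynamicVolume,
    mask: np.ndarray,
    label: str = "",
    tracer: TracerInfo | None = None,
) -> TimeActivityCurve:
    """Per-frame unweighted mean over the voxels inside a 3-D boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.data.shape[:3]:
        raise ValueError("mask shape must match the volume's spatial grid")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    values = volume.data[mask].mean(axis=0)
    return TimeActivityCurve(volume.schedule, values, region_label=label, tracer=tracer)


# ---------------------------------------------------------------------------
# File formats


def write_tac_csv(path: str | Path, schedule: FrameSchedule, regions: dict[str, np.ndarray]) -> None:
    """TAC CSV: ``frame_start_s,frame_end_s,<region1>,...``, one row per frame."""
    names = list(regions)
    cols = [np.asarray(regions[n], dtype=float) for n in names]
    for n, c in zip(names, cols):
        if c.shape != (schedule.n_frames,):
            raise ValueError(f"region {n!r} does not have one value per frame")
        if not np.all(np.isfinite(c)):
            raise ValueError(f"region {n!r} contains non-finite values")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_start_s", "frame_end_s", *names])
        for i in range(schedule.n_frames):
            writer.writerow(
                [repr(float(schedule.frame_starts[i])), repr(float(schedule.frame_ends[i]))]
                + [repr(float(c[i])) for c in cols]
            )


def read_tac_csv(path: str | Path) -> tuple[FrameSchedule, dict[str, np.ndarray]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["frame_start_s", "frame_end_s"]:
            raise ValueError("TAC CSV must start with frame_start_s,frame_end_s columns")
        names = header[2:]
        rows = [[float(x) for x in row] for row in reader if row]
    arr = np.asarray(rows, dtype=float)
    if arr.size == 0:
        raise ValueError("TAC CSV has no frames")
    schedule = FrameSchedule(arr[:, 0], arr[:, 1] - arr[:, 0])
    return schedule, {n: arr[:, 2 + i].copy() for i, n in enumerate(names)}


def write_injection_json(
    path: str | Path, tracer: TracerInfo, injection: InjectionRecord
) -> None:
    payload = {
        "tracer": tracer.name,
        "half_life_min": tracer.half_life_min,
        "injected_MBq": injection.injected_activity_mbq,
        "body_weight_g": injection.body_weight_g,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_injection_json(path: str | Path) -> tuple[TracerInfo, InjectionRecord]:
    payload = json.loads(Path(path).read_text())
    tracer = TracerInfo(payload["tracer"], payload["half_life_min"])
    injection = InjectionRecord(payload["injected_MBq"], payload["body_weight_g"])
    return tracer, injection


def load_dynamic_volume(path: str | Path, schedule: FrameSchedule) -> DynamicVolume:
    """Load a 4-D NIfTI-1 dynamic image (frames on the 4th axis)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[:3]
    return DynamicVolume(data, schedule, voxel_size_mm=tuple(float(z) for z in zooms))


def load_mask(path: str | Path) -> np.ndarray:
    """Load a 3-D NIfTI-1 mask; nonzero voxels are inside the ROI."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) != 0
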