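"""Segmented polar-map (bullseye) representation of per-region K1.

A polar map projects the left-ventricular myocardium onto a disc divided
into segments (the 17-segment AHA layout by default) and colours each
segment by its fitted K1.  Infarct sizing follows the viability-threshold
convention: the map is normalised to the highest K1 in viable myocardium
(set to 100%) and every segment strictly below 60% of that maximum counts
as non-viable; the infarct area is the area-weighted percentage of
non-viable segments.

Because the global maximum of the map is itself viable under any cutoff
below 100%, normalising to the global maximum is equivalent to
normalising to the viable maximum -- this resolves the apparent
circularity of "normalise to the viable maximum, then threshold".
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PolarMap",
    "SegmentAssignment",
    "AHA17_SEGMENT_IDS",
    "normalize_polar_map",
    "infarct_fraction",
    "region_k1",
    "remote_mi_ratio",
    "polar_map_from_fits",
    "read_polar_map_csv",
    "write_polar_map_csv",
    "read_assignment_json",
    "write_assignment_json",
    "plot_bullseye",
]

#: Standard AHA 17-segment numbering (1-16 basal/mid/apical rings + 17 apex).
AHA17_SEGMENT_IDS = tuple(range(1, 18))


@dataclass(frozen=True)
class PolarMap:
    """Per-segment K1 values with area weights.

    ``values`` are K1 in mL/min/mL, or percent of the viable maximum
    after :func:`normalize_polar_map` (then ``normalized`` is True).
    """

    segment_ids: tuple
    area_weights: np.ndarray
    values: np.ndarray
    normalized: bool = False
    tracer: str = ""

    def __post_init__(self):
        ids = tuple(self.segment_ids)
        w = np.asarray(self.area_weights, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "segment_ids", ids)
        object.__setattr__(self, "area_weights", w)
        object.__setattr__(self, "values", v)
        if len(ids) == 0:
            raise ValueError("polar map has no segments")
        if len(set(ids)) != len(ids):
            raise ValueError("segment ids must be unique")
        if w.shape != (len(ids),) or v.shape != (len(ids),):
            raise ValueError("area_weights and values must match segment_ids")
        if np.any(w <= 0):
            raise ValueError("area weights must be positive")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("segment values must be finite and non-negative")

    def index_of(self, segment_id) -> int:
        try:
            return self.segment_ids.index(segment_id)
        except ValueError:
            raise KeyError(f"unknown segment id {segment_id!r}") from None

    @classmethod
    def equal_area(cls, values: Sequence[float], segment_ids=None, **kwargs) -> "PolarMap":
        v = np.asarray(values, dtype=float)
        ids = tuple(segment_ids) if segment_ids is not None else tuple(range(1, v.size + 1))
        return cls(ids, np.ones(v.size), v, **kwargs)


@dataclass(frozen=True)
class SegmentAssignment:
    """Which segments quantify the remote vs the infarcted myocardium."""

    remote_ids: frozenset
    infarct_ids: frozenset

    def __post_init__(self):
        object.__setattr__(self, "remote_ids", frozenset(self.remote_ids))
        object.__setattr__(self, "infarct_ids", frozenset(self.infarct_ids))
        if self.remote_ids & self.infarct_ids:
            raise ValueError("remote and infarct segment sets must be disjoint")
        if not self.remote_ids or not self.infarct_ids:
            raise ValueError("remote and infarct segment sets must be non-empty")

    def validate_against(self, pm: PolarMap) -> None:
        missing = (self.remote_ids | self.infarct_ids) - set(pm.segment_ids)
        if missing:
            raise KeyError(f"assignment references unknown segments: {sorted(missing)}")


def normalize_polar_map(pm: PolarMap) -> PolarMap:
    """Rescale to percent of the maximal (necessarily viable) K1."""
    if pm.normalized:
        raise ValueError("polar map is already normalized")
    peak = pm.values.max()
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero polar map (no viable reference)")
    return replace(pm, values=100.0 * pm.values / peak, normalized=True)


def infarct_fraction(pm: PolarMap, cutoff_percent: float = 60.0) -> float:
    """Percent of myocardial area strictly below the viability cutoff.

    A segment exactly at the cutoff is viable (the criterion is
    strictly-less-than).
    """
    if not pm.normalized:
        raise ValueError("infarct_fraction requires a normalized polar map")
    if not 0.0 < cutoff_percent <= 100.0:
        raise ValueError("cutoff_percent must lie in (0, 100]")
    below = pm.values < cutoff_percent
    return float(100.0 * pm.area_weights[below].sum() / pm.area_weights.sum())


def region_k1(pm: PolarMap, ids: Iterable, aggregation: str = "area_weighted_mean") -> float:
    """Area-weighted mean K1 over a set of segments."""
    idx = np.array([pm.index_of(i) for i in ids], dtype=int)
    if idx.size == 0:
        raise ValueError("empty segment set")
    if aggregation != "area_weighted_mean":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    w = pm.area_weights[idx]
    return float((w * pm.values[idx]).sum() / w.sum())


def remote_mi_ratio(remote_k1: float, mi_k1: float) -> float:
    """Remote-over-infarct K1 ratio (the orientation is in the name)."""
    if mi_k1 <= 0:
        raise ValueError("remote/MI ratio is undefined for non-positive infarct K1")
    return remote_k1 / mi_k1


def polar_map_from_fits(
    fits: Mapping, area_weights: Mapping | None = None, tracer: str = ""
) -> PolarMap:
    """Assemble a polar map from per-segment fit results (or raw K1 values).

    Failed fits (exceptions stored by ``fit_region_set``) are rejected --
    build the map only from successful segments or re-fit first.
    """
    ids = sorted(fits)
    values = []
    for sid in ids:
        r = fits[sid]
        if isinstance(r, Exception):
            raise ValueError(f"segment {sid!r} carries a failed fit: {r}")
        values.append(r.params.K1 if hasattr(r, "params") else float(r))
    if area_weights is None:
        w = np.ones(len(ids))
    else:
        w = np.array([area_weights[sid] for sid in ids], dtype=float)
    return PolarMap(tuple(ids), w, np.asarray(values), tracer=tracer)


# ---------------------------------------------------------------------------
# File formats


def write_polar_map_csv(path: str | Path, pm: PolarMap) -> None:
    """Polar-map CSV: ``segment_id,area_weight,k1``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["segment_id", "area_weight", "k1"])
        for sid, w, v in zip(pm.segment_ids, pm.area_weights, pm.values):
            writer.writerow([sid, repr(float(w)), repr(float(v))])


def read_polar_map_csv(path: str | Path, tracer: str = "") -> PolarMap:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header != ["segment_id", "area_weight", "k1"]:
            raise ValueError("polar-map CSV must have header segment_id,area_weight,k1")
        ids, weights, values = [], [], []
        for row in reader:
            if not row:
                continue
            sid = row[0]
            ids.append(int(sid) if sid.lstrip("-").isdigit() else sid)
            weights.append(float(row[1]))
            values.append(float(row[2]))
    return PolarMap(tuple(ids), np.asarray(weights), np.asarray(values), tracer=tracer)


def write_assignment_json(path: str | Path, assignment: SegmentAssignment) -> None:
    payload = {
        "remote": sorted(assignment.remote_ids),
        "infarct": sorted(assignment.infarct_ids),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_assignment_json(path: str | Path) -> SegmentAssignment:
    payload = json.loads(Path(path).read_text())
    return SegmentAssignment(frozenset(payload["remote"]), frozenset(payload["infarct"]))


def plot_bullseye(pm: PolarMap, ax=None, cmap: str = "viridis"):
    """Basic debug bullseye for a 17-segment map (rings 6/6/4 + apex)."""
    import matplotlib
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, Wedge

    if len(pm.segment_ids) != 17:
        raise ValueError("bullseye rendering supports the 17-segment layout only")
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"aspect": "equal"})
    norm = plt.Normalize(vmin=0.0, vmax=pm.values.max())
    colours = matplotlib.colormaps[cmap] if isinstance(cmap, str) else cmap
    rings = [(1.0, 0.75, 6), (0.75, 0.5, 6), (0.5, 0.25, 4)]
    seg_iter = iter(range(17))
    for outer, inner, count in rings:
        for j in range(count):
            i = next(seg_iter)
            theta0 = 90.0 + j * 360.0 / count
            ax.add_patch(
                Wedge(
                    (0, 0), outer, theta0, theta0 + 360.0 / count,
                    width=outer - inner, facecolor=colours(norm(pm.values[i])),
                    edgecolor="k", linewidth=0.5,
                )
            )
    ax.add_patch(Circle((0, 0), 0.25, facecolor=colours(norm(pm.values[16])), edgecolor="k", linewidth=0.5))
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.axis("off")
    return ax
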