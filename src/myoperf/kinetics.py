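"""One-tissue compartment model (1TCM): simulation and weighted NLLS fitting.

The model describes tracer exchange between blood and a single tissue
compartment,

    dCt/dt = K1 * Ca(t) - k2 * Ct(t),      Ct(0) = 0,

where Ca is the arterial input (here the image-derived left-ventricular
TAC), K1 (mL/min/mL) is the uptake rate -- the perfusion surrogate -- and
k2 (1/min) the tissue-to-blood clearance.  The measured PET signal mixes
tissue and blood through the fractional blood volume Vb:

    C_PET(t) = (1 - Vb) * Ct(t) + Vb * Ca(t).

The tissue solution is evaluated by the exact convolution
``Ct(t) = K1 * int_0^t Ca(s) exp(-k2 (t-s)) ds`` with piecewise-linear Ca
on a uniform fine grid, advanced by a recursive exponential update (each
step propagates Ct analytically across one grid interval).  The continuous
model is then averaged over the acquisition frames before being compared
with measured TACs.

Fitting follows a statsmodels-like pattern::

    model = OneTissueModel(tissue_tac, input_tac, fit_window_s=600)
    res = model.fit()
    print(res.summary())

`fit()` minimises the frame-duration-weighted residual sum of squares
under box bounds with a fixed set of starting points, and reports
asymptotic standard errors from the weighted Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .tac import FrameSchedule, TimeActivityCurve, truncate_schedule
from .units import SECONDS_PER_MINUTE, seconds_to_minutes

__all__ = [
    "KineticParams",
    "FineCurve",
    "OneTissueModel",
    "OneTissueResults",
    "simulate_tissue_curve",
    "frame_average",
    "FrameAverager",
    "input_curve_from_tac",
    "fit_1tcm",
    "fit_region_set",
    "write_fit_report_csv",
    "DEFAULT_FIT_WINDOW_S",
    "PARAM_BOUNDS",
    "MULTISTART_INITS",
]

#: Default fit windows per tracer mode (seconds): the 10-minute acetate
#: scan vs the full 30-minute chelate scan.
DEFAULT_FIT_WINDOW_S: dict[str, float] = {
    "c11-acetate": 600.0,
    "ga68-dota": 1800.0,
}

#: Box bounds for (K1, k2, Vb); inclusive.
PARAM_BOUNDS = (np.array([0.0, 0.0, 0.0]), np.array([10.0, 20.0, 1.0]))

#: Fixed multi-start initial points (K1, k2, Vb) -- deterministic fits.
MULTISTART_INITS = (
    (0.1, 0.1, 0.05),
    (0.5, 0.5, 0.1),
    (2.0, 2.0, 0.2),
)

_PARAM_NAMES = ("K1", "k2", "Vb")


@dataclass(frozen=True)
class KineticParams:
    """1TCM parameter triplet.

    K1 : uptake/perfusion rate, mL blood per min per mL tissue
    k2 : clearance rate, 1/min (oxidative metabolism for 11C-acetate)
    Vb : fractional blood volume, dimensionless in [0, 1]
    """

    K1: float
    k2: float
    Vb: float

    def __post_init__(self):
        for name in ("K1", "k2", "Vb"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if self.K1 < 0 or self.k2 < 0:
            raise ValueError("K1 and k2 must be non-negative")
        if not 0.0 <= self.Vb <= 1.0:
            raise ValueError("Vb must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.Vb])


@dataclass(frozen=True)
class FineCurve:
    """Values on a uniform fine time grid (minutes), starting at 0."""

    times_min: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or t.size < 2 or v.shape != t.shape:
            raise ValueError("FineCurve needs matching 1-D grids with >= 2 points")
        steps = np.diff(t)
        if steps[0] <= 0 or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("fine grid must be uniform with positive spacing")

    @property
    def dt(self) -> float:
        return float(self.times_min[1] - self.times_min[0])


def simulate_tissue_curve(params: KineticParams, input_curve: FineCurve) -> FineCurve:
    """Forward 1TCM: convolution of the input with ``K1 exp(-k2 t)`` plus
    the blood-volume term, evaluated on the input's fine grid."""
    ca = input_curve.values
    h = input_curve.dt
    k1, k2, vb = params.K1, params.k2, params.Vb

    a = ca[:-1]
    b = np.diff(ca) / h
    if k2 * h > 1e-8:
        e = np.exp(-k2 * h)
        i0 = (1.0 - e) / k2                       # int_0^h exp(-k2 u) du
        j = (1.0 - e * (1.0 + k2 * h)) / k2**2    # int_0^h u exp(-k2 u) du
        i1 = h * i0 - j                           # int_0^h s exp(-k2 (h-s)) ds
    else:
        e = 1.0 - k2 * h
        i0, i1 = h, h * h / 2.0
    u = k1 * (a * i0 + b * i1)
    # Ct[i+1] = e * Ct[i] + u[i]; Ct[0] = 0 -- a first-order linear filter.
    ct = np.concatenate([[0.0], lfilter([1.0], [1.0, -e], u)])
    return FineCurve(input_curve.times_min, (1.0 - vb) * ct + vb * ca)


@dataclass(frozen=True)
class FrameAverager:
    """Precomputed trapezoidal frame-averaging weights for one (grid, schedule).

    Frame value i is the time-average ``(1/dt_i) int_frame curve`` on the
    fine grid; precomputing the weight matrix makes the operation a single
    matvec inside the fit loop.  Frame boundaries must land on grid points.
    """

    weights: np.ndarray  # (n_frames, n_grid)

    @classmethod
    def build(cls, times_min: np.ndarray, schedule: FrameSchedule) -> "FrameAverager":
        t = np.asarray(times_min, dtype=float)
        h = t[1] - t[0]
        bounds_min = np.concatenate(
            [seconds_to_minutes(schedule.frame_starts), [seconds_to_minutes(schedule.frame_ends[-1])]]
        )
        if bounds_min[0] < t[0] - 1e-12 or bounds_min[-1] > t[-1] + 1e-12:
            raise ValueError("schedule extends past the fine curve")
        idx_f = (bounds_min - t[0]) / h
        idx = np.rint(idx_f).astype(int)
        if not np.allclose(idx_f, idx, rtol=0, atol=1e-6):
            raise ValueError("frame boundaries must coincide with fine-grid points")
        w = np.zeros((schedule.n_frames, t.size))
        for i in range(schedule.n_frames):
            lo, hi = idx[i], idx[i + 1]
            row = np.full(hi - lo + 1, h)
            row[0] = row[-1] = h / 2.0
            w[i, lo : hi + 1] = row / seconds_to_minutes(schedule.frame_durations[i])
        return cls(w)

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return self.weights @ values


def frame_average(
    curve: FineCurve,
    schedule: FrameSchedule,
    region_label: str = "",
    **tac_kwargs,
) -> TimeActivityCurve:
    """Average a continuous model curve over acquisition frames.

    Uses trapezoidal integration on the fine grid, inserting interpolated
    points at frame boundaries that fall between grid points.
    """
    t = curve.times_min
    bounds = np.concatenate(
        [seconds_to_minutes(schedule.frame_starts), [seconds_to_minutes(schedule.frame_ends[-1])]]
    )
    if bounds[0] < t[0] - 1e-12 or bounds[-1] > t[-1] + 1e-12:
        raise ValueError("schedule extends past the fine curve")
    grid = np.union1d(t, bounds)
    vals = np.interp(grid, t, curve.values)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (vals[1:] + vals[:-1]) * np.diff(grid))])
    pos = np.searchsorted(grid, bounds)
    integrals = np.diff(cum[pos])
    means = integrals / seconds_to_minutes(schedule.frame_durations)
    return TimeActivityCurve(schedule, means, region_label=region_label, **tac_kwargs)


def input_curve_from_tac(
    input_tac: TimeActivityCurve,
    fine_step_s: float = 0.5,
    t_end_s: float | None = None,
) -> FineCurve:
    """Piecewise-linear fine-grid input from a frame-sampled LV TAC.

    Frame values are treated as samples at frame midpoints; the curve is
    anchored at (0, 0) before the first midpoint (the scan starts before
    the bolus) and held constant past the last midpoint.
    """
    sched = input_tac.schedule
    if t_end_s is None:
        t_end_s = float(sched.frame_ends[-1])
    n = int(round(t_end_s / fine_step_s))
    if not np.isclose(n * fine_step_s, t_end_s, rtol=0, atol=1e-9):
        raise ValueError("fine_step_s must divide the scan length")
    t_min = seconds_to_minutes(np.arange(n + 1) * fine_step_s)
    mids_min = seconds_to_minutes(sched.frame_mids)
    xp = np.concatenate([[0.0], mids_min])
    fp = np.concatenate([[0.0], input_tac.values])
    return FineCurve(t_min, np.interp(t_min, xp, fp))


@dataclass
class OneTissueResults:
    """Estimates and diagnostics from a 1TCM fit."""

    params: KineticParams
    bse: np.ndarray
    wrss: float
    converged: bool
    n_frames_used: int
    fit_window_s: float
    at_bounds: tuple[bool, bool, bool]
    fitted_values: np.ndarray
    region_label: str = ""
    tracer_mode: str | None = None

    @property
    def se_dict(self) -> dict[str, float]:
        return dict(zip(_PARAM_NAMES, self.bse))

    def summary(self) -> str:
        lines = [
            "One-tissue compartment model fit",
            "=" * 48,
            f"region: {self.region_label or '<unnamed>'}"
            + (f"    tracer mode: {self.tracer_mode}" if self.tracer_mode else ""),
            f"frames used: {self.n_frames_used}    fit window: {self.fit_window_s:g} s",
            f"weighted RSS: {self.wrss:.6g}    converged: {self.converged}",
            "-" * 48,
            f"{'param':>6} {'estimate':>12} {'std err':>12}  {'at bound':>8}",
        ]
        est = self.params.as_array()
        for name, v, se, ab in zip(_PARAM_NAMES, est, self.bse, self.at_bounds):
            lines.append(f"{name:>6} {v:>12.5g} {se:>12.4g}  {str(ab):>8}")
        lines.append("=" * 48)
        return "\n".join(lines)


class OneTissueModel:
    """Weighted nonlinear least-squares 1TCM estimator for one region.

    Parameters
    ----------
    tissue_tac, input_tac
        Frame-aligned TACs sharing a schedule; the input is the
        image-derived LV curve, which also feeds the Vb term (whole blood
        treated as plasma; no metabolite correction).
    fit_window_s
        Portion of the scan to fit, ending on a frame boundary.  Defaults
        to the whole schedule.
    weights_mode
        'duration' (w_i proportional to frame duration; standard PET
        weighting), 'uniform', or an explicit per-frame array.  Weights
        are normalised to sum to 1, so the argmin is scale-invariant.
    fine_step_s
        Fine-grid step for the convolution engine; well below the
        shortest (3 s) frame by default.
    """

    def __init__(
        self,
        tissue_tac: TimeActivityCurve,
        input_tac: TimeActivityCurve,
        fit_window_s: float | None = None,
        weights_mode: str | np.ndarray = "duration",
        fine_step_s: float = 0.5,
    ):
        if tissue_tac.schedule.n_frames != input_tac.schedule.n_frames or not np.allclose(
            tissue_tac.schedule.frame_starts, input_tac.schedule.frame_starts
        ):
            raise ValueError("tissue and input TACs must share the frame schedule")
        full = tissue_tac.schedule
        if fit_window_s is None:
            fit_window_s = float(full.frame_ends[-1])
        self.schedule, keep = truncate_schedule(full, fit_window_s)
        if self.schedule.n_frames < 3:
            raise ValueError("need at least as many frames as parameters (3)")
        self.observed = tissue_tac.values[keep]
        self.region_label = tissue_tac.region_label
        self.fit_window_s = float(fit_window_s)
        self.fine_step_s = float(fine_step_s)

        self.input_curve = input_curve_from_tac(input_tac, fine_step_s, t_end_s=fit_window_s)
        self._averager = FrameAverager.build(self.input_curve.times_min, self.schedule)

        if isinstance(weights_mode, str):
            if weights_mode == "duration":
                w = self.schedule.frame_durations.astype(float)
            elif weights_mode == "uniform":
                w = np.ones(self.schedule.n_frames)
            else:
                raise ValueError(f"unknown weights_mode {weights_mode!r}")
        else:
            w = np.asarray(weights_mode, dtype=float)
            if w.shape != (self.schedule.n_frames,) or np.any(w < 0):
                raise ValueError("explicit weights must be non-negative, one per fitted frame")
        self.weights = w / w.sum()
        self._sqrt_w = np.sqrt(self.weights)

    def predict(self, params: KineticParams) -> np.ndarray:
        """Frame-averaged model TAC for the fitted window."""
        fine = simulate_tissue_curve(params, self.input_curve)
        return self._averager(fine.values)

    def _predict_vec(self, p: np.ndarray) -> np.ndarray:
        return self.predict(KineticParams(*np.clip(p, PARAM_BOUNDS[0], PARAM_BOUNDS[1])))

    def _residuals(self, p: np.ndarray) -> np.ndarray:
        return self._sqrt_w * (self.observed - self._predict_vec(p))

    def fit(
        self,
        starts: Sequence[Sequence[float]] = MULTISTART_INITS,
        xtol: float = 1e-8,
        max_nfev: int = 500,
        tracer_mode: str | None = None,
    ) -> OneTissueResults:
        """Bounded multi-start weighted least squares.

        The best of the fixed starting points by weighted RSS is kept
        (ties broken toward the lower K1); standard errors are the
        asymptotic values from the weighted Jacobian at the optimum.
        """
        best = None
        for x0 in starts:
            sol = least_squares(
                self._residuals,
                np.asarray(x0, dtype=float),
                bounds=PARAM_BOUNDS,
                xtol=xtol,
                ftol=None,
                gtol=None,
                max_nfev=max_nfev,
                method="trf",
            )
            if (
                best is None
                or sol.cost < best.cost - 1e-15
                or (abs(sol.cost - best.cost) <= 1e-15 and sol.x[0] < best.x[0])
            ):
                best = sol
        assert best is not None
        wrss = 2.0 * best.cost
        n, p = self.schedule.n_frames, 3
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.pinv(jtj) * (wrss / max(n - p, 1))
            bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:  # pragma: no cover
            bse = np.full(3, np.nan)
        lo, hi = PARAM_BOUNDS
        at_bounds = tuple(
            bool(np.isclose(best.x[i], lo[i]) or np.isclose(best.x[i], hi[i])) for i in range(3)
        )
        params = KineticParams(*np.clip(best.x, lo, hi))
        return OneTissueResults(
            params=params,
            bse=bse,
            wrss=float(wrss),
            converged=bool(best.status > 0),
            n_frames_used=n,
            fit_window_s=self.fit_window_s,
            at_bounds=at_bounds,
            fitted_values=self.predict(params),
            region_label=self.region_label,
            tracer_mode=tracer_mode,
        )


def fit_1tcm(
    tissue_tac: TimeActivityCurve,
    input_tac: TimeActivityCurve,
    fit_window_s: float | None = None,
    weights_mode: str | np.ndarray = "duration",
    **fit_options,
) -> OneTissueResults:
    """Convenience wrapper: build a :class:`OneTissueModel` and fit it."""
    return OneTissueModel(
        tissue_tac, input_tac, fit_window_s=fit_window_s, weights_mode=weights_mode
    ).fit(**fit_options)


def fit_region_set(
    tac_table: Mapping[str, TimeActivityCurve],
    input_tac: TimeActivityCurve,
    tracer_mode: str | None = None,
    fit_window_s: float | None = None,
    weights_mode: str | np.ndarray = "duration",
) -> dict[str, OneTissueResults | Exception]:
    """Fit every region independently against the shared input.

    ``tracer_mode`` selects the default fit window ('c11-acetate': 600 s,
    'ga68-dota': 1800 s) unless ``fit_window_s`` is given.  One region's
    failure does not abort the others: the exception is stored in its slot.
    """
    if fit_window_s is None and tracer_mode is not None:
        fit_window_s = DEFAULT_FIT_WINDOW_S[tracer_mode]
    out: dict[str, OneTissueResults | Exception] = {}
    for region, tac in tac_table.items():
        try:
            out[region] = OneTissueModel(
                tac, input_tac, fit_window_s=fit_window_s, weights_mode=weights_mode
            ).fit(tracer_mode=tracer_mode)
        except Exception as exc:  # noqa: BLE001 -- per-region isolation
            out[region] = exc
    return out


def write_fit_report_csv(
    path: str | Path,
    results: Mapping[str, OneTissueResults],
    tracer: str = "",
) -> None:
    """Fit report CSV: region,tracer,K1,k2,Vb,se_K1,se_k2,se_Vb,wrss,converged,fit_window_s."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["region", "tracer", "K1", "k2", "Vb", "se_K1", "se_k2", "se_Vb", "wrss", "converged", "fit_window_s"]
        )
        for region in sorted(results):
            r = results[region]
            writer.writerow(
                [
                    region,
                    tracer or (r.tracer_mode or ""),
                    repr(r.params.K1),
                    repr(r.params.k2),
                    repr(r.params.Vb),
                    repr(float(r.bse[0])),
                    repr(float(r.bse[1])),
                    repr(float(r.bse[2])),
                    repr(float(r.wrss)),
                    r.converged,
                    repr(float(r.fit_window_s)),
                ]
            )
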