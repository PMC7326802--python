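"""Synthetic dynamic-PET studies with known ground truth.

Stands in for the scanner and the animal cohort: generates bolus-shaped
left-ventricular input functions (a Feng-type model), per-segment 1TCM
tissue kinetics with a remote-vs-infarct K1 contrast, frame-averaged
TACs with frame-duration-dependent noise, 17-segment polar-map hearts
with a contiguous anterior/anterolateral defect, and autoradiograph
phantoms with an infarct/remote density contrast.

The generator's defaults describe a two-tracer rat myocardial-infarction
study: 6 coronary-ligation (MI) and 6 sham animals, a 52-frame 30-minute
acquisition, remote myocardial K1 near 0.9 mL/min/mL with a ~4.7x
(11C-acetate) / ~4.3x (68Ga-DOTA) remote-to-infarct contrast, and late
tracer retention in the infarct modelled as a reduced infarct k2 (slower
washout of tracer pooled in the enlarged extracellular space), which
makes the infarct TAC peak lower early but cross above the remote TAC at
late times.

All randomness flows from one integer seed through fixed
(animal, stage) substreams, so regenerating any single animal, or
reordering the cohort, reproduces identical draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .autorad import AutoradImage
from .kinetics import (
    FineCurve,
    KineticParams,
    frame_average,
    simulate_tissue_curve,
)
from .tac import (
    FrameSchedule,
    InjectionRecord,
    TimeActivityCurve,
    TracerInfo,
    make_frame_schedule,
    truncate_schedule,
    write_injection_json,
    write_tac_csv,
)
from .units import HALF_LIVES_MIN, seconds_to_minutes

__all__ = [
    "InputFunctionParams",
    "StudyDesign",
    "AnimalTruth",
    "GroundTruthStudy",
    "SyntheticStudy",
    "default_schedule",
    "feng_input",
    "make_ground_truth",
    "simulate_study",
    "simulate_autorad",
    "write_study",
    "TRACER_ACETATE",
    "TRACER_DOTA",
]

TRACER_ACETATE = "c11-acetate"
TRACER_DOTA = "ga68-dota"

_TRACER_NUCLIDE = {TRACER_ACETATE: "11C", TRACER_DOTA: "68Ga"}
_TRACER_CODE = {TRACER_ACETATE: 0, TRACER_DOTA: 1}

# Substream stage codes for the counter-based seeding scheme.
_STAGE_TRUTH = 0
_STAGE_NOISE = 1
_STAGE_AUTORAD = 2


def default_schedule() -> FrameSchedule:
    """The 52-frame dynamic cardiac protocol: 30x3 + 9x10 + 4x30 + 5x60 + 4x300 s."""
    return make_frame_schedule([(30, 3), (9, 10), (4, 30), (5, 60), (4, 300)])


@dataclass(frozen=True)
class InputFunctionParams:
    """Feng-type bolus input model.

    Cp(t) = 0 for t <= tau; for t > tau,
    Cp(t) = (A1 (t - tau) - A2 - A3) e^{-l1 (t-tau)}
            + A2 e^{-l2 (t-tau)} + A3 e^{-l3 (t-tau)}

    tau is the bolus arrival delay (min), A1 (kBq/mL/min) the first-pass
    amplitude, A2 and A3 (kBq/mL) recirculation amplitudes, and
    l1 > l2 > l3 > 0 (1/min) the eigenrates.  The default peaks ~16 s
    post-injection (arrival 6 s + 1/l1 = 10 s rise) at roughly
    2.2 MBq/mL, with a slow tail that leaves blood activity near
    0.1 MBq/mL at 25-30 min -- a rat-bolus scale for a ~29 MBq injection.
    """

    tau: float = 0.1
    A1: float = 36000.0
    A2: float = 600.0
    A3: float = 560.0
    lambda1: float = 6.0
    lambda2: float = 1.2
    lambda3: float = 0.06

    def __post_init__(self):
        if not self.lambda1 > self.lambda2 > self.lambda3 > 0:
            raise ValueError("eigenrates must satisfy lambda1 > lambda2 > lambda3 > 0")

    def scaled(self, factor: float) -> "InputFunctionParams":
        return replace(self, A1=self.A1 * factor, A2=self.A2 * factor, A3=self.A3 * factor)


def feng_values(params: InputFunctionParams, times_min: np.ndarray) -> np.ndarray:
    t = np.asarray(times_min, dtype=float) - params.tau
    t = np.where(t > 0, t, 0.0)
    cp = (
        (params.A1 * t - params.A2 - params.A3) * np.exp(-params.lambda1 * t)
        + params.A2 * np.exp(-params.lambda2 * t)
        + params.A3 * np.exp(-params.lambda3 * t)
    )
    return np.where(t > 0, cp, 0.0)


def feng_input(params: InputFunctionParams, times_min: np.ndarray) -> FineCurve:
    """Evaluate the bolus model on a uniform fine grid (minutes)."""
    return FineCurve(np.asarray(times_min, dtype=float), feng_values(params, times_min))


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout, kinetic-truth distributions and noise model.

    These defaults ARE the emulated study conditions; deviate only by
    constructing an explicit alternative design.
    """

    n_mi: int = 6
    n_sham: int = 6
    n_segments: int = 17
    #: contiguous anterior/anterolateral defect (AHA ids)
    infarct_segments: tuple = (1, 6, 7, 12, 13, 16)
    #: septal segments used for the remote reference
    remote_segments: tuple = (2, 3, 8, 9, 14)
    tracers: tuple = (TRACER_ACETATE, TRACER_DOTA)

    remote_k1_mean: float = 0.9      # mL/min/mL
    remote_k1_sd: float = 0.15       # between-animal
    segment_rel_sd: float = 0.05     # within-animal, relative
    #: remote-to-infarct K1 ratio, mean and between-animal SD per tracer
    k1_ratio_mean: Mapping[str, float] = field(
        default_factory=lambda: {TRACER_ACETATE: 4.7, TRACER_DOTA: 4.3}
    )
    k1_ratio_sd: Mapping[str, float] = field(
        default_factory=lambda: {TRACER_ACETATE: 0.6, TRACER_DOTA: 1.0}
    )
    k2_mean: Mapping[str, float] = field(
        default_factory=lambda: {TRACER_ACETATE: 0.5, TRACER_DOTA: 1.0}
    )
    k2_rel_sd: float = 0.1
    #: late-retention mechanism: infarct k2 = remote k2 * this scale
    infarct_k2_scale: Mapping[str, float] = field(
        default_factory=lambda: {TRACER_ACETATE: 0.3, TRACER_DOTA: 0.25}
    )
    vb_mean: float = 0.12
    vb_sd: float = 0.02

    #: injected dose (mean, sd) in MBq per (tracer, group)
    dose_mbq: Mapping[tuple, tuple] = field(
        default_factory=lambda: {
            (TRACER_ACETATE, "MI"): (27.0, 5.0),
            (TRACER_ACETATE, "sham"): (27.0, 5.0),
            (TRACER_DOTA, "MI"): (29.0, 3.0),
            (TRACER_DOTA, "sham"): (14.0, 1.0),
        }
    )
    body_weight_g: tuple = (300.0, 25.0)
    input_params: InputFunctionParams = field(default_factory=InputFunctionParams)
    #: dose/weight reference at which input_params amplitudes apply
    reference_dose_mbq: float = 29.0
    reference_weight_g: float = 300.0

    #: noise level alpha in sd_i = alpha*sqrt(max(cbar_i, c_floor)/dt_i[min])
    noise_alpha: float = 0.3
    c_floor: float = 0.01

    def __post_init__(self):
        if self.noise_alpha < 0:
            raise ValueError("noise_alpha must be non-negative")
        for tr in self.tracers:
            if self.k1_ratio_mean[tr] <= 1:
                raise ValueError("remote-to-infarct K1 ratio must exceed 1")
        if self.n_mi > 0 and not self.infarct_segments:
            raise ValueError("MI group requires a non-empty infarct segment set")
        bad = set(self.infarct_segments) & set(self.remote_segments)
        if bad:
            raise ValueError(f"infarct and remote segments overlap: {sorted(bad)}")


@dataclass(frozen=True)
class AnimalTruth:
    animal_id: str
    group: str  # "MI" | "sham"
    index_key: int  # stable per-animal substream key
    body_weight_g: float
    injections: dict  # tracer -> InjectionRecord
    params: dict      # tracer -> {segment_id: KineticParams}
    true_k1_ratio: dict  # tracer -> configured remote/infarct ratio (MI only)


@dataclass(frozen=True)
class GroundTruthStudy:
    design: StudyDesign
    seed: int
    animals: tuple


@dataclass(frozen=True)
class SyntheticStudy:
    """Simulated measurements plus the truth that generated them."""

    ground_truth: GroundTruthStudy
    schedule: FrameSchedule
    #: animal_id -> tracer -> {"input": TAC, "segments": {id: TAC}}
    data: dict


def _rng(seed: int, index_key: int, stage: int, tracer: str | None = None) -> np.random.Generator:
    tr = 0 if tracer is None else _TRACER_CODE[tracer] + 1
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index_key, stage, tr))
    return np.random.default_rng(ss)


def _positive_normal(rng, mean, sd, floor):
    return max(float(rng.normal(mean, sd)), floor)


def make_ground_truth(
    design: StudyDesign | None = None, seed: int = 0, **overrides
) -> GroundTruthStudy:
    """Draw per-animal, per-segment true kinetic parameters.

    MI animals carry the contiguous infarct segment set with K1 reduced
    by the configured remote-to-infarct ratio and k2 reduced by the
    late-retention scale; sham animals are kinetically homogeneous.
    Reproducible: the same seed yields the same study, animal by animal.
    """
    if design is None:
        design = StudyDesign(**overrides)
    elif overrides:
        design = replace(design, **overrides)

    segment_ids = tuple(range(1, design.n_segments + 1))
    missing = set(design.infarct_segments) - set(segment_ids)
    if missing:
        raise ValueError(f"infarct segments outside the layout: {sorted(missing)}")

    animals = []
    specs = [("MI", i, i) for i in range(design.n_mi)] + [
        ("sham", i, 1000 + i) for i in range(design.n_sham)
    ]
    for group, i, key in specs:
        rng = _rng(seed, key, _STAGE_TRUTH)
        weight = _positive_normal(rng, *design.body_weight_g, 150.0)
        animal_id = f"{'MI' if group == 'MI' else 'SH'}{i + 1:02d}"
        remote_k1 = _positive_normal(rng, design.remote_k1_mean, design.remote_k1_sd, 0.05)
        vb = float(np.clip(rng.normal(design.vb_mean, design.vb_sd), 0.0, 1.0))
        injections, params, ratios = {}, {}, {}
        for tracer in design.tracers:
            dose = _positive_normal(rng, *design.dose_mbq[(tracer, group)], 1.0)
            injections[tracer] = InjectionRecord(dose, weight)
            k2_remote = _positive_normal(
                rng, design.k2_mean[tracer], design.k2_rel_sd * design.k2_mean[tracer], 0.01
            )
            if group == "MI":
                ratio = _positive_normal(
                    rng, design.k1_ratio_mean[tracer], design.k1_ratio_sd[tracer], 1.5
                )
            else:
                ratio = 1.0
            ratios[tracer] = ratio
            seg_params = {}
            for sid in segment_ids:
                infarcted = group == "MI" and sid in design.infarct_segments
                base_k1 = remote_k1 / ratio if infarcted else remote_k1
                k1 = base_k1 * _positive_normal(rng, 1.0, design.segment_rel_sd, 0.2)
                k2 = k2_remote * (design.infarct_k2_scale[tracer] if infarcted else 1.0)
                k2 *= _positive_normal(rng, 1.0, design.segment_rel_sd, 0.2)
                seg_params[sid] = KineticParams(K1=k1, k2=k2, Vb=vb)
            params[tracer] = seg_params
        animals.append(
            AnimalTruth(
                animal_id=animal_id,
                group=group,
                index_key=key,
                body_weight_g=weight,
                injections=injections,
                params=params,
                true_k1_ratio=ratios,
            )
        )
    return GroundTruthStudy(design=design, seed=seed, animals=tuple(animals))


def _noise_sd(frame_means: np.ndarray, schedule: FrameSchedule, alpha: float, c_floor: float):
    dt_min = seconds_to_minutes(schedule.frame_durations)
    return alpha * np.sqrt(np.maximum(frame_means, c_floor) / dt_min)


def _tracer_schedule(schedule: FrameSchedule, tracer: str) -> FrameSchedule:
    # the acetate scan covers only the first 10 minutes of the protocol
    if tracer == TRACER_ACETATE and schedule.total_duration > 600.0:
        return truncate_schedule(schedule, 600.0)[0]
    return schedule


def simulate_study(
    gt: GroundTruthStudy,
    schedule: FrameSchedule | None = None,
    noise_alpha: float | None = None,
    fine_step_s: float = 0.5,
) -> SyntheticStudy:
    """Forward-simulate measured TACs for every animal, tracer and segment.

    Per segment: 1TCM forward model on a fine grid, frame averaging, then
    zero-mean Gaussian noise with sd_i = alpha*sqrt(max(cbar_i, c_floor)/dt_i)
    (a count-statistics proxy: long frames are quieter).  The LV input TAC
    receives the same treatment.  Fully determined by the study seed.
    """
    if schedule is None:
        schedule = default_schedule()
    design = gt.design
    alpha = design.noise_alpha if noise_alpha is None else noise_alpha
    if alpha < 0:
        raise ValueError("noise level must be non-negative")

    data: dict = {}
    for animal in gt.animals:
        per_tracer = {}
        for tracer in design.tracers:
            sched = _tracer_schedule(schedule, tracer)
            rng = _rng(gt.seed, animal.index_key, _STAGE_NOISE, tracer)
            tracer_info = TracerInfo(tracer, HALF_LIVES_MIN[_TRACER_NUCLIDE[tracer]])
            inj = animal.injections[tracer]
            scale = (inj.injected_activity_mbq / design.reference_dose_mbq) * (
                design.reference_weight_g / inj.body_weight_g
            )
            n_fine = int(round(sched.frame_ends[-1] / fine_step_s))
            t_min = seconds_to_minutes(np.arange(n_fine + 1) * fine_step_s)
            input_fine = feng_input(design.input_params.scaled(scale), t_min)

            curves = {"input": frame_average(input_fine, sched, region_label="LV",
                                             tracer=tracer_info)}
            for sid in sorted(animal.params[tracer]):
                fine = simulate_tissue_curve(animal.params[tracer][sid], input_fine)
                curves[sid] = frame_average(fine, sched, region_label=f"seg{sid:02d}",
                                            tracer=tracer_info)
            if alpha > 0:
                for key, tac in curves.items():
                    sd = _noise_sd(tac.values, sched, alpha, design.c_floor)
                    noisy = tac.values + rng.normal(0.0, 1.0, sd.shape) * sd
                    curves[key] = replace(tac, values=noisy)
            per_tracer[tracer] = {
                "input": curves["input"],
                "segments": {k: v for k, v in curves.items() if k != "input"},
            }
        data[animal.animal_id] = per_tracer
    return SyntheticStudy(ground_truth=gt, schedule=schedule, data=data)


def simulate_autorad(
    rho: float = 4.3,
    remote_density: float = 6.5,
    background_density: float = 0.0,
    noise_sd_density: float = 0.0,
    shape: tuple = (200, 200),
    pixel_size_mm: float = 0.025,
    infarct_angle_deg: tuple = (30.0, 120.0),
    seed: int = 0,
) -> tuple[AutoradImage, dict]:
    """Autoradiograph phantom: an LV short-axis annulus with an infarct sector.

    The myocardial ring has count density ``remote_density`` (PSL/mm²)
    except in the infarct sector, where it is ``rho`` times higher; a
    uniform ``background_density`` covers the whole plate, plus optional
    Gaussian noise.  Returns the image and infarct / remote / background
    ROI masks (masks carry a safety margin off the sector borders).
    """
    if rho <= 0:
        raise ValueError("intensity ratio rho must be positive")
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r = np.hypot(y - cy, x - cx)
    theta = np.degrees(np.arctan2(y - cy, x - cx)) % 360.0
    r_out, r_in = 0.42 * min(ny, nx), 0.22 * min(ny, nx)
    if r_out >= min(cy, cx):
        raise ValueError("annulus does not fit inside the grid")
    annulus = (r <= r_out) & (r >= r_in)
    a0, a1 = infarct_angle_deg
    in_sector = (theta >= a0) & (theta < a1)
    infarct_region = annulus & in_sector

    px_area = pixel_size_mm**2
    density = np.full(shape, float(background_density))
    density[annulus] += remote_density
    density[infarct_region] += (rho - 1.0) * remote_density
    if noise_sd_density > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STAGE_AUTORAD,)))
        density = density + rng.normal(0.0, noise_sd_density, shape)
    img = AutoradImage(density * px_area, pixel_size_mm)

    margin = 8.0  # degrees off the sector borders
    radial_ok = (r <= r_out - 2) & (r >= r_in + 2)
    infarct_roi = radial_ok & (theta >= a0 + margin) & (theta < a1 - margin)
    opp0, opp1 = (a0 + 180.0) % 360.0, (a1 + 180.0) % 360.0
    if opp0 < opp1:
        remote_roi = radial_ok & (theta >= opp0 + margin) & (theta < opp1 - margin)
    else:
        remote_roi = radial_ok & ((theta >= opp0 + margin) | (theta < opp1 - margin))
    bg = np.zeros(shape, dtype=bool)
    k = max(4, int(0.1 * min(ny, nx)))
    bg[2 : 2 + k, 2 : 2 + k] = True
    masks = {"infarct": infarct_roi, "remote": remote_roi, "background": bg}
    for name, m in masks.items():
        if not m.any():
            raise ValueError(f"{name} ROI is empty for this geometry")
    return img, masks


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Write a study to disk in the package's standard file formats.

    Per animal and tracer: a TAC CSV (LV input + one column per segment)
    and an injection JSON sidecar; plus a manifest JSON and a
    ground-truth CSV for test harnesses.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt = study.ground_truth
    manifest = {"seed": gt.seed, "n_animals": len(gt.animals), "animals": []}
    truth_rows = ["animal_id,group,tracer,segment_id,K1,k2,Vb"]
    for animal in gt.animals:
        entry = {"animal_id": animal.animal_id, "group": animal.group, "tracers": {}}
        for tracer in gt.design.tracers:
            block = study.data[animal.animal_id][tracer]
            sched = block["input"].schedule
            regions = {"LV": block["input"].values}
            for sid, tac in sorted(block["segments"].items()):
                regions[f"seg{sid:02d}"] = tac.values
            tac_path = outdir / f"{animal.animal_id}_{tracer}_tac.csv"
            write_tac_csv(tac_path, sched, regions)
            inj_path = outdir / f"{animal.animal_id}_{tracer}_injection.json"
            write_injection_json(inj_path, block["input"].tracer, animal.injections[tracer])
            entry["tracers"][tracer] = {
                "tac_csv": tac_path.name,
                "injection_json": inj_path.name,
            }
            for sid, p in sorted(animal.params[tracer].items()):
                truth_rows.append(
                    f"{animal.animal_id},{animal.group},{tracer},{sid},{p.K1!r},{p.k2!r},{p.Vb!r}"
                )
        manifest["animals"].append(entry)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (outdir / "ground_truth.csv").write_text("\n".join(truth_rows) + "\n")
    return outdir
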