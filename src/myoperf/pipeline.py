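"""End-to-end study orchestration: generate/load -> fit -> polar map -> autorad -> stats.

A :class:`StudyConfig` describes one reproducible run -- either a
synthetic cohort (the generator's defaults emulate a 6 MI + 6 sham
two-tracer rat study) or a directory of TAC CSV files.  :func:`run_study`
fits the one-tissue model per segment, builds normalised polar maps,
sizes the infarct with the <60% viability cutoff, computes late-phase
SUV retention, quantifies autoradiograph phantoms, and runs the group
statistics; everything it reports is also written to intermediate CSV /
JSON files so each number can be recomputed from disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .autorad import (
    background_subtract,
    count_density,
    fold_ratio,
    roi_area_mm2,
    write_autorad_report_csv,
)
from .kinetics import (
    DEFAULT_FIT_WINDOW_S,
    OneTissueResults,
    fit_region_set,
    write_fit_report_csv,
)
from .polarmap import (
    SegmentAssignment,
    infarct_fraction,
    normalize_polar_map,
    polar_map_from_fits,
    region_k1,
    remote_mi_ratio,
    write_polar_map_csv,
)
from .stats import (
    GroupSummary,
    RegressionResult,
    TestResult,
    linear_regression,
    summarize,
    t_test,
    write_stats_report_json,
)
from .synthetic import (
    TRACER_ACETATE,
    TRACER_DOTA,
    StudyDesign,
    SyntheticStudy,
    make_ground_truth,
    simulate_autorad,
    simulate_study,
)
from .tac import (
    FrameSchedule,
    InjectionRecord,
    TimeActivityCurve,
    make_frame_schedule,
    read_injection_json,
    read_tac_csv,
)

__all__ = [
    "StudyConfig",
    "StudySummary",
    "run_study",
    "compare_defect_sizes",
    "load_study",
]

logger = logging.getLogger("myoperf")

DEFAULT_SCHEDULE_SPEC = [[30, 3], [9, 10], [4, 30], [5, 60], [4, 300]]


@dataclass
class StudyConfig:
    """One reproducible study run.

    Exactly one input source: ``synthetic`` (generator overrides; may be
    empty for the defaults) or ``files`` (a directory written by
    :func:`myoperf.synthetic.write_study` or laid out the same way).
    """

    synthetic: dict | None = None
    files: str | None = None
    seed: int = 0
    schedule_spec: list = field(default_factory=lambda: [list(p) for p in DEFAULT_SCHEDULE_SPEC])
    fit_windows_s: dict = field(default_factory=lambda: dict(DEFAULT_FIT_WINDOW_S))
    cutoff_percent: float = 60.0
    late_window_s: tuple = (1500.0, 1800.0)
    early_window_s: tuple = (0.0, 20.0)
    #: segments quantifying remote vs infarct (defaults follow the generator)
    remote_segments: list | None = None
    infarct_segments: list | None = None
    #: sham contrast: anterior wall vs septum
    sham_anterior_segments: list = field(default_factory=lambda: [1, 7, 13])
    autorad: dict = field(
        default_factory=lambda: {
            "n_sections": 3,
            "remote_density": [6.5, 0.7],
            "infarct_density": [28.0, 1.5],
            "background_density": 2.0,
            "noise_sd_density": 0.2,
            "shape": [200, 200],
        }
    )

    def __post_init__(self):
        if (self.synthetic is None) == (self.files is None):
            raise ValueError("config must name exactly one input source: synthetic or files")
        if not 0.0 < self.cutoff_percent <= 100.0:
            raise ValueError("cutoff_percent must lie in (0, 100]")

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["late_window_s"] = list(self.late_window_s)
        d["early_window_s"] = list(self.early_window_s)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudySummary:
    """Everything a study run reports, with provenance.

    ``per_animal`` has one row per animal x tracer with the fitted remote
    and infarct (or anterior/septal) K1, their ratio, the infarct area
    percent, and late-window SUVs; group tables, t-tests, the cross-tracer
    regression and the autoradiography block aggregate over animals.
    """

    per_animal: pd.DataFrame
    group_tables: dict
    tests: dict
    regression: RegressionResult | None
    autorad: dict
    config_hash: str
    seed: int

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (GroupSummary, TestResult, RegressionResult)):
                return asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "per_animal": self.per_animal.to_dict(orient="records"),
            "group_tables": self.group_tables,
            "tests": self.tests,
            "regression": self.regression,
            "autorad": self.autorad,
        }
        return json.dumps(payload, indent=2, default=default, sort_keys=True)


def _window_mean(tac: TimeActivityCurve, window_s: tuple) -> float:
    lo, hi = window_s
    sel = (tac.schedule.frame_starts >= lo - 1e-9) & (tac.schedule.frame_ends <= hi + 1e-9)
    if not sel.any():
        raise ValueError(f"no frames inside window {window_s}")
    w = tac.schedule.frame_durations[sel]
    return float((tac.values[sel] * w).sum() / w.sum())


def _suv_scale(injection: InjectionRecord) -> float:
    return injection.injected_activity_mbq * 1000.0 / injection.body_weight_g


def load_study(directory: str | Path, schedule: FrameSchedule) -> tuple[dict, dict]:
    """Read a study directory (manifest + TAC CSVs + injection sidecars).

    Returns ``(data, injections)`` in the same nested layout that
    :func:`myoperf.synthetic.simulate_study` produces.
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    data: dict = {}
    injections: dict = {}
    for entry in manifest["animals"]:
        aid, group = entry["animal_id"], entry["group"]
        data[aid] = {"group": group}
        injections[aid] = {}
        for tracer, paths in entry["tracers"].items():
            sched, regions = read_tac_csv(directory / paths["tac_csv"])
            tracer_info, injection = read_injection_json(directory / paths["injection_json"])
            segments = {}
            input_tac = None
            for name, values in regions.items():
                tac = TimeActivityCurve(sched, values, region_label=name, tracer=tracer_info)
                if name == "LV":
                    input_tac = tac
                else:
                    segments[int(name.removeprefix("seg"))] = tac
            if input_tac is None:
                raise ValueError(f"{aid}/{tracer}: TAC CSV has no LV input column")
            data[aid][tracer] = {"input": input_tac, "segments": segments}
            injections[aid][tracer] = injection
    return data, injections


def _fit_animal_tracer(
    block: dict, tracer: str, fit_window_s: float
) -> dict[int, OneTissueResults]:
    fits = fit_region_set(
        block["segments"], block["input"], tracer_mode=tracer, fit_window_s=fit_window_s
    )
    failures = {k: v for k, v in fits.items() if isinstance(v, Exception)}
    for sid, exc in failures.items():
        logger.warning("segment %s fit failed: %s", sid, exc)
    return {k: v for k, v in fits.items() if not isinstance(v, Exception)}


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> StudySummary:
    """Execute the full analysis described by ``config``.

    Deterministic given (config, seed): rerunning writes byte-identical
    outputs.  When ``outdir`` is given, all intermediate files (fit
    reports, polar maps, autorad report, stats JSON, run log) are written
    there.
    """
    schedule = make_frame_schedule([tuple(p) for p in config.schedule_spec])
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    groups: dict[str, str] = {}
    if config.synthetic is not None:
        design = StudyDesign(**config.synthetic)
        gt = make_ground_truth(design, seed=config.seed)
        study = simulate_study(gt, schedule)
        data = dict(study.data)
        injections = {a.animal_id: a.injections for a in gt.animals}
        groups = {a.animal_id: a.group for a in gt.animals}
        tracers = list(design.tracers)
        remote_ids = list(config.remote_segments or design.remote_segments)
        infarct_ids = list(config.infarct_segments or design.infarct_segments)
    else:
        if config.remote_segments is None or config.infarct_segments is None:
            raise ValueError("file-based runs must specify remote_segments and infarct_segments")
        data, injections = load_study(config.files, schedule)
        groups = {aid: blk.pop("group") for aid, blk in data.items()}
        tracers = sorted(next(iter(data.values())).keys())
        remote_ids = list(config.remote_segments)
        infarct_ids = list(config.infarct_segments)

    assignment = SegmentAssignment(frozenset(remote_ids), frozenset(infarct_ids))
    rows: list[dict] = []
    for aid in sorted(data):
        group = groups[aid]
        for tracer in tracers:
            block = data[aid][tracer]
            window = float(config.fit_windows_s.get(tracer, schedule.total_duration))
            fits = _fit_animal_tracer(block, tracer, window)
            pm = polar_map_from_fits(fits, tracer=tracer)
            assignment.validate_against(pm)
            pm_norm = normalize_polar_map(pm)

            inj = injections[aid][tracer]
            suv = _suv_scale(inj)
            late_ok = block["input"].schedule.frame_ends[-1] >= config.late_window_s[1] - 1e-9
            row: dict[str, Any] = {
                "animal_id": aid,
                "group": group,
                "tracer": tracer,
                "n_segments_fit": len(fits),
            }
            if group == "MI":
                rk1 = region_k1(pm, assignment.remote_ids)
                ik1 = region_k1(pm, assignment.infarct_ids)
                row.update(
                    remote_k1=rk1,
                    infarct_k1=ik1,
                    k1_ratio=remote_mi_ratio(rk1, ik1),
                    infarct_pct=infarct_fraction(pm_norm, config.cutoff_percent),
                )
                er = np.mean(
                    [_window_mean(block["segments"][s], config.early_window_s) for s in sorted(assignment.remote_ids)]
                ) / suv
                ei = np.mean(
                    [_window_mean(block["segments"][s], config.early_window_s) for s in sorted(assignment.infarct_ids)]
                ) / suv
                row.update(early_suv_remote=er, early_suv_infarct=ei)
                if late_ok:
                    lr = np.mean(
                        [_window_mean(block["segments"][s], config.late_window_s) for s in sorted(assignment.remote_ids)]
                    ) / suv
                    li = np.mean(
                        [_window_mean(block["segments"][s], config.late_window_s) for s in sorted(assignment.infarct_ids)]
                    ) / suv
                    row.update(late_suv_remote=lr, late_suv_infarct=li, late_suv_mi_remote_ratio=li / lr)
            else:
                septal = sorted(assignment.remote_ids)
                anterior = sorted(config.sham_anterior_segments)
                ak1 = region_k1(pm, anterior)
                sk1 = region_k1(pm, septal)
                row.update(
                    anterior_k1=ak1,
                    septal_k1=sk1,
                    k1_ratio=ak1 / sk1,
                )
                if late_ok:
                    la = np.mean([_window_mean(block["segments"][s], config.late_window_s) for s in anterior]) / suv
                    ls = np.mean([_window_mean(block["segments"][s], config.late_window_s) for s in septal]) / suv
                    row.update(
                        late_suv_anterior=la,
                        late_suv_septum=ls,
                        late_suv_anterior_septum_ratio=la / ls,
                    )
            rows.append(row)
            if out is not None:
                write_fit_report_csv(out / f"{aid}_{tracer}_fits.csv", fits, tracer=tracer)
                write_polar_map_csv(out / f"{aid}_{tracer}_polarmap.csv", pm)

    per_animal = pd.DataFrame(rows)
    mi = per_animal[per_animal.group == "MI"]
    sham = per_animal[per_animal.group == "sham"]

    group_tables: dict = {}
    tests: dict = {}
    for tracer in tracers:
        mt = mi[mi.tracer == tracer]
        if len(mt):
            group_tables[f"remote_mi_k1_ratio[{tracer}]"] = summarize(mt.k1_ratio)
            group_tables[f"infarct_pct[{tracer}]"] = summarize(mt.infarct_pct)
            if len(mt) >= 2:
                tests[f"remote_vs_infarct_k1[{tracer}][paired]"] = t_test(
                    mt.remote_k1, mt.infarct_k1, paired=True
                )
        st = sham[sham.tracer == tracer]
        if len(st):
            group_tables[f"sham_anterior_septum_k1_ratio[{tracer}]"] = summarize(st.k1_ratio)
    if "early_suv_remote" in mi.columns:
        dm = mi[mi.tracer == TRACER_DOTA].dropna(subset=["early_suv_remote"])
        if len(dm):
            group_tables["early_suv_remote[ga68-dota]"] = summarize(dm.early_suv_remote)
            group_tables["early_suv_infarct[ga68-dota]"] = summarize(dm.early_suv_infarct)
    if "late_suv_mi_remote_ratio" in mi.columns:
        dota_mi = mi[mi.tracer == TRACER_DOTA].dropna(subset=["late_suv_mi_remote_ratio"])
        if len(dota_mi):
            group_tables["late_suv_mi_remote_ratio[ga68-dota]"] = summarize(
                dota_mi.late_suv_mi_remote_ratio
            )
            if len(dota_mi) >= 2:
                tests["late_suv_infarct_vs_remote[ga68-dota][paired]"] = t_test(
                    dota_mi.late_suv_infarct, dota_mi.late_suv_remote, paired=True
                )
    dota_sham = sham[sham.tracer == TRACER_DOTA]
    if "late_suv_anterior_septum_ratio" in sham.columns and len(dota_sham) >= 2:
        dss = dota_sham.dropna(subset=["late_suv_anterior_septum_ratio"])
        if len(dss) >= 2:
            group_tables["late_suv_anterior_septum_ratio[sham]"] = summarize(
                dss.late_suv_anterior_septum_ratio
            )
    dota_mi_r = mi[mi.tracer == TRACER_DOTA]
    if len(dota_mi_r) >= 2 and len(dota_sham) >= 2:
        tests["mi_ratio_vs_sham_ratio[ga68-dota][unpaired]"] = t_test(
            dota_mi_r.k1_ratio, dota_sham.k1_ratio, paired=False
        )

    regression: RegressionResult | None = None
    if set((TRACER_ACETATE, TRACER_DOTA)) <= set(tracers) and len(mi):
        wide = mi.pivot(index="animal_id", columns="tracer", values=["remote_k1", "infarct_k1"])
        x = np.concatenate(
            [wide[("remote_k1", TRACER_ACETATE)].to_numpy(), wide[("infarct_k1", TRACER_ACETATE)].to_numpy()]
        )
        y = np.concatenate(
            [wide[("remote_k1", TRACER_DOTA)].to_numpy(), wide[("infarct_k1", TRACER_DOTA)].to_numpy()]
        )
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3:
            regression = linear_regression(x[ok], y[ok])

    autorad_block = _run_autorad(config, [a for a in sorted(data) if groups[a] == "MI"], out)

    if len(mi) and {TRACER_ACETATE, TRACER_DOTA} <= set(mi.tracer):
        defect_df, defect_test = compare_defect_sizes_frame(mi)
        if defect_test is not None:
            tests["defect_size_dota_vs_acetate[paired]"] = defect_test

    summary = StudySummary(
        per_animal=per_animal,
        group_tables=group_tables,
        tests=tests,
        regression=regression,
        autorad=autorad_block,
        config_hash=config.config_hash(),
        seed=config.seed,
    )
    if out is not None:
        per_animal.to_csv(out / "per_animal.csv", index=False)
        (out / "summary.json").write_text(summary.to_json() + "\n")
        write_stats_report_json(
            out / "stats.json", tests, {"dota_vs_acetate_k1": regression} if regression else {}
        )
        (out / "run_log.txt").write_text(
            f"myoperf {__version__}\nseed: {config.seed}\nconfig_hash: {config.config_hash()}\n"
            f"n_animals: {len(data)}\ntracers: {tracers}\n"
        )
        (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n")
    return summary


def _run_autorad(config: StudyConfig, mi_animals: list, out: Path | None) -> dict:
    """Autoradiograph phantoms for the ex-vivo subgroup of MI animals."""
    cfg = config.autorad
    n = min(int(cfg.get("n_sections", 3)), len(mi_animals))
    if n == 0:
        return {}
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(7,)))
    rows, infarct_d, remote_d = [], [], []
    for i in range(n):
        rem = max(float(rng.normal(*cfg["remote_density"])), 0.5)
        inf = max(float(rng.normal(*cfg["infarct_density"])), rem)
        img, masks = simulate_autorad(
            rho=inf / rem,
            remote_density=rem,
            background_density=float(cfg["background_density"]),
            noise_sd_density=float(cfg["noise_sd_density"]),
            shape=tuple(cfg["shape"]),
            seed=config.seed * 1000 + i,
        )
        bg = count_density(img, masks["background"])
        for roi in ("infarct", "remote"):
            d = count_density(img, masks[roi])
            corrected = background_subtract(d, bg)
            if corrected < 0:
                logger.warning("negative corrected density for %s/%s", mi_animals[i], roi)
            rows.append(
                {
                    "section_id": mi_animals[i],
                    "roi": roi,
                    "area_mm2": roi_area_mm2(img, masks[roi]),
                    "density_psl_per_mm2": d,
                    "background": bg,
                    "density_corrected": corrected,
                }
            )
            (infarct_d if roi == "infarct" else remote_d).append(corrected)
    block = {
        "sections": rows,
        "infarct_density": summarize(infarct_d),
        "remote_density": summarize(remote_d),
        "fold_ratio": fold_ratio(float(np.mean(infarct_d)), float(np.mean(remote_d))),
    }
    if len(infarct_d) >= 2:
        block["infarct_vs_remote_test"] = t_test(infarct_d, remote_d, paired=True)
    if out is not None:
        write_autorad_report_csv(out / "autorad_report.csv", rows)
    return block


def compare_defect_sizes_frame(mi_frame: pd.DataFrame):
    """Per-animal (infarct% acetate, infarct% DOTA) pairs plus a paired t-test."""
    wide = mi_frame.pivot(index="animal_id", columns="tracer", values="infarct_pct").dropna()
    if not {TRACER_ACETATE, TRACER_DOTA} <= set(wide.columns):
        raise ValueError("defect-size comparison needs both tracers fitted per animal")
    test = None
    if len(wide) >= 2:
        test = t_test(wide[TRACER_DOTA], wide[TRACER_ACETATE], paired=True)
    return wide, test


def compare_defect_sizes(summary: StudySummary):
    """Defect-size agreement between tracers from a finished run.

    Returns (per-animal wide table, paired t-test or None when n < 2 --
    the comparison is then flagged as underpowered).
    """
    mi = summary.per_animal[summary.per_animal.group == "MI"]
    if mi.empty:
        raise ValueError("no MI animals in this study")
    return compare_defect_sizes_frame(mi)
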