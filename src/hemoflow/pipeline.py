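"""End-to-end study replica: generate, fit, simulate, summarize, compare.

One :func:`run_study` call reproduces the full within-subject design:
a paired cohort of viscosity curves is generated and Casson-fitted; a
per-participant-side geometry cohort is meshed; every participant-side
is simulated twice — before- and after-saline Casson parameters on the
*same* geometry and waveform, isolating the rheological effect exactly
as the within-subject design does; wall summaries are reduced to
study-style shear-rate and WSS tables with paired statistics and a
percent-difference report.

All randomness derives from the single study seed.  A
:class:`RunManifest` records the configuration snapshot and a SHA-256
hash of every artifact, so a rerun with the same config and seed is
bit-checkable.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from hemoflow import __version__
from hemoflow.geometry import (BifurcationGeometry, build_planform,
                               geometry_to_dict)
from hemoflow.hemodynamics import (HemodynamicSummary, detect_recirculation,
                                   shear_rate_field, summarize, summarize_all,
                                   wall_shear_stress)
from hemoflow.meshing import label_regions, triangulate, write_vtk
from hemoflow.rheology import (CassonFit, CassonParams, fit_casson,
                               group_viscosity_summary, percent_difference,
                               percent_difference_truncated, write_fit_csv,
                               write_viscosity_csv)
from hemoflow.solver import FlowField, SimulationConfig, run_simulation
from hemoflow.stats import build_comparison_tables, render_markdown
from hemoflow.synthetic import (CohortSpec, WaveformSpec, condition_mean_params,
                                curves_flat, generate_cohort, generate_geometry_cohort,
                                generate_waveform)

SUMMARY_SHEAR_RATES = (1.0, 10.0, 100.0, 300.0, 1000.0)
ALL_REGIONS = ("whole", "ica", "ica_bulb", "bifurcation_apex_zone", "cca", "eca")


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class StudyConfig:
    """Everything one study run needs; ``seed`` fixes all randomness."""

    seed: int = 0
    n_participants: int = 8
    sides: Tuple[str, ...] = ("left", "right")
    waveform: WaveformSpec = field(default_factory=WaveformSpec)
    base_geometry: BifurcationGeometry = field(default_factory=BifurcationGeometry)
    geometry_cv: float = 0.05
    between_subject_cv: float = 0.10
    measurement_noise_cv: float = 0.02
    mesh_h: float = 0.7e-3          # [m]
    dt: float = 2.5e-3              # [s]
    n_cycles: int = 3
    save_stride: int = 8
    density: float = 1060.0
    export_fields: bool = True
    outdir: str = "results/study"


def smoke_config(outdir: str = "results/smoke", seed: int = 0) -> StudyConfig:
    """Coarse, fast profile: 2 participants, one side, coarse mesh."""
    return StudyConfig(seed=seed, n_participants=2, sides=("left",),
                       mesh_h=1.1e-3, dt=5.0e-3, save_stride=4,
                       outdir=outdir)


def paper_scale_config(outdir: str = "results/paper_scale", seed: int = 0
                       ) -> StudyConfig:
    """Full-cohort profile: 8 participants, both sides (16 arteries)."""
    return StudyConfig(seed=seed, outdir=outdir)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: List[str]
    file_hashes: Dict[str, str]
    wall_seconds: float

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "version": self.version,
             "stages": self.stages, "file_hashes": self.file_hashes,
             "wall_seconds": round(self.wall_seconds, 1)},
            indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_snapshot(config: StudyConfig) -> dict:
    d = asdict(config)
    d["waveform"] = asdict(config.waveform)
    d["base_geometry"] = geometry_to_dict(config.base_geometry)
    return d


def _derive_seeds(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def simulate_participant_side(mesh, waveform_t, waveform_v,
                              params: CassonParams, *, dt: float,
                              n_cycles: int, save_stride: int,
                              density: float = 1060.0) -> FlowField:
    cfg = SimulationConfig(casson=params, density=density, dt=dt,
                           n_cycles=n_cycles, save_stride=save_stride,
                           waveform_t=waveform_t, waveform_v=waveform_v)
    return run_simulation(mesh, cfg)


def run_study(config: StudyConfig) -> RunManifest:
    """Execute all stages; writes artifacts under ``config.outdir``."""
    t_start = _time.perf_counter()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: List[str] = []
    files: Dict[str, Path] = {}

    seeds = _derive_seeds(config.seed, 2)

    # ------------------------------------------------ cohort generation
    stage = "generate_cohort"
    try:
        cohort_spec = CohortSpec(n_participants=config.n_participants,
                                 seed=seeds[0],
                                 between_subject_cv=config.between_subject_cv,
                                 measurement_noise_cv=config.measurement_noise_cv)
        cohort = generate_cohort(cohort_spec)
        flat = curves_flat(cohort)
        files["cohort.csv"] = out / "cohort.csv"
        write_viscosity_csv(flat, files["cohort.csv"])
        stages.append(stage)
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    # ------------------------------------------------ rheology fitting
    stage = "fit_rheology"
    try:
        fits: Dict[Tuple[str, str], CassonFit] = {
            (c.participant_id, c.condition): fit_casson(c) for c in flat}
        files["casson_fits.csv"] = out / "casson_fits.csv"
        write_fit_csv(fits, files["casson_fits.csv"])
        visc_summary = group_viscosity_summary(flat, SUMMARY_SHEAR_RATES)
        files["viscosity_summary.csv"] = out / "viscosity_summary.csv"
        visc_summary.to_csv(files["viscosity_summary.csv"], index=False)
        stages.append(stage)
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    # ------------------------------------------------ waveform, geometry
    stage = "generate_inputs"
    try:
        wt, wv = generate_waveform(config.waveform)
        files["waveform.csv"] = out / "waveform.csv"
        pd.DataFrame({"t_s": wt, "v_m_per_s": wv}).to_csv(
            files["waveform.csv"], index=False)
        n_geo = config.n_participants * len(config.sides)
        geoms = generate_geometry_cohort(n_geo, seeds[1],
                                         config.base_geometry, config.geometry_cv)
        files["geometries.yaml"] = out / "geometries.yaml"
        files["geometries.yaml"].write_text(yaml.safe_dump(
            [geometry_to_dict(g) for g in geoms], sort_keys=True))
        stages.append(stage)
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    # ------------------------------------------------ simulations
    stage = "simulate"
    summaries: List[HemodynamicSummary] = []
    recirc_rows = []
    try:
        geo_idx = 0
        for before_curve, after_curve in cohort:
            pid = before_curve.participant_id
            for side in config.sides:
                geom = geoms[geo_idx]
                geo_idx += 1
                mesh = label_regions(triangulate(build_planform(geom),
                                                 config.mesh_h))
                for cond, curve in (("before", before_curve),
                                    ("after", after_curve)):
                    params = fits[(pid, cond)].params
                    flow = simulate_participant_side(
                        mesh, wt, wv, params, dt=config.dt,
                        n_cycles=config.n_cycles,
                        save_stride=config.save_stride,
                        density=config.density)
                    ws = wall_shear_stress(flow, mesh, params)
                    summaries.extend(summarize_all(
                        ws, ALL_REGIONS, side=side, condition=cond,
                        participant_id=pid))
                    recirc_rows.append({
                        "participant_id": pid, "side": side, "condition": cond,
                        "recirc_ica_bulb": detect_recirculation(ws, "ica_bulb"),
                        "recirc_whole": detect_recirculation(ws, "whole")})
                    if config.export_fields and geo_idx == 1:
                        fdir = out / "fields"
                        fdir.mkdir(exist_ok=True)
                        name = f"{pid}_{side}_{cond}_end_diastole.vtk"
                        sr = shear_rate_field(flow, mesh)
                        write_vtk(fdir / name, mesh, point_data={
                            "velocity": flow.velocity[-1][:mesh.n_vertices],
                            "pressure": flow.pressure[-1],
                            "shear_rate": sr[-1]})
                        files[f"fields/{name}"] = fdir / name
        stages.append(stage)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    # ------------------------------------------------ summaries & stats
    stage = "compare"
    try:
        srows = pd.DataFrame([{
            "participant_id": s.participant_id, "side": s.side,
            "condition": s.condition, "region": s.region,
            "quantity": s.quantity, "minimal": s.minimal,
            "time_averaged": s.time_averaged, "maximal": s.maximal}
            for s in summaries])
        files["summaries.csv"] = out / "summaries.csv"
        srows.to_csv(files["summaries.csv"], index=False)
        files["recirculation.csv"] = out / "recirculation.csv"
        pd.DataFrame(recirc_rows).to_csv(files["recirculation.csv"], index=False)

        comparison = build_comparison_tables(summaries)
        files["comparison.csv"] = out / "comparison.csv"
        comparison.to_csv(files["comparison.csv"], index=False)
        files["comparison.md"] = out / "comparison.md"
        files["comparison.md"].write_text(render_markdown(comparison))

        pct = report_percent_differences(comparison, visc_summary)
        files["percent_differences.csv"] = out / "percent_differences.csv"
        pct.to_csv(files["percent_differences.csv"], index=False)
        stages.append(stage)
    except Exception as err:
        raise PipelineError(stage, str(err)) from err

    manifest = RunManifest(
        config=_config_snapshot(config), version=__version__, stages=stages,
        file_hashes={k: _sha256(p) for k, p in sorted(files.items())},
        wall_seconds=_time.perf_counter() - t_start)
    manifest.write(out / "manifest.json")
    return manifest


def report_percent_differences(comparison: pd.DataFrame,
                               viscosity_summary: pd.DataFrame) -> pd.DataFrame:
    """Percent-difference report, denominator-after convention.

    One row per variable: group-mean viscosity at selected shear rates
    plus every (region, side, statistic) cell of both comparison
    tables, each rendered as the 2-dp percentage and its
    integer-truncated form.  Positive values mean the variable is lower
    after saline.
    """
    rows = []
    vs = viscosity_summary
    for sr in sorted(vs["shear_rate"].unique()):
        try:
            b = float(vs[(vs.condition == "before") & (vs.shear_rate == sr)]
                      ["mean_cP"].iloc[0])
            a = float(vs[(vs.condition == "after") & (vs.shear_rate == sr)]
                      ["mean_cP"].iloc[0])
        except IndexError as err:
            raise PipelineError("percent_differences",
                                f"missing condition at shear rate {sr}") from err
        rows.append({"variable": f"viscosity@{sr:g}/s", "before": b, "after": a,
                     "pct_2dp": round(percent_difference(b, a), 2),
                     "pct_int": percent_difference_truncated(b, a)})
    for _, r in comparison.iterrows():
        rows.append({
            "variable": f"{r.quantity}/{r.region}/{r.side}/{r.statistic}",
            "before": r.before_mean, "after": r.after_mean,
            "pct_2dp": round(percent_difference(r.before_mean, r.after_mean), 2),
            "pct_int": percent_difference_truncated(r.before_mean, r.after_mean)})
    return pd.DataFrame(rows)


def headline_effect_run(seed: int = 0, mesh_h: float = 0.7e-3,
                        dt: float = 2.5e-3, n_cycles: int = 3,
                        save_stride: int = 8,
                        geometry: Optional[BifurcationGeometry] = None) -> dict:
    """Before-vs-after condition-mean comparison on one seeded geometry.

    The direct replica of the study's headline contrast: same geometry,
    same waveform, only the Casson parameters switch from the
    before-condition means to the after-condition means.  Returns
    per-region summary triples, recirculation fractions, and the two
    flow fields.
    """
    if geometry is None:
        geometry = generate_geometry_cohort(1, seed, BifurcationGeometry(),
                                            cv=0.05)[0]
    mesh = label_regions(triangulate(build_planform(geometry), mesh_h))
    wt, wv = generate_waveform(WaveformSpec())
    result: dict = {"geometry": geometry, "mesh": mesh, "summaries": {},
                    "recirculation": {}, "flows": {}}
    for cond in ("before", "after"):
        params = condition_mean_params(cond)
        flow = simulate_participant_side(mesh, wt, wv, params, dt=dt,
                                         n_cycles=n_cycles,
                                         save_stride=save_stride)
        ws = wall_shear_stress(flow, mesh, params)
        result["flows"][cond] = flow
        result["summaries"][cond] = {
            region: {q: summarize(ws, region, q)
                     for q in ("shear_rate", "wss")}
            for region in ALL_REGIONS}
        result["recirculation"][cond] = {
            region: detect_recirculation(ws, region) for region in ALL_REGIONS}
    return result
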