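"""End-to-end orchestration: synthesize -> quantify -> (optionally) CFD.

A run generates a cohort of synthetic embryos (normal, banded, or a paired
normal/banded set sharing seeds), extracts the five analysis cross-sections,
computes wall-motion metrics and 2D area plots, optionally runs the
quasi-steady CFD on a representative embryo, and writes everything (CSV
tables, PLY/VTK fields, figures, a config snapshot and a stage log) to the
output directory.  Runs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry, hemo, synth, wallmotion

__all__ = ["RunConfig", "GroupSummary", "run", "compare_groups", "make_cohort", "summarize_group"]

#: Default cohort sizes: 7 control and 6 banded embryos.
N_CONTROL = 7
N_BANDED = 6

#: Fractions of the cardiac cycle simulated by the CFD stage.
OPEN_FRACTION = {"normal": 0.51, "banded": 0.40}


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    scenario: str = "normal"  # normal | banded | paired
    seed: int = 0
    outdir: str = "oftflow_out"
    n_embryos: int | None = None  # default: 7 normal / 6 banded
    jitter: float = 0.05  # inter-embryo relative variation
    shape: dict = field(default_factory=dict)  # OftShapeParams overrides
    motion: dict = field(default_factory=dict)  # MotionParams overrides
    band: dict = field(default_factory=dict)  # BandParams overrides
    n_rings: int = 40
    n_theta: int = 32
    cfd: bool = False
    n_radial: int = 5
    export_meshes: bool = False

    def __post_init__(self) -> None:
        if self.scenario not in ("normal", "banded", "paired"):
            raise ValueError(f"unknown scenario {self.scenario!r}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def shape_params(self) -> synth.OftShapeParams:
        return synth.OftShapeParams(**self.shape)

    def motion_params(self) -> synth.MotionParams:
        return synth.MotionParams(**self.motion)

    def band_params(self) -> synth.BandParams:
        return synth.BandParams(**self.band)


@dataclass
class GroupSummary:
    """Per-section mean ± SD of wall-motion metrics for one group."""

    name: str
    n: int
    table: pd.DataFrame  # columns: section, layer, metric, mean, sd


def make_cohort(
    config: RunConfig, banded: bool, n: int | None = None, seed_offset: int = 0
):
    """Generate a cohort of embryos; returns a list of per-embryo bundles.

    Each bundle is ``(lumen_frames, myo_frames, ground_truth)``.  Seeded
    parameter jitter provides inter-embryo variation; a paired banded cohort
    uses the same seeds as the controls, so pairs share base anatomy.
    """
    if n is None:
        n = config.n_embryos or (N_BANDED if banded else N_CONTROL)
    band = config.band_params() if banded else None
    out = []
    for k in range(n):
        out.append(
            synth.generate_motion(
                shape=config.shape_params(),
                motion=config.motion_params(),
                band=band,
                seed=config.seed + seed_offset + k,
                n_rings=config.n_rings,
                n_theta=config.n_theta,
                jitter=config.jitter,
            )
        )
    return out


def analyze_embryo(lumen_frames, myo_frames, gt, label: str = ""):
    """Cross-section extraction + wall-motion metrics for one embryo.

    The centerline is computed from the myocardium surface of the most
    contracted frame (minimum total lumen area), mirroring an analysis that
    starts from the most contracted phase of the imaged heart.
    """
    total_area = [f.ring_areas().sum() for f in lumen_frames]
    most_contracted = int(np.argmin(total_area))
    centerline = geometry.compute_centerline(myo_frames[most_contracted])
    traces = geometry.extract_cross_sections(
        lumen_frames, myo_frames, centerline, times=gt.times, period=gt.period
    )
    metrics = wallmotion.compute_metrics(traces, label=label)
    return traces, metrics, centerline


def summarize_group(metrics_list, name: str) -> GroupSummary:
    rows = []
    frames = [m.to_frame() for m in metrics_list]
    allm = pd.concat(frames, ignore_index=True)
    for (sec, layer), grp in allm.groupby(["section", "layer"]):
        for metric in (
            "asf",
            "max_strain",
            "expanding_fraction",
            "contracting_fraction",
            "closed_fraction",
            "total_closure_fraction",
        ):
            rows.append(
                {
                    "section": sec,
                    "layer": layer,
                    "metric": metric,
                    "mean": float(grp[metric].mean()),
                    "sd": float(grp[metric].std(ddof=0)),
                }
            )
    return GroupSummary(name=name, n=len(metrics_list), table=pd.DataFrame(rows))


def compare_groups(normal_metrics, banded_metrics, band_station: float | None = None):
    """Group summaries plus a per-section difference table.

    ``band_station`` (normalized coordinate) flags, per section, whether the
    band sits within one inter-section spacing — the sections where local
    contractility suppression is expected.
    """
    if not normal_metrics or not banded_metrics:
        raise ValueError("both groups need at least one embryo")
    gn = summarize_group(normal_metrics, "normal")
    gb = summarize_group(banded_metrics, "banded")
    merged = gn.table.merge(
        gb.table, on=["section", "layer", "metric"], suffixes=("_normal", "_banded")
    )
    merged["difference"] = merged["mean_banded"] - merged["mean_normal"]
    if band_station is not None:
        n_sections = merged["section"].nunique()
        spacing = 1.0 / (n_sections + 1)
        merged["at_band"] = (
            (merged["section"] * spacing - band_station).abs() <= spacing
        )
    return gn, gb, merged


def _run_cfd_stage(config: RunConfig, bundle, scenario: str, outdir: Path, log):
    lumen_frames, _, gt = bundle
    trace = synth.synthesize_doppler(
        lumen_frames,
        gt.dp,
        gt.probe_point,
        gt.times,
        n_radial=config.n_radial,
    )
    sim = hemo.simulate_cycle(
        lumen_frames,
        trace,
        gt.probe_point,
        n_radial=config.n_radial,
        open_fraction=OPEN_FRACTION.get(scenario),
    )
    diag = hemo.diagnostics(sim.solutions, lumen_frames)
    pd.DataFrame(
        {
            "frame": np.arange(len(gt.times)),
            "time_s": gt.times,
            "dp_fitted_Pa": sim.dp,
            "dp_true_Pa": gt.dp,
        }
    ).to_csv(outdir / f"{scenario}_dp.csv", index=False)
    peak = sim.peak_solution
    pd.DataFrame(
        {"section": np.arange(peak.mesh.n_rings), "Q_m3_per_s": peak.flow_rates()}
    ).to_csv(outdir / f"{scenario}_flow_rates.csv", index=False)
    wss = sim.wss_maps[int(np.argmax([s.peak_velocity for s in sim.solutions]))]
    wss.to_frame().to_csv(outdir / f"{scenario}_wss_peak.csv")
    with open(outdir / f"{scenario}_diagnostics.json", "w") as fh:
        json.dump(
            {
                "reynolds": diag.reynolds,
                "womersley": diag.womersley,
                "peak_velocity_m_per_s": diag.peak_velocity,
                "diameter_m": diag.diameter,
                "excluded_frames": [[int(j), r] for j, r in sim.excluded],
            },
            fh,
            indent=2,
        )
    if config.export_meshes:
        peak.mesh.save_vtk(
            outdir / f"{scenario}_peak_flow.vtk",
            {"velocity": peak.velocity, "pressure": peak.pressure},
        )
    log(f"cfd[{scenario}]: Re={diag.reynolds:.2f} Wo={diag.womersley:.3f} "
        f"{len(sim.solutions)} frames solved, {len(sim.excluded)} excluded")
    return sim, diag


def run(config: RunConfig):
    """Execute a full pipeline run; returns a result dict and writes files."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    t0 = _time.perf_counter()
    config.to_yaml(outdir / "config.yaml")

    scenarios = (
        ["normal", "banded"] if config.scenario == "paired" else [config.scenario]
    )
    results: dict = {"config": config, "scenarios": {}}
    group_metrics: dict = {}
    for scen in scenarios:
        t_s = _time.perf_counter()
        cohort = make_cohort(config, banded=(scen == "banded"))
        log(f"synth[{scen}]: {len(cohort)} embryos generated")
        metrics_list = []
        rows = []
        for k, bundle in enumerate(cohort):
            label = f"{scen}{k + 1}"
            traces, metrics, _ = analyze_embryo(*bundle, label=label)
            metrics_list.append(metrics)
            rows.append(metrics.to_frame())
            if config.export_meshes:
                from .io import save_surface_series

                save_surface_series(bundle[0], outdir / "meshes", f"{label}_lumen")
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / f"{scen}_metrics.csv", index=False
        )
        # area plot of embryo 1
        lumen_frames = cohort[0][0]
        mat = wallmotion.area_plot(lumen_frames)
        pd.DataFrame(mat).to_csv(outdir / f"{scen}_area_plot.csv", index=False)
        _render_area_plot(mat, outdir / f"{scen}_area_plot.png")
        summary = summarize_group(metrics_list, scen)
        summary.table.to_csv(outdir / f"{scen}_summary.csv", index=False)
        group_metrics[scen] = metrics_list
        results["scenarios"][scen] = {
            "metrics": metrics_list,
            "summary": summary,
            "cohort": cohort,
        }
        log(f"metrics[{scen}]: {len(metrics_list)} embryos in "
            f"{_time.perf_counter() - t_s:.1f}s")
        if config.cfd:
            sim, diag = _run_cfd_stage(config, cohort[0], scen, outdir, log)
            results["scenarios"][scen]["cfd"] = (sim, diag)

    if config.scenario == "paired":
        gn, gb, diff = compare_groups(
            group_metrics["normal"],
            group_metrics["banded"],
            band_station=config.band_params().position,
        )
        diff.to_csv(outdir / "group_comparison.csv", index=False)
        results["comparison"] = diff

    log(f"total: {_time.perf_counter() - t0:.1f}s")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return results


def _render_area_plot(mat: np.ndarray, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    im = ax.imshow(
        mat,
        origin="lower",
        aspect="auto",
        extent=(0, 1, 0, 1),
        cmap="jet",
        vmin=0.0,
        vmax=max(1.0, float(mat.max())),
    )
    ax.set_xlabel("t / T")
    ax.set_ylabel("normalized length (VEN → AOS)")
    fig.colorbar(im, ax=ax, label="area / max area")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
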