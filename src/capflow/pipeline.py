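"""Pipeline stages behind the CLI: simulate -> analyze -> report.

Pure functions over the library; the CLI wraps them with flags, logging and
exit codes.  All artifacts carry the config hash and seed so a full run is
reproducible byte for byte.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io
from .analysis import (
    VelocityProfile,
    compare_groups,
    estimate_surface_params,
    finite_difference_velocity,
    fit_viscosity,
    height_window,
    reciprocal_window_filter,
)
from .config import ExperimentConfig
from .core_model import equilibrium_height
from .errors import DegenerateDataError, UnfittableProfileError
from .synthetic import simulate_experiment

log = logging.getLogger("capflow")

#: number of trailing samples averaged for the per-capillary equilibrium estimate
N_TAIL = 3
#: cap on profile points stored per strip in the analysis JSON
MAX_STORED_POINTS = 500


def run_simulate(config: ExperimentConfig, outdir: Path) -> Dict[str, Path]:
    """Simulate the configured experiment; write CSV + sidecar + run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df, sidecar = simulate_experiment(config)
    paths = {
        "dataset": outdir / "dataset.csv",
        "sidecar": outdir / "sidecar.json",
        "config": outdir / "config.yaml",
    }
    io.write_dataset(df, paths["dataset"])
    io.write_json(sidecar, paths["sidecar"])
    config.to_file(paths["config"])
    log.info(
        "simulated %d rows (%d strips) with seed=%d config=%s",
        len(df),
        len(sidecar["strips"]),
        config.seed,
        config.config_hash(),
    )
    return paths


def analyze_dataset(df: pd.DataFrame, config: ExperimentConfig) -> dict:
    """Run the analysis chain on a long-format dataset.

    Per strip: per-capillary equilibrium estimates, windowed velocity
    profile, viscosity fit (using the straight-strip surface calibration of
    the same fluid).  Per fluid: surface fit from the straight strip and
    ANOVA + Tukey across devices at the comparison timepoint.
    """
    geom = config.resolve_geometry()
    fluids = config.resolve_fluids()
    devices = config.resolve_devices()
    window = config.window_inv_H()
    timepoint = config.comparison_timepoint()
    warnings_out: list = []

    trajs = io.dataset_to_trajectories(df, devices=devices, fluids=fluids)
    strips: Dict[str, list] = {}
    for tr in trajs:
        strips.setdefault(tr.strip_id, []).append(tr)

    def split_sid(sid: str):
        if "@" not in sid:
            return None, None
        f, d = sid.split("@", 1)
        return (f if f in fluids else None), (d if d in devices else None)

    # --- per-capillary equilibrium estimates (mean of trailing samples)
    strip_eq: Dict[str, np.ndarray] = {}
    for sid, caps in strips.items():
        strip_eq[sid] = np.array([tr.H[-N_TAIL:].mean() for tr in caps])

    # --- surface fits from straight strips
    surface_fits: Dict[str, dict] = {}
    for sid, eq in strip_eq.items():
        fname, dname = split_sid(sid)
        if fname is None or dname is None:
            warnings_out.append(f"strip '{sid}' not resolvable to fluid@device; skipped fits")
            continue
        if devices[dname].loop_length == 0:
            fit = estimate_surface_params(eq, fluids[fname].rho, geom, fluid_name=fname)
            surface_fits[fname] = {
                "gamma_cos_theta_hat": fit.gamma_cos_theta_hat,
                "sd_gamma_cos_theta": fit.sd_gamma_cos_theta,
                "mean_equilibrium_mm": float(eq.mean()),
                "sd_equilibrium_mm": fit.sd_height,
                "n_replicates": fit.n_replicates,
                "device": dname,
            }

    # --- per-strip profiles and viscosity fits
    strip_results: Dict[str, dict] = {}
    for sid, caps in strips.items():
        fname, dname = split_sid(sid)
        entry: dict = {
            "fluid": fname,
            "device": dname,
            "n_capillaries": len(caps),
            "equilibrium_mm": {
                "mean": float(strip_eq[sid].mean()),
                "sd": float(strip_eq[sid].std(ddof=1)) if len(caps) > 1 else 0.0,
                "per_capillary": [float(x) for x in strip_eq[sid]],
            },
        }
        if fname is not None and dname is not None:
            fluid = fluids[fname]
            if fname in surface_fits:
                fluid = fluid.with_gamma_cos_theta(
                    surface_fits[fname]["gamma_cos_theta_hat"]
                )
            prof_parts = [finite_difference_velocity(tr) for tr in caps]
            prof = VelocityProfile(
                H_mid=np.concatenate([p.H_mid for p in prof_parts]),
                inv_H=np.concatenate([p.inv_H for p in prof_parts]),
                v=np.concatenate([p.v for p in prof_parts]),
                t_mid=np.concatenate([p.t_mid for p in prof_parts]),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wprof = reciprocal_window_filter(prof, window)
            entry["n_windowed_points"] = int(len(wprof))
            try:
                vf = fit_viscosity(wprof, fluid, geom, devices[dname])
                entry["viscosity_fit"] = {
                    "mu_cp": vf.mu_cp,
                    "residual_norm": vf.residual_norm,
                    "n_points": vf.n_points,
                }
            except UnfittableProfileError as exc:
                entry["viscosity_fit"] = None
                warnings_out.append(f"strip '{sid}': viscosity unfittable ({exc})")
            step = max(1, len(wprof) // MAX_STORED_POINTS)
            entry["profile_points"] = {
                "inv_H_per_mm": [float(x) for x in wprof.inv_H[::step]],
                "v_mm_s": [float(x) for x in wprof.v[::step]],
            }
            entry["model_equilibrium_mm"] = float(equilibrium_height(fluid, geom))
        strip_results[sid] = entry

    # --- ANOVA across devices at the comparison timepoint, per fluid
    anova: Dict[str, dict] = {}
    by_fluid: Dict[str, dict] = {}
    for sid, caps in strips.items():
        fname, dname = split_sid(sid)
        if fname is None or dname is None:
            continue
        heights = []
        for tr in caps:
            idx = int(np.argmin(np.abs(tr.t - timepoint)))
            heights.append(tr.H[idx])
        by_fluid.setdefault(fname, {})[dname] = np.asarray(heights)
    for fname, groups in by_fluid.items():
        if len(groups) < 2:
            warnings_out.append(
                f"fluid '{fname}': only one device group; ANOVA omitted"
            )
            continue
        try:
            comp = compare_groups(groups)
        except DegenerateDataError as exc:
            warnings_out.append(f"fluid '{fname}': ANOVA degenerate ({exc})")
            continue
        anova[fname] = comp.to_dict()

    hw = height_window(window)
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "window": {
            "inv_H_per_mm": [float(window[0]), float(window[1])],
            "height_mm": [float(hw[0]), float(hw[1])],
        },
        "comparison_timepoint_s": timepoint,
        "surface_fits": surface_fits,
        "strips": strip_results,
        "anova": anova,
        "warnings": warnings_out,
    }


def run_analyze(
    dataset_path: Path, config: ExperimentConfig, outdir: Path, sidecar: Optional[dict] = None
) -> Path:
    """Analyze a dataset file; write analysis.json and return its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = io.read_dataset(dataset_path)
    result = analyze_dataset(df, config)
    if sidecar is not None and sidecar.get("config_hash") != config.config_hash():
        result["warnings"].append(
            "config hash mismatch between sidecar and analysis config"
        )
        log.warning("config hash mismatch between sidecar and analysis config")
    out = outdir / "analysis.json"
    io.write_json(result, out)
    for w in result["warnings"]:
        log.warning("%s", w)
    log.info("analysis written to %s", out)
    return out


# ---------------------------------------------------------------- reporting


def render_report(analysis: dict) -> str:
    """Human-readable summary tables from an analysis dict."""
    lines = []
    lines.append(f"capflow analysis report  (config {analysis.get('config_hash', '?')}, "
                 f"seed {analysis.get('seed', '?')})")
    win = analysis.get("window")
    if win:
        lines.append(
            "analysis window: 1/H in [{:.4g}, {:.4g}] 1/mm "
            "(heights {:.1f}-{:.1f} mm)".format(
                win["inv_H_per_mm"][0],
                win["inv_H_per_mm"][1],
                win["height_mm"][0],
                win["height_mm"][1],
            )
        )
    lines.append("")

    strips = analysis.get("strips", {})
    if strips:
        rows = []
        for sid, s in sorted(strips.items()):
            eq = s.get("equilibrium_mm", {})
            vf = s.get("viscosity_fit")
            rows.append(
                {
                    "strip": sid,
                    "n": s.get("n_capillaries"),
                    "H_eq obs (mm)": f"{eq.get('mean', float('nan')):.1f} +/- {eq.get('sd', float('nan')):.1f}",
                    "H_eq model (mm)": (
                        f"{s['model_equilibrium_mm']:.1f}" if "model_equilibrium_mm" in s else "not computed"
                    ),
                    "mu fit (cP)": f"{vf['mu_cp']:.2f}" if vf else "not computed",
                }
            )
        lines.append("Equilibrium heights and viscosity fits")
        lines.append(pd.DataFrame(rows).to_string(index=False))
        lines.append("")

    sf = analysis.get("surface_fits", {})
    if sf:
        rows = [
            {
                "fluid": f,
                "gamma*cos(theta) (N/m)": f"{d['gamma_cos_theta_hat']:.5f}",
                "+/- (N/m)": f"{d['sd_gamma_cos_theta']:.5f}",
                "from H_eq (mm)": f"{d['mean_equilibrium_mm']:.1f}",
                "n": d["n_replicates"],
            }
            for f, d in sorted(sf.items())
        ]
        lines.append("Surface-parameter fits (straight strips)")
        lines.append(pd.DataFrame(rows).to_string(index=False))
        lines.append("")

    anova = analysis.get("anova", {})
    if anova:
        lines.append("Loop effect on heights at t = "
                     f"{analysis.get('comparison_timepoint_s', '?')} s (one-way ANOVA + Tukey HSD)")
        for fname, comp in sorted(anova.items()):
            lines.append(
                f"  {fname}: F({comp['df_between']},{comp['df_within']}) = "
                f"{comp['F']:.1f}, p = {comp['p_value']:.2g}"
            )
            for row in comp.get("tukey", []):
                lines.append(
                    f"    {row['group1']} vs {row['group2']}: "
                    f"diff = {row['diff']:.2f} mm, p_adj = {row['p_adj']:.2g}"
                )
        lines.append("")
    else:
        lines.append("Group comparison: not computed")
        lines.append("")

    for w in analysis.get("warnings", []):
        lines.append(f"warning: {w}")
    return "\n".join(lines)


def plot_overlays(analysis: dict, config: ExperimentConfig, outdir: Path) -> list:
    """v vs 1/H scatter with model overlay, one figure per fluid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .analysis import predict_velocity_curve

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geom = config.resolve_geometry()
    fluids = config.resolve_fluids()
    devices = config.resolve_devices()
    sf = analysis.get("surface_fits", {})
    made = []
    for fname, fluid in fluids.items():
        fig, ax = plt.subplots(figsize=(5, 4))
        if fname in sf:
            fluid = fluid.with_gamma_cos_theta(sf[fname]["gamma_cos_theta_hat"])
        plotted = False
        for sid, s in sorted(analysis.get("strips", {}).items()):
            if s.get("fluid") != fname or "profile_points" not in s:
                continue
            pts = s["profile_points"]
            ax.scatter(pts["inv_H_per_mm"], pts["v_mm_s"], s=8, alpha=0.5, label=f"{s['device']} data")
            dev = devices.get(s["device"])
            if dev is not None:
                h_eq = equilibrium_height(fluid, geom)
                H = np.linspace(0.999 * h_eq, max(1.0, 0.05 * h_eq), 200)
                prof = predict_velocity_curve(fluid, geom, dev, H)
                ax.plot(prof.inv_H, prof.v, lw=1.2, label=f"{s['device']} model")
            plotted = True
        if not plotted:
            plt.close(fig)
            continue
        ax.set_xlabel("1/H (1/mm)")
        ax.set_ylabel("dH/dt (mm/s)")
        ax.set_title(f"{fname}: velocity vs reciprocal height")
        ax.legend(fontsize=7)
        fig.tight_layout()
        path = outdir / f"overlay_{fname}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        made.append(path)
    return made
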