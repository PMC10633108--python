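"""Diagnostic plots: H vs t, H vs log t, and u vs 1/H with model overlay.

Figures are written as PNG with deterministic styling; the numeric data
behind each figure is additionally dumped as CSV so the plotted values
are testable without image comparison.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .flow_simulator import RiseTrajectory
from .property_fitting import FitResult, MultiplierCurveFamily, _model_u, _curvature
from .strip_imaging import VelocitySeries

__all__ = ["plot_heights", "plot_velocity_vs_reciprocal_height"]


def plot_heights(
    trajectories: Sequence[RiseTrajectory], out_dir: str | Path, stem: str = "heights"
) -> list[Path]:
    """H vs t on linear and log-x axes; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    rows = []
    for log_x in (False, True):
        fig, ax = plt.subplots(figsize=(5, 3.5), dpi=120)
        for tr in trajectories:
            ax.plot(tr.times, tr.heights * 1e3, lw=0.8,
                    label=f"s{tr.strip_id}c{tr.capillary_id}")
        if log_x:
            ax.set_xscale("log")
            pos = trajectories[0].times > 0
            ax.set_xlim(left=max(trajectories[0].times[pos].min(), 1e-2))
        ax.set_xlabel("time (s)")
        ax.set_ylabel("height (mm)")
        if len(trajectories) <= 10:
            ax.legend(fontsize=5, ncol=2)
        fig.tight_layout()
        path = out_dir / f"{stem}{'_logt' if log_x else ''}.png"
        fig.savefig(path)
        plt.close(fig)
        written.append(path)
    for tr in trajectories:
        rows.append(pd.DataFrame({"time_s": tr.times, "strip_id": tr.strip_id,
                                  "capillary_id": tr.capillary_id,
                                  "height_mm": tr.heights * 1e3}))
    csv_path = out_dir / f"{stem}.csv"
    pd.concat(rows, ignore_index=True).to_csv(csv_path, index=False,
                                              float_format="%.9g")
    written.append(csv_path)
    return written


def plot_velocity_vs_reciprocal_height(
    series_list: Sequence[VelocitySeries],
    out_dir: str | Path,
    fit: FitResult | None = None,
    family: MultiplierCurveFamily | None = None,
    dip_depth: float = 3e-3,
    stem: str = "velocity_vs_reciprocal_height",
) -> list[Path]:
    """u vs 1/H scatter with optional fitted-model / multiplier overlays."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 3.5), dpi=120)
    rows = []
    for ser in series_list:
        keep = np.isfinite(ser.reciprocal_heights)
        x = ser.reciprocal_heights[keep] * 1e-3  # 1/mm
        y = ser.velocities[keep] * 1e3  # mm/s
        ax.plot(x, y, ".", ms=3, alpha=0.6)
        rows.append(pd.DataFrame({"inv_height_per_mm": x, "velocity_mm_s": y,
                                  "strip_id": ser.strip_id,
                                  "capillary_id": ser.capillary_id,
                                  "kind": "data"}))
    x_all = np.concatenate([r["inv_height_per_mm"].to_numpy() for r in rows])
    grid = np.linspace(max(x_all.min(), 1e-3), x_all.max(), 200)  # 1/mm
    if family is not None:
        for m in family.multipliers:
            u = family.velocity(m, grid * 1e3) * 1e3
            ax.plot(grid, u, lw=1.2, label=f"{m:g}x viscosity")
            rows.append(pd.DataFrame({"inv_height_per_mm": grid,
                                      "velocity_mm_s": u, "strip_id": -1,
                                      "capillary_id": -1, "kind": f"model_{m:g}x"}))
        ax.legend(fontsize=6)
    elif fit is not None and fit.viscosity is not None and fit.geometry is not None:
        u = _model_u(fit.surface_drive, fit.viscosity, grid * 1e3,
                     _curvature(fit.geometry), fit.geometry.hydraulic_diameter,
                     fit.density, 9.81, dip_depth) * 1e3
        ax.plot(grid, u, "k-", lw=1.2, label="fitted model")
        rows.append(pd.DataFrame({"inv_height_per_mm": grid, "velocity_mm_s": u,
                                  "strip_id": -1, "capillary_id": -1,
                                  "kind": "model_fit"}))
        ax.legend(fontsize=6)
    ax.set_xlabel("1/H (1/mm)")
    ax.set_ylabel("dH/dt (mm/s)")
    fig.tight_layout()
    png = out_dir / f"{stem}.png"
    fig.savefig(png)
    plt.close(fig)
    csv = out_dir / f"{stem}.csv"
    pd.concat(rows, ignore_index=True).to_csv(csv, index=False, float_format="%.9g")
    return [png, csv]
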