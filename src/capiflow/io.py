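"""Shared file formats: trajectory CSV, TIFF frame stacks, JSON reports.

The long-format trajectory CSV (columns ``time_s, strip_id,
capillary_id, height_mm, blocked``) is the pipeline contract: the
simulator and the meniscus tracker emit the identical schema, so fitted
analyses cannot tell synthetic and tracked data apart, and a real
instrument export can replace either.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import ConfigurationError
from .flow_simulator import RiseTrajectory
from .property_fitting import FitResult
from .strip_imaging import FrameStack

__all__ = [
    "write_trajectories",
    "read_trajectories",
    "write_frame_stack",
    "read_frame_stack",
    "write_fit_report",
    "write_layout",
    "read_layout",
]

TRAJECTORY_COLUMNS = ["time_s", "strip_id", "capillary_id", "height_mm", "blocked"]


def write_trajectories(
    path: str | Path, trajectories: Sequence[RiseTrajectory], seed: int | None = None
) -> None:
    """Write trajectories to the shared long-format CSV (heights in mm)."""
    rows = []
    for tr in trajectories:
        blocked = np.zeros(tr.times.size, dtype=int)
        if tr.blocked_at is not None:
            blocked[tr.times >= tr.blocked_at] = 1
        rows.append(
            pd.DataFrame(
                {
                    "time_s": tr.times,
                    "strip_id": tr.strip_id,
                    "capillary_id": tr.capillary_id,
                    "height_mm": tr.heights * 1e3,
                    "blocked": blocked,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)[TRAJECTORY_COLUMNS]
    with open(path, "w") as fh:
        fh.write(f"# capiflow {__version__} seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_trajectories(path: str | Path) -> list[RiseTrajectory]:
    """Read the shared trajectory CSV back into RiseTrajectory objects."""
    df = pd.read_csv(path, comment="#")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"trajectory CSV missing columns {sorted(missing)}")
    out = []
    for (s, c), grp in df.groupby(["strip_id", "capillary_id"], sort=True):
        grp = grp.sort_values("time_s")
        blocked_at = None
        hit = grp.loc[grp["blocked"] == 1, "time_s"]
        if len(hit):
            blocked_at = float(hit.iloc[0])
        out.append(
            RiseTrajectory(
                times=grp["time_s"].to_numpy(),
                heights=grp["height_mm"].to_numpy() * 1e-3,
                strip_id=int(s),
                capillary_id=int(c),
                blocked_at=blocked_at,
            )
        )
    return out


def _columns_to_json(columns: dict) -> dict:
    return {f"s{s}_c{c}": list(map(int, rng)) for (s, c), rng in columns.items()}


def _columns_from_json(d: dict) -> dict:
    out = {}
    for key, rng in d.items():
        s, c = key.lstrip("s").split("_c")
        out[(int(s), int(c))] = (int(rng[0]), int(rng[1]))
    return out


def write_frame_stack(
    tiff_path: str | Path, stack: FrameStack, seed: int | None = None
) -> None:
    """Write a multi-page grayscale TIFF plus its JSON sidecar."""
    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, stack.frames, photometric="minisblack")
    sidecar = {
        "capiflow_version": __version__,
        "seed": seed,
        "timestamps_s": [float(t) for t in stack.timestamps],
        "scale_mm_per_px": stack.scale,
        "baseline_row": stack.baseline_row,
        "columns": _columns_to_json(stack.columns),
    }
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_frame_stack(tiff_path: str | Path) -> FrameStack:
    """Read a TIFF frame stack, validating it against its JSON sidecar."""
    tiff_path = Path(tiff_path)
    sidecar_path = tiff_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ConfigurationError(f"missing sidecar JSON {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    n_expected = len(sidecar["timestamps_s"])
    if len(frames) != n_expected:
        raise ConfigurationError(
            f"TIFF has {len(frames)} pages but sidecar lists {n_expected} timestamps"
        )
    return FrameStack(
        frames=frames.astype(np.uint8),
        timestamps=np.asarray(sidecar["timestamps_s"], dtype=float),
        scale=float(sidecar["scale_mm_per_px"]),
        columns=_columns_from_json(sidecar["columns"]),
        baseline_row=int(sidecar["baseline_row"]),
    )


def write_layout(path: str | Path, layout, seed: int | None = None) -> None:
    """Serialize per-capillary ellipse axes (the measured bore geometry).

    The bench workflow measures each bore's major/minor axes from
    end-face micrographs; fits need them, so simulations export theirs.
    """
    doc = {
        "capiflow_version": __version__,
        "seed": seed,
        "strip_length_m": layout.strip_length,
        "geometries": [[g.to_json_dict() for g in strip]
                       for strip in layout.geometries],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_layout(path: str | Path):
    from .core_model import CapillaryGeometry
    from .flow_simulator import StripLayout

    doc = json.loads(Path(path).read_text())
    geoms = [[CapillaryGeometry.from_json_dict(g) for g in strip]
             for strip in doc["geometries"]]
    return StripLayout(geometries=geoms,
                       strip_length=float(doc["strip_length_m"]))


def write_fit_report(
    path: str | Path,
    fit: FitResult,
    sample_class: str = "unknown",
    seed: int | None = None,
    extra: dict | None = None,
) -> dict:
    """Serialize a fit result to the report JSON schema; returns the dict."""
    def clean(v):
        return None if isinstance(v, float) and math.isnan(v) else v

    report = {
        "capiflow_version": __version__,
        "sample_class": sample_class,
        "sigma_eff_N_m": clean(fit.surface_drive),
        "mu_cP": None if fit.viscosity is None else fit.viscosity * 1e3,
        "mu_status": "fitted" if fit.viscosity_identifiable else "not identifiable",
        "rho_kg_m3": fit.density,
        "H_eq_mm": clean(fit.equilibrium_height * 1e3),
        "residual_rms_mm_s": fit.residual_rms * 1e3,
        "constraints": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in fit.constraint_record.items()
        },
        "flags": list(fit.flags),
        "n_points": fit.n_points,
        "capillary_ids": list(fit.capillary_ids),
        "seed": seed,
    }
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, indent=1))
    return report
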