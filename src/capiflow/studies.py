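"""End-to-end synthetic studies built from the pipeline stages.

These routines reproduce, at desk scale, the structure of the bench
validation experiments: the glycerol–water equilibrium calibration, the
noisy Monte-Carlo parameter-recovery sweep, and the thrombin-dose
stimulation panel.  They are ordinary library functions (seeded,
deterministic) so the same code path serves tests, the acceptance script
and exploratory use.
"""

from __future__ import annotations

import math
import numpy as np

from .core_model import (
    CapillaryGeometry,
    FluidProperties,
    PhysicsConfig,
    contact_angle_from_equilibrium,
    ellipse_geometry,
    equilibrium_height,
    laplace_pressure,
)
from .flow_simulator import (
    MEAN_DIAMETERS_UM,
    THROMBIN_DOSES_U_ML,
    SimulationConfig,
    integrate_rise_batch,
    simulate_stimulated_rise,
    viscosity_schedule,
)
from .property_fitting import (
    ConstraintSet,
    FitResult,
    constrained_fit,
    multiplier_curves,
    classify_stimulated_series,
)
from .samples import GLYCEROL_FRACTIONS, glycerol_mixture
from .strip_imaging import estimate_velocity
from .flow_simulator import RiseTrajectory

__all__ = [
    "glycerol_equilibrium_study",
    "noisy_recovery_study",
    "stimulation_panel",
    "circle",
]


def circle(diameter_um: float, length_m: float = 0.12) -> CapillaryGeometry:
    """Circular-bore geometry helper (a = b = diameter)."""
    d = diameter_um * 1e-6
    return ellipse_geometry(d, d, capillary_length=length_m)


def glycerol_equilibrium_study(
    fractions=GLYCEROL_FRACTIONS,
    diameters_um=MEAN_DIAMETERS_UM,
    total_time: float = 600.0,
    time_step: float = 10e-3,
    physics: PhysicsConfig = PhysicsConfig(),
) -> list[dict]:
    """Long-time integrated rise vs the closed-form equilibrium height.

    Integrates every glycerol fraction x bore diameter combination to
    near-equilibrium and compares the final height with H_eq = dP_L/(rho
    g), also inverting the equilibrium for the contact angle.  Returns one
    record per combination.
    """
    fluids = [glycerol_mixture(f) for f in fractions]
    geoms = [circle(d) for d in diameters_um]
    combos = [(f, fl, d, gm) for f, fl in zip(fractions, fluids)
              for d, gm in zip(diameters_um, geoms)]
    cfg = SimulationConfig(time_step=time_step, total_time=total_time,
                           frame_interval=total_time, height_noise=0.0,
                           time_jitter=0.0)
    _, heights, _ = integrate_rise_batch(
        np.array([laplace_pressure(fl, gm) for _, fl, _, gm in combos]),
        np.array([gm.hydraulic_diameter for _, _, _, gm in combos]),
        np.array([fl.viscosity for _, fl, _, gm in combos]),
        np.array([fl.density for _, fl, _, gm in combos]),
        np.array([gm.capillary_length for _, _, _, gm in combos]),
        cfg,
        physics,
    )
    final = heights[-1]
    out = []
    for (frac, fl, d_um, gm), h_end in zip(combos, final):
        h_eq = equilibrium_height(fl, gm, physics)
        theta = contact_angle_from_equilibrium(
            min(h_end, h_eq), fl.surface_tension, fl.density, gm, physics
        )
        out.append(
            {
                "glycerol_pct": frac,
                "diameter_um": d_um,
                "H_final_mm": h_end * 1e3,
                "H_eq_mm": h_eq * 1e3,
                "rel_error_pct": 100.0 * abs(h_end - h_eq) / h_eq,
                "contact_angle_deg": theta,
            }
        )
    return out


def noisy_recovery_study(
    fluid: FluidProperties,
    diameter_um: float,
    n_replicates: int = 200,
    n_capillaries: int = 10,
    seed: int = 0,
    height_noise: float = 0.01,
    time_jitter: float = 0.02,
    total_time: float = 30.0,
    time_step: float = 1e-3,
    diameter_cv: float = 0.094,
    aspect_ratio: float = 1.25,
    constraints: ConstraintSet | None = None,
    tolerance_pct: float = 13.0,
    physics: PhysicsConfig = PhysicsConfig(),
) -> dict:
    """Monte-Carlo parameter recovery under measurement noise.

    Each replicate simulates ``n_capillaries`` bores (lognormal diameter
    scatter, elliptical cross-sections), samples heights at 6 frames/s
    with multiplicative noise and frame-timing jitter, estimates
    velocities, and pools the capillaries into one constrained fit.  All
    replicates integrate in a single vectorized pass.

    Returns per-replicate percent deviations of (sigma_eff, mu) and the
    fraction of replicates where both fall within ``tolerance_pct``.
    """
    rng = np.random.default_rng(seed)
    n = n_replicates * n_capillaries
    sigma_ln = math.sqrt(math.log(1.0 + diameter_cv**2))
    jitter_d = rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln, size=n)
    d = diameter_um * 1e-6 * jitter_d
    sqrt_q = math.sqrt(aspect_ratio)
    geoms = [ellipse_geometry(di * sqrt_q, di / sqrt_q, capillary_length=0.12)
             for di in d]

    cfg = SimulationConfig(time_step=time_step, total_time=total_time,
                           height_noise=0.0, time_jitter=0.0, seed=seed)
    n_frames = int(math.floor(total_time / cfg.frame_interval + 1e-9)) + 1
    jit = (rng.uniform(-time_jitter, time_jitter, size=(n_frames, n))
           if time_jitter > 0 else None)
    times, heights, _ = integrate_rise_batch(
        np.array([laplace_pressure(fluid, g) for g in geoms]),
        np.array([g.hydraulic_diameter for g in geoms]),
        fluid.viscosity,
        fluid.density,
        np.array([g.capillary_length for g in geoms]),
        cfg,
        physics,
        sample_jitter=jit,
    )
    if height_noise > 0:
        heights = heights * (1.0 + height_noise * rng.standard_normal(heights.shape))
        heights = np.maximum(heights, 0.0)

    cons = constraints or ConstraintSet()
    truth_sigma = fluid.sigma_eff
    truth_mu = fluid.viscosity
    sigma_dev, mu_dev = [], []
    for r in range(n_replicates):
        members = range(r * n_capillaries, (r + 1) * n_capillaries)
        series = [
            estimate_velocity(
                RiseTrajectory(times=times, heights=heights[:, i], capillary_id=i)
            )
            for i in members
        ]
        fit = constrained_fit(
            series, [geoms[i] for i in members], fluid.density, cons,
            physics, dip_depth=cfg.dip_depth,
        )
        sigma_dev.append(100.0 * (fit.surface_drive - truth_sigma) / truth_sigma)
        mu_dev.append(100.0 * (fit.viscosity - truth_mu) / truth_mu)
    sigma_dev = np.asarray(sigma_dev)
    mu_dev = np.asarray(mu_dev)
    ok = (np.abs(sigma_dev) <= tolerance_pct) & (np.abs(mu_dev) <= tolerance_pct)
    return {
        "sigma_dev_pct": sigma_dev,
        "mu_dev_pct": mu_dev,
        "within_tolerance_fraction": float(np.mean(ok)),
        "n_replicates": n_replicates,
        "tolerance_pct": tolerance_pct,
    }


def stimulation_panel(
    fluid: FluidProperties,
    geom: CapillaryGeometry,
    doses=THROMBIN_DOSES_U_ML,
    total_time: float = 40.0,
    readout_time: float = 30.0,
    time_step: float = 1e-3,
    physics: PhysicsConfig = PhysicsConfig(),
) -> dict:
    """Dose panel: simulate stimulated rises and classify them.

    Simulates one capillary per dose with the dose-mapped viscosity ramp,
    records the fixed-time heights, and classifies each velocity series
    against the fixed-multiplier curve family of the unstimulated
    baseline.  Returns the schedules, trajectories, fixed-time heights and
    per-dose onset estimates.
    """
    cfg = SimulationConfig(time_step=time_step, total_time=total_time,
                           height_noise=0.0, time_jitter=0.0)
    schedules = [viscosity_schedule(d) for d in doses]
    trajs = [simulate_stimulated_rise(fluid, geom, sch, cfg, physics)
             for sch in schedules]
    baseline = FitResult(
        surface_drive=fluid.sigma_eff, viscosity=fluid.viscosity,
        density=fluid.density,
        equilibrium_height=equilibrium_height(fluid, geom, physics),
        residual_rms=0.0, geometry=geom,
    )
    family = multiplier_curves(baseline, geom, (2.0, 3.0, 4.0, 6.0),
                               physics, dip_depth=cfg.dip_depth)
    onsets, terminals = [], []
    for tr in trajs:
        cls = classify_stimulated_series(estimate_velocity(tr), family)
        onsets.append(cls["onset_time"])
        terminals.append(cls["terminal_multiplier"])
    idx = int(np.searchsorted(trajs[0].times, readout_time))
    idx = min(idx, trajs[0].times.size - 1)
    heights_at_readout = [float(tr.heights[idx]) for tr in trajs]
    return {
        "doses": list(doses),
        "schedules": schedules,
        "trajectories": trajs,
        "readout_time_s": float(trajs[0].times[idx]),
        "heights_at_readout_m": heights_at_readout,
        "onset_estimates_s": onsets,
        "terminal_multipliers": terminals,
        "family": family,
    }
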