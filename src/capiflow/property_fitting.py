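"""Recovery of fluid properties from velocity/height data.

The quasi-steady balance with L ~ H predicts a linear relation between
the instantaneous velocity and the reciprocal height,

    u = s * (1/H) + c,    s = dP_L d_h^2 / (32 mu),
                          c = - rho g d_h^2 / (32 mu),

so an ordinary least-squares line through (1/H, u) identifies the
viscosity from the (negative) intercept and the surface-drive term
sigma_eff = cos(theta)*gamma from the slope.  The full nonlinear model
(L = H + L_dip, velocity clamped at equilibrium) is fitted by
box-constrained least squares seeded from the linear solution; density is
always fixed, never fitted, and for blood-like samples only the combined
sigma_eff is reported since surface tension and contact angle cannot be
separated.

A fixed-multiplier curve family (u vs 1/H at m x the baseline viscosity,
surface drive held fixed) supports the qualitative read-out of
stimulation experiments: observations sliding from the baseline curve
onto higher-multiplier curves indicate a coagulation-driven viscosity
increase.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core_model import CapillaryGeometry, PhysicsConfig
from .errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
)
from .strip_imaging import VelocitySeries

__all__ = [
    "FitResult",
    "ConstraintSet",
    "MultiplierCurveFamily",
    "TABLE_CONSTRAINTS",
    "linear_transient_fit",
    "constrained_fit",
    "equilibrium_only_fit",
    "multiplier_curves",
    "classify_stimulated_series",
    "recovery_report",
]

#: Observed velocities above this (m/s) are down-weighted: they come from
#: very short inter-frame intervals where timing noise dominates.
FAST_VELOCITY_THRESHOLD = 20e-3


@dataclass
class FitResult:
    """Recovered parameters of one pooled fit."""

    surface_drive: float  # sigma_eff = cos(theta)*gamma, N/m
    viscosity: float | None  # mu, Pa s; None when not identifiable
    density: float  # fixed rho used, kg/m^3
    equilibrium_height: float  # H_eq implied by sigma_eff, m
    residual_rms: float  # m/s
    constraint_record: dict = field(default_factory=dict)
    n_points: int = 0
    capillary_ids: tuple = ()
    viscosity_identifiable: bool = True
    flags: tuple[str, ...] = ()
    geometry: CapillaryGeometry | None = None


@dataclass(frozen=True)
class ConstraintSet:
    """Viscosity (and optional surface-drive) box for one sample class.

    Viscosity entries are in cP at the interface; ``fixed_viscosity_cP``
    pins the viscosity entirely (e.g. water), in which case only the
    surface drive is fitted.
    """

    viscosity_lo_cP: float | None = None
    viscosity_hi_cP: float | None = None
    fixed_viscosity_cP: float | None = None
    sigma_lo_N_m: float = 1e-3
    sigma_hi_N_m: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.viscosity_lo_cP, self.viscosity_hi_cP
        if lo is not None and hi is not None and not lo < hi:
            raise ConfigurationError(f"viscosity bounds infeasible: [{lo}, {hi}]")
        if not self.sigma_lo_N_m < self.sigma_hi_N_m:
            raise ConfigurationError("sigma bounds infeasible")

    def mu_bounds_Pa_s(self) -> tuple[float, float]:
        lo = 1e-5 if self.viscosity_lo_cP is None else self.viscosity_lo_cP * 1e-3
        hi = 1.0 if self.viscosity_hi_cP is None else self.viscosity_hi_cP * 1e-3
        return lo, hi

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "ConstraintSet":
        return cls(
            viscosity_lo_cP=d.get("mu_lo_cP"),
            viscosity_hi_cP=d.get("mu_hi_cP"),
            fixed_viscosity_cP=d.get("mu_fixed_cP"),
            sigma_lo_N_m=d.get("sigma_lo_N_m", 1e-3),
            sigma_hi_N_m=d.get("sigma_hi_N_m", 0.1),
        )


#: Expected-range constraints per sample class: water and saline are
#: pinned at the handbook viscosity, plasma is bounded above by 1.7 cP,
#: and cellular samples lie between 2 and 6 cP.
TABLE_CONSTRAINTS: dict[str, ConstraintSet] = {
    "water": ConstraintSet(fixed_viscosity_cP=1.04),
    "HBS": ConstraintSet(fixed_viscosity_cP=1.04),
    "PPP": ConstraintSet(viscosity_hi_cP=1.7),
    "PRP": ConstraintSet(viscosity_hi_cP=1.7),
    "RBC": ConstraintSet(viscosity_lo_cP=2.0, viscosity_hi_cP=6.0),
    "WB": ConstraintSet(viscosity_lo_cP=2.0, viscosity_hi_cP=6.0),
}


def _curvature(geom: CapillaryGeometry) -> float:
    # Laplace prefactor: dP_L = sigma_eff * curv
    return 2.0 * (1.0 / geom.major_axis + 1.0 / geom.minor_axis)


def _weights(u_ref: np.ndarray) -> np.ndarray:
    w = np.ones_like(u_ref)
    fast = np.abs(u_ref) > FAST_VELOCITY_THRESHOLD
    w[fast] = FAST_VELOCITY_THRESHOLD / np.abs(u_ref[fast])
    return w


def _usable(series: VelocitySeries) -> np.ndarray:
    return np.isfinite(series.reciprocal_heights) & (series.heights > 0)


def _fit_velocities(series: VelocitySeries) -> np.ndarray:
    # prefer raw signed differences: clamped (rectified) velocities would
    # bias the fit upward wherever the true velocity is comparable to noise
    if series.signed_velocities is not None:
        return series.signed_velocities
    return series.velocities


def linear_transient_fit(
    series: VelocitySeries,
    geom: CapillaryGeometry,
    density: float,
    cfg: PhysicsConfig = PhysicsConfig(),
    downweight_fast: bool = True,
) -> FitResult:
    """Closed-form parameter recovery from the u-vs-1/H line (L ~ H regime).

    Weighted least squares of u on 1/H; the slope gives dP_L d_h^2/(32 mu)
    and the intercept -rho g d_h^2/(32 mu), so mu and sigma_eff follow in
    closed form.  A non-negative intercept means the gravity term was not
    resolved by the data; the fit is then flagged and the viscosity left
    undetermined.
    """
    keep = _usable(series)
    x = series.reciprocal_heights[keep]
    y = _fit_velocities(series)[keep]
    if np.unique(x).size < 5:
        raise InsufficientDataError(
            f"need >= 5 distinct usable points, got {np.unique(x).size}"
        )
    w = _weights(y) if downweight_fast else np.ones_like(y)
    slope, intercept = np.polyfit(x, y, 1, w=w)
    d_h = geom.hydraulic_diameter
    resid = y - (slope * x + intercept)
    rms = float(np.sqrt(np.mean(resid**2)))
    if intercept >= 0:
        return FitResult(
            surface_drive=float("nan"), viscosity=None, density=density,
            equilibrium_height=float("nan"), residual_rms=rms,
            n_points=int(keep.sum()), capillary_ids=(series.capillary_id,),
            viscosity_identifiable=False, flags=("nonphysical_intercept",),
            geometry=geom,
        )
    mu = -density * cfg.gravity * d_h**2 / (32.0 * intercept)
    dp_l = 32.0 * mu * slope / d_h**2
    sigma = dp_l / _curvature(geom)
    return FitResult(
        surface_drive=float(sigma), viscosity=float(mu), density=density,
        equilibrium_height=float(dp_l / (density * cfg.gravity)),
        residual_rms=rms, n_points=int(keep.sum()),
        capillary_ids=(series.capillary_id,),
        constraint_record={"slope_m2_s": float(slope), "intercept_m_s": float(intercept)},
        geometry=geom,
    )


def _model_u(
    sigma: float, mu: float, inv_h: np.ndarray, curv: float, d_h: float,
    rho: float, g: float, dip_depth: float,
) -> np.ndarray:
    h = 1.0 / inv_h
    net = np.maximum(sigma * curv - rho * g * h, 0.0)
    return net * d_h**2 / (32.0 * mu * (h + dip_depth))


def constrained_fit(
    series_list: Sequence[VelocitySeries],
    geom_list: Sequence[CapillaryGeometry],
    density: float,
    constraints: ConstraintSet,
    cfg: PhysicsConfig = PhysicsConfig(),
    dip_depth: float = 3e-3,
    downweight_fast: bool = True,
) -> FitResult:
    """Box-constrained least squares over pooled capillaries (full model).

    Minimizes the weighted sum of squared velocity residuals of the full
    quasi-steady model (L = H + dip_depth, no linearization) over
    (sigma_eff, mu), pooling all capillaries of one sample class with
    their individual geometries.  Residuals use the raw signed velocity
    differences (rectified velocities would bias the parameters upward
    near equilibrium), and the fast-velocity down-weighting is refreshed
    once from the model prediction so the weights do not correlate with
    the measurement noise.  Seeded from the closed-form linear fit;
    bounds from the sample-class constraint set, with active bounds
    reported.  Density is fixed, never fitted.
    """
    if len(series_list) != len(geom_list):
        raise ConfigurationError("one geometry per velocity series required")
    xs, ys, curvs, dhs = [], [], [], []
    for ser, geom in zip(series_list, geom_list):
        keep = _usable(ser)
        xs.append(ser.reciprocal_heights[keep])
        ys.append(_fit_velocities(ser)[keep])
        curvs.append(np.full(int(keep.sum()), _curvature(geom)))
        dhs.append(np.full(int(keep.sum()), geom.hydraulic_diameter))
    inv_h = np.concatenate(xs)
    u_obs = np.concatenate(ys)
    curv = np.concatenate(curvs)
    d_h = np.concatenate(dhs)
    if np.unique(inv_h).size < 5:
        raise InsufficientDataError("need >= 5 distinct usable points pooled")
    w = _weights(u_obs) if downweight_fast else np.ones_like(u_obs)

    g = cfg.gravity
    sig_lo, sig_hi = constraints.sigma_lo_N_m, constraints.sigma_hi_N_m

    # closed-form seed from a pooled linear fit with a representative geometry
    slope, intercept = np.polyfit(inv_h, u_obs, 1, w=w)
    dh_ref = float(np.median(d_h))
    curv_ref = float(np.median(curv))
    mu0 = (
        -density * g * dh_ref**2 / (32.0 * intercept) if intercept < 0 else 3e-3
    )
    sigma0 = 32.0 * mu0 * max(slope, 1e-12) / dh_ref**2 / curv_ref

    fixed_mu = constraints.fixed_viscosity_cP
    if fixed_mu is not None:
        mu_fix = fixed_mu * 1e-3

        def model(p):
            return _model_u(p[0], mu_fix, inv_h, curv, d_h, density, g, dip_depth)

        x0 = [float(np.clip(sigma0, sig_lo, sig_hi))]
        bounds = ([sig_lo], [sig_hi])
        x_scale = [1e-2]
        mu_lo = mu_hi = mu_fix
    else:
        mu_lo, mu_hi = constraints.mu_bounds_Pa_s()
        if not mu_lo < mu_hi:
            raise ConfigurationError("infeasible viscosity constraint box")

        def model(p):
            return _model_u(p[0], p[1], inv_h, curv, d_h, density, g, dip_depth)

        x0 = [float(np.clip(sigma0, sig_lo, sig_hi)),
              float(np.clip(mu0, mu_lo, mu_hi))]
        bounds = ([sig_lo, mu_lo], [sig_hi, mu_hi])
        x_scale = [1e-2, 1e-3]

    sol = least_squares(lambda p: w * (model(p) - u_obs), x0, bounds=bounds,
                        method="trf", x_scale=x_scale)
    if downweight_fast:  # one reweighting pass with model-based weights
        w = _weights(model(sol.x))
        sol = least_squares(lambda p: w * (model(p) - u_obs), sol.x,
                            bounds=bounds, method="trf", x_scale=x_scale)
    if fixed_mu is not None:
        sigma, mu = float(sol.x[0]), mu_fix
    else:
        sigma, mu = float(sol.x[0]), float(sol.x[1])

    r = _model_u(sigma, mu, inv_h, curv, d_h, density, g, dip_depth) - u_obs
    rms = float(np.sqrt(np.mean(r**2)))

    def near(v, b):
        return b is not None and abs(v - b) <= 1e-6 * max(abs(b), 1e-12)

    record = {
        "sigma_bounds_N_m": (sig_lo, sig_hi),
        "mu_bounds_cP": (mu_lo * 1e3, mu_hi * 1e3),
        "mu_fixed": fixed_mu is not None,
        "sigma_active": near(sigma, sig_lo) or near(sigma, sig_hi),
        "mu_active": fixed_mu is None and (near(mu, mu_lo) or near(mu, mu_hi)),
    }
    dp_l_ref = sigma * curv_ref
    return FitResult(
        surface_drive=sigma, viscosity=mu, density=density,
        equilibrium_height=dp_l_ref / (density * g), residual_rms=rms,
        constraint_record=record, n_points=inv_h.size,
        capillary_ids=tuple(s.capillary_id for s in series_list),
        geometry=geom_list[0],
    )


def equilibrium_only_fit(
    H_eq_obs: float,
    geom: CapillaryGeometry,
    density: float,
    cfg: PhysicsConfig = PhysicsConfig(),
) -> FitResult:
    """Surface drive from an equilibrium height alone.

    Equilibrium rise carries no viscosity information (no flow, no
    friction), so the returned fit marks the viscosity as not
    identifiable.
    """
    if H_eq_obs < 0:
        raise DomainError("equilibrium height must be >= 0")
    sigma = density * cfg.gravity * H_eq_obs / _curvature(geom)
    return FitResult(
        surface_drive=float(sigma), viscosity=None, density=density,
        equilibrium_height=float(H_eq_obs), residual_rms=0.0,
        n_points=1, viscosity_identifiable=False,
        flags=("equilibrium_only",), geometry=geom,
    )


@dataclass
class MultiplierCurveFamily:
    """Model u-vs-1/H curves at fixed multiples of the baseline viscosity."""

    baseline: FitResult
    geometry: CapillaryGeometry
    multipliers: tuple[float, ...]  # includes the baseline 1.0 first
    dip_depth: float
    physics: PhysicsConfig = PhysicsConfig()

    def velocity(self, multiplier: float, inv_h: np.ndarray) -> np.ndarray:
        """Model velocity at ``multiplier`` x the baseline viscosity."""
        return _model_u(
            self.baseline.surface_drive,
            multiplier * self.baseline.viscosity,
            np.asarray(inv_h, dtype=float),
            _curvature(self.geometry),
            self.geometry.hydraulic_diameter,
            self.baseline.density,
            self.physics.gravity,
            self.dip_depth,
        )


def multiplier_curves(
    baseline: FitResult,
    geom: CapillaryGeometry,
    multipliers: Sequence[float] = (2.0, 3.0, 4.0, 6.0),
    cfg: PhysicsConfig = PhysicsConfig(),
    dip_depth: float = 3e-3,
) -> MultiplierCurveFamily:
    """Fixed-viscosity-multiplier family for stimulation read-out.

    For each multiplier m the model curve u(1/H) is evaluated with mu =
    m * mu_baseline and the surface drive held fixed; larger multipliers
    give strictly lower velocities at every 1/H.
    """
    if baseline.viscosity is None:
        raise ConfigurationError("baseline fit has no identifiable viscosity")
    ms = tuple(float(m) for m in multipliers)
    if any(m < 1.0 for m in ms):
        raise DomainError(f"multipliers must be >= 1, got {ms}")
    full = (1.0,) + tuple(m for m in ms if m != 1.0)
    return MultiplierCurveFamily(
        baseline=baseline, geometry=geom, multipliers=full,
        dip_depth=dip_depth, physics=cfg,
    )


def classify_stimulated_series(
    series: VelocitySeries, family: MultiplierCurveFamily
) -> dict:
    """Assign each observation to its nearest multiplier curve.

    For every (1/H, u) observation the family curve with the smallest
    absolute velocity residual is recorded (ties resolve to the smaller
    multiplier).  Returns the per-point multipliers, the terminal
    multiplier (last observation), and the onset estimate: the first time
    the best match exceeds the baseline, or None for unstimulated data.
    """
    if len(family.multipliers) < 2:
        raise ConfigurationError("family needs at least two multiplier curves")
    keep = _usable(series)
    if not np.any(keep):
        raise InsufficientDataError("no usable observations to classify")
    inv_h = series.reciprocal_heights[keep]
    u_obs = series.velocities[keep]
    t = series.times[keep]
    resid = np.stack(
        [np.abs(u_obs - family.velocity(m, inv_h)) for m in family.multipliers]
    )  # multipliers are ascending, so argmin takes the smaller on ties
    best = np.asarray(family.multipliers)[np.argmin(resid, axis=0)]
    beyond = best > 1.0
    onset = float(t[np.argmax(beyond)]) if np.any(beyond) else None
    return {
        "times": t,
        "multiplier_per_point": best,
        "terminal_multiplier": float(best[-1]),
        "onset_time": onset,
    }


def recovery_report(true_params: Mapping, fit: FitResult) -> dict:
    """Signed percent deviation of fitted vs generating parameters.

    ``true_params`` keys: ``surface_drive`` (N/m) and/or ``viscosity``
    (Pa s).  Adds ``max_abs_pct`` over the reported deviations.
    """
    out: dict = {}
    devs = []
    for key in ("surface_drive", "viscosity"):
        if key in true_params:
            truth = float(true_params[key])
            est = getattr(fit, key)
            if est is None:
                out[f"{key}_pct"] = None
                continue
            dev = 100.0 * (est - truth) / truth
            out[f"{key}_pct"] = dev
            devs.append(abs(dev))
    out["max_abs_pct"] = max(devs) if devs else None
    return out
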