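"""Quasi-steady pressure-balance physics of vertical capillary rise.

A wetting liquid drawn into a narrow vertical capillary is driven by the
Laplace pressure drop across the curved meniscus and resisted by the
hydrostatic head of the raised column and by laminar viscous friction
(Darcy–Weisbach with f_D = 64/Re).  At the low Reynolds numbers of
microcapillary rise (Re < 10) inertia is negligible, so the instantaneous
superficial velocity ``u`` follows from a quasi-steady balance

    dP_laplace = dP_friction(u) + dP_head,

which is linear in ``u`` and can be solved in closed form.  All quantities
in this module are strict SI (m, s, kg, Pa); the I/O layer converts from
the bench units (mm, cP, mN/m, degrees).

The capillaries of melt-extruded multi-bore strips are elliptical; the
Laplace pressure uses the two-curvature elliptical form and friction uses
the hydraulic diameter d_h = 4A/P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import (
    ConfigurationError,
    DomainError,
    InfeasibleObservationError,
    InvalidGeometryError,
    SingularStateError,
)

__all__ = [
    "FluidProperties",
    "CapillaryGeometry",
    "FlowState",
    "PhysicsConfig",
    "ellipse_geometry",
    "laplace_pressure",
    "friction_pressure",
    "quasi_steady_velocity",
    "equilibrium_height",
    "contact_angle_from_equilibrium",
    "wall_shear_rate",
    "REYNOLDS_LAMINAR_LIMIT",
]

#: Reynolds number above which the laminar 64/Re friction law is flagged.
REYNOLDS_LAMINAR_LIMIT = 2000.0


@dataclass(frozen=True)
class PhysicsConfig:
    """Physical constants of the model; only gravity is tunable."""

    gravity: float = 9.81  # m s^-2

    def __post_init__(self) -> None:
        if not self.gravity >= 0.0:
            raise ConfigurationError(f"gravity must be >= 0, got {self.gravity}")


@dataclass(frozen=True)
class FluidProperties:
    """Bulk and interfacial properties of a sample.

    Parameters
    ----------
    density : float
        Mass density rho, kg m^-3.
    viscosity : float
        Dynamic viscosity mu, Pa s.
    surface_tension : float, optional
        Liquid–air surface tension gamma, N m^-1.
    contact_angle_deg : float, optional
        Liquid–wall contact angle theta, degrees; must satisfy
        0 <= theta < 90 (hydrophilic wall).
    surface_drive : float, optional
        Combined surface-drive term sigma_eff = cos(theta) * gamma,
        N m^-1.  For opaque samples such as blood, gamma and theta cannot
        be separated and only this product is identifiable; either supply
        it directly or supply both gamma and theta.
    """

    density: float
    viscosity: float
    surface_tension: float | None = None
    contact_angle_deg: float | None = None
    surface_drive: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.density) and self.density > 0):
            raise DomainError(f"density must be positive, got {self.density}")
        if not (math.isfinite(self.viscosity) and self.viscosity > 0):
            raise DomainError(f"viscosity must be positive, got {self.viscosity}")
        if self.contact_angle_deg is not None:
            if not (0.0 <= self.contact_angle_deg < 90.0):
                raise DomainError(
                    "contact angle must lie in [0, 90) degrees for a wetting "
                    f"wall, got {self.contact_angle_deg}"
                )
        if (
            self.surface_drive is not None
            and self.surface_tension is not None
            and self.contact_angle_deg is not None
        ):
            implied = self.surface_tension * math.cos(
                math.radians(self.contact_angle_deg)
            )
            if abs(self.surface_drive - implied) > 1e-12 * max(abs(implied), 1e-30):
                raise ConfigurationError(
                    "surface_drive inconsistent with cos(theta)*gamma: "
                    f"{self.surface_drive} vs {implied}"
                )

    @property
    def sigma_eff(self) -> float:
        """cos(theta) * gamma, N m^-1; raises if surface data is missing."""
        if self.surface_drive is not None:
            return self.surface_drive
        if self.surface_tension is not None and self.contact_angle_deg is not None:
            return self.surface_tension * math.cos(
                math.radians(self.contact_angle_deg)
            )
        raise ConfigurationError(
            "Laplace computation needs surface_drive or both surface_tension "
            "and contact_angle_deg"
        )

    def with_viscosity(self, viscosity: float) -> "FluidProperties":
        return replace(self, viscosity=viscosity)

    @classmethod
    def from_json_dict(cls, d: dict) -> "FluidProperties":
        """Build from the bench-unit JSON descriptor.

        Keys: ``rho_kg_m3``, ``mu_cP``, optional ``gamma_mN_m``,
        ``theta_deg``, ``sigma_eff_N_m``.
        """
        gamma = d.get("gamma_mN_m")
        return cls(
            density=float(d["rho_kg_m3"]),
            viscosity=float(d["mu_cP"]) * 1e-3,
            surface_tension=None if gamma is None else float(gamma) * 1e-3,
            contact_angle_deg=d.get("theta_deg"),
            surface_drive=d.get("sigma_eff_N_m"),
        )

    def to_json_dict(self) -> dict:
        return {
            "rho_kg_m3": self.density,
            "mu_cP": self.viscosity * 1e3,
            "gamma_mN_m": None
            if self.surface_tension is None
            else self.surface_tension * 1e3,
            "theta_deg": self.contact_angle_deg,
            "sigma_eff_N_m": self.surface_drive,
        }


@dataclass(frozen=True)
class CapillaryGeometry:
    """Elliptical bore geometry; axes are FULL major/minor axes in metres."""

    major_axis: float
    minor_axis: float
    cross_section: float
    perimeter: float
    hydraulic_diameter: float
    capillary_length: float = 0.1  # physical strip length, m

    @classmethod
    def from_json_dict(cls, d: dict) -> "CapillaryGeometry":
        """Build from micrometre-unit JSON: major_axis_um, minor_axis_um, length_mm."""
        return ellipse_geometry(
            float(d["major_axis_um"]) * 1e-6,
            float(d["minor_axis_um"]) * 1e-6,
            capillary_length=float(d.get("length_mm", 100.0)) * 1e-3,
        )

    def to_json_dict(self) -> dict:
        return {
            "major_axis_um": self.major_axis * 1e6,
            "minor_axis_um": self.minor_axis * 1e6,
            "length_mm": self.capillary_length * 1e3,
        }


def _ramanujan_perimeter(semi_a: float, semi_b: float) -> float:
    # Ramanujan's first approximation; < 0.01% error for aspect ratios <~ 3.
    return math.pi * (
        3.0 * (semi_a + semi_b)
        - math.sqrt((3.0 * semi_a + semi_b) * (semi_a + 3.0 * semi_b))
    )


def ellipse_geometry(
    a: float, b: float, capillary_length: float = 0.1
) -> CapillaryGeometry:
    """Derive cross-section, perimeter and hydraulic diameter of an elliptical bore.

    Parameters
    ----------
    a, b : float
        Full major and minor axes in metres, ``a >= b > 0``.
    capillary_length : float
        Physical length of the strip, metres.
    """
    if not (math.isfinite(a) and math.isfinite(b) and b > 0 and a > 0):
        raise InvalidGeometryError(f"axes must be positive finite, got a={a}, b={b}")
    if a < b:
        raise InvalidGeometryError(
            f"major axis must be >= minor axis (a={a}, b={b}); order the axes"
        )
    if not capillary_length > 0:
        raise InvalidGeometryError(f"capillary_length must be > 0, got {capillary_length}")
    area = math.pi * a * b / 4.0
    perim = _ramanujan_perimeter(a / 2.0, b / 2.0)
    return CapillaryGeometry(
        major_axis=a,
        minor_axis=b,
        cross_section=area,
        perimeter=perim,
        hydraulic_diameter=4.0 * area / perim,
        capillary_length=capillary_length,
    )


@dataclass(frozen=True)
class FlowState:
    """Instantaneous flow state produced by the quasi-steady balance."""

    height: float  # H, meniscus above reservoir level, m
    wetted_length: float  # L, total fluid length in the capillary, m
    velocity: float  # u, superficial velocity, m s^-1
    laplace: float  # dP_L, Pa
    friction: float  # dP_F, Pa
    head: float  # dP_H, Pa
    reynolds: float | None = None
    friction_factor: float | None = None
    wall_shear_rate: float | None = None
    laminar_violated: bool = False


def laplace_pressure(fluid: FluidProperties, geom: CapillaryGeometry) -> float:
    """Laplace pressure drop across the meniscus of an elliptical bore.

    dP_L = 2 sigma_eff (1/a + 1/b) with a, b the full axes; reduces to
    4 sigma_eff / d for a circular bore of diameter d.
    """
    sigma = fluid.sigma_eff
    if sigma < 0:
        raise DomainError(f"surface drive must be >= 0 (wetting), got {sigma}")
    return 2.0 * sigma * (1.0 / geom.major_axis + 1.0 / geom.minor_axis)


def friction_pressure(
    fluid: FluidProperties,
    geom: CapillaryGeometry,
    u: float,
    L: float,
) -> tuple[float, float | None, float | None]:
    """Laminar Darcy–Weisbach friction drop over wetted length ``L``.

    Returns ``(dP_F, Re, f_D)``.  With f_D = 64/Re the product collapses to
    the Hagen–Poiseuille form dP_F = 32 mu L u / d_h^2, which is what is
    evaluated (it is finite at u = 0 where Re and f_D are undefined).
    """
    if u < 0:
        raise DomainError(f"superficial velocity must be >= 0, got {u}")
    if not L > 0:
        raise DomainError(f"wetted length must be > 0, got {L}")
    d_h = geom.hydraulic_diameter
    dp_f = 32.0 * fluid.viscosity * L * u / d_h**2
    if u == 0.0:
        return 0.0, None, None
    re = fluid.density * u * d_h / fluid.viscosity
    return dp_f, re, 64.0 / re


def wall_shear_rate(u: float, geom: CapillaryGeometry) -> float:
    """Mean wall shear rate gamma_w = 8 u / d_h for laminar tube flow, s^-1."""
    return 8.0 * u / geom.hydraulic_diameter


def quasi_steady_velocity(
    fluid: FluidProperties,
    geom: CapillaryGeometry,
    H: float,
    L: float,
    cfg: PhysicsConfig = PhysicsConfig(),
) -> FlowState:
    """Solve the quasi-steady pressure balance for the rise velocity.

    u = max(0, (dP_L - rho g H) d_h^2 / (32 mu L)).  Negative net pressure
    (meniscus above its equilibrium height) clamps u to zero — the model
    does not describe meniscus retreat.
    """
    if L == 0.0:
        raise SingularStateError(
            "wetted length L = 0 is singular; regularize with a dip depth"
        )
    if not (L >= H >= 0.0 and L > 0.0):
        raise DomainError(f"need L >= H >= 0 with L > 0, got H={H}, L={L}")
    dp_l = laplace_pressure(fluid, geom)
    dp_h = fluid.density * cfg.gravity * H
    d_h = geom.hydraulic_diameter
    u = max(0.0, (dp_l - dp_h) * d_h**2 / (32.0 * fluid.viscosity * L))
    dp_f, re, f_d = friction_pressure(fluid, geom, u, L)
    return FlowState(
        height=H,
        wetted_length=L,
        velocity=u,
        laplace=dp_l,
        friction=dp_f,
        head=dp_h,
        reynolds=re,
        friction_factor=f_d,
        wall_shear_rate=wall_shear_rate(u, geom),
        laminar_violated=(re is not None and re >= REYNOLDS_LAMINAR_LIMIT),
    )


def equilibrium_height(
    fluid: FluidProperties,
    geom: CapillaryGeometry,
    cfg: PhysicsConfig = PhysicsConfig(),
) -> float:
    """Equilibrium rise H_eq = dP_L / (rho g); independent of viscosity."""
    if cfg.gravity == 0.0:
        raise DomainError("equilibrium height is unbounded at zero gravity")
    return laplace_pressure(fluid, geom) / (fluid.density * cfg.gravity)


def contact_angle_from_equilibrium(
    H_eq: float,
    surface_tension: float,
    density: float,
    geom: CapillaryGeometry,
    cfg: PhysicsConfig = PhysicsConfig(),
) -> float:
    """Invert the equilibrium balance for the contact angle, degrees.

    From rho g H_eq = 2 gamma cos(theta) (1/a + 1/b); used for calibration
    samples (e.g. glycerol–water mixtures) whose surface tension is known.

    Raises
    ------
    InfeasibleObservationError
        If the observed H_eq implies cos(theta) > 1 (rise too high for the
        stated surface tension) or cos(theta) <= 0 with H_eq > 0.
    """
    if H_eq < 0:
        raise DomainError(f"H_eq must be >= 0, got {H_eq}")
    if not surface_tension > 0:
        raise DomainError(f"surface tension must be > 0, got {surface_tension}")
    curv = 2.0 * (1.0 / geom.major_axis + 1.0 / geom.minor_axis)
    cos_theta = density * cfg.gravity * H_eq / (surface_tension * curv)
    if cos_theta > 1.0 + 1e-12:
        raise InfeasibleObservationError(
            f"observed H_eq={H_eq} m implies cos(theta)={cos_theta:.4f} > 1; "
            "the stated surface tension cannot produce this rise"
        )
    if cos_theta < 0.0:
        raise InfeasibleObservationError(
            f"implied cos(theta)={cos_theta:.4f} <= 0 is outside the wetting model"
        )
    return math.degrees(math.acos(min(cos_theta, 1.0)))
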