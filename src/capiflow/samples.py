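"""Reference fluid properties used by the synthetic-data generators.

Blood-component presets use the combined surface-drive term sigma_eff =
cos(theta)*gamma (the two factors are not separately identifiable for
opaque samples) together with fixed literature densities; glycerol–water
calibration mixtures carry explicit surface tension and a common contact
angle of 61 degrees (polyvinyl-alcohol-coated fluoropolymer wall), so the
full equilibrium inversion can be exercised on them.

Viscosities are 20-25 C handbook values; densities in kg m^-3,
viscosities in Pa s, tensions in N m^-1.
"""

from __future__ import annotations

from .core_model import FluidProperties
from .errors import ConfigurationError

__all__ = ["FLUID_PRESETS", "glycerol_mixture", "GLYCEROL_FRACTIONS", "preset"]

#: Contact angle of water on the hydrophilic coating, degrees.
COATING_CONTACT_ANGLE_DEG = 61.0

#: sigma_eff (N/m), mu (Pa s), rho (kg/m^3) for the bench sample classes.
FLUID_PRESETS: dict[str, FluidProperties] = {
    "water": FluidProperties(density=998.0, viscosity=1.04e-3, surface_drive=0.025),
    "HBS": FluidProperties(density=1005.0, viscosity=1.04e-3, surface_drive=0.025),
    "PPP": FluidProperties(density=1025.0, viscosity=1.70e-3, surface_drive=0.023),
    "PRP": FluidProperties(density=1025.0, viscosity=1.70e-3, surface_drive=0.024),
    "RBC": FluidProperties(density=1045.0, viscosity=2.86e-3, surface_drive=0.034),
    "WB": FluidProperties(density=1055.0, viscosity=4.58e-3, surface_drive=0.034),
}

#: Glycerol mass fractions (% w/w) of the calibration suite.
GLYCEROL_FRACTIONS = (0.0, 20.0, 40.0, 60.0)

# (rho kg/m^3, mu Pa s, gamma N/m) at ~20 C
_GLYCEROL_TABLE = {
    0.0: (998.0, 1.005e-3, 0.0728),
    20.0: (1047.0, 1.76e-3, 0.0717),
    40.0: (1099.0, 3.72e-3, 0.0706),
    60.0: (1154.0, 10.8e-3, 0.0690),
}


def glycerol_mixture(
    percent_w_w: float, contact_angle_deg: float = COATING_CONTACT_ANGLE_DEG
) -> FluidProperties:
    """Glycerol–water mixture at one of the tabulated mass fractions."""
    try:
        rho, mu, gamma = _GLYCEROL_TABLE[float(percent_w_w)]
    except KeyError:
        raise ConfigurationError(
            f"no glycerol table entry for {percent_w_w}% w/w; "
            f"available: {sorted(_GLYCEROL_TABLE)}"
        ) from None
    return FluidProperties(
        density=rho,
        viscosity=mu,
        surface_tension=gamma,
        contact_angle_deg=contact_angle_deg,
    )


def preset(name: str) -> FluidProperties:
    """Look up a sample-class preset by name (case-insensitive)."""
    for key, val in FLUID_PRESETS.items():
        if key.lower() == name.lower():
            return val
    raise ConfigurationError(
        f"unknown sample class {name!r}; known: {sorted(FLUID_PRESETS)}"
    )
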