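import numpy as np
import pytest

import capiflow as cf
from capiflow.studies import circle


@pytest.fixture
def water():
    """Water with the combined surface-drive term (transient-fit scale)."""
    return cf.samples.preset("water")


@pytest.fixture
def water_gamma():
    """Water with explicit surface tension and equilibrium contact angle."""
    return cf.FluidProperties(
        density=998.0, viscosity=1.04e-3, surface_tension=0.0728,
        contact_angle_deg=61.0,
    )


@pytest.fixture
def whole_blood():
    return cf.samples.preset("WB")


@pytest.fixture
def circle_156():
    """Circular bore at the smallest mean strip diameter."""
    return circle(156.3)


@pytest.fixture
def ellipse_200x160():
    return cf.ellipse_geometry(200e-6, 160e-6, capillary_length=0.12)


@pytest.fixture
def fast_cfg():
    """Coarse, noiseless simulation settings for quick unit tests."""
    return cf.SimulationConfig(time_step=5e-3, total_time=10.0,
                               height_noise=0.0, time_jitter=0.0)


def model_velocity_series(fluid, geom, heights, dip_depth=0.0):
    """Exact velocity series evaluated from the quasi-steady balance.

    With dip_depth = 0 the wetted length equals the height (the linear
    u-vs-1/H regime); used as noiseless model data for fitting tests.
    """
    heights = np.asarray(heights, dtype=float)
    u = np.array(
        [cf.quasi_steady_velocity(fluid, geom, H, H + dip_depth).velocity
         if H + dip_depth > 0 else 0.0
         for H in heights]
    )
    return cf.VelocitySeries(
        times=np.arange(heights.size, dtype=float),
        velocities=u,
        reciprocal_heights=1.0 / heights,
        heights=heights,
        clamped=np.zeros(heights.size, dtype=bool),
        signed_velocities=u,
    )
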