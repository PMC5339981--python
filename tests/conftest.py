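import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pcflow.phantom import BaseFlow, JetSpec, PlaneSpec, make_velocity_field

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_plane() -> PlaneSpec:
    """Compact plane that still samples the waveform peak exactly (t=160 ms)."""
    return PlaneSpec(grid_nx=32, grid_ny=32, pixel_size=1.95, n_frames=12,
                     frame_dt=40.0)


@pytest.fixture
def aligned_jet_field(small_plane):
    """Single untilted 300 cm/s jet, no base flow, no noise source."""
    return make_velocity_field(small_plane, [JetSpec(peak_speed=300.0)])


@pytest.fixture
def uniform_flow_field(small_plane):
    """Uniform 50 cm/s through-plane flow inside the lumen (for noise tests)."""
    f = make_velocity_field(small_plane, [], BaseFlow(peak_speed=0.0))
    f.vz[:, f.lumen_mask] = 50.0
    return f


def curve_times(n_frames: int = 4000, t_total_ms: float = 800.0) -> np.ndarray:
    return np.linspace(0.0, t_total_ms, n_frames)


@pytest.fixture
def dense_halfsine_curve():
    """Densely sampled half-sine peak-velocity curve (Vp=400 cm/s, Tsys=320 ms)."""
    from pcflow.quantify import PeakCurve

    t = curve_times()
    vp, tsys = 400.0, 320.0
    v = np.where(t <= tsys, vp * np.sin(np.pi * np.clip(t / tsys, 0, 1)), 0.0)
    return PeakCurve(t=t, v=np.clip(v, 0.0, None), plane_index=0)
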