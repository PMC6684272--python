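import numpy as np
import pytest

from perchgrip.surface_metrology import SurfaceProfile
from perchgrip.synthetic_data import SurfaceGenSpec, gen_surface_profile


@pytest.fixture
def rough_surface() -> SurfaceProfile:
    """Self-affine profile, 30 um RMS, 5 um spacing (fine enough for 50 um tips)."""
    return gen_surface_profile(
        SurfaceGenSpec(target_rms_um=30.0, spectral_exponent=2.0, length_mm=5.0, spacing_um=5.0, seed=42)
    )


@pytest.fixture
def sawtooth_surface():
    """Symmetric triangular profile with 20 degree faces, 200 um tooth pitch."""
    spacing_um = 0.2
    pitch_um = 200.0
    n = 10_000
    x_um = np.arange(n) * spacing_um
    phase = (x_um % pitch_um) / pitch_um
    tri = np.where(phase < 0.5, phase, 1.0 - phase)  # 0..0.5 triangle
    heights = tri * pitch_um * np.tan(np.radians(20.0))
    return SurfaceProfile(x_um / 1000.0, heights)
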