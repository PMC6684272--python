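"""1D surface-profile conditioning and roughness statistics.

A :class:`SurfaceProfile` is a uniformly sampled height profile along a
circumferential arc coordinate.  The processing pipeline mirrors standard
profile metrology: long-wavelength form is removed with a zero-phase
high-pass detrend, and roughness is summarized as the RMS of the residual
heights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "SurfaceProfile",
    "RoughnessResult",
    "highpass_detrend",
    "compute_rms",
    "read_profile_csv",
    "write_profile_csv",
]

_SPACING_RTOL = 1e-9


@dataclass(frozen=True)
class SurfaceProfile:
    """Uniformly sampled 1D surface height profile.

    Attributes
    ----------
    positions : ndarray
        Monotone arc-length coordinates in mm, uniformly spaced.
    heights : ndarray
        Local surface heights y_i in micrometres.
    """

    positions: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        hts = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "heights", hts)
        if pos.ndim != 1 or hts.ndim != 1 or pos.size != hts.size:
            raise ValueError("positions and heights must be 1D arrays of equal length")
        if pos.size < 2:
            raise ValueError("profile needs at least 2 samples")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(hts))):
            raise ValueError("profile contains non-finite values")
        steps = np.diff(pos)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly increasing")
        mean_step = steps.mean()
        if np.any(np.abs(steps - mean_step) > _SPACING_RTOL * max(abs(mean_step), 1.0) + 1e-12):
            bad = int(np.argmax(np.abs(steps - mean_step) > _SPACING_RTOL * abs(mean_step)))
            raise ValueError(f"non-uniform spacing at sample index {bad + 1}")

    @property
    def spacing_mm(self) -> float:
        """Sample spacing in mm."""
        return float(self.positions[1] - self.positions[0])

    @property
    def spacing_um(self) -> float:
        """Sample spacing in micrometres."""
        return self.spacing_mm * 1000.0

    @property
    def n_samples(self) -> int:
        return int(self.heights.size)

    def with_heights(self, heights: np.ndarray) -> "SurfaceProfile":
        return SurfaceProfile(self.positions.copy(), np.asarray(heights, dtype=float))


@dataclass(frozen=True)
class RoughnessResult:
    r_rms: float          # micrometres
    n_samples: int
    cutoff_wavelength: float | None = None  # mm, if a detrend preceded the measurement


def highpass_detrend(profile: SurfaceProfile, cutoff_wavelength: float) -> SurfaceProfile:
    """Remove the long-wavelength component below ``cutoff_wavelength`` (mm).

    The low-pass estimate is a zero-phase moving-average smoother of window
    width equal to the cutoff wavelength, with reflect padding; the smoothed
    profile is subtracted from the input.  Zero phase keeps asperity
    positions unshifted, which matters for downstream tip-path tracing.
    """
    if cutoff_wavelength <= 2.0 * profile.spacing_mm:
        raise ValueError(
            f"cutoff_wavelength ({cutoff_wavelength} mm) must exceed twice the "
            f"sample spacing ({profile.spacing_mm} mm)"
        )
    window = int(round(cutoff_wavelength / profile.spacing_mm))
    window = max(window, 3)
    lowpass = uniform_filter1d(profile.heights, size=window, mode="reflect")
    return profile.with_heights(profile.heights - lowpass)


def compute_rms(profile: SurfaceProfile, cutoff_wavelength: float | None = None) -> RoughnessResult:
    """Root-mean-square of the profile heights (no implicit mean removal).

    Detrending is an explicit, separate step; this operation is the plain
    quadratic mean sqrt(sum(y_i^2)/n).
    """
    heights = profile.heights
    if heights.size == 0:
        raise ValueError("cannot compute RMS of an empty profile")
    r_rms = float(np.sqrt(np.mean(heights**2)))
    return RoughnessResult(r_rms=r_rms, n_samples=heights.size, cutoff_wavelength=cutoff_wavelength)


def read_profile_csv(path) -> SurfaceProfile:
    """Read a 2-column CSV (position_mm, height_um) with a header row.

    Non-uniform spacing is rejected with an error naming the first
    offending row.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("profile CSV needs columns position_mm, height_um")
    cols = list(df.columns)
    if "position_mm" in cols and "height_um" in cols:
        pos = df["position_mm"].to_numpy(dtype=float)
        hts = df["height_um"].to_numpy(dtype=float)
    else:
        pos = df.iloc[:, 0].to_numpy(dtype=float)
        hts = df.iloc[:, 1].to_numpy(dtype=float)
    steps = np.diff(pos)
    if steps.size:
        ref = steps[0]
        bad = np.abs(steps - ref) > _SPACING_RTOL * max(abs(ref), 1.0) + 1e-12
        if np.any(bad):
            # step j spans data rows j+1 -> j+2 (1-based, excluding the header)
            row = int(np.argmax(bad)) + 2
            raise ValueError(f"non-uniform spacing first detected at CSV data row {row}")
    return SurfaceProfile(pos, hts)


def write_profile_csv(profile: SurfaceProfile, path) -> None:
    pd.DataFrame(
        {"position_mm": profile.positions, "height_um": profile.heights}
    ).to_csv(path, index=False)
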