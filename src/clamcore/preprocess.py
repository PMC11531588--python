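"""Depth profiling, analysis-window detection and volume standardization.

The usable part of each A-scan lies between the sediment-surface reflection
and its multiple (the spurious second copy of the surface echo). The window
is located on the summed-XY depth profile, the volume is cropped to it, and
the retained depth range is resampled to a common grid so every bucket
presents the classifier the same input shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .volume import AcousticVolume


class WindowingError(RuntimeError):
    """Raised when the two reflection peaks cannot be located.

    Carries the (smoothed) depth profile as ``profile`` for diagnostics.
    """

    def __init__(self, message: str, profile: np.ndarray | None = None):
        super().__init__(message)
        self.profile = profile


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open depth range ``[z_start, z_end)`` between the reflections."""

    z_start: int
    z_end: int
    profile: np.ndarray

    def __post_init__(self) -> None:
        if not 0 <= self.z_start < self.z_end:
            raise ValueError(f"invalid window [{self.z_start}, {self.z_end})")

    @property
    def length(self) -> int:
        return self.z_end - self.z_start


def depth_profile(vol: AcousticVolume | np.ndarray) -> np.ndarray:
    """Total reflection intensity in the XY plane for each z-coordinate."""
    grid = vol.intensity if isinstance(vol, AcousticVolume) else np.asarray(vol)
    return grid.sum(axis=(0, 1))


def detect_analysis_window(
    profile: np.ndarray,
    smooth: int = 5,
    band_margin: int = 15,
    prominence_frac: float = 0.1,
) -> AnalysisWindow:
    """Locate the inter-reflection analysis window on a depth profile.

    The profile is smoothed with a ``smooth``-sample moving average, its two
    most prominent local maxima are taken as the surface and multiple
    reflections (ordered by depth), and ``band_margin`` samples around each
    peak are excluded from the returned window.

    Raises
    ------
    WindowingError
        If fewer than two sufficiently prominent peaks exist.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 2 * band_margin + 4:
        raise WindowingError(
            f"profile too short ({profile.size} samples) for window detection",
            profile,
        )
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        smoothed = np.convolve(profile, kernel, mode="same")
    else:
        smoothed = profile
    span = smoothed.max() - smoothed.min()
    peaks, props = find_peaks(smoothed, prominence=prominence_frac * span)
    if len(peaks) < 2:
        raise WindowingError(
            f"found {len(peaks)} prominent peaks; need the surface and "
            "multiple reflections",
            smoothed,
        )
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    z1, z2 = int(top2.min()), int(top2.max())
    z_start, z_end = z1 + band_margin, z2 - band_margin
    if z_end - z_start < 2:
        raise WindowingError(
            f"window between peaks at z={z1}, z={z2} shorter than 2 samples "
            f"after a {band_margin}-sample band margin",
            smoothed,
        )
    return AnalysisWindow(z_start=z_start, z_end=z_end, profile=profile)


def map_z(z: np.ndarray | float, window: AnalysisWindow, target_nz: int) -> np.ndarray:
    """Map original depth indices into standardized-grid coordinates."""
    length = window.length
    scale = (target_nz - 1) / (length - 1) if length > 1 else 0.0
    return (np.asarray(z, dtype=float) - window.z_start) * scale


def standardize_volume(
    vol: AcousticVolume, window: AnalysisWindow, target_nz: int = 693
) -> AcousticVolume:
    """Crop to the analysis window and linearly resample depth to ``target_nz``.

    The x/y axes are untouched; the z coordinate map is monotone, so depth
    ordering of structures is preserved. When the window already spans
    ``target_nz`` samples this is a pure crop.
    """
    if window.length < 2:
        raise ValueError("analysis window must span at least 2 samples")
    if window.z_end > vol.nz:
        raise ValueError("window exceeds volume depth")
    crop = vol.intensity[:, :, window.z_start : window.z_end]
    length = crop.shape[2]
    if length == target_nz:
        out = crop.copy()
    else:
        pos = np.linspace(0.0, length - 1, target_nz)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, length - 1)
        w = (pos - lo).astype(crop.dtype)
        out = crop[:, :, lo] * (1 - w) + crop[:, :, hi] * w
    return AcousticVolume(
        intensity=out,
        bucket_id=vol.bucket_id,
        bucket_type=vol.bucket_type,
        scan_pitch_mm=vol.scan_pitch_mm,
        provenance=vol.provenance,
        attrs={**vol.attrs, "z_start": window.z_start, "z_end": window.z_end,
               "target_nz": target_nz},
    )


def normalize_volume(vol: AcousticVolume, mode: str = "max") -> AcousticVolume:
    """Normalize intensities for model input.

    ``none`` leaves values as-is; ``max`` divides by the volume maximum;
    ``zscore`` standardizes then clips negatives at zero so the envelope
    non-negativity contract holds.
    """
    grid = vol.intensity
    if mode == "none":
        out = grid
    elif mode == "max":
        m = grid.max()
        out = grid / m if m > 0 else grid
    elif mode == "zscore":
        sd = grid.std()
        out = np.clip((grid - grid.mean()) / sd, 0.0, None) if sd > 0 else grid
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return AcousticVolume(
        intensity=out,
        bucket_id=vol.bucket_id,
        bucket_type=vol.bucket_type,
        scan_pitch_mm=vol.scan_pitch_mm,
        provenance=vol.provenance,
        attrs=dict(vol.attrs),
    )


def preprocess_volume(
    vol: AcousticVolume,
    target_nz: int = 693,
    smooth: int = 5,
    band_margin: int = 15,
    normalize: str = "max",
) -> tuple[AcousticVolume, AnalysisWindow]:
    """Full preprocessing: profile -> window -> standardize -> normalize."""
    window = detect_analysis_window(
        depth_profile(vol), smooth=smooth, band_margin=band_margin
    )
    std = standardize_volume(vol, window, target_nz=target_nz)
    return normalize_volume(std, mode=normalize), window
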