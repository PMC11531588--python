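"""In-memory container for one bucket's acoustic-coring volume.

An acoustic-coring scan rasters an ultrasonic focus probe over the sediment
surface and records the envelope-processed echo at each (x, y) scan position,
yielding a non-negative reflection-intensity grid indexed ``(x, y, z)`` where
``z`` is the depth-sample axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BUCKET_TYPES = ("C", "A", "M", "AM")


@dataclass
class AcousticVolume:
    """One bucket's 3D reflection-intensity grid plus scan metadata.

    Parameters
    ----------
    intensity
        Non-negative float array of shape ``(nx, ny, nz)`` indexed
        ``(x, y, z)``, 0-based. ``z`` increases with depth (later echo
        arrival).
    bucket_id
        Identifier of the sediment container, e.g. ``"A1"``.
    bucket_type
        One of ``C`` (sand only), ``A`` (clams), ``M`` (mussels),
        ``AM`` (clams + mussels + other material).
    scan_pitch_mm
        Horizontal raster pitch of the scan in millimetres.
    provenance
        ``"measured"`` or ``"simulated"``.
    """

    intensity: np.ndarray
    bucket_id: str
    bucket_type: str
    scan_pitch_mm: float = 2.0
    provenance: str = "simulated"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 3:
            raise ValueError(
                f"intensity must be 3D (x, y, z); got shape {self.intensity.shape}"
            )
        if self.bucket_type not in BUCKET_TYPES:
            raise ValueError(
                f"bucket_type must be one of {BUCKET_TYPES}; got {self.bucket_type!r}"
            )
        if np.any(self.intensity < 0):
            raise ValueError("envelope intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def nx(self) -> int:
        return self.intensity.shape[0]

    @property
    def ny(self) -> int:
        return self.intensity.shape[1]

    @property
    def nz(self) -> int:
        return self.intensity.shape[2]
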