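"""Physics-inspired simulator for acoustic-coring volumes of buried fauna.

The generator emulates the structures that the downstream analysis relies
on, for buckets of sediment scanned from above with a focused ultrasonic
probe:

* a bright sediment-surface reflection band at depth index ``surface_z``;
* a weaker second copy of that band (the multiple reflection) at
  ``multiple_z``, bounding the usable analysis window from below;
* one localized, anisotropic-Gaussian backscatter blob per buried clam,
  placed strictly between the two bands;
* optional confounder blobs (mussels / stones) with smaller amplitude and
  size, so mixed buckets are harder than clam-only buckets;
* exponential depth attenuation of everything below the sediment surface;
* additive Gaussian noise, clipped at zero to mimic envelope output.

Four bucket types are supported: ``C`` (sand only), ``A`` (clams), ``M``
(mussels), ``AM`` (clams + mussels + other material), with 40 clams per
A/AM bucket by default.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .volume import BUCKET_TYPES, AcousticVolume


class PlacementError(ValueError):
    """Raised when targets cannot be placed without exceeding the density cap."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated bucket.

    Geometry defaults mirror the acoustic-coring scan: a 125 x 100 raster at
    2 mm pitch with 693 depth samples per A-scan.
    """

    grid_nx: int = 125
    grid_ny: int = 100
    grid_nz: int = 693
    scan_pitch_mm: float = 2.0
    z_pitch_mm: float = 0.15  # sediment depth per z sample, for attenuation
    bucket_type: str = "A"
    n_clams: int | None = None  # None -> 40 for A/AM, 0 otherwise
    n_confounders: int | None = None  # None -> 15 for M/AM, 0 otherwise
    surface_z: int = 80
    multiple_z: int = 580
    surface_amplitude: float = 1.0
    multiple_amplitude: float = 0.35
    band_sigma_z: float = 4.0
    clam_amplitude: float = 0.6
    clam_sigma_xy: float = 1.5  # ~3 px blob radius at 2 mm pitch (4 mm beam)
    clam_sigma_z: float = 8.0
    confounder_amplitude: float = 0.3
    confounder_sigma_xy: float = 1.0
    confounder_sigma_z: float = 5.0
    # clam depths as fractions of the surface->multiple gap; clams burrow in
    # the upper sediment, and deeper placements vanish under attenuation
    depth_band: tuple[float, float] = (0.15, 0.6)
    min_separation_px: float = 8.0
    # probability that a placed clam is retained and detectable on the scan
    # day; applied per bucket by simulate_study so measured counts vary
    clam_retention: float = 0.9
    attenuation_db_per_m: float = 100.0
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bucket_type not in BUCKET_TYPES:
            raise ValueError(f"bucket_type must be one of {BUCKET_TYPES}")
        if self.n_clams is None:
            self.n_clams = 40 if self.bucket_type in ("A", "AM") else 0
        if self.n_confounders is None:
            self.n_confounders = 15 if self.bucket_type in ("M", "AM") else 0
        if not (0 <= self.surface_z < self.multiple_z < self.grid_nz):
            raise ValueError(
                "require 0 <= surface_z < multiple_z < grid_nz; got "
                f"surface_z={self.surface_z}, multiple_z={self.multiple_z}, "
                f"grid_nz={self.grid_nz}"
            )
        for name in ("clam_amplitude", "confounder_amplitude", "surface_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_clams < 0 or self.n_confounders < 0:
            raise ValueError("target counts must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class GroundTruth:
    """Inserted target positions for one simulated bucket.

    Each record is ``(bucket_id, x, y, z, kind)`` with ``kind`` in
    ``{"clam", "confounder"}``. Depth ``z`` is stored even though the
    window-labeling rule uses only (x, y); attention-map checks use it.
    """

    positions: list[tuple[str, int, int, int, str]]
    bucket_type: str

    def clam_xy(self) -> np.ndarray:
        """(n_clams, 2) array of clam scan positions."""
        pts = [(x, y) for _, x, y, _, kind in self.positions if kind == "clam"]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    @property
    def n_clams(self) -> int:
        return sum(1 for rec in self.positions if rec[4] == "clam")


def _place_targets(
    rng: np.random.Generator,
    n: int,
    nx: int,
    ny: int,
    min_sep: float,
    existing: list[tuple[float, float]],
    margin: int = 3,
    max_attempts_per_target: int = 400,
) -> list[tuple[int, int]]:
    """Rejection-sample integer (x, y) centers with a minimum pairwise distance."""
    placed: list[tuple[int, int]] = []
    all_pts = list(existing)
    for _ in range(n):
        for attempt in range(max_attempts_per_target):
            x = int(rng.integers(margin, nx - margin))
            y = int(rng.integers(margin, ny - margin))
            if all(
                (x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in all_pts
            ):
                placed.append((x, y))
                all_pts.append((x, y))
                break
        else:
            raise PlacementError(
                f"could not place {n} targets with min separation {min_sep} px "
                f"on a {nx} x {ny} grid ({len(placed)} placed); lower the count "
                "or the separation"
            )
    return placed


def _add_blob(
    vol: np.ndarray,
    cx: int,
    cy: int,
    cz: int,
    amp: float,
    sx: float,
    sy: float,
    sz: float,
) -> None:
    """Add an anisotropic Gaussian blob in place, truncated at 4 sigma."""
    nx, ny, nz = vol.shape
    x0, x1 = max(0, int(cx - 4 * sx)), min(nx, int(np.ceil(cx + 4 * sx)) + 1)
    y0, y1 = max(0, int(cy - 4 * sy)), min(ny, int(np.ceil(cy + 4 * sy)) + 1)
    z0, z1 = max(0, int(cz - 4 * sz)), min(nz, int(np.ceil(cz + 4 * sz)) + 1)
    xs = np.arange(x0, x1, dtype=float)[:, None, None]
    ys = np.arange(y0, y1, dtype=float)[None, :, None]
    zs = np.arange(z0, z1, dtype=float)[None, None, :]
    blob = amp * np.exp(
        -0.5
        * (
            ((xs - cx) / sx) ** 2
            + ((ys - cy) / sy) ** 2
            + ((zs - cz) / sz) ** 2
        )
    )
    vol[x0:x1, y0:y1, z0:z1] += blob


def _attenuation_factor(cfg: SimulationConfig, z: np.ndarray | float) -> np.ndarray:
    """Two-way amplitude attenuation below the sediment surface.

    100 dB/m absorption over the two-way path from the surface down to depth
    sample ``z`` and back.
    """
    depth_m = np.maximum(np.asarray(z, dtype=float) - cfg.surface_z, 0.0) * (
        cfg.z_pitch_mm / 1000.0
    )
    db = 2.0 * cfg.attenuation_db_per_m * depth_m
    return 10.0 ** (-db / 20.0)


def simulate_bucket(
    config: SimulationConfig, bucket_id: str | None = None
) -> tuple[AcousticVolume, GroundTruth]:
    """Simulate one bucket's envelope volume and its ground-truth positions.

    Returns
    -------
    volume
        ``AcousticVolume`` of shape ``(grid_nx, grid_ny, grid_nz)`` with
        non-negative intensities.
    ground_truth
        ``GroundTruth`` listing every inserted clam and confounder.

    The same config (including ``seed``) yields bit-identical output.
    """
    cfg = config
    if bucket_id is None:
        bucket_id = f"{cfg.bucket_type}{cfg.seed}"
    rng = np.random.default_rng(cfg.seed)
    vol = np.zeros((cfg.grid_nx, cfg.grid_ny, cfg.grid_nz), dtype=np.float64)

    # Reflection bands: Gaussian along z, uniform across the scan plane.
    zs = np.arange(cfg.grid_nz, dtype=float)
    band = cfg.surface_amplitude * np.exp(
        -0.5 * ((zs - cfg.surface_z) / cfg.band_sigma_z) ** 2
    )
    # the multiple's extra path is through the water column, so it is not
    # subject to sediment attenuation
    band += cfg.multiple_amplitude * np.exp(
        -0.5 * ((zs - cfg.multiple_z) / cfg.band_sigma_z) ** 2
    )
    vol += band[None, None, :]

    # Target depth band strictly between the reflections.
    gap = cfg.multiple_z - cfg.surface_z
    lo_frac, hi_frac = cfg.depth_band
    if not (0.0 < lo_frac < hi_frac < 1.0):
        raise ValueError("depth_band fractions must satisfy 0 < lo < hi < 1")
    z_lo = cfg.surface_z + int(np.ceil(lo_frac * gap))
    z_hi = cfg.surface_z + int(np.floor(hi_frac * gap))
    if z_hi <= z_lo:
        raise ValueError("depth band between reflections is empty; widen it")

    clam_xy = _place_targets(
        rng, cfg.n_clams, cfg.grid_nx, cfg.grid_ny, cfg.min_separation_px, []
    )
    conf_xy = _place_targets(
        rng,
        cfg.n_confounders,
        cfg.grid_nx,
        cfg.grid_ny,
        cfg.min_separation_px,
        existing=[(float(x), float(y)) for x, y in clam_xy],
    )

    positions: list[tuple[str, int, int, int, str]] = []
    for (x, y), kind in [((p), "clam") for p in clam_xy] + [
        ((p), "confounder") for p in conf_xy
    ]:
        cz = int(rng.integers(z_lo, z_hi))
        amp, sx, sz = (
            (cfg.clam_amplitude, cfg.clam_sigma_xy, cfg.clam_sigma_z)
            if kind == "clam"
            else (cfg.confounder_amplitude, cfg.confounder_sigma_xy, cfg.confounder_sigma_z)
        )
        _add_blob(
            vol, x, y, cz, amp * float(_attenuation_factor(cfg, cz)), sx, sx, sz
        )
        positions.append((bucket_id, int(x), int(y), int(cz), kind))

    if cfg.noise_sigma > 0:
        vol += rng.normal(0.0, cfg.noise_sigma, size=vol.shape)
    np.clip(vol, 0.0, None, out=vol)

    volume = AcousticVolume(
        intensity=vol.astype(np.float32),
        bucket_id=bucket_id,
        bucket_type=cfg.bucket_type,
        scan_pitch_mm=cfg.scan_pitch_mm,
        provenance="simulated",
        attrs={"surface_z": cfg.surface_z, "multiple_z": cfg.multiple_z,
               "seed": cfg.seed},
    )
    return volume, GroundTruth(positions=positions, bucket_type=cfg.bucket_type)


def simulate_study(
    n_per_type: int = 5,
    seed: int = 0,
    base_config: SimulationConfig | None = None,
    n_clams_per_bucket: int | None = None,
    n_confounders_per_bucket: int | None = None,
) -> list[tuple[AcousticVolume, GroundTruth]]:
    """Simulate a full study: ``n_per_type`` buckets of each of C, A, M, AM.

    Bucket ids follow the study convention ``A1..An, C1..Cn, ...``. Each
    bucket gets an independent seed derived from ``seed``. Clam/confounder
    counts default to the bucket-type conventions (40 clams in A/AM before
    retention, 15 confounders in M/AM); the overrides exist for reduced
    geometries.
    """
    base = base_config if base_config is not None else SimulationConfig()
    out: list[tuple[AcousticVolume, GroundTruth]] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(4 * n_per_type) % (2**31)
    k = 0
    for btype in BUCKET_TYPES:
        for i in range(n_per_type):
            bucket_seed = int(child_seeds[k])
            clams = n_clams_per_bucket if btype in ("A", "AM") else 0
            confs = n_confounders_per_bucket if btype in ("M", "AM") else 0
            cfg = replace(
                base,
                bucket_type=btype,
                n_clams=clams,
                n_confounders=confs,
                seed=bucket_seed,
            )
            if cfg.n_clams > 0 and cfg.clam_retention < 1.0:
                n_rng = np.random.default_rng(bucket_seed + 1)
                cfg = replace(
                    cfg,
                    n_clams=int(n_rng.binomial(cfg.n_clams, cfg.clam_retention)),
                )
            out.append(simulate_bucket(cfg, bucket_id=f"{btype}{i + 1}"))
            k += 1
    return out


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Write ground-truth positions as CSV (bucket_id, x, y, z, kind)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bucket_id", "x", "y", "z", "kind"])
        for rec in gt.positions:
            writer.writerow(rec)
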