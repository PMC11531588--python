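"""Sliding-window voxel extraction and label assignment.

Each standardized bucket volume is cut into overlapping 25 x 25 (scan
pixels) x full-depth local voxels, shifted one pixel at a time. A clam is
attributed to a window if its annotated (x, y) position falls inside the
window footprint or lies within a threshold distance (default strictly less
than 11 px) of the footprint rectangle — backscatter near a window border
still contributes signal to that window. Presence labels and count labels
(0 / 1 / "2 or more") derive from the attributed-clam multiset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT_CLASSES = ("0", "1", "ge2")
PRESENCE_CLASSES = ("absence", "presence")


@dataclass
class LocalVoxel:
    """One classifier input sample: a w x w x nz sub-volume plus labels."""

    data: np.ndarray
    bucket_id: str
    origin: tuple[int, int]
    presence_label: str | None = None
    count_label: str | None = None
    clam_ids: list[int] = field(default_factory=list)


def enumerate_windows(
    nx: int, ny: int, w: int = 25, stride: int = 1
) -> np.ndarray:
    """All window origins ``(x0, y0)`` on an ``nx x ny`` grid, row-major.

    Origins satisfy ``0 <= x0 <= nx - w`` and ``0 <= y0 <= ny - w`` on the
    given stride; x varies slowest. The default unit stride on a 125 x 100
    grid yields 101 x 76 = 7,676 origins; stride ``w`` gives the
    non-overlapping 5 x 4 = 20-voxel bucket tiling.
    """
    if w > nx or w > ny:
        raise ValueError(f"window size {w} exceeds grid ({nx}, {ny})")
    xs = np.arange(0, nx - w + 1, stride)
    ys = np.arange(0, ny - w + 1, stride)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.stack([gx.ravel(), gy.ravel()], axis=1)


def point_rect_distance(
    points: np.ndarray, origins: np.ndarray, w: int, metric: str = "euclidean"
) -> np.ndarray:
    """Distance from each point to each window footprint rectangle.

    ``points`` is (k, 2), ``origins`` is (m, 2); returns an (m, k) matrix.
    The footprint of a window at (x0, y0) is the pixel block
    ``[x0, x0+w-1] x [y0, y0+w-1]``; points inside have distance 0.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    origins = np.asarray(origins, dtype=float).reshape(-1, 2)
    px, py = points[:, 0][None, :], points[:, 1][None, :]
    x0, y0 = origins[:, 0][:, None], origins[:, 1][:, None]
    dx = np.maximum(np.maximum(x0 - px, px - (x0 + w - 1)), 0.0)
    dy = np.maximum(np.maximum(y0 - py, py - (y0 + w - 1)), 0.0)
    if metric == "euclidean":
        return np.hypot(dx, dy)
    if metric == "chebyshev":
        return np.maximum(dx, dy)
    raise ValueError(f"unknown metric {metric!r}")


def assign_labels(
    origins: np.ndarray,
    positions: pd.DataFrame | np.ndarray,
    w: int = 25,
    threshold_px: float = 11.0,
    grid_shape: tuple[int, int] | None = None,
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Attribute clams to windows and derive presence / count labels.

    Parameters
    ----------
    origins
        (m, 2) window origins from :func:`enumerate_windows`.
    positions
        Clam positions as an (k, 2) array of (x, y) or a DataFrame with
        ``x``/``y`` columns (rows of other kinds are ignored if a ``kind``
        column exists).
    threshold_px
        A clam is attributed to a window iff it lies inside the footprint
        or strictly closer than this distance to it.
    grid_shape
        Optional (nx, ny) used to validate that positions lie on the grid.

    Returns
    -------
    DataFrame with one row per origin: ``x0, y0, n_clams, presence, count``
    plus a ``clam_ids`` column of index lists into ``positions``.
    """
    if isinstance(positions, pd.DataFrame):
        df = positions
        if "kind" in df.columns:
            df = df[df["kind"] == "clam"]
        pts = df[["x", "y"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(positions, dtype=float).reshape(-1, 2)
    if grid_shape is not None and len(pts):
        nx, ny = grid_shape
        bad = (pts[:, 0] < 0) | (pts[:, 0] >= nx) | (pts[:, 1] < 0) | (pts[:, 1] >= ny)
        if bad.any():
            raise ValueError(
                f"positions outside the {nx} x {ny} grid: "
                f"{pts[bad].astype(int).tolist()}"
            )
    origins = np.asarray(origins, dtype=int).reshape(-1, 2)
    if len(pts):
        dist = point_rect_distance(pts, origins, w, metric=metric)
        attributed = (dist == 0.0) | (dist < threshold_px)
        n_clams = attributed.sum(axis=1).astype(int)
        clam_ids = [list(np.nonzero(row)[0]) for row in attributed]
    else:
        n_clams = np.zeros(len(origins), dtype=int)
        clam_ids = [[] for _ in range(len(origins))]
    return pd.DataFrame(
        {
            "x0": origins[:, 0],
            "y0": origins[:, 1],
            "n_clams": n_clams,
            "presence": np.where(n_clams >= 1, "presence", "absence"),
            "count": [collapse_count(int(n)) for n in n_clams],
            "clam_ids": clam_ids,
        }
    )


def collapse_count(n: int) -> str:
    """Collapse a raw clam count to the 3-class label {0, 1, ge2}.

    Windows holding three or more clams are rare, so they are pooled with
    the two-clam class.
    """
    if n < 0:
        raise ValueError("count must be non-negative")
    return "0" if n == 0 else ("1" if n == 1 else "ge2")


def build_manifest(
    volumes: dict[str, "object"],
    positions: pd.DataFrame,
    bucket_types: dict[str, str],
    w: int = 25,
    stride: int = 1,
    threshold_px: float = 11.0,
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Label every window of every bucket; returns one long manifest table.

    ``volumes`` maps bucket_id to anything with a ``shape`` of (nx, ny, nz)
    (an array, an ``AcousticVolume``, or an HDF5 dataset).
    """
    frames = []
    for bucket_id, vol in volumes.items():
        shape = getattr(vol, "shape")
        nx, ny = shape[0], shape[1]
        origins = enumerate_windows(nx, ny, w=w, stride=stride)
        bucket_pos = positions[positions["bucket_id"] == bucket_id]
        labels = assign_labels(
            origins,
            bucket_pos,
            w=w,
            threshold_px=threshold_px,
            grid_shape=(nx, ny),
            metric=metric,
        )
        labels.insert(0, "bucket_id", bucket_id)
        labels.insert(1, "bucket_type", bucket_types[bucket_id])
        frames.append(labels)
    return pd.concat(frames, ignore_index=True)


def build_balanced_dataset(
    manifest: pd.DataFrame,
    task: str,
    per_label_target: int,
    seed: int,
) -> pd.DataFrame:
    """Sample a label-balanced dataset from the window manifest.

    Draws ``per_label_target`` windows uniformly without replacement within
    each label stratum (``presence`` task: absence/presence; ``count`` task:
    0/1/ge2). A stratum with fewer windows than the target is included in
    full with a logged warning; an empty stratum is an error.
    """
    if task == "presence":
        label_col, classes = "presence", PRESENCE_CLASSES
    elif task == "count":
        label_col, classes = "count", COUNT_CLASSES
    else:
        raise ValueError(f"unknown task {task!r}")
    rng = np.random.default_rng(seed)
    picks = []
    for cls in classes:
        stratum = manifest.index[manifest[label_col] == cls].to_numpy()
        if len(stratum) == 0:
            raise ValueError(f"no windows with {label_col}={cls!r} available")
        if len(stratum) < per_label_target:
            logger.warning(
                "stratum %s=%s has only %d windows (target %d); using all",
                label_col, cls, len(stratum), per_label_target,
            )
            chosen = stratum
        else:
            chosen = rng.choice(stratum, size=per_label_target, replace=False)
        picks.append(np.sort(chosen))
    out = manifest.loc[np.concatenate(picks)].copy()
    out["label"] = out[label_col]
    out["sampling_seed"] = seed
    return out.reset_index(drop=True)


def extract_voxel(
    grid, x0: int, y0: int, w: int = 25, z_downsample: int = 1
) -> np.ndarray:
    """Slice one w x w x nz window out of a volume grid (array or HDF5).

    ``z_downsample > 1`` mean-pools blocks along z (truncating a remainder),
    reducing depth resolution for CPU-budget training.
    """
    data = np.asarray(grid[x0 : x0 + w, y0 : y0 + w, :], dtype=np.float32)
    if z_downsample > 1:
        nz = data.shape[2] - data.shape[2] % z_downsample
        data = data[:, :, :nz].reshape(w, w, nz // z_downsample, z_downsample)
        data = data.mean(axis=3)
    return data
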