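"""Bucket-level abundance estimation from per-voxel count predictions.

Each bucket's scan footprint is tiled into 20 non-overlapping 25 x 25
voxels (the 5 x 4 stride-25 tiling of the 125 x 100 grid); the trained
count classifier labels each tile 0 / 1 / "2 or more", and the bucket's
clam count is estimated by summing the per-tile classes. The "2 or more"
class contributes its lower bound (2) by default, which biases estimates
low where clams are dense — overlapping backscatter makes higher counts
unresolvable anyway. Accuracy is summarized by MAE, MRE (clam-holding
bucket types only) and the Pearson correlation of estimated vs measured
counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

from .voxelize import COUNT_CLASSES

CLASS_VALUES = {"0": 0.0, "1": 1.0, "ge2": 2.0}


@dataclass
class BucketEstimate:
    """Integrated count estimate for one bucket."""

    bucket_id: str
    bucket_type: str
    predicted_count: float
    true_count: int
    voxel_predictions: list = field(default_factory=list)


def integrate_counts(
    voxel_predictions: list[str] | np.ndarray, ge2_value: float = 2.0
) -> float:
    """Sum per-voxel class labels into a bucket count.

    ``voxel_predictions`` holds class tokens from ``{"0", "1", "ge2"}``
    (or integer class indices). ``ge2_value`` sets what a "2 or more"
    voxel contributes.
    """
    preds = list(voxel_predictions)
    if not preds:
        raise ValueError("no voxel predictions to integrate")
    total = 0.0
    for p in preds:
        token = COUNT_CLASSES[p] if isinstance(p, (int, np.integer)) else str(p)
        if token not in CLASS_VALUES:
            raise ValueError(f"unknown count class {p!r}")
        total += ge2_value if token == "ge2" else CLASS_VALUES[token]
    return total


def expected_count(probs: np.ndarray, ge2_value: float = 2.0) -> float:
    """Probability-weighted alternative to argmax integration."""
    probs = np.asarray(probs, dtype=float)
    values = np.array([0.0, 1.0, ge2_value])
    return float((probs @ values).sum())


def mae(estimates, truths) -> float:
    """Mean absolute error of estimated vs measured counts."""
    e = np.asarray(estimates, dtype=float)
    t = np.asarray(truths, dtype=float)
    if e.shape != t.shape:
        raise ValueError("estimates and truths must have equal length")
    return float(np.abs(e - t).mean())


def mre(estimates, truths) -> float:
    """Mean relative error; entries with zero true count are omitted.

    Relative error is undefined for empty buckets, so bucket types without
    clams contribute nothing (a warning notes any omission).
    """
    e = np.asarray(estimates, dtype=float)
    t = np.asarray(truths, dtype=float)
    if e.shape != t.shape:
        raise ValueError("estimates and truths must have equal length")
    keep = t > 0
    if not keep.all():
        warnings.warn(
            f"omitting {int((~keep).sum())} bucket(s) with zero true count "
            "from MRE"
        )
    if not keep.any():
        raise ValueError("MRE undefined: all true counts are zero")
    return float((np.abs(e[keep] - t[keep]) / t[keep]).mean())


def count_correlation(
    estimates, truths, bucket_types=None, subset: tuple[str, ...] | None = None
) -> float:
    """Pearson correlation of estimated vs measured bucket counts.

    ``subset`` restricts to the given bucket types (e.g. ``("A", "AM")``).
    """
    e = np.asarray(estimates, dtype=float)
    t = np.asarray(truths, dtype=float)
    if subset is not None:
        if bucket_types is None:
            raise ValueError("subset filtering requires bucket_types")
        keep = np.isin(np.asarray(bucket_types), subset)
        e, t = e[keep], t[keep]
    if len(e) < 2:
        raise ValueError("correlation needs at least 2 points")
    if np.std(e) == 0 or np.std(t) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: zero variance in estimates or truths"
        )
    return float(pearsonr(e, t).statistic)


class UndefinedCorrelationError(ValueError):
    pass


def summarize_by_type(estimates: list[BucketEstimate]) -> dict:
    """Per-type MAE (all types) and MRE (clam-holding types only)."""
    out: dict[str, dict[str, float]] = {}
    for btype in sorted({e.bucket_type for e in estimates}):
        group = [e for e in estimates if e.bucket_type == btype]
        preds = [e.predicted_count for e in group]
        trues = [e.true_count for e in group]
        entry = {"mae": mae(preds, trues), "n_buckets": len(group)}
        if all(t > 0 for t in trues):
            entry["mre"] = mre(preds, trues)
        out[btype] = entry
    return out


def render_distribution_map(
    origins: np.ndarray,
    predictions: list[str],
    grid_shape: tuple[int, int] = (125, 100),
    w: int = 25,
    out_png=None,
    out_csv=None,
):
    """Class-colored tile map of one bucket's predictions.

    ``origins`` is the stride-``w`` tiling (20 tiles for the default grid);
    returns the (tiles_x, tiles_y) class-index grid and optionally writes a
    PNG overlay and a CSV of the grid.
    """
    origins = np.asarray(origins, dtype=int)
    nx, ny = grid_shape
    tiles_x, tiles_y = nx // w, ny // w
    if len(origins) != tiles_x * tiles_y or len(predictions) != len(origins):
        raise ValueError(
            f"need one prediction for each of the {tiles_x * tiles_y} tiles; "
            f"got {len(predictions)} predictions on {len(origins)} origins"
        )
    class_index = {c: i for i, c in enumerate(COUNT_CLASSES)}
    grid = np.zeros((tiles_x, tiles_y), dtype=int)
    for (x0, y0), pred in zip(origins, predictions):
        token = (
            COUNT_CLASSES[pred] if isinstance(pred, (int, np.integer)) else str(pred)
        )
        grid[x0 // w, y0 // w] = class_index[token]
    if out_csv is not None:
        np.savetxt(out_csv, grid, fmt="%d", delimiter=",")
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3.2))
        im = ax.imshow(grid.T, origin="upper", cmap="viridis", vmin=0, vmax=2)
        ax.set_xlabel("x tile")
        ax.set_ylabel("y tile")
        cbar = fig.colorbar(im, ax=ax, ticks=[0, 1, 2])
        cbar.ax.set_yticklabels(["0", "1", "2+"])
        fig.tight_layout()
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return grid
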