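"""Grad-CAM attention volumes for the 3D-CNN classifiers.

Gradient-weighted class activation mapping: the gradient of the target
class score with respect to a convolutional feature map is averaged over
the map's spatial extent to yield one weight per channel; the weighted sum
of feature maps, rectified at zero, localizes the evidence for the
prediction. The rectified map is trilinearly upsampled to the input voxel
shape and normalized to a maximum of 1. For display, volumes are averaged
in blocks along z (10 samples by default), giving one 2D panel per depth
block — 70 panels for a 693-deep voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .nn.model import Conv3DClassifier


@dataclass
class AttentionVolume:
    """Non-negative, max-normalized heat grid aligned to the input voxel."""

    heat: np.ndarray
    target_class: int
    layer_name: str


def grad_cam(
    model: Conv3DClassifier,
    voxel: np.ndarray,
    target_class: int,
    layer: str | None = None,
) -> AttentionVolume:
    """Compute the Grad-CAM attention volume for one input voxel.

    Parameters
    ----------
    model
        A trained classifier exposing named layers.
    voxel
        One input of shape (25, 25, nz) (or with a leading channel axis).
    target_class
        Class whose score is explained.
    layer
        Convolutional layer whose feature map is weighted; defaults to the
        last conv block.

    If the class score has zero gradient everywhere the heat is all-zero
    (with a warning) rather than dividing by zero during normalization.
    """
    if layer is None:
        layer = model.conv_layer_names[-1]
    voxel = np.asarray(voxel, dtype=np.float32)
    activation, gradient = model.activation_and_gradient(
        voxel, target_class, layer
    )
    # (1, C, x, y, z) -> weights: global average of the gradient per channel
    weights = gradient.mean(axis=(2, 3, 4))  # (1, C)
    cam = np.einsum("ncxyz,nc->nxyz", activation, weights)[0]
    cam = np.maximum(cam, 0.0)
    target_shape = voxel.shape[-3:]
    factors = [t / s for t, s in zip(target_shape, cam.shape)]
    heat = zoom(cam, factors, order=1)
    # guard against rounding in the zoom output shape
    heat = heat[: target_shape[0], : target_shape[1], : target_shape[2]]
    m = heat.max()
    if m > 0:
        heat = heat / m
    else:
        warnings.warn(
            "Grad-CAM gradient is zero everywhere; returning an all-zero heat"
        )
        heat = np.zeros(target_shape, dtype=heat.dtype)
    return AttentionVolume(heat=heat, target_class=target_class, layer_name=layer)


def z_average_panels(volume: np.ndarray, block: int = 10) -> list[np.ndarray]:
    """Average a (x, y, z) grid in blocks along z; one 2D panel per block.

    Returns ``ceil(nz / block)`` panels; the last panel averages the
    remainder slices. A block larger than the depth yields a single
    whole-volume mean panel.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    volume = np.asarray(volume)
    nz = volume.shape[2]
    panels = []
    for start in range(0, nz, block):
        panels.append(volume[:, :, start : min(start + block, nz)].mean(axis=2))
    return panels


def explanation_prefix(
    out_dir, bucket_id: str, origin: tuple[int, int], predicted: str, truth: str
) -> str:
    """Output-file prefix encoding bucket, origin and labels."""
    from pathlib import Path

    name = f"{bucket_id}_x{origin[0]}_y{origin[1]}_pred-{predicted}_gt-{truth}"
    return str(Path(out_dir) / name)


def render_explanation(
    voxel: np.ndarray,
    heat: np.ndarray,
    out_prefix,
    block: int = 10,
    bucket_id: str = "",
    origin: tuple[int, int] = (0, 0),
    predicted: str = "",
    truth: str = "",
) -> dict:
    """Paired grayscale/heatmap panel figure plus a CSV of the heat values.

    Writes ``<prefix>.png`` (input left, attention right, one row per depth
    block) and ``<prefix>_heat.csv`` (flattened heat, deterministic), with
    the prediction and ground truth recorded in the figure title and the
    returned metadata.
    """
    voxel = np.asarray(voxel)
    heat = np.asarray(heat)
    if voxel.shape != heat.shape:
        raise ValueError(
            f"voxel shape {voxel.shape} != heat shape {heat.shape}"
        )
    vox_panels = z_average_panels(voxel, block=block)
    heat_panels = z_average_panels(heat, block=block)
    n = len(vox_panels)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ncols = 10
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(
        nrows, 2 * ncols, figsize=(2 * ncols * 1.1, nrows * 1.2), squeeze=False
    )
    vmax = max(float(voxel.max()), 1e-12)
    for k in range(nrows * ncols):
        r, c = divmod(k, ncols)
        ax_v, ax_h = axes[r][2 * c], axes[r][2 * c + 1]
        for ax in (ax_v, ax_h):
            ax.set_xticks([])
            ax.set_yticks([])
        if k < n:
            ax_v.imshow(vox_panels[k].T, cmap="gray", vmin=0, vmax=vmax)
            ax_h.imshow(heat_panels[k].T, cmap="jet", vmin=0, vmax=1)
        else:
            ax_v.axis("off")
            ax_h.axis("off")
    title = f"{bucket_id} ({origin[0]},{origin[1]}) pred={predicted} gt={truth}"
    fig.suptitle(title, fontsize=9)
    png_path = f"{out_prefix}.png"
    csv_path = f"{out_prefix}_heat.csv"
    fig.savefig(png_path, dpi=100)
    plt.close(fig)
    np.savetxt(csv_path, heat.reshape(heat.shape[0], -1), delimiter=",", fmt="%.6e")
    return {
        "png": png_path,
        "heat_csv": csv_path,
        "bucket_id": bucket_id,
        "origin": list(origin),
        "predicted": predicted,
        "truth": truth,
        "n_panels": n,
    }
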