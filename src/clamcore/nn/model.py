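"""3D-CNN classifier assembly for the presence and count tasks.

The network follows the standard voxel-classification inventory —
convolutional, pooling, and fully connected layers: a few Conv3D+ReLU+
MaxPool blocks with aggressive pooling along the deep z axis, global
average pooling, optional hidden dense layers, and a softmax output with
2 classes (absence / presence) or 3 classes (0 / 1 / 2-or-more clams).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .layers import (
    Conv3D,
    Dense,
    GlobalAvgPool,
    Layer,
    MaxPool3D,
    ReLU,
    cross_entropy,
    softmax,
)

logger = logging.getLogger(__name__)

#: (channels, kernel, stride, pool) per conv block. The first block strides
#: aggressively along the deep z axis so the im2col matrices stay small.
_DEFAULT_BLOCKS = [
    (8, (3, 3, 5), (2, 2, 4), (2, 2, 2)),
    (16, (3, 3, 3), (1, 1, 1), (2, 2, 2)),
]


def _parse_block(block) -> tuple[int, tuple, tuple, tuple]:
    """Accept (channels, kernel, pool) or (channels, kernel, stride, pool)."""
    if len(block) == 3:
        ch, kernel, pool = block
        stride = (1, 1, 1)
    elif len(block) == 4:
        ch, kernel, stride, pool = block
    else:
        raise ValueError(f"conv block must have 3 or 4 entries; got {block!r}")
    return int(ch), tuple(kernel), tuple(stride), tuple(pool)


@dataclass
class ModelSpec:
    """Architecture hyper-parameters of one classifier.

    ``conv_blocks`` is a list of ``(channels, kernel, pool)`` triples; the
    z components are larger because the depth axis is far deeper than the
    25 x 25 scan footprint.
    """

    task: str  # "presence" | "count"
    input_shape: tuple[int, int, int] = (25, 25, 693)
    conv_blocks: list = field(default_factory=lambda: [b for b in _DEFAULT_BLOCKS])
    dense_widths: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.task not in ("presence", "count"):
            raise ValueError(f"unknown task {self.task!r}")

    @property
    def n_classes(self) -> int:
        return 2 if self.task == "presence" else 3


class Conv3DClassifier:
    """Sequential 3D-CNN with explicit backprop and named layers."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        shape = spec.input_shape
        layers: list[tuple[str, Layer]] = []
        in_ch = 1
        size = np.array(shape, dtype=int)
        for i, block in enumerate(spec.conv_blocks, start=1):
            ch, kernel, stride, pool = _parse_block(block)
            prev = size.copy()
            size = (size - np.array(kernel)) // np.array(stride) + 1
            if np.any(size < 1):
                raise ValueError(
                    f"conv{i} kernel {kernel} does not fit feature map of "
                    f"size {tuple(prev)}"
                )
            layers.append((f"conv{i}", Conv3D(in_ch, ch, kernel, rng, stride)))
            layers.append((f"relu{i}", ReLU()))
            size = size // np.array(pool)
            if np.any(size < 1):
                raise ValueError(
                    f"pool{i} schedule {pool} collapses the feature map; "
                    "reduce pooling or enlarge the input"
                )
            layers.append((f"pool{i}", MaxPool3D(pool)))
            in_ch = ch
        layers.append(("gap", GlobalAvgPool()))
        width = in_ch
        for j, hidden in enumerate(spec.dense_widths, start=1):
            layers.append((f"dense{j}", Dense(width, hidden, rng)))
            layers.append((f"dense{j}_relu", ReLU()))
            width = hidden
        layers.append(("head", Dense(width, spec.n_classes, rng)))
        self.layers = layers
        logger.info(
            "%s model: %d parameters", spec.task, self.n_parameters
        )

    # ------------------------------------------------------------------ core
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch shaped (N, 25, 25, nz) or (N, 1, 25, 25, nz)."""
        if x.ndim == 4:
            x = x[:, None]
        if x.shape[2:] != tuple(self.spec.input_shape):
            raise ValueError(
                f"input shape {x.shape[2:]} != spec {tuple(self.spec.input_shape)}"
            )
        out = x.astype(np.float32, copy=False)
        for _, layer in self.layers:
            out = layer.forward(out)
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Per-class probabilities; rows sum to 1."""
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        probs = [
            softmax(self.forward(x[i : i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(probs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)

    def loss_and_grad(self, x: np.ndarray, labels: np.ndarray) -> float:
        """Mean cross-entropy; leaves parameter gradients in each layer."""
        logits = self.forward(x)
        loss, dlogits = cross_entropy(logits, labels)
        grad = dlogits
        for _, layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss

    # ------------------------------------------------------- introspection
    def activation_and_gradient(
        self, x: np.ndarray, target_class: int, layer_name: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Feature map of ``layer_name`` and d(target logit)/d(feature map).

        Backpropagates the raw class score (not the loss) from the output
        down to the named layer's output; used by Grad-CAM.
        """
        names = [n for n, _ in self.layers]
        if layer_name not in names:
            raise KeyError(f"no layer named {layer_name!r}; have {names}")
        idx = names.index(layer_name)
        if x.ndim == 3:
            x = x[None]
        if x.ndim == 4:
            x = x[:, None]
        out = x.astype(np.float32, copy=False)
        activation = None
        for i, (_, layer) in enumerate(self.layers):
            out = layer.forward(out)
            if i == idx:
                activation = out
        logits = out
        grad = np.zeros_like(logits)
        grad[:, target_class] = 1.0
        for _, layer in reversed(self.layers[idx + 1 :]):
            grad = layer.backward(grad)
        return activation, grad

    @property
    def conv_layer_names(self) -> list[str]:
        return [n for n, l in self.layers if isinstance(l, Conv3D)]

    @property
    def n_parameters(self) -> int:
        return sum(
            p.size for _, layer in self.layers for p in layer.params.values()
        )

    # ------------------------------------------------------------- weights
    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [
            {k: v.copy() for k, v in layer.params.items()}
            for _, layer in self.layers
        ]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        for (_, layer), w in zip(self.layers, weights, strict=True):
            for k in layer.params:
                layer.params[k] = w[k].copy()

    def save(self, path) -> None:
        """Serialize weights to ``.npz`` (one entry per layer/param)."""
        flat = {
            f"{i}.{k}": v
            for i, w in enumerate(self.get_weights())
            for k, v in w.items()
        }
        np.savez(path, **flat)

    def load(self, path) -> None:
        with np.load(path) as data:
            weights = self.get_weights()
            for key in data.files:
                i, k = key.split(".", 1)
                weights[int(i)][k] = data[key]
        self.set_weights(weights)


def build_model(spec: ModelSpec, seed: int = 0) -> Conv3DClassifier:
    """Construct a classifier from its spec with seeded initialization."""
    return Conv3DClassifier(spec, seed=seed)
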