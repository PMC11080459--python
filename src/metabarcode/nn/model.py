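"""The two 1D CNN classifier architectures.

``original`` is the 6-conv-layer pretraining network operating on all
averaged metapixel spectra: 128 filters (kernel 5, stride 2), 100 filters
(kernel 3), then 80/60/40/20 filters with kernel 1, ReLU after each of the
first five layers, and a fully connected softmax head with two outputs.
``pruned`` is the simplified network for a single selected metapixel
spectrum: four conv layers of 8/16/32/32 filters with kernels 7/5/5/5, each
followed by ReLU, and the same two-class head.

Metapixel spectra enter as input channels by default (``arrangement=
'channels'``: shape (n_metapixels, n_wavenumbers)); the alternative
``'concat'`` arrangement lays all spectra end-to-end along the length axis as
a single channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .layers import DTYPE, Conv1d, Dropout, Flatten, Linear, ReLU, conv_out_len

__all__ = ["ORIGINAL_CONV", "PRUNED_CONV", "ModelSpec", "CNN1D",
           "build_model", "save_model", "load_model"]

# (filters, kernel, stride) per conv layer
ORIGINAL_CONV = ((128, 5, 2), (100, 3, 1), (80, 1, 1), (60, 1, 1),
                 (40, 1, 1), (20, 1, 1))
PRUNED_CONV = ((8, 7, 1), (16, 5, 1), (32, 5, 1), (32, 5, 1))


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters; ``conv_layers`` follows the variant."""

    variant: str = "original"
    n_metapixels: int = 49
    n_wavenumbers: int = 251
    arrangement: str = "channels"
    dropout: float = 0.2
    conv_layers: tuple[tuple[int, int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.variant == "original":
            convs = ORIGINAL_CONV
        elif self.variant == "pruned":
            convs = PRUNED_CONV
            if self.n_metapixels != 1:
                object.__setattr__(self, "n_metapixels", 1)
        else:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.arrangement not in ("channels", "concat"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        object.__setattr__(self, "conv_layers", convs)

    @property
    def input_shape(self) -> tuple[int, int]:
        """(channels, length) as fed to the first convolution."""
        if self.arrangement == "channels":
            return (self.n_metapixels, self.n_wavenumbers)
        return (1, self.n_metapixels * self.n_wavenumbers)

    def to_dict(self) -> dict:
        return {"variant": self.variant, "n_metapixels": self.n_metapixels,
                "n_wavenumbers": self.n_wavenumbers,
                "arrangement": self.arrangement, "dropout": self.dropout}


class CNN1D:
    """Sequential conv net with a two-class softmax head."""

    def __init__(self, spec: ModelSpec, layers: list, head_in: int):
        self.spec = spec
        self.layers = layers
        self.head_in = head_in

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits of shape (batch, 2).  ``x``: (batch, channels, length)."""
        if x.ndim != 3 or x.shape[1:] != self.spec.input_shape:
            raise ValueError(f"expected input shape (B, {self.spec.input_shape[0]}, "
                             f"{self.spec.input_shape[1]}), got {x.shape}")
        # layers run channels-last: (B, L, C)
        h = np.ascontiguousarray(np.asarray(x, dtype=DTYPE).transpose(0, 2, 1))
        for layer in self.layers:
            if isinstance(layer, Dropout):
                h = layer.forward(h, rng=rng, train=train)
            else:
                h = layer.forward(h)
        return h

    def backward(self, dlogits: np.ndarray,
                 need_input_grad: bool = True) -> np.ndarray | None:
        """Backpropagate; fills parameter gradients.  The gradient w.r.t. the
        input (needed for attribution, not for training) is returned unless
        ``need_input_grad`` is False."""
        g = dlogits.astype(DTYPE)
        for layer in reversed(self.layers[1:]):
            g = layer.backward(g)
        g = self.layers[0].backward(g, need_input_grad=need_input_grad) \
            if isinstance(self.layers[0], Conv1d) else self.layers[0].backward(g)
        if g is None:
            return None
        return g.transpose(0, 2, 1)  # back to (B, C, L)

    # -- prediction ---------------------------------------------------------
    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        out = np.empty((len(x), 2), dtype=np.float64)
        for lo in range(0, len(x), batch):
            logits = self.forward(x[lo:lo + batch]).astype(np.float64)
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out[lo:lo + batch] = e / e.sum(axis=1, keepdims=True)
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def input_gradients(self, x: np.ndarray,
                        target_class: np.ndarray) -> np.ndarray:
        """d logit[target] / d input, evaluated in inference mode."""
        logits = self.forward(x, train=False)
        dlogits = np.zeros_like(logits)
        dlogits[np.arange(len(x)), target_class] = 1.0
        return self.backward(dlogits)

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


def build_model(spec: ModelSpec, seed: int = 0) -> CNN1D:
    """Instantiate a seeded, freshly initialized classifier."""
    rng = np.random.default_rng(seed)
    c_in, length = spec.input_shape
    layers: list = []
    n_convs = len(spec.conv_layers)
    for i, (c_out, kernel, stride) in enumerate(spec.conv_layers):
        if length < kernel:
            raise ValueError(f"input length {length} shorter than kernel "
                             f"{kernel} of conv layer {i}")
        layers.append(Conv1d(c_in, c_out, kernel, stride, rng))
        length = conv_out_len(length, kernel, stride)
        # original variant: ReLU after each of the first 5 of 6 conv layers;
        # pruned variant: ReLU after every conv layer
        if spec.variant == "pruned" or i < n_convs - 1:
            layers.append(ReLU())
        c_in = c_out
    if spec.dropout > 0:
        layers.append(Dropout(spec.dropout))
    layers.append(Flatten())
    head_in = c_in * length
    layers.append(Linear(head_in, 2, rng))
    return CNN1D(spec, layers, head_in)


def save_model(model: CNN1D, weights_path: str | Path,
               sidecar_path: str | Path | None = None,
               extra: dict | None = None) -> None:
    """Weights as .npz plus a JSON sidecar describing the architecture."""
    np.savez(weights_path, *model.params())
    if sidecar_path is not None:
        doc = {"spec": model.spec.to_dict(), "n_params": model.n_params}
        doc.update(extra or {})
        Path(sidecar_path).write_text(json.dumps(doc, indent=1))


def load_model(spec: ModelSpec, weights_path: str | Path) -> CNN1D:
    model = build_model(spec, seed=0)
    with np.load(weights_path) as data:
        arrays = [data[k] for k in data.files]
    for p, a in zip(model.params(), arrays, strict=True):
        p[...] = a
    return model
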