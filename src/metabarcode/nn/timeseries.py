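"""Per-frame state prediction along a switching trajectory."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..datasets import LABELS
from .model import CNN1D

__all__ = ["classify_timeseries"]


def classify_timeseries(model: CNN1D, frames: np.ndarray,
                        times_s: np.ndarray | None = None,
                        excluded: np.ndarray | None = None) -> pd.DataFrame:
    """Classify the selected metapixel's spectrum of every frame.

    ``frames``: (n_frames, n_wavenumbers) spectra of the single metapixel the
    pruned model was trained on.  Excluded frames (LED on, equilibration) are
    carried through flagged but still predicted.  Returns a tidy frame
    (time_s, p_cis, label, excluded).
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim == 1:
        frames = frames[None]
    n, width = frames.shape
    if width != model.spec.n_wavenumbers:
        raise ValueError(f"frame length {width} does not match model grid "
                         f"({model.spec.n_wavenumbers} wavenumbers)")
    proba = model.predict_proba(frames[:, None, :])
    p_cis = proba[:, 1]
    labels = [LABELS[i] for i in (p_cis >= 0.5).astype(int)]
    if times_s is None:
        times_s = np.arange(n, dtype=float)
    if excluded is None:
        excluded = np.zeros(n, dtype=bool)
    return pd.DataFrame({"time_s": np.asarray(times_s, dtype=float),
                         "p_cis": p_cis, "label": labels,
                         "excluded": np.asarray(excluded, dtype=bool)})
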