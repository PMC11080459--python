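"""Classify the photoswitching trajectory frame by frame.

Loads the pruned single-metapixel CNN of analysis/04 and applies it to the
selected metapixel's spectrum of every frame of a simulated 3-cycle UV/VIS
switching experiment.  Writes the tidy per-frame prediction table and a
figure of predicted state vs the generating cis fraction.

Run after analysis/04:  python analysis/05_timeseries_classification.py
"""

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import metabarcode as mb
from metabarcode.extraction import exclusion_flags
from metabarcode.kinetics import KineticsParams, MembraneState, default_protocol
from metabarcode.nn import ModelSpec, classify_timeseries
from metabarcode.nn.model import load_model

ROOT = Path(__file__).resolve().parents[1]
MODELS = ROOT / "scratch" / "models"
RESULTS = ROOT / "results"
SEED = 0


def main() -> None:
    meta = json.loads((MODELS / "pruned.json").read_text())
    selected = meta["selected_metapixel"]
    pruned = load_model(ModelSpec("pruned", n_wavenumbers=251),
                        MODELS / "pruned.npz")

    protocol = default_protocol()
    times, states, frames = mb.trajectory_spectra(
        protocol, KineticsParams(), MembraneState(0.1), seed=SEED)
    excluded = exclusion_flags(times, protocol)
    df = classify_timeseries(pruned, frames[:, selected, :], times, excluded)
    df["true_cis_fraction"] = [s.cis_fraction for s in states]
    df.to_csv(RESULTS / "timeseries_predictions.csv", index=False)

    true = np.array([s.cis_fraction >= 0.5 for s in states])
    pred = (df.p_cis >= 0.5).to_numpy()
    used = ~excluded
    print(f"{len(df)} frames ({used.sum()} usable); frame-wise agreement "
          f"with ground truth: {np.mean(pred[used] == true[used]):.3f}")
    inc = np.flatnonzero(used)
    changes = [times[inc[i]] / 60 for i in range(1, len(inc))
               if pred[inc[i]] != pred[inc[i - 1]]]
    offs = [e.end_s / 60 for e in protocol.events]
    print(f"predicted transitions at (min): {np.round(changes, 1).tolist()}")
    print(f"LED-off boundaries at (min):   {np.round(offs, 1).tolist()}")

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(times / 60, df.true_cis_fraction, "k-", lw=1,
            label="generating cis fraction")
    ax.plot(times[used] / 60, df.p_cis[used], "o", ms=3,
            label="pruned-CNN P(cis), used frames")
    ax.plot(times[~used] / 60, df.p_cis[~used], "x", ms=3, color="0.6",
            label="excluded frames")
    for e in protocol.events:
        ax.axvspan(e.start_s / 60, e.end_s / 60, alpha=0.15,
                   color="purple" if e.led == "UV" else "green")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cis fraction / P(cis)")
    ax.legend(fontsize=7, loc="center left")
    fig.tight_layout()
    fig.savefig(RESULTS / "timeseries_prediction.png", dpi=150)
    print(f"table -> {RESULTS}/timeseries_predictions.csv; "
          f"figure -> {RESULTS}/timeseries_prediction.png")


if __name__ == "__main__":
    main()
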