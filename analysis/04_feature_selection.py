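"""Integrated-gradients feature selection and CNN pruning.

Loads the pretrained 6-layer CNN of analysis/03, computes per-metapixel
integrated-gradients importance over the validation set, selects the
top-scoring metapixel, trains the pruned 4-layer CNN on that single
metapixel's spectra, and compares the two models.

Outputs: results/importances.csv, results/pruning_report.json, and the
pruned weights in scratch/models/.

Run after analysis/03:  python analysis/04_feature_selection.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import metabarcode as mb
from metabarcode.nn import (ModelSpec, TrainConfig, build_model, evaluate,
                            importance_from_model, select_top_metapixels,
                            split_dataset, train)
from metabarcode.nn.model import load_model, save_model

ROOT = Path(__file__).resolve().parents[1]
MODELS = ROOT / "scratch" / "models"
RESULTS = ROOT / "results"
SEED = 0


def main() -> None:
    ds = mb.generate_labeled_dataset(n_per_class=247, seed=SEED)
    train_set, val_set = split_dataset(ds, 0.7, seed=SEED)
    original = load_model(ModelSpec("original", n_wavenumbers=len(ds.grid)),
                          MODELS / "original.npz")

    importances = importance_from_model(original, val_set.X, n_steps=64,
                                        max_items=64)
    pd.DataFrame({"metapixel": np.arange(49), "nu0": ds.nu0s,
                  "importance": importances}) \
        .to_csv(RESULTS / "importances.csv", index=False)
    selected = int(select_top_metapixels(importances, ds.nu0s, 1)[0])
    print(f"top metapixel by IG importance: {selected} "
          f"(nu0 = {ds.nu0s[selected]:.1f} cm^-1)")
    runners_up = select_top_metapixels(importances, ds.nu0s, 5)
    print(f"top-5: {runners_up.tolist()} "
          f"(nu0 = {np.round(ds.nu0s[runners_up], 1).tolist()})")

    pruned = build_model(ModelSpec("pruned", n_wavenumbers=len(ds.grid)),
                         seed=SEED)
    print(f"pruned 4-conv-layer CNN: {pruned.n_params} parameters "
          f"({pruned.n_params / original.n_params:.1%} of the original)")
    train(pruned, (train_set.X[:, [selected], :], train_set.y),
          TrainConfig(epochs=160, seed=SEED))
    rep_p = evaluate(pruned, (val_set.X[:, [selected], :], val_set.y))
    rep_o = evaluate(original, val_set)
    agree = float(np.mean(
        original.predict(val_set.X) ==
        pruned.predict(val_set.X[:, [selected], :])))
    print(f"validation accuracy: original {rep_o.accuracy:.4f}, "
          f"pruned {rep_p.accuracy:.4f}; prediction agreement {agree:.3f}")

    save_model(pruned, MODELS / "pruned.npz", MODELS / "pruned.json",
               extra={"seed": SEED, "selected_metapixel": selected})
    (RESULTS / "pruning_report.json").write_text(json.dumps({
        "selected_metapixel": selected, "selected_nu0": ds.nu0s[selected],
        "original": rep_o.to_dict(), "pruned": rep_p.to_dict(),
        "agreement": agree}, indent=1))
    print(f"report -> {RESULTS}/pruning_report.json")


if __name__ == "__main__":
    main()
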