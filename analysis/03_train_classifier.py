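"""Train the 6-layer 1D CNN on labeled synthetic membrane spectra.

Builds the default labeled dataset (247 cis + 247 trans sets of 49 averaged
metapixel reflectance spectra), splits it 70/30 stratified, trains for 160
epochs with dropout 0.2, and reports the validation confusion matrix and
accuracy.  The trained weights go to scratch/models/ for the follow-up
feature-selection and pruning steps; the evaluation report goes to results/.

Run:  python analysis/03_train_classifier.py
"""

import json
import time
from pathlib import Path

import metabarcode as mb
from metabarcode.nn import (ModelSpec, TrainConfig, build_model, evaluate,
                            split_dataset, train)
from metabarcode.nn.model import save_model

ROOT = Path(__file__).resolve().parents[1]
MODELS = ROOT / "scratch" / "models"
RESULTS = ROOT / "results"
SEED = 0


def main() -> None:
    MODELS.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    ds = mb.generate_labeled_dataset(n_per_class=247, seed=SEED)
    train_set, val_set = split_dataset(ds, 0.7, seed=SEED)
    print(f"dataset: {len(ds)} spectra sets "
          f"({len(train_set)} train / {len(val_set)} validation)")

    spec = ModelSpec("original", n_wavenumbers=len(ds.grid))
    model = build_model(spec, seed=SEED)
    print(f"original 6-conv-layer CNN: {model.n_params} parameters")
    t0 = time.perf_counter()
    log = train(model, train_set, TrainConfig(epochs=160, seed=SEED))
    report = evaluate(model, val_set)
    print(f"trained 160 epochs in {time.perf_counter() - t0:.0f}s; "
          f"final training loss {log['epoch_loss'][-1]:.2e}")
    print(f"validation accuracy: {report.accuracy:.4f}")
    print(f"confusion (rows=predicted, cols=actual):\n{report.confusion}")

    save_model(model, MODELS / "original.npz", MODELS / "original.json",
               extra={"seed": SEED, "epochs": 160})
    (RESULTS / "classifier_report.json").write_text(json.dumps({
        "seed": SEED, "n_train": len(train_set), "n_val": len(val_set),
        "original": report.to_dict()}, indent=1))
    print(f"weights -> {MODELS}/original.npz; report -> "
          f"{RESULTS}/classifier_report.json")


if __name__ == "__main__":
    main()
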