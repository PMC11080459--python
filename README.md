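# metabarcode

Simulation and analysis of **metasurface molecular barcodes**: in situ
surface-enhanced infrared (SEIRA) biospectroscopy of photoswitchable lipid
membranes, read out by an explainable 1D convolutional neural network.

## The problem

Mid-IR vibrational spectroscopy can distinguish the *cis* and *trans*
conformations of azobenzene photolipids (AzoPC) in a supported bilayer, but a
monolayer's absorbance is minute and the measurement lives in strongly
absorbing D₂O.  A pixelated all-dielectric metasurface solves the sensitivity
problem: 49 high-Q (Q > 80) resonances spaced linearly over 1400–1800 cm⁻¹,
each resonance attenuated by the molecular absorption at its own wavenumber,
so a camera image of the chip becomes a **molecular barcode** — an
unambiguous map from spectrum to space.  This package implements, on fully
synthetic data, the complete analysis the measurement needs:

1. **Forward model** — coupled-mode (Fano) metapixel reflectance
   R(ν) = bg(ν)·|r_bg + aγ_r/(i(ν−ν₀) + γ_r + γ_nr + ℓ(ν))|² with molecular
   Lorentzian loss channels ℓ(ν), D₂O background, photoswitching kinetics
   dc/dt = k(pss − c), pixel noise and slow drifts; time-resolved
   hyperspectral cubes (one per 64 s frame).
2. **Barcode layout** — 49 designs, pixel doubling + 2 extras = 100 physical
   pixels, seeded random 10×10 arrangement, and the inverse mapping.
3. **Spectral extraction** — block averaging, duplicate averaging (→ 49
   spectra), absorbance A = −log₁₀(R_sample/R_D₂O) at each resonance,
   Savitzky–Golay reconstruction, 7×7 absorption maps.
4. **Explainable classification** — a 6-conv-layer 1D CNN on all 49 spectra,
   integrated-gradients attribution aggregated to per-metapixel importance,
   selection of the top metapixel, and a pruned 4-conv-layer CNN operating on
   that single spectrum; confusion-matrix evaluation and frame-by-frame
   classification of switching trajectories.

The CNN stack (layers, Adam, integrated gradients) is implemented directly on
numpy with analytic backprop, verified against finite differences; all
randomness is seeded and runs are bit-reproducible.

## Worked example

```bash
python analysis/01_simulate_cubes.py         # hyperspectral cubes -> scratch/
python analysis/02_extract_absorbance.py     # absorbance series + barcode maps
python analysis/03_train_classifier.py       # train the 6-layer CNN
python analysis/04_feature_selection.py      # IG importance + pruned CNN
python analysis/05_timeseries_classification.py
```

Representative output (seed 0):

```
dataset: 494 spectra sets (344 train / 150 validation)
original 6-conv-layer CNN: 91070 parameters
validation accuracy: 1.0000
confusion (rows=predicted, cols=actual):
[[75  0]
 [ 0 75]]

top metapixel by IG importance: 13 (nu0 = 1508.3 cm^-1)
top-5: [13, 14, 12, 15, 11] (nu0 = [1508.3, 1516.7, 1500.0, 1525.0, 1491.7])
pruned 4-conv-layer CNN: 23378 parameters (25.7% of the original)
validation accuracy: original 1.0000, pruned 1.0000; prediction agreement 1.000

176 frames (138 usable); frame-wise agreement with ground truth: 1.000
predicted transitions at (min): [74.7, 94.9, 114.1, 133.3, 152.5, 172.8]
LED-off boundaries at (min):   [74.5, 94.0, 113.5, 133.0, 152.5, 172.0]
```

Reading it: with the default synthetic contrast (the cis-only N=N band at
1511 cm⁻¹ plus the ≈17 % lipid-density drop of the expanded cis membrane)
both networks separate the states perfectly on held-out data; attribution
picks the metapixel resonant at 1508 cm⁻¹ — the N=N marker — as the single
most informative pixel; and the pruned model, watching only that one
spectrum, flags every cis↔trans transition within ~1 frame of the LED
turning off.  When the class contrast is instead confined to a band at
1742 cm⁻¹ (the anhydrous-ester C=O stretch), the selected metapixel is the
one resonant nearest 1742 cm⁻¹ — the attribution follows the chemistry, not
the pixel layout.  On zero-contrast (bare-substrate analogue) data the same
training protocol yields chance-level accuracy, confirming the classifier
does not hallucinate structure from noise or drift.

There is also a CLI for the same stages:

```bash
metabarcode run-full --seed 1 --out runs/full
metabarcode simulate --seed 1 --out runs/sim
```

## Layout

```
src/metabarcode/      library: grid, designs, molecular, kinetics, resonance,
                      barcode, cube, datasets, extraction, nn/, pipeline, cli
analysis/             numbered narrative drivers (simulate -> ... -> classify)
tests/                pytest suite incl. end-to-end acceptance tests
scripts/acceptance.py headline-number reproduction
docs/methods.md       model assumptions, defaults, numerical choices, limits
```
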