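"""Extract metapixel spectra, absorbance time series, and barcode maps.

Reads the simulated cubes of analysis/01, averages the doubled metapixels
(100 physical pixels -> 49 spectra), references each design against the
D2O-only lead-in frames, and produces:

  results/absorbance_timeseries.csv -- A(t) of the N=N-resonant metapixel,
      with LED-on / pre-illumination frames flagged excluded
  results/barcode_map_cis.csv, barcode_map_trans.csv -- 7x7 molecular
      barcodes of the two photostationary phases
  results/barcode_maps.png -- heat-map rendering of both

Run after analysis/01:  python analysis/02_extract_absorbance.py
"""

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from metabarcode.barcode import load_layout
from metabarcode.cube import load_cube
from metabarcode.extraction import (average_doubled, exclusion_flags,
                                    extract_metapixel_spectra,
                                    per_pixel_absorbance, render_barcode_map,
                                    timeseries_absorbance)
from metabarcode.kinetics import LedEvent, SwitchProtocol

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cubes"
RESULTS = ROOT / "results"


def main() -> None:
    layout = load_layout(SCRATCH / "layout.json")
    gt = json.loads((SCRATCH / "ground_truth.json").read_text())
    cubes = [load_cube(p) for p in gt["cubes"]]
    times = np.array(gt["times_s"])
    protocol = SwitchProtocol(
        tuple(LedEvent(e["led"], e["start_s"], e["duration_s"])
              for e in gt["events"]), 64.0)

    # reference: the first 10 frames (pure D2O, before membrane formation)
    nn_design = int(np.argmin([abs(layout.designs[i].nu0 - 1511.0)
                               for i in range(49)]))
    ts = timeseries_absorbance(cubes, layout, list(range(10)), nn_design,
                               protocol)
    ts.to_csv(RESULTS / "absorbance_timeseries.csv", index=False)
    used = ts[~ts.excluded]
    print(f"absorbance time series of metapixel {nn_design} "
          f"(nu0 = {layout.designs[nn_design].nu0:.1f} cm^-1): "
          f"{len(used)} usable frames, A in "
          f"[{used.absorbance.min():.4f}, {used.absorbance.max():.4f}]")

    # barcode maps of the last cis-phase and trans-phase frames
    cis_frac = np.array(gt["cis_fraction"])
    refs = average_doubled(extract_metapixel_spectra(cubes[5], layout), layout)
    maps = {}
    for name, mask in [("cis", cis_frac >= 0.5),
                       ("trans", (cis_frac < 0.5) & (times > times[12]))]:
        idx = int(np.flatnonzero(mask & ~exclusion_flags(times, protocol))[-1])
        samples = average_doubled(
            extract_metapixel_spectra(cubes[idx], layout), layout)
        pp = per_pixel_absorbance(samples, refs, layout)
        bmap = render_barcode_map(pp)
        maps[name] = bmap
        np.savetxt(RESULTS / f"barcode_map_{name}.csv", bmap, delimiter=",")
        print(f"{name} barcode map from frame {idx}: "
              f"max A = {bmap.max():.4f} at design "
              f"{int(np.argmax(bmap))} "
              f"(nu0 = {layout.designs[int(np.argmax(bmap))].nu0:.0f} cm^-1)")

    fig, axes = plt.subplots(1, 2, figsize=(7, 3))
    vmax = max(m.max() for m in maps.values())
    for ax, (name, bmap) in zip(axes, maps.items()):
        im = ax.imshow(bmap, cmap="inferno", vmin=0, vmax=vmax)
        ax.set_title(f"{name} membrane")
        ax.set_xticks([])
        ax.set_yticks([])
    fig.colorbar(im, ax=axes, label="absorbance", shrink=0.8)
    fig.savefig(RESULTS / "barcode_maps.png", dpi=150)
    print(f"maps -> {RESULTS}/barcode_map_*.csv, barcode_maps.png")


if __name__ == "__main__":
    main()
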