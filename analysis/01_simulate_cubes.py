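"""Simulate a desk-scale in situ photoswitching experiment.

Generates the time-resolved hyperspectral reflectance cubes of a supported
AzoPC membrane on the 100-pixel metasurface barcode: 70 min lead-in (D2O
then membrane formation), then three UV/VIS switching cycles (LED on 4 min
30 s, off 15 min), one cube per 64 s.  Cubes (HDF5) go to scratch/ (bulky,
regenerable); the layout and ground-truth trajectory go to results/.

Run:  python analysis/01_simulate_cubes.py
"""

import json
import shutil
from pathlib import Path

from metabarcode.pipeline import PipelineConfig, run_simulate

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cubes"
RESULTS = ROOT / "results"

CONFIG = PipelineConfig(experiment="switching-experiment", seed=0,
                        block_px=4, lead_in_s=4200.0, n_cycles=3)


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    sidecar = run_simulate(CONFIG, SCRATCH)
    n = len(sidecar["cubes"])
    t_end = sidecar["times_s"][-1]
    print(f"simulated {n} cubes ({t_end / 60:.0f} min at 64 s per frame)")
    print(f"LED events: {[(e['led'], e['start_s'] / 60) for e in sidecar['events']]}")
    shutil.copy(SCRATCH / "layout.json", RESULTS / "layout.json")
    gt = {k: v for k, v in sidecar.items() if k != "cubes"}
    (RESULTS / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    print(f"cubes -> {SCRATCH}; layout and ground truth -> {RESULTS}")


if __name__ == "__main__":
    main()
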