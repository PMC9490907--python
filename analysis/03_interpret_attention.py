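#!/usr/bin/env python
"""Interpret the best-fold model: attention heatmaps, z-scored per-tile
attention, and the white-matter vs grey-matter region comparison.

Prints the per-region median attention z-scores and the paired t-test
across slides; writes heatmap PNGs and the per-tile attention table under
results/run/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from run_config import CONFIG

import numpy as np

from lfbmil.pipeline import run_stage


def main() -> int:
    outdir = run_stage("interpret", CONFIG)
    region = json.loads((outdir / "region_attention.json").read_text())
    wm = float(np.median(region["wm_median"]))
    gm = float(np.median(region["gm_median"]))
    print(f"median WM attention z = {wm:+.2f}; median GM attention z = {gm:+.2f}")
    print(f"paired t = {region['t']:.2f}, p = {region['p']:.2e} "
          f"({len(region['slide_ids'])} slides, {region['n_excluded']} excluded)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
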