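#!/usr/bin/env python
"""Quantify dark-blue (myelin-like) staining in the top-attention tiles.

For every slide, counts dark- and light-blue positive pixels in the tiles
the best-fold model attends to most, summarizes each slide by its median
dark count and dark/light ratio, and compares the predicted-impaired and
predicted-unimpaired groups with Welch t-tests. Tables and the 2-D kernel
density surface land under results/run/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from run_config import CONFIG

from lfbmil.pipeline import run_stage


def main() -> int:
    outdir = run_stage("quantify", CONFIG)
    tests = json.loads((outdir / "stain_tests.json").read_text())
    for grouping in ("predicted", "labeled"):
        for metric in ("median_dark", "median_ratio"):
            res = tests[grouping][metric]
            if res is None:
                print(f"{grouping}/{metric}: skipped (a group was too small)")
                continue
            print(f"{grouping} CI vs NCI, {metric}: "
                  f"{res['mean_a']:.1f} vs {res['mean_b']:.1f}, "
                  f"Welch t = {res['t']:.2f}, p = {res['p']:.2e}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
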