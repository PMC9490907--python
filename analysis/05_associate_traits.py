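#!/usr/bin/env python
"""Associate model outputs and stain metrics with pathoclinical traits.

Rank-correlates the predicted impairment probability and the top-tile
median dark count with age, Braak stage, ARTAG, cerebrovascular disease
and the cognitive label; runs the conditional-independence G-tests among
label, age and staining; writes the final JSON/Markdown summary.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from run_config import CONFIG

import pandas as pd

from lfbmil.pipeline import run_stage


def main() -> int:
    run_stage("associate", CONFIG)
    outdir = run_stage("report", CONFIG)
    print(pd.read_csv(outdir / "correlations.csv").to_string(index=False))
    ci = json.loads((outdir / "ci_tests.json").read_text())
    for name, res in ci.items():
        if res is None:
            print(f"{name}: skipped")
        else:
            print(f"{name}: G = {res['g']:.1f} (MI = {res['mi']:.4f} nats), "
                  f"df = {res['df']}, p = {res['p']:.2e}")
    print(f"summary written to {outdir / 'summary.json'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
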