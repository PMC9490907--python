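#!/usr/bin/env python
"""Tile the slides, extract features, and train the attention-MIL
classifier across ten Monte Carlo cross-validation folds.

Prints the per-fold test AUCs, their mean, and the Wilcoxon signed-rank
test against chance (0.5). Artifacts (feature bags, fold models, fold
evaluations, per-slide probabilities) land under results/run/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from run_config import CONFIG

from lfbmil.pipeline import run_stage


def main() -> int:
    for stage in ("featurize", "split", "train", "evaluate"):
        outdir = run_stage(stage, CONFIG)
    result = json.loads((outdir / "eval.json").read_text())
    print("fold AUCs:", [round(a, 3) for a in result["fold_auc"]])
    print(f"mean AUC = {result['mean_auc']:.3f}, "
          f"Wilcoxon vs 0.5: p = {result['wilcoxon_auc']['p']:.4f}")
    print(f"mean balanced accuracy = {result['mean_balanced_accuracy']:.3f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
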