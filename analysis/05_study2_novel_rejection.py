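#!/usr/bin/env python
"""Rejection-latency analysis for novel compounds.

Latency recipe: remove items below 70% accuracy, frequency-filter by
constituent counts, inverse-transform the response times (per the
Box-Cox suggestion), fit both proximity models with crossed random
intercepts per character, select by AIC, and run the speed-accuracy
concordance check on an accuracy model with the same design.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from caoss.pipeline import PipelineConfig, report, run_study

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    cfg = PipelineConfig(recipe="novel_rejection", threshold=10, seed=seed,
                         out_dir=ROOT / "study2",
                         embeddings_path=ROOT / "data" / "embeddings.w2v.txt",
                         lexicon_path=ROOT / "data" / "lexicon.tsv",
                         behaviour_path=ROOT / "data" / "behaviour_rt.tsv")
    bundle = run_study(cfg)
    print(report(bundle))
    acc = bundle["exclusions"].get("accuracy_filter")
    if acc:
        print(f"\naccuracy filter removed {acc['n_before'] - acc['n_after']} items "
              f"(drop rate {acc['drop_rate_percent']}%)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
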