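#!/usr/bin/env python
"""Recognition-latency analysis for existing compounds.

Same latency recipe as the novel-compound analysis, but for existing
words: the whole-word frequency filter applies in addition to the
constituent filter, and log word frequency enters the model as a
control covariate (typically the dominant predictor of recognition
latencies).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from caoss.pipeline import PipelineConfig, report, run_study

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    cfg = PipelineConfig(recipe="existing_recognition", threshold=10, seed=seed,
                         out_dir=ROOT / "study3",
                         embeddings_path=ROOT / "data" / "embeddings.w2v.txt",
                         lexicon_path=ROOT / "data" / "lexicon.tsv",
                         behaviour_path=ROOT / "data" / "behaviour_rt_existing.tsv")
    bundle = run_study(cfg)
    print(report(bundle))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
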