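#!/usr/bin/env python
"""Sensibility-rating analysis: which proximity measure fits best?

Runs the full recipe on the rating table: frequency filter, train the
composition model, score proximities under both models, compare the two
crossed-random-intercept mixed models by AIC, and report the winning
coefficient table.  Also computes the inter-rater ICC on a
participant-level rating matrix, the agreement check that precedes
averaging ratings per item.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from caoss.behaviour import icc
from caoss.embeddings import load_embeddings
from caoss.lexicon import read_lexicon
from caoss.pipeline import PipelineConfig, report, run_study
from caoss.synthetic import SyntheticConfig, gen_rating_matrix
from caoss.composition import score_proximities
from caoss.synthetic import generate_dataset

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    cfg = PipelineConfig(recipe="sensibility", threshold=10, seed=seed,
                         out_dir=ROOT / "study1",
                         embeddings_path=ROOT / "data" / "embeddings.w2v.txt",
                         lexicon_path=ROOT / "data" / "lexicon.tsv",
                         behaviour_path=ROOT / "data" / "behaviour_rating.tsv")
    bundle = run_study(cfg)
    print(report(bundle))

    # inter-rater agreement on a participant-level matrix from the same
    # generating process (three subsets of items, as in a split design)
    ds = generate_dataset(SyntheticConfig(seed=seed))
    rng = np.random.default_rng(seed + 17)
    iccs = []
    for subset in range(3):
        M = gen_rating_matrix(ds.config, ds.lexicon, ds.true_proximities, rng, n_items=500)
        iccs.append(icc(M, model="twoway", type="consistency", unit="average"))
    print("\nICC (two-way, consistency, average) per item subset: "
          + ", ".join(f"{v:.2f}" for v in iccs))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
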