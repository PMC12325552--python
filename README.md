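# caoss — position-specific compositional semantics for two-character compounds

Most words in Chinese are compounds of two characters, and the position
of a character changes what it contributes: 蜜蜂 ("honey-bee", a bee)
and 蜂蜜 ("bee-honey", honey) contain the same characters in opposite
orders.  This package implements and tests a computational account of
how readers combine character meanings into compound meanings, for
psycholinguists who want to relate distributional-semantic measures to
item-level reading behaviour (sensibility ratings, lexical-decision
latencies, accuracy).

## The models

Characters and words live in a d-dimensional embedding space (word2vec
text format).  Two composition models map the constituent vectors
v_C1, v_C2 of a compound to a compound vector:

- **CAOSS** (Composition as Abstract Operation in Semantic Space):
  `c = W_C1 · v_C1 + W_C2 · v_C2`, where W_C1 and W_C2 are d×d
  *position-specific* matrices estimated by penalized least squares
  against the observed whole-compound vectors of the training lexicon
  (minimum-norm solution when unpenalized; optional ridge penalty with
  cross-validated selection).
- **Additive baseline**: `c = v_C1 + v_C2`, position-blind — reversible
  compounds AB and BA get identical representations.

From either model, the **proximity** of each constituent is the cosine
of the composed vector with the (transformed) constituent vector, e.g.
`CosSim(c, W_C1 v_C1)` for CAOSS.  **Transparency** is the cosine of
the *observed* whole-word vector with the raw constituent vector; its
correlation with human transparency ratings across frequency-exclusion
thresholds calibrates the training-set frequency cutoff (counts > 10).

Behavioural analyses fit linear mixed models by maximum likelihood with
*crossed* random intercepts for first and second character:

```
dv ~ log C1 family size + C1 proximity + log C2 family size + C2 proximity
     (+ log word frequency)  +  (1|C1) + (1|C2)
```

with mean-centered predictors, Box–Cox-guided DV transformation
(latencies → 1/RT), AIC selection between the two proximity models,
Satterthwaite denominator df, and Edwards-style semipartial R² per
fixed effect.  The mixed-model engine is implemented here (ML in the
random-effects space via the Woodbury identity) and is verified against
R's `lmerTest` in the test suite.

Because no corpus, pretrained embedding, or megastudy ships with the
package, a seeded synthetic generator (`caoss.synthetic`) produces every
input with stored ground truth: spherical character vectors, planted
composition matrices, power-law word frequencies with extra embedding
noise on rare items, transparency ratings, and behavioural tables
generated from the true proximities with crossed random intercepts.

## Worked example

```
python analysis/01_simulate.py          # synthetic corpus -> results/data/
python analysis/02_train_composition.py
python analysis/04_study1_sensibility.py
```

The training step prints

```
frequency filter (>10): 3000 -> 1924 compounds (drop rate 35.9%)
trained on 1924 compounds; relative Frobenius error vs ground truth: W1 0.106, W2 0.103
```

— about a third of the synthetic lexicon falls at or below the
frequency cutoff, and the estimated position matrices recover the
generating ones to ~10% relative error at this noise level.  The
sensibility analysis then reports

```
AIC comparison (smaller is better):
  caoss      AIC = 4842.6  (dAIC = 0.0)  <- selected
  additive   AIC = 4938.6  (dAIC = 96.0)

Coefficients (caoss proximities):
  Predictor       Estimate       SE        t        p  Semipartial R2
  intercept          2.524    0.019   136.37   <.0001               -
  log_c1_fs          0.132    0.048     2.77   0.0059            2.3%
  prox_c1            1.131    0.166     6.80   <.0001            3.9%
  log_c2_fs          0.078    0.045     1.74   0.0821            0.8%
  prox_c2            0.707    0.167     4.23   <.0001            1.5%
```

— the position-specific proximities fit the ratings better than the
additive ones (ΔAIC = 96), and both proximity effects are positive:
novel compounds whose constituents sit closer to the composed meaning
are judged easier to make sense of.  Scripts 05/06 run the latency
recipes (inverse-transformed RTs, accuracy filter, speed–accuracy
concordance check).

A `caoss` command-line tool exposes the same steps
(`simulate`, `train`, `score-proximity`, `calibrate`, `analyze`,
`run-study`, `report`); see `caoss --help`.

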