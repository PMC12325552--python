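# Methods

## Composition models and their estimation

The position-specific model represents a two-character compound as
c = W1 v1 + W2 v2, with v1, v2 the embedding vectors of the standalone
characters and W1, W2 ∈ R^{d×d} learned from the training lexicon.
Stacking x_i = [v1_i; v2_i] ∈ R^{2d} and the observed compound vectors
w_i as rows of Y, estimation solves

    min_B  ‖Y − X B‖²_F + λ‖B‖²_F ,    B ∈ R^{2d×d},

and splits B into W1 (top d rows, transposed) and W2 (bottom d rows).
With λ = 0 the solver returns the minimum-norm (pseudoinverse) solution,
so rank-deficient designs are well defined.  There is no intercept:
the model form has no bias term (a `fit_intercept` flag is deliberately
absent; composition is linear in the constituents).  λ defaults to 0;
`ridge_lambda="auto"` selects it by 5-fold cross-validated
reconstruction error over the grid {0, 10⁻³, …, 10³} with a seeded
shuffle.  Training items lacking any of the three vectors are skipped
and counted.  Training always uses the frequency-filtered lexicon;
family size is computed on the full pre-filter lexicon (it is a corpus
property, not a training-set property), with the alternative available.

One stacked regression is solved rather than two independent
per-position regressions: the two terms share the residual w −
(W1 v1 + W2 v2), which is exactly the stated least-squares objective;
solving per position would minimize a different criterion.

Vectors are stored un-normalized; normalization happens only inside
cosine similarity (which is norm-free).  A `normalize_inputs`-style
preprocessing step is intentionally not applied before training.

## Proximity, transparency, and a degeneracy worth knowing

Proximity compares the composed vector with the *transformed*
constituents (W1 v1, W2 v2) for the matrix model, and with the raw
constituents for the additive baseline.  Transparency compares the
*observed* whole-word vector with the raw constituents.

A mathematical property of the additive baseline matters for synthetic
work: when constituent vectors share a common norm (as the generator's
unit-norm characters do), cos(v1+v2, v1) = (1 + v1·v2)/‖v1+v2‖ =
cos(v1+v2, v2) — the additive model's two proximities are *identical*.
Real embedding tables have varying norms, so the two measures merely
correlate highly there; under equal norms they collapse exactly, and a
design containing both is singular.  `prepare_design` detects this
exact collinearity and keeps a single shared proximity predictor for
the additive model (logged, and flagged in the design's metadata).  The
position-specific model is unaffected because W1 v1 and W2 v2 have
different norms.

## Frequency filter and calibration sweep

The training filter keeps entries whose whole-word and both constituent
frequencies strictly exceed the threshold (default 10): the quantitative
exclusion criterion is "frequency ≤ threshold", so the boundary is
exclusive; an inclusive variant is exposed behind a flag.  The
calibration sweep refilters the lexicon at each candidate threshold,
computes transparency for surviving rated items, and reports Spearman's
ρ (average ranks for ties, via rank-transformed correlation) against
human ratings per constituent, with the surviving n.  Because rare
items carry noisier embeddings, ρ rises as the threshold grows toward
the adopted cutoff and then flattens while n shrinks — the pattern that
justifies the cutoff.

## Mixed-model engine

Behavioural analyses fit y = Xβ + Z1 u1 + Z2 u2 + ε with crossed
random intercepts per first and second character, by maximum likelihood
(the reported analyses all use ML; REML exists behind a flag for
sensitivity checks).  With γ_k = τ_k²/σ² and M = I_q + D^{1/2} Z'Z
D^{1/2}, the Woodbury identity reduces each likelihood evaluation to
q×q linear algebra (q = number of distinct characters), and β and σ²
are profiled analytically.  The 2-dimensional optimization over log γ
uses Nelder–Mead from three fixed starts (the surface can be flat near
the boundary), relative function tolerance 1e-10.  A variance ratio
below 1e-6 is reported as a singular (boundary) fit — a success with a
note, not an error; an optimizer that converges from no start raises an
explicit convergence failure carrying per-start diagnostics.

Satterthwaite denominator df use the delta method on θ = (τ1², τ2²,
σ²): df_j = 2 C_jj²/(g_j' A g_j) with C = σ²(X'V₀⁻¹X)⁻¹, g_j the
central-difference gradient of C_jj in θ, and A the inverse observed
information from the numerical Hessian of the β-profiled
log-likelihood.  Components estimated at the boundary are held at zero
and excluded from θ — they are not interior parameters, and
differencing across zero is meaningless; in the all-boundary limit the
df reduce to ≈ n, matching the OLS large-sample answer.  If the
information matrix is not invertible, df fall back to n − p with a
logged downgrade.  The engine reproduces lmerTest (ML, Satterthwaite)
on crossed test fixtures to ~5 decimal places in estimates, SEs, df,
variance components and AIC; that oracle comparison runs in the suite.

AIC is 2k − 2·logLik with k counting fixed effects plus the two
intercept variances plus the residual variance.  AIC comparisons
require identical row counts and DV; ties keep input order.
Semipartial R² per fixed effect uses the single-predictor
Edwards-style statistic R² = F/(F + ν), F = t², ν = that coefficient's
Satterthwaite df — an approximation to the commonly used package
default, recorded as such.

## Transformation suggestion

`suggest_transform` scans the Box–Cox profile likelihood on λ ∈ [−3, 3]
in steps of 0.01 and maps λ̂ to a conventional transform when it lies
within 0.25 of −1 (inverse), 0 (log) or 1 (none).  Two practical
points:

- With covariates supplied, the scan uses the original *regression*
  formulation (profile likelihood of the transformed response given
  the design), since a strong covariate — word frequency and latencies
  being the canonical case — can skew the marginal distribution and
  mislead a marginal scan.
- When the residual coefficient of variation is small the profile is
  nearly flat and λ̂ has large sampling error.  The study recipes
  therefore fall back to the conventional transform for the DV kind
  (1/RT in seconds for latencies — so positive coefficients on the
  transformed scale mean faster responses — identity otherwise)
  whenever the mapped suggestion is a non-conventional power, recording
  both the suggestion and what was applied.

## Accuracy analyses

Items below 70% accuracy are removed (strictly-below boundary).  The
speed–accuracy concordance check refits the winning fixed/random
structure on empirical-logit item accuracy, log((k+0.5)/(n−k+0.5)), and
classifies each shared predictor: concordant when the faster-direction
sign agrees with the more-accurate sign, trade-off when they oppose,
inconclusive unless both |t| > 2.  A latency model on a raw or log
scale flips the faster-direction convention; the pipeline passes the
correct sign for the transform it applied.  An identity-scale accuracy
option exists; a logistic model was deliberately not guessed at.

ICC for rater agreement implements the standard ANOVA formulations
(one-way/two-way, consistency/agreement, single/average).  The default
— two-way random effects, consistency, average measures — matches
designs where per-item means over a fixed rater panel are carried into
analysis.  All variants are selectable; the suite verifies every
variant against pingouin on random matrices to 1e-10.

## Synthetic generator

The generator emulates the study inputs with stored ground truth:

- **Characters**: i.i.d. unit-norm spherical vectors (d = 50,
  n = 300 by default) — the simplest geometry free of accidental
  anisotropy.
- **True weights**: W* = 0.6·I + 0.15·G, independent standard-normal G
  per position, so positions genuinely differ and reversible pairs get
  distinct meanings.
- **Lexicon**: 3,000 distinct ordered pairs; 5% of compounds exist in
  both orders.  Word frequency is drawn from the truncated power law
  P(k) ∝ k^(−1.1) on {1..10⁵}; this places roughly 40% of compounds at
  or below frequency 10, so the default filter removes a realistic
  share of the lexicon.  Character frequencies are the summed
  frequencies of the compounds containing them.
- **Compound vectors**: W1* v1 + W2* v2 + N(0, 0.1²·I), with additional
  N(0, 0.5²·I) noise for compounds below frequency 10 — rare words get
  poor embeddings, which is what the calibration sweep detects.
- **Transparency ratings**: affine map of the noiseless transparency to
  a 1–7 scale plus N(0, 0.5) noise, clamped (clamping, not
  truncate-resample; the small edge bias is accepted).
- **Behaviour**: η = β·x + u_C1 + u_C2 with x the centered true-proximity
  and log-family-size predictors.  Ratings add N(0, 0.5) and clamp to
  1–5 (β = (2.5, 0.141, 0.956, 0.082, 0.792), τ = 0.2).  Latencies put
  η on the inverse-RT scale (β intercept 1.382 s⁻¹, small negative
  effects for novel-compound rejection; a positive-signed set plus a
  word-frequency term for existing-word recognition) with RT =
  1/max(η, 0.2) — positivity guaranteed, inverse-transformed RT exactly
  linear.  Accuracy is binomial over 33 responses through a logistic
  link with its own coefficients.  All coefficients, variances and the
  reversible-pair list are serialized with the data.

What the generator does *not* emulate: real orthography or
character-internal structure, polysemy, participant-level RT
distributions (latencies are item-level means), anisotropic embedding
geometry, and the varying vector norms of real embedding tables (see
the additive degeneracy above).  Passing tests therefore demonstrate
correctness of the machinery and recoverability under the stated
generative assumptions, not performance on real corpora — the real
embedding table, corpus lexicon and megastudy norms remain external
inputs the pipeline can consume through the same file formats.

## Problem sizes and numerical choices

Unit tests run on a scaled-down world (d = 16, 60 characters, 400
compounds).  End-to-end checks use the default generator (d = 50,
3,000 compounds) with 20 replicates for the AIC comparison; mixed-model
recovery uses 100 replicates of n = 1,200 items over 40×40 crossed
levels (50 replicates in the acceptance script).  Comparisons in tests
use absolute tolerance 1e-6 for closed-form values, 1e-8 for oracle
equivalence of the trained matrices, and 1e-10 for ICC-vs-oracle.
Embedding files are written with 8 significant digits; duplicate tokens
keep the first occurrence with a warning; duplicate *compounds* in a
lexicon are an error, to surface upstream corpus problems rather than
hide them.

## Known limitations

- Satterthwaite df near (but not at) a variance boundary inherit
  finite-difference noise; exactly-at-boundary components are handled
  by exclusion as described.
- The semipartial R² is the F-to-R² mapping, not the
  standardized-generalized-variance statistic; values can differ from
  other software for correlated predictors.
- The additive baseline under equal-norm embeddings carries one fewer
  proximity predictor by construction (see above), so its AIC penalty
  differs by 2 from the position-specific model's.
- Random slopes, generalized (logistic) mixed models and Bayesian
  fitting are out of scope.
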