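"""Synthetic embedding-lexicon-behaviour generator with stored ground truth.

Everything the pipeline consumes can be generated here: character
embeddings, a ground-truth pair of position-specific composition
matrices, a compound lexicon with power-law frequencies, human-like
transparency ratings, and item-level behavioural tables (sensibility
ratings, response times, accuracy) produced by a linear model with
crossed random intercepts per constituent character.  The generating
parameters — including the true W1*, W2*, the behavioural coefficients,
and the random-effect standard deviations — are returned alongside the
data so that recovery tests never have to re-derive them.

Generator geometry
------------------
* Characters are i.i.d. unit-norm spherical vectors: the simplest
  geometry with no accidental anisotropy.
* True weights are W* = alpha * I + gamma * G with standard-normal G,
  drawn independently per position, so the two positions genuinely
  differ (reversible compounds AB / BA get distinct meanings).
* Observed compound vectors are W1* v1 + W2* v2 plus isotropic Gaussian
  noise; *rare* compounds (frequency below a cutoff) receive extra
  noise, emulating the poor embeddings of low-frequency words that
  motivate frequency-thresholding the training set.
* Word frequencies are drawn from the truncated power law
  P(k) proportional to k^(-zipf_exponent) on k in {1..max_freq}; with
  the default exponent 1.1 about 40% of compounds fall at or below
  frequency 10, so the default frequency filter removes a realistic
  share of the lexicon.
* Response times follow RT = 1 / max(eta, 0.2) seconds with eta linear
  in the predictors, so a Box-Cox scan of the raw RTs lands on the
  inverse transform and inverse-transformed RTs are exactly linear.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import CompositionWeights, score_proximities
from .embeddings import EmbeddingTable, save_embeddings
from .lexicon import CompoundEntry, CompoundLexicon, write_lexicon

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "gen_weights",
    "gen_characters",
    "gen_lexicon",
    "gen_transparency_ratings",
    "gen_behaviour",
    "gen_rating_matrix",
    "generate_dataset",
    "write_dataset",
]


@dataclass
class SyntheticConfig:
    """All generator parameters; identical config (incl. seed) gives
    bit-identical outputs."""

    d: int = 50
    n_characters: int = 300
    n_compounds: int = 3000
    reversible_fraction: float = 0.05
    zipf_exponent: float = 1.1
    max_freq: int = 100_000
    compound_noise_sd: float = 0.1
    rare_noise_sd: float = 0.5
    rare_freq_cutoff: int = 10
    weight_alpha: float = 0.6
    weight_gamma: float = 0.15
    # sensibility-rating DV (5-point scale)
    beta_rating: tuple = (2.5, 0.141, 0.956, 0.082, 0.792)
    rating_tau_c1: float = 0.2
    rating_tau_c2: float = 0.2
    rating_sigma: float = 0.5
    rating_bounds: tuple = (1.0, 5.0)
    rater_sd: float = 0.3
    n_raters: int = 10
    # response-time DV: eta is on the inverse-RT (1/s) scale
    beta_rt: tuple = (1.382, -0.026, -0.196, -0.016, -0.090)
    beta_rt_word_freq: float = 0.045
    rt_tau_c1: float = 0.015
    rt_tau_c2: float = 0.015
    rt_sigma: float = 0.04
    rt_eta_floor: float = 0.2
    # accuracy DV (binomial over n_responses, logistic link)
    beta_accuracy: tuple = (2.2, -0.3, -1.2, -0.2, -0.8)
    acc_tau_c1: float = 0.3
    acc_tau_c2: float = 0.3
    n_responses: int = 33
    # transparency ratings (7-point scale)
    trans_noise_sd: float = 0.5
    trans_bounds: tuple = (1.0, 7.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.reversible_fraction <= 1.0:
            raise ValueError("reversible_fraction must be in [0, 1]")
        for name in ("compound_noise_sd", "rare_noise_sd", "rating_sigma", "rt_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    table: EmbeddingTable          # characters + observed compound vectors
    lexicon: CompoundLexicon
    truth_weights: CompositionWeights
    true_proximities: pd.DataFrame  # caoss proximities under W*
    transparency_ratings: dict[str, tuple[float, float]]
    behaviour: dict[str, pd.DataFrame]  # "rating" | "rt" | "accuracy"
    truth: dict                     # serializable ground-truth record


def gen_weights(config: SyntheticConfig, rng: np.random.Generator) -> CompositionWeights:
    """Ground-truth W* = alpha*I + gamma*G, independent G per position."""
    d = config.d
    w1 = config.weight_alpha * np.eye(d) + config.weight_gamma * rng.standard_normal((d, d))
    w2 = config.weight_alpha * np.eye(d) + config.weight_gamma * rng.standard_normal((d, d))
    return CompositionWeights(w1=w1, w2=w2, ridge_lambda=0.0, n_train=0,
                              mean_sq_reconstruction_error=0.0, seed=config.seed)


def gen_characters(config: SyntheticConfig, rng: np.random.Generator | None = None) -> EmbeddingTable:
    """n_characters i.i.d. unit-norm spherical vectors, tokens c0001..."""
    if config.d < 2:
        raise ValueError("d must be >= 2 for spherical character vectors")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vecs = rng.standard_normal((config.n_characters, config.d))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    entries = {f"c{i + 1:04d}": vecs[i] for i in range(config.n_characters)}
    return EmbeddingTable(dimension=config.d, entries=entries, source_label="synthetic")


def _sample_power_law_freqs(config: SyntheticConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    ks = np.arange(1, config.max_freq + 1, dtype=float)
    pmf = ks ** (-config.zipf_exponent)
    cdf = np.cumsum(pmf)
    cdf /= cdf[-1]
    return (np.searchsorted(cdf, rng.random(n)) + 1).astype(int)


def power_law_cdf(config: SyntheticConfig) -> np.ndarray:
    """CDF of the configured frequency law (for distribution checks)."""
    ks = np.arange(1, config.max_freq + 1, dtype=float)
    pmf = ks ** (-config.zipf_exponent)
    cdf = np.cumsum(pmf)
    return cdf / cdf[-1]


def gen_lexicon(
    config: SyntheticConfig,
    chars: EmbeddingTable,
    truth: CompositionWeights,
    rng: np.random.Generator,
) -> tuple[CompoundLexicon, EmbeddingTable, dict]:
    """Sample compound pairs, frequencies, and noisy observed compound vectors.

    A ``reversible_fraction`` of the compounds exist in both orders
    (AB and BA).  The returned table contains the character vectors
    plus the observed (noisy) compound vectors; the truth record stores
    which compounds are reversible and the per-compound noiseless
    vectors' construction parameters.
    """
    tokens = list(chars.entries.keys())
    n_chars = len(tokens)
    capacity = n_chars * (n_chars - 1)
    if config.n_compounds > capacity:
        raise ValueError(f"n_compounds={config.n_compounds} exceeds distinct-pair capacity {capacity}")

    n_rev = math.ceil(config.reversible_fraction * config.n_compounds)
    n_base = config.n_compounds - n_rev

    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    while len(pairs) < n_base:
        i, j = rng.integers(0, n_chars, size=2)
        if i == j:
            continue
        pair = (tokens[i], tokens[j])
        if pair in seen:
            continue
        seen.add(pair)
        pairs.append(pair)

    # add reverses of randomly chosen base pairs whose reverse is absent
    order = rng.permutation(n_base)
    reversible: list[tuple[str, str]] = []
    for idx in order:
        if len(reversible) == n_rev:
            break
        a, b = pairs[idx]
        if (b, a) not in seen:
            seen.add((b, a))
            reversible.append((b, a))
    if len(reversible) < n_rev:
        raise ValueError("could not place the requested number of reversible pairs")
    pairs.extend(reversible)

    word_freqs = _sample_power_law_freqs(config, len(pairs), rng)

    char_freq: dict[str, int] = {t: 0 for t in tokens}
    for (a, b), f in zip(pairs, word_freqs):
        char_freq[a] += int(f)
        char_freq[b] += int(f)

    table = EmbeddingTable(dimension=config.d, entries=dict(chars.entries),
                           source_label="synthetic+compounds")
    entries = []
    for (a, b), f in zip(pairs, word_freqs):
        v1, v2 = chars.entries[a], chars.entries[b]
        w = truth.w1 @ v1 + truth.w2 @ v2
        w = w + rng.normal(0.0, config.compound_noise_sd, size=config.d)
        if f < config.rare_freq_cutoff and config.rare_noise_sd > 0:
            w = w + rng.normal(0.0, config.rare_noise_sd, size=config.d)
        compound = a + b
        table.add(compound, w)
        entries.append(CompoundEntry(compound=compound, c1=a, c2=b, word_freq=int(f),
                                     c1_freq=char_freq[a], c2_freq=char_freq[b]))

    lexicon = CompoundLexicon(entries)
    truth_record = {
        "reversible_pairs": [[a + b, b + a] for (b, a) in reversible],
        "n_reversible": len(reversible),
    }
    return lexicon, table, truth_record


def gen_transparency_ratings(
    config: SyntheticConfig,
    lexicon: CompoundLexicon,
    chars: EmbeddingTable,
    truth: CompositionWeights,
    rng: np.random.Generator,
) -> dict[str, tuple[float, float]]:
    """Human-like transparency ratings on a 1-7 scale.

    Ratings are an affine map of the *noiseless* transparency — the
    cosine of the true composed vector with each raw character vector —
    plus Gaussian noise, clamped to the scale.  Because the rating
    reflects the noiseless geometry while the measured transparency uses
    the noisy observed compound vector, rare (extra-noisy) items degrade
    the model-human correlation, which is what the threshold calibration
    sweep detects.
    """
    lo, hi = config.trans_bounds
    mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    out: dict[str, tuple[float, float]] = {}
    for e in lexicon:
        v1, v2 = chars.entries[e.c1], chars.entries[e.c2]
        c_true = truth.w1 @ v1 + truth.w2 @ v2
        t1 = float(c_true @ v1 / (np.linalg.norm(c_true) * np.linalg.norm(v1)))
        t2 = float(c_true @ v2 / (np.linalg.norm(c_true) * np.linalg.norm(v2)))
        r1 = mid + half * t1 + rng.normal(0.0, config.trans_noise_sd)
        r2 = mid + half * t2 + rng.normal(0.0, config.trans_noise_sd)
        out[e.compound] = (float(np.clip(r1, lo, hi)), float(np.clip(r2, lo, hi)))
    return out


def _centered_predictors(
    lexicon: CompoundLexicon, prox_true: pd.DataFrame, include_word_freq: bool
) -> tuple[pd.DataFrame, np.ndarray]:
    prox = prox_true[prox_true["model"] == "caoss"].set_index("compound")
    rows = []
    for e in lexicon:
        p = prox.loc[e.compound]
        rows.append((e.compound, e.c1, e.c2,
                     math.log(lexicon.family_size(e.c1, 1)),
                     float(p["prox_c1"]),
                     math.log(lexicon.family_size(e.c2, 2)),
                     float(p["prox_c2"]),
                     e.word_freq))
    frame = pd.DataFrame(rows, columns=["item", "c1", "c2", "log_c1_fs", "prox_c1",
                                        "log_c2_fs", "prox_c2", "word_freq"])
    cols = ["log_c1_fs", "prox_c1", "log_c2_fs", "prox_c2"]
    Xc = frame[cols].to_numpy() - frame[cols].to_numpy().mean(axis=0)
    if include_word_freq:
        lwf = np.log(frame["word_freq"].to_numpy(dtype=float))
        Xc = np.column_stack([Xc, lwf - lwf.mean()])
    return frame, Xc


def _random_intercepts(
    frame: pd.DataFrame, tau1: float, tau2: float, rng: np.random.Generator
) -> np.ndarray:
    u1 = {c: rng.normal(0.0, tau1) for c in pd.unique(frame["c1"])}
    u2 = {c: rng.normal(0.0, tau2) for c in pd.unique(frame["c2"])}
    return np.array([u1[a] + u2[b] for a, b in zip(frame["c1"], frame["c2"])])


def gen_behaviour(
    config: SyntheticConfig,
    lexicon: CompoundLexicon,
    prox_true: pd.DataFrame,
    rng: np.random.Generator,
    include_word_freq: bool = False,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Item-level behavioural tables generated from the true proximities.

    Returns rating, RT and accuracy variants plus the ground-truth
    coefficients actually used.  ``include_word_freq`` adds a log
    word-frequency effect to the RT variant (existing-compound recipe).
    """
    frame, Xc = _centered_predictors(lexicon, prox_true, include_word_freq)
    n = len(frame)

    # --- sensibility ratings
    beta_r = np.asarray(config.beta_rating, dtype=float)
    eta_r = beta_r[0] + Xc[:, :4] @ beta_r[1:5]
    eta_r = eta_r + _random_intercepts(frame, config.rating_tau_c1, config.rating_tau_c2, rng)
    rating = eta_r + rng.normal(0.0, config.rating_sigma, size=n)
    rating = np.clip(rating, *config.rating_bounds)

    # --- response times (eta on the inverse-RT scale; RT = 1/max(eta, floor))
    beta_t = list(config.beta_rt)
    if include_word_freq:
        beta_t = beta_t + [config.beta_rt_word_freq]
    beta_t = np.asarray(beta_t, dtype=float)
    eta_t = beta_t[0] + Xc @ beta_t[1:]
    eta_t = eta_t + _random_intercepts(frame, config.rt_tau_c1, config.rt_tau_c2, rng)
    eta_t = eta_t + rng.normal(0.0, config.rt_sigma, size=n)
    n_floored = int(np.sum(eta_t < config.rt_eta_floor))
    if n_floored:
        logger.info("gen_behaviour: clamped %d RT linear predictor(s) at the floor", n_floored)
    rt = 1.0 / np.maximum(eta_t, config.rt_eta_floor)

    # --- accuracy (binomial over n_responses, logistic link)
    beta_a = np.asarray(config.beta_accuracy, dtype=float)
    eta_a = beta_a[0] + Xc[:, :4] @ beta_a[1:5]
    eta_a = eta_a + _random_intercepts(frame, config.acc_tau_c1, config.acc_tau_c2, rng)
    p_correct = 1.0 / (1.0 + np.exp(-eta_a))
    k_correct = rng.binomial(config.n_responses, p_correct)
    accuracy = k_correct / config.n_responses

    base = frame[["item", "c1", "c2", "word_freq"]]
    tables = {
        "rating": base.assign(dv_kind="rating", dv=rating, n_responses=config.n_raters),
        "rt": base.assign(dv_kind="rt", dv=rt, n_responses=config.n_responses,
                          accuracy=accuracy),
        "accuracy": base.assign(dv_kind="accuracy", dv=accuracy,
                                n_responses=config.n_responses),
    }
    truth = {
        "beta_rating": beta_r.tolist(),
        "beta_rt": beta_t.tolist(),
        "beta_accuracy": beta_a.tolist(),
        "rating_tau": [config.rating_tau_c1, config.rating_tau_c2],
        "rt_tau": [config.rt_tau_c1, config.rt_tau_c2],
        "rating_sigma": config.rating_sigma,
        "rt_sigma": config.rt_sigma,
        "n_rt_floored": n_floored,
        "include_word_freq": include_word_freq,
    }
    return tables, truth


def gen_rating_matrix(
    config: SyntheticConfig,
    lexicon: CompoundLexicon,
    prox_true: pd.DataFrame,
    rng: np.random.Generator,
    n_items: int | None = None,
) -> np.ndarray:
    """Participant-level rating matrix (items x raters) for ICC checks.

    Each rater adds an idiosyncratic intercept (sd ``rater_sd``) plus
    trial noise on top of the item's latent sensibility.
    """
    frame, Xc = _centered_predictors(lexicon, prox_true, include_word_freq=False)
    beta_r = np.asarray(config.beta_rating, dtype=float)
    eta = beta_r[0] + Xc[:, :4] @ beta_r[1:5]
    eta = eta + _random_intercepts(frame, config.rating_tau_c1, config.rating_tau_c2, rng)
    if n_items is not None:
        eta = eta[:n_items]
    b = rng.normal(0.0, config.rater_sd, size=config.n_raters)
    noise = rng.normal(0.0, config.rating_sigma, size=(len(eta), config.n_raters))
    return np.clip(eta[:, None] + b[None, :] + noise, *config.rating_bounds)


def generate_dataset(config: SyntheticConfig, include_word_freq: bool = False) -> SyntheticDataset:
    """End-to-end generation from a single seeded RNG chain."""
    rng = np.random.default_rng(config.seed)
    truth_w = gen_weights(config, rng)
    chars = gen_characters(config, rng)
    lexicon, table, truth_record = gen_lexicon(config, chars, truth_w, rng)
    prox_true = score_proximities(lexicon, chars, weights=truth_w, models=("caoss",))
    trans = gen_transparency_ratings(config, lexicon, chars, truth_w, rng)
    behaviour, truth_b = gen_behaviour(config, lexicon, prox_true, rng,
                                       include_word_freq=include_word_freq)
    truth = {
        "config": asdict(config),
        "w1": truth_w.w1.tolist(),
        "w2": truth_w.w2.tolist(),
        **truth_record,
        **truth_b,
    }
    return SyntheticDataset(
        config=config, table=table, lexicon=lexicon, truth_weights=truth_w,
        true_proximities=prox_true, transparency_ratings=trans,
        behaviour=behaviour, truth=truth,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Serialize a dataset bundle as plain text (word2vec text, TSV, JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_embeddings(ds.table, out / "embeddings.w2v.txt")
    write_lexicon(ds.lexicon, out / "lexicon.tsv")
    trans = pd.DataFrame(
        [(k, v[0], v[1]) for k, v in ds.transparency_ratings.items()],
        columns=["compound", "rating_c1", "rating_c2"],
    )
    trans.to_csv(out / "transparency_ratings.tsv", sep="\t", index=False)
    for name, frame in ds.behaviour.items():
        frame.to_csv(out / f"behaviour_{name}.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(ds.truth, fh, sort_keys=True)
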