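"""Position-specific matrix composition (CAOSS) and the additive baseline.

The CAOSS model represents a two-character compound as

    c = W1 @ v1 + W2 @ v2,

where v1, v2 are the embedding vectors of the standalone characters and
W1, W2 are d-by-d weight matrices specific to first and second position.
The matrices are estimated by penalized least squares against the
observed whole-compound vectors: stacking x_i = [v1_i; v2_i] in R^{2d},
we solve

    min_B  sum_i || w_i - B^T x_i ||^2  +  lambda ||B||_F^2,

with B in R^{2d x d}; W1 and W2 are the transposed top and bottom d-row
blocks of B.  With lambda = 0 and a rank-deficient design the
minimum-norm (pseudoinverse) solution is returned.  The additive
baseline is simply c = v1 + v2, blind to position — it assigns reversed
compounds (AB vs BA) identical meanings, which is exactly what the
position-specific model is there to fix.

Proximity is the cosine similarity between the composed compound vector
and the (transformed) constituent vectors; transparency is the cosine
between the *observed* whole-word vector and the raw constituent
vectors.  ``threshold_sweep`` reruns the transparency-vs-human-rating
correlation under a grid of frequency exclusion thresholds, the
calibration used to pick the training-set frequency cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .embeddings import DegenerateVectorError, EmbeddingTable, cosine
from .lexicon import CompoundEntry, CompoundLexicon, apply_frequency_filter

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionWeights",
    "ProximityRecord",
    "train_caoss",
    "compose_caoss",
    "compose_additive",
    "proximity",
    "score_proximities",
    "transparency",
    "threshold_sweep",
    "save_weights",
    "load_weights",
]

LAMBDA_GRID = (0.0, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0, 1000.0)


@dataclass
class CompositionWeights:
    """Estimated position-specific matrices plus fit provenance."""

    w1: np.ndarray
    w2: np.ndarray
    ridge_lambda: float
    n_train: int
    mean_sq_reconstruction_error: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        d = self.w1.shape[0]
        if self.w1.shape != (d, d) or self.w2.shape != (d, d):
            raise ValueError(f"W1/W2 must be square with shared d; got {self.w1.shape}, {self.w2.shape}")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")

    @property
    def d(self) -> int:
        return self.w1.shape[0]


@dataclass(frozen=True)
class ProximityRecord:
    compound: str
    model: str  # "caoss" | "additive"
    prox_c1: float
    prox_c2: float

    def __post_init__(self) -> None:
        for v in (self.prox_c1, self.prox_c2):
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"proximity {v} outside [-1, 1]")


def _training_arrays(
    lexicon: CompoundLexicon, table: EmbeddingTable
) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack design X = [v1; v2] and target W rows, skipping items missing any vector."""
    xs, ws, skipped = [], [], 0
    for e in lexicon:
        v1, v2, w = table.lookup(e.c1), table.lookup(e.c2), table.lookup(e.compound)
        if v1 is None or v2 is None or w is None:
            skipped += 1
            continue
        xs.append(np.concatenate([v1, v2]))
        ws.append(w)
    if skipped:
        logger.info("training: skipped %d item(s) lacking a vector", skipped)
    if not xs:
        raise ValueError("no trainable items: every entry lacked a vector")
    return np.asarray(xs), np.asarray(ws), skipped


def _solve(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Solve min_B ||Y - X B||_F^2 + lam ||B||_F^2 (min-norm when lam=0)."""
    if lam == 0.0:
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        return B
    k = X.shape[1]
    return np.linalg.solve(X.T @ X + lam * np.eye(k), X.T @ Y)


def _cv_lambda(X: np.ndarray, Y: np.ndarray, seed: int, n_folds: int = 5) -> float:
    """Pick lambda from LAMBDA_GRID by k-fold cross-validated reconstruction MSE."""
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, min(n_folds, n))
    best_lam, best_err = 0.0, np.inf
    for lam in LAMBDA_GRID:
        err = 0.0
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            if mask.sum() == 0:
                continue
            B = _solve(X[mask], Y[mask], lam)
            resid = Y[fold] - X[fold] @ B
            err += float(np.mean(resid**2)) * len(fold)
        err /= n
        if err < best_err:
            best_lam, best_err = lam, err
    return best_lam


def train_caoss(
    lexicon: CompoundLexicon,
    table: EmbeddingTable,
    ridge_lambda: float | str = 0.0,
    seed: int = 0,
) -> CompositionWeights:
    """Estimate W1, W2 from (c1, c2, compound) vector triples.

    ``ridge_lambda`` may be a nonnegative float or ``"auto"``, which
    selects the penalty by 5-fold cross-validated reconstruction error
    over a fixed log grid (seeded shuffle, so reproducible).
    """
    X, Y, _ = _training_arrays(lexicon, table)
    d = table.dimension
    if X.shape[1] != 2 * d:
        raise ValueError("design width != 2d")

    if ridge_lambda == "auto":
        lam = _cv_lambda(X, Y, seed=seed)
        logger.info("cross-validated ridge penalty: lambda=%g", lam)
    else:
        lam = float(ridge_lambda)
        if lam < 0:
            raise ValueError("ridge_lambda must be >= 0")

    B = _solve(X, Y, lam)
    msre = float(np.mean((Y - X @ B) ** 2))
    return CompositionWeights(
        w1=B[:d].T, w2=B[d:].T, ridge_lambda=lam, n_train=X.shape[0],
        mean_sq_reconstruction_error=msre, seed=seed,
    )


def compose_caoss(weights: CompositionWeights, v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """c = W1 @ v1 + W2 @ v2."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != (weights.d,) or v2.shape != (weights.d,):
        raise ValueError(f"constituent vectors must have length d={weights.d}")
    return weights.w1 @ v1 + weights.w2 @ v2


def compose_additive(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """c = v1 + v2 (position-blind baseline)."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(f"shape mismatch: {v1.shape} vs {v2.shape}")
    return v1 + v2


def proximity(
    model: str,
    v1: np.ndarray,
    v2: np.ndarray,
    weights: CompositionWeights | None = None,
    compound: str = "",
) -> ProximityRecord:
    """Cosine of the composed compound vector with each (transformed) constituent.

    For the position-specific model the constituents are compared after
    transformation (W1 v1, W2 v2); for the additive baseline they are
    compared raw.  A zero-norm composed or transformed vector raises
    :class:`DegenerateVectorError`.
    """
    if model == "caoss":
        if weights is None:
            raise ValueError("caoss proximity requires trained weights")
        t1, t2 = weights.w1 @ np.asarray(v1, float), weights.w2 @ np.asarray(v2, float)
        c = t1 + t2
    elif model == "additive":
        t1, t2 = np.asarray(v1, float), np.asarray(v2, float)
        c = compose_additive(t1, t2)
    else:
        raise ValueError(f"model must be 'caoss' or 'additive', got {model!r}")
    return ProximityRecord(compound=compound, model=model,
                           prox_c1=cosine(c, t1), prox_c2=cosine(c, t2))


def score_proximities(
    lexicon: CompoundLexicon,
    table: EmbeddingTable,
    weights: CompositionWeights | None = None,
    models: tuple[str, ...] = ("caoss", "additive"),
) -> pd.DataFrame:
    """Batch proximity scoring over a lexicon.

    Items lacking a constituent vector, or hitting a degenerate-vector
    condition, are skipped with a logged count.  Returns a long-format
    frame with columns compound, model, prox_c1, prox_c2.
    """
    rows, skipped = [], 0
    for e in lexicon:
        v1, v2 = table.lookup(e.c1), table.lookup(e.c2)
        if v1 is None or v2 is None:
            skipped += 1
            continue
        for model in models:
            try:
                rec = proximity(model, v1, v2, weights=weights, compound=e.compound)
            except DegenerateVectorError:
                skipped += 1
                continue
            rows.append((rec.compound, rec.model, rec.prox_c1, rec.prox_c2))
    if skipped:
        logger.info("proximity scoring: skipped %d record(s)", skipped)
    return pd.DataFrame(rows, columns=["compound", "model", "prox_c1", "prox_c2"])


def transparency(table: EmbeddingTable, entry: CompoundEntry) -> tuple[float, float] | None:
    """Cosine of the *observed* whole-word vector with each raw constituent vector.

    Returns ``None`` (missing-marker) when any of the three vectors is
    absent from the table.
    """
    w = table.lookup(entry.compound)
    v1 = table.lookup(entry.c1)
    v2 = table.lookup(entry.c2)
    if w is None or v1 is None or v2 is None:
        logger.info("transparency: missing vector for %r", entry.compound)
        return None
    return cosine(w, v1), cosine(w, v2)


def threshold_sweep(
    lexicon: CompoundLexicon,
    table: EmbeddingTable,
    human_ratings: dict[str, tuple[float, float]],
    thresholds: list[int],
) -> pd.DataFrame:
    """Transparency-vs-rating calibration across frequency thresholds.

    For each threshold, the lexicon is filtered (keep frequency >
    threshold), model transparency is computed per surviving rated item,
    and Spearman's rho between model transparency and human rating is
    reported per constituent, with the surviving item count.  Rows with
    fewer than 3 usable items report rho as NaN.
    """
    rows = []
    for thr in thresholds:
        filtered, _ = apply_frequency_filter(lexicon, thr)
        t1s, t2s, r1s, r2s = [], [], [], []
        for e in filtered:
            if e.compound not in human_ratings:
                continue
            t = transparency(table, e)
            if t is None:
                continue
            r1, r2 = human_ratings[e.compound]
            t1s.append(t[0]); t2s.append(t[1]); r1s.append(r1); r2s.append(r2)
        n = len(t1s)
        if n < 3:
            rho1 = rho2 = float("nan")
        else:
            rho1 = float(stats.spearmanr(t1s, r1s).statistic)
            rho2 = float(stats.spearmanr(t2s, r2s).statistic)
        rows.append((thr, n, rho1, rho2))
    return pd.DataFrame(rows, columns=["criterion", "n_observations", "rho_c1", "rho_c2"])


def save_weights(weights: CompositionWeights, path: str | Path, precision: int = 10) -> None:
    """Delimited-text export: header ``d=<d> lambda=<lam>``, then d rows of W1, d rows of W2."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"d={weights.d} lambda={weights.ridge_lambda!r}\n")
        for mat in (weights.w1, weights.w2):
            for row in mat:
                fh.write(" ".join(format(x, f".{precision}g") for x in row) + "\n")


def load_weights(path: str | Path) -> CompositionWeights:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        d = int(header[0].split("=")[1])
        lam = float(header[1].split("=")[1])
        rows = [np.fromstring(line, sep=" ") for line in fh if line.strip()]
    if len(rows) != 2 * d:
        raise ValueError(f"{path}: expected {2*d} matrix rows, found {len(rows)}")
    w1 = np.vstack(rows[:d])
    w2 = np.vstack(rows[d:])
    return CompositionWeights(w1=w1, w2=w2, ridge_lambda=lam, n_train=0,
                              mean_sq_reconstruction_error=float("nan"))
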