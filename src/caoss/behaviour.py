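"""Behavioural analysis scheme: transforms, design prep, model comparison.

This module wraps the mixed-model engine into the analysis recipe used
for item-level compound reading data: a Box-Cox scan suggests the DV
transformation (response times land on the inverse transform, 1/RT in
seconds); predictors — log positional family size and the per-model
proximity measures, optionally log whole-word frequency for existing
words — are mean-centered; competing proximity measures are compared by
AIC of otherwise identical crossed-random-intercept models; ICC
quantifies inter-rater agreement on ratings; and an accuracy model with
the same design guards against speed-accuracy trade-offs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lexicon import CompoundLexicon
from .lmm import AnalysisResult, fit_lmm

logger = logging.getLogger(__name__)

__all__ = [
    "suggest_transform",
    "apply_transform",
    "prepare_design",
    "fit_lmm",
    "compare_models",
    "icc",
    "accuracy_filter",
    "empirical_logit",
    "speed_accuracy_check",
]

FIXED_EFFECT_ORDER = ["log_c1_fs", "prox_c1", "log_c2_fs", "prox_c2", "log_word_freq"]


# ---------------------------------------------------------------------------
# Transformation suggestion (Box-Cox)

@dataclass(frozen=True)
class TransformSuggestion:
    lambda_hat: float
    transform: str  # "none" | "log" | "inverse" | "boxcox"

    def __str__(self) -> str:
        return self.transform if self.transform != "boxcox" else f"boxcox({self.lambda_hat:.2f})"


def suggest_transform(y: np.ndarray, X: np.ndarray | None = None) -> TransformSuggestion:
    """Scan the Box-Cox profile likelihood on lambda in [-3, 3] (step 0.01).

    When a covariate matrix ``X`` is supplied the scan uses the original
    regression formulation — normality is profiled on the *residuals* of
    the transformed response given the predictors, not on its marginal
    distribution.  This matters whenever a strong covariate skews the
    marginal (e.g. word frequency and latencies): the marginal scan then
    reflects the covariate's distribution rather than the error law.
    Without ``X`` the scan reduces to the intercept-only (marginal) case.

    The maximizing lambda is mapped to a conventional transform when it
    sits near one: inverse for lambda ~ -1, log for lambda ~ 0, none for
    lambda ~ 1 (each within 0.25); otherwise the raw Box-Cox power is
    suggested.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 observations to suggest a transform")
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive data")
    n = y.size
    grid = np.arange(-3.0, 3.0 + 1e-9, 0.01)
    if X is None:
        llf = np.array([stats.boxcox_llf(lam, y) for lam in grid])
    else:
        X = np.column_stack([np.ones(n), np.asarray(X, dtype=float)])
        Q, _ = np.linalg.qr(X)
        log_y_sum = float(np.sum(np.log(y)))
        llf = np.empty(len(grid))
        for i, lam in enumerate(grid):
            z = np.log(y) if abs(lam) < 1e-12 else (y**lam - 1.0) / lam
            rss = float(z @ z - (Q.T @ z) @ (Q.T @ z))
            llf[i] = -0.5 * n * np.log(rss / n) + (lam - 1.0) * log_y_sum
    lam_hat = float(grid[int(np.argmax(llf))])
    if abs(lam_hat + 1.0) <= 0.25:
        name = "inverse"
    elif abs(lam_hat) <= 0.25:
        name = "log"
    elif abs(lam_hat - 1.0) <= 0.25:
        name = "none"
    else:
        name = "boxcox"
    return TransformSuggestion(lambda_hat=lam_hat, transform=name)


def apply_transform(y: np.ndarray, transform: str, lam: float | None = None) -> np.ndarray:
    """Apply a suggested transform; ``inverse`` is plain 1/y (y in seconds)."""
    y = np.asarray(y, dtype=float)
    if transform == "none":
        return y.copy()
    if transform == "log":
        return np.log(y)
    if transform == "inverse":
        return 1.0 / y
    if transform == "boxcox":
        if lam is None:
            raise ValueError("boxcox transform needs lambda")
        return (y**lam - 1.0) / lam if lam != 0 else np.log(y)
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# Design preparation

def prepare_design(
    items: pd.DataFrame,
    lexicon: CompoundLexicon,
    proximities: pd.DataFrame,
    model: str,
    include_word_freq: bool = False,
    transform: str = "none",
    lam: float | None = None,
    dv_col: str = "dv",
) -> pd.DataFrame:
    """Join items with proximity records and family sizes; center predictors.

    ``items`` must have columns item, c1, c2 and `dv_col` (plus
    word_freq when ``include_word_freq``).  Family sizes are taken from
    the supplied reference lexicon (normally the unfiltered corpus
    lexicon).  The DV is transformed per ``transform``; every fixed
    predictor is mean-centered so its column mean is numerically zero.
    Items that fail to join are dropped with a logged count.
    """
    prox = proximities[proximities["model"] == model]
    merged = items.merge(prox, left_on="item", right_on="compound", how="inner")
    n_dropped = len(items) - len(merged)
    if n_dropped:
        logger.info("prepare_design: dropped %d unjoinable item(s)", n_dropped)
    if merged.empty:
        raise ValueError("no items joined to proximity records")

    fs1 = np.array([lexicon.family_size(c, 1) for c in merged["c1"]], dtype=float)
    fs2 = np.array([lexicon.family_size(c, 2) for c in merged["c2"]], dtype=float)
    if np.any(fs1 <= 0) or np.any(fs2 <= 0):
        raise ValueError("zero family size as predictor (items must come from the lexicon)")

    out = pd.DataFrame({
        "item": merged["item"],
        "c1": merged["c1"],
        "c2": merged["c2"],
        "dv": apply_transform(merged[dv_col].to_numpy(dtype=float), transform, lam),
        "log_c1_fs": np.log(fs1),
        "prox_c1": merged["prox_c1"].to_numpy(dtype=float),
        "log_c2_fs": np.log(fs2),
        "prox_c2": merged["prox_c2"].to_numpy(dtype=float),
    })
    predictors = ["log_c1_fs", "prox_c1", "log_c2_fs", "prox_c2"]
    if include_word_freq:
        wf = merged["word_freq"].to_numpy(dtype=float)
        if np.any(wf <= 0):
            raise ValueError("nonpositive word frequency (apply the frequency filter first)")
        out["log_word_freq"] = np.log(wf)
        predictors.append("log_word_freq")
    for col in predictors:
        out[col] = out[col] - out[col].mean()
    # Under equal-norm embeddings the additive model's two proximities
    # coincide identically (cos(v1+v2, v1) = cos(v1+v2, v2)); a singular
    # design is useless, so the pair collapses into one shared predictor.
    p1, p2 = out["prox_c1"].to_numpy(), out["prox_c2"].to_numpy()
    if np.std(p1) > 0 and np.std(p2) > 0 and abs(np.corrcoef(p1, p2)[0, 1]) > 1 - 1e-9:
        logger.info("prepare_design(%s): prox_c1 and prox_c2 are collinear; "
                    "using a single shared proximity predictor", model)
        predictors = [c for c in predictors if c != "prox_c2"]
        out.attrs["collinear_proximities"] = True
    out.attrs["predictors"] = predictors
    out.attrs["transform"] = transform
    return out


def design_predictors(design: pd.DataFrame) -> list[str]:
    return list(design.attrs.get(
        "predictors",
        [c for c in FIXED_EFFECT_ORDER if c in design.columns],
    ))


# ---------------------------------------------------------------------------
# AIC model comparison

def compare_models(results: list[AnalysisResult]) -> pd.DataFrame:
    """Rank fits of the same DV on the same rows by AIC (ascending).

    Ties keep input order (stable sort).  Fits on different row counts
    are not comparable and raise.
    """
    if not results:
        raise ValueError("nothing to compare")
    ns = {r.n_items for r in results}
    if len(ns) > 1:
        raise ValueError(f"AIC comparison invalid across different row counts: {sorted(ns)}")
    frame = pd.DataFrame({
        "model": [r.model_label for r in results],
        "aic": [r.aic for r in results],
        "loglik": [r.loglik for r in results],
        "n_items": [r.n_items for r in results],
    })
    frame = frame.sort_values("aic", kind="stable").reset_index(drop=True)
    frame["delta_aic"] = frame["aic"] - frame["aic"].iloc[0]
    frame["winner"] = [i == 0 for i in range(len(frame))]
    return frame


# ---------------------------------------------------------------------------
# Intraclass correlation (McGraw & Wong ANOVA formulations)

def icc(
    ratings: np.ndarray,
    model: str = "twoway",
    type: str = "consistency",
    unit: str = "average",
) -> float:
    """ANOVA-based intraclass correlation for an items x raters matrix.

    Rows are items (targets), columns are raters.  Rows or columns with
    any missing value are dropped (listwise-complete submatrix).  The
    default variant — two-way random effects, consistency, average
    measures — matches analyses where per-item means over a fixed panel
    of raters are carried forward.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2:
        raise ValueError("ratings must be a 2-D items x raters matrix")
    # listwise completion: drop all-missing columns, then incomplete rows
    col_ok = ~np.all(np.isnan(R), axis=0)
    R = R[:, col_ok]
    row_ok = ~np.any(np.isnan(R), axis=1)
    R = R[row_ok]
    n, k = R.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 complete items and 2 raters")

    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((R - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    ms_within = (ss_cols + ss_err) / (n * (k - 1))

    if model == "oneway":
        if unit == "single":
            val = (ms_rows - ms_within) / (ms_rows + (k - 1) * ms_within)
        else:
            val = (ms_rows - ms_within) / ms_rows
    elif model == "twoway":
        if type == "consistency":
            if unit == "single":
                val = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
            else:
                val = (ms_rows - ms_err) / ms_rows
        elif type == "agreement":
            if unit == "single":
                val = (ms_rows - ms_err) / (
                    ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
                )
            else:
                val = (ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n)
        else:
            raise ValueError(f"type must be 'consistency' or 'agreement', got {type!r}")
    else:
        raise ValueError(f"model must be 'oneway' or 'twoway', got {model!r}")
    return float(val)


# ---------------------------------------------------------------------------
# Accuracy handling

def accuracy_filter(
    items: pd.DataFrame, threshold: float = 0.70, acc_col: str = "accuracy"
) -> tuple[pd.DataFrame, dict]:
    """Remove items whose across-participant accuracy is below threshold.

    The boundary is a strictly-less-than removal: items at exactly the
    threshold survive.
    """
    keep = items[acc_col].to_numpy(dtype=float) >= threshold
    surviving = items[keep].reset_index(drop=True)
    n_before, n_after = len(items), len(surviving)
    report = {
        "n_before": n_before,
        "n_after": n_after,
        "threshold": threshold,
        "drop_rate_percent": round(100.0 * (1.0 - n_after / n_before), 1) if n_before else 0.0,
    }
    logger.info("accuracy filter (<%.0f%% removed): %d -> %d items",
                100 * threshold, n_before, n_after)
    return surviving, report


def empirical_logit(accuracy: np.ndarray, n_responses: np.ndarray) -> np.ndarray:
    """log((k + 0.5) / (n - k + 0.5)) with k = accuracy * n per item."""
    acc = np.asarray(accuracy, dtype=float)
    n = np.asarray(n_responses, dtype=float)
    k = acc * n
    return np.log((k + 0.5) / (n - k + 0.5))


def speed_accuracy_check(
    rt_result: AnalysisResult,
    acc_result: AnalysisResult,
    t_threshold: float = 2.0,
    faster_sign: float = 1.0,
) -> dict:
    """Compare effect directions between a latency model and an accuracy model.

    Both fits must share the fixed-effect structure.  ``faster_sign``
    encodes the latency model's scale: +1 when a positive coefficient
    means *faster* responses (inverse-transformed RT, the default), -1
    when positive means slower (raw or log RT).  A positive accuracy
    coefficient means *more accurate*.  A trade-off is
    faster-and-less-accurate or slower-and-more-accurate, i.e. opposite
    effective signs; same signs are concordant ("no trade-off"); a
    predictor is inconclusive unless both |t| exceed ``t_threshold``.
    """
    shared = [fe.name for fe in rt_result.fixed_effects
              if fe.name != "intercept" and any(g.name == fe.name for g in acc_result.fixed_effects)]
    per_predictor = {}
    verdicts = []
    for name in shared:
        rt_fe = rt_result.effect(name)
        acc_fe = acc_result.effect(name)
        if abs(rt_fe.t) <= t_threshold or abs(acc_fe.t) <= t_threshold:
            status = "inconclusive"
        elif math.copysign(1, faster_sign * rt_fe.estimate) == math.copysign(1, acc_fe.estimate):
            status = "concordant"
        else:
            status = "trade-off"
        per_predictor[name] = {
            "rt_estimate": rt_fe.estimate, "rt_t": rt_fe.t,
            "accuracy_estimate": acc_fe.estimate, "accuracy_t": acc_fe.t,
            "status": status,
        }
        verdicts.append(status)
    if "trade-off" in verdicts:
        overall = "trade-off"
    elif "concordant" in verdicts:
        overall = "no trade-off"
    else:
        overall = "inconclusive"
    return {"per_predictor": per_predictor, "overall": overall}
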