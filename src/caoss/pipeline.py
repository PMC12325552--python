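"""End-to-end study recipes: filter -> train -> score -> transform -> fit -> compare.

A recipe takes an embedding table, a compound lexicon and one item-level
behavioural table, and produces the full analysis an individual study
reports: the frequency filter report, proximity scores under both
composition models, the suggested DV transform, per-model mixed-model
fits, the AIC comparison, the winning model's coefficient table, and
(for latency recipes) the accuracy concordance check.  Every stochastic
step draws from the single root seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour as bh
from .composition import score_proximities, train_caoss
from .embeddings import EmbeddingTable, load_embeddings
from .lexicon import CompoundLexicon, apply_frequency_filter, read_lexicon
from .lmm import AnalysisResult, fit_lmm

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_study", "report"]

RECIPES = ("sensibility", "novel_rejection", "existing_recognition")


@dataclass
class PipelineConfig:
    recipe: str
    embeddings_path: str | Path | None = None
    lexicon_path: str | Path | None = None
    behaviour_path: str | Path | None = None
    threshold: int = 10
    models: tuple[str, ...] = ("caoss", "additive")
    ridge_lambda: float | str = 0.0
    accuracy_threshold: float = 0.70
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.recipe not in RECIPES:
            raise ValueError(f"recipe must be one of {RECIPES}, got {self.recipe!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial results."""

    def __init__(self, stage: str, cause: Exception, partial: dict):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial = partial


def _log_stage(stage: str, n_in: int, n_out: int, t0: float) -> None:
    logger.info("stage=%s n_in=%d n_out=%d elapsed=%.2fs", stage, n_in, n_out, time.time() - t0)


def run_study(
    config: PipelineConfig,
    table: EmbeddingTable | None = None,
    lexicon: CompoundLexicon | None = None,
    items: pd.DataFrame | None = None,
) -> dict:
    """Execute one study recipe; returns (and optionally writes) the report bundle.

    Inputs may be passed in memory (synthetic bundles) or resolved from
    the config paths.  The bundle is a plain JSON-serializable dict so a
    rerun with the same seed is byte-identical on disk.
    """
    bundle: dict = {"recipe": config.recipe, "seed": config.seed,
                    "threshold": config.threshold, "exclusions": {}}
    stage = "load"
    try:
        t0 = time.time()
        if table is None:
            table = load_embeddings(config.embeddings_path)
        if lexicon is None:
            lexicon = read_lexicon(config.lexicon_path)
        if items is None:
            items = pd.read_csv(config.behaviour_path, sep="\t",
                                dtype={"item": str, "c1": str, "c2": str})
        n_input = len(items)
        _log_stage(stage, n_input, n_input, t0)

        # --- training-set frequency filter and model training
        stage = "train"
        t0 = time.time()
        filtered, filter_report = apply_frequency_filter(lexicon, config.threshold)
        weights = train_caoss(filtered, table, ridge_lambda=config.ridge_lambda,
                              seed=config.seed)
        bundle["filter_report"] = json.loads(filter_report.to_json())
        bundle["ridge_lambda"] = weights.ridge_lambda
        bundle["n_train"] = weights.n_train
        _log_stage(stage, len(lexicon), weights.n_train, t0)

        # --- proximity scoring for both composition models
        stage = "score"
        t0 = time.time()
        prox = score_proximities(lexicon, table, weights=weights, models=config.models)
        _log_stage(stage, len(lexicon), len(prox), t0)

        # --- item-level exclusions
        stage = "item_filter"
        t0 = time.time()
        if "accuracy" in items.columns and config.recipe != "sensibility":
            items, acc_report = bh.accuracy_filter(items, config.accuracy_threshold)
            bundle["exclusions"]["accuracy_filter"] = acc_report
        by_compound = {e.compound: e for e in lexicon}
        include_wf = config.recipe == "existing_recognition"

        def _freq_ok(item: str) -> bool:
            e = by_compound.get(item)
            if e is None:
                return False
            ok = e.c1_freq > config.threshold and e.c2_freq > config.threshold
            if include_wf:
                ok = ok and e.word_freq > config.threshold
            return ok

        n_before = len(items)
        items = items[items["item"].map(_freq_ok)].reset_index(drop=True)
        bundle["exclusions"]["frequency_filter"] = {"n_before": n_before, "n_after": len(items)}
        _log_stage(stage, n_before, len(items), t0)

        # --- DV transform suggestion (regression Box-Cox: residual normality
        # given the model's own predictors, not marginal normality)
        stage = "transform"
        dv_kind = str(items["dv_kind"].iloc[0]) if "dv_kind" in items.columns else "rating"
        probe = bh.prepare_design(items, lexicon, prox, model=config.models[0],
                                  include_word_freq=include_wf, transform="none")
        suggestion = bh.suggest_transform(
            probe["dv"].to_numpy(dtype=float),
            X=probe[bh.design_predictors(probe)].to_numpy(),
        )
        # when the scan does not land on a conventional transform (flat
        # profile at low residual CV), apply the conventional one for the
        # DV kind: inverse for latencies, identity otherwise
        if suggestion.transform == "boxcox":
            transform = "inverse" if dv_kind == "rt" else "none"
        else:
            transform = suggestion.transform
        bundle["transform"] = {"lambda_hat": suggestion.lambda_hat, "applied": transform,
                               "suggested": suggestion.transform, "dv_kind": dv_kind}

        # --- per-model design + fit
        stage = "fit"
        t0 = time.time()
        results: list[AnalysisResult] = []
        for model in config.models:
            design = bh.prepare_design(items, lexicon, prox, model=model,
                                       include_word_freq=include_wf, transform=transform)
            res = fit_lmm(design, "dv", bh.design_predictors(design),
                          groups=("c1", "c2"), model_label=model)
            results.append(res)
        comparison = bh.compare_models(results)
        winner_label = comparison["model"].iloc[0]
        winner = next(r for r in results if r.model_label == winner_label)
        bundle["aic_comparison"] = comparison.to_dict(orient="records")
        bundle["winner"] = winner.to_dict()
        bundle["fits"] = {r.model_label: r.to_dict() for r in results}
        _log_stage(stage, len(items), len(items), t0)

        # --- speed-accuracy concordance for latency recipes
        if config.recipe in ("novel_rejection", "existing_recognition") and "accuracy" in items.columns:
            stage = "speed_accuracy"
            acc_items = items.copy()
            acc_items["dv"] = bh.empirical_logit(
                acc_items["accuracy"].to_numpy(dtype=float),
                acc_items.get("n_responses", pd.Series(np.full(len(acc_items), 30))).to_numpy(dtype=float),
            )
            acc_design = bh.prepare_design(acc_items, lexicon, prox, model=winner_label,
                                           include_word_freq=include_wf, transform="none")
            acc_res = fit_lmm(acc_design, "dv", bh.design_predictors(acc_design),
                              groups=("c1", "c2"), model_label=f"{winner_label}-accuracy")
            faster_sign = 1.0 if transform == "inverse" else -1.0
            bundle["speed_accuracy"] = bh.speed_accuracy_check(winner, acc_res,
                                                               faster_sign=faster_sign)

        bundle["exclusions"]["bookkeeping"] = {
            "n_input": n_input,
            "n_analyzed": winner.n_items,
            "n_excluded": n_input - winner.n_items,
        }
    except Exception as exc:  # annotate with the failing stage
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc, bundle) from exc

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        prox.to_csv(out / "proximities.tsv", sep="\t", index=False)
        with open(out / f"{config.recipe}_summary.json", "w", encoding="utf-8") as fh:
            json.dump(bundle, fh, sort_keys=True, indent=1)
    return bundle


def report(bundle: dict) -> str:
    """Human-readable rendering: AIC table, then the winner's coefficient table."""
    lines = [f"Recipe: {bundle['recipe']} (n = {bundle['winner']['n_items']:,})", ""]
    lines.append("AIC comparison (smaller is better):")
    for row in bundle["aic_comparison"]:
        flag = "  <- selected" if row["winner"] else ""
        lines.append(f"  {row['model']:<10s} AIC = {row['aic']:.1f}  (dAIC = {row['delta_aic']:.1f}){flag}")
    lines.append("")
    lines.append(f"Coefficients ({bundle['winner']['model_label']} proximities):")
    header = f"  {'Predictor':<14s} {'Estimate':>9s} {'SE':>8s} {'t':>8s} {'p':>8s} {'Semipartial R2':>15s}"
    lines.append(header)
    for fe in bundle["winner"]["fixed_effects"]:
        p = "<.0001" if fe["p"] < 1e-4 else f"{fe['p']:.4f}"
        r2 = "-" if fe["semipartial_r2"] is None else f"{100 * fe['semipartial_r2']:.1f}%"
        lines.append(f"  {fe['name']:<14s} {fe['estimate']:>9.3f} {fe['se']:>8.3f} "
                     f"{fe['t']:>8.2f} {p:>8s} {r2:>15s}")
    if "speed_accuracy" in bundle:
        lines.append("")
        lines.append(f"Speed-accuracy check: {bundle['speed_accuracy']['overall']}")
    return "\n".join(lines)
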