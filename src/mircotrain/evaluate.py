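"""Confidence-based view combination, AUPRC, the repeated-split evaluation
harness and statistical comparisons between learning strategies.

The combined classifier accepts, for each instance, the predicted class of
whichever view is more confident, where a view's confidence in its own
prediction is ``|score - 0.5|``. For example, when the sequence view gives an
instance a 70% probability of being a miRNA while the expression view gives
it a 60% probability of *not* being one, the combined prediction is miRNA.
The winning view's positive-class score is used as the combined ranking
score for precision-recall analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

from .datatypes import NEGATIVE, POSITIVE, SplitSpec, ViewDataset
from .cotrain import (
    ClassifierFactory,
    CoTrainConfig,
    TrainingTrace,
    ViewState,
    default_classifier_factory,
    run_cotraining,
    run_passive,
    run_selftraining,
)
from .io import split_and_seed

STRATEGIES = ("no-learning", "passive", "self-training", "co-training")


@dataclass(frozen=True)
class PredictionPair:
    """The two views' positive-class scores for one instance."""

    instance_id: str
    score_seq: float
    score_expr: float

    def __post_init__(self) -> None:
        for name in ("score_seq", "score_expr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def combine_predictions(
    pair: PredictionPair, tie_break: str = "expr"
) -> tuple[int, float]:
    """Accept the more confident view's prediction.

    Confidence is ``|score - 0.5|``; a confidence tie goes to the view named
    by ``tie_break`` (default: expression, empirically the stronger view on
    most datasets). Returns ``(predicted_class, combined_score)`` where the
    combined score is the winning view's positive-class probability (so
    positives rank above negatives in a PR sweep); a score of exactly 0.5
    counts as positive.
    """
    if tie_break not in ("seq", "expr"):
        raise ValueError("tie_break must be 'seq' or 'expr'")
    conf_seq = abs(pair.score_seq - 0.5)
    conf_expr = abs(pair.score_expr - 0.5)
    if conf_seq == conf_expr:
        winner = pair.score_expr if tie_break == "expr" else pair.score_seq
    elif conf_seq > conf_expr:
        winner = pair.score_seq
    else:
        winner = pair.score_expr
    predicted = POSITIVE if winner >= 0.5 else NEGATIVE
    return predicted, winner


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall step curve.

    Computed by a descending-score threshold sweep with tied scores grouped
    (the average-precision step sum). Requires at least one positive and one
    negative label.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels == POSITIVE
    if not pos.any() or pos.all():
        raise ValueError("auprc requires both classes in the labels")
    value = float(average_precision_score(pos.astype(int), scores))
    return min(1.0, max(0.0, value))  # guard 1-ulp float spill


# ---------------------------------------------------------------------------
# repeated-split experiment harness
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """AUPRC table over repetitions x strategies x views.

    ``frame`` columns: repetition, strategy, view, auprc. The combined
    classifier appears as view ``"combined"`` under strategy
    ``"co-training"``. ``audit`` columns: repetition, strategy, view,
    n_transfers, n_incorrect (hidden-truth mislabel counts from the traces).
    """

    frame: pd.DataFrame
    audit: pd.DataFrame
    skipped: list[int] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean +/- sd AUPRC per (strategy, view)."""
        return (
            self.frame.groupby(["strategy", "view"])["auprc"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )

    def mean_auprc(self, strategy: str, view: str) -> float:
        sel = self.frame[
            (self.frame.strategy == strategy) & (self.frame.view == view)
        ]
        return float(sel["auprc"].mean())

    def paired(self, strategy_a: str, strategy_b: str, view: str) -> tuple[np.ndarray, np.ndarray]:
        """AUPRC vectors of two strategies on one view, paired by repetition."""
        piv = self.frame[self.frame.view == view].pivot(
            index="repetition", columns="strategy", values="auprc"
        )
        piv = piv.dropna(subset=[strategy_a, strategy_b])
        return piv[strategy_a].to_numpy(), piv[strategy_b].to_numpy()


def _combined_auprc(
    models: dict,
    holdout_views: dict[str, ViewDataset],
    view_names: tuple[str, str],
) -> float:
    name_a, name_b = view_names
    hold_a, hold_b = holdout_views[name_a], holdout_views[name_b]
    scores_a = models[name_a].score(hold_a.values)
    scores_b = models[name_b].score(hold_b.values)
    combined = [
        combine_predictions(
            PredictionPair(instance_id=iid, score_seq=float(sa), score_expr=float(sb))
        )[1]
        for iid, sa, sb in zip(hold_a.instance_ids, scores_a, scores_b)
    ]
    return auprc(np.array(combined), hold_a.labels)


def run_experiment(
    dataset_seq: ViewDataset,
    dataset_expr: ViewDataset,
    n_reps: int = 100,
    config: Optional[CoTrainConfig] = None,
    split: Optional[SplitSpec] = None,
    classifier_factory: ClassifierFactory = default_classifier_factory,
    view_names: tuple[str, str] = ("seq", "expr"),
    strategies: Sequence[str] = STRATEGIES,
) -> ExperimentResult:
    """Repeated-split evaluation of all learning strategies.

    Each repetition draws a fresh stratified holdout/seed/pool split (both
    views aligned on instance ids), runs the requested strategies, and
    records each view's final holdout AUPRC plus the combined classifier's.
    Deterministic given ``config.rng_seed`` (the master seed). Repetitions
    where a split cannot be formed (class scarcity) are recorded in
    ``skipped`` and excluded from the table.
    """
    config = config or CoTrainConfig()
    split = split or SplitSpec()
    if dataset_seq.instance_ids != dataset_expr.instance_ids:
        raise ValueError("the two views must cover identical instances, in order")
    if dataset_seq.labels is None or dataset_expr.labels is None:
        raise ValueError("both views must be labelled")
    if not np.array_equal(dataset_seq.labels, dataset_expr.labels):
        raise ValueError("the two views disagree on labels")

    master = np.random.default_rng(config.rng_seed)
    rep_seeds = master.integers(2**31, size=n_reps)

    rows: list[dict] = []
    audit_rows: list[dict] = []
    skipped: list[int] = []
    name_a, name_b = view_names

    for rep in range(n_reps):
        rep_seed = int(rep_seeds[rep])
        rep_split = replace(split, rng_seed=rep_seed)
        rep_config = replace(config, rng_seed=rep_seed)
        try:
            seed_a, pool_a, hold_a = split_and_seed(dataset_seq, rep_split)
            seed_b, pool_b, hold_b = split_and_seed(dataset_expr, rep_split)
        except ValueError:
            skipped.append(rep)
            continue
        holdouts = {name_a: hold_a, name_b: hold_b}

        def fresh_views() -> tuple[ViewState, ViewState]:
            return (
                ViewState(name_a, seed_a.subset(seed_a.instance_ids), pool_a.subset(pool_a.instance_ids)),
                ViewState(name_b, seed_b.subset(seed_b.instance_ids), pool_b.subset(pool_b.instance_ids)),
            )

        def record(strategy: str, view: str, value: float) -> None:
            rows.append(
                {"repetition": rep, "strategy": strategy, "view": view, "auprc": value}
            )

        def record_audit(strategy: str, trace: TrainingTrace, views: Sequence[str]) -> None:
            for v in views:
                n_tr = sum(1 for t in trace.transfers if t.view == v)
                audit_rows.append(
                    {
                        "repetition": rep,
                        "strategy": strategy,
                        "view": v,
                        "n_transfers": n_tr,
                        "n_incorrect": trace.n_incorrect(v),
                    }
                )

        if "no-learning" in strategies:
            va, vb = fresh_views()
            none_cfg = replace(rep_config, iterations=0)
            _, trace0 = run_cotraining(
                va, vb, (hold_a, hold_b), none_cfg, classifier_factory
            )
            record("no-learning", name_a, trace0.auprc[name_a][-1])
            record("no-learning", name_b, trace0.auprc[name_b][-1])

        if "passive" in strategies:
            va, vb = fresh_views()
            _, trace_p = run_passive(
                va, vb, (hold_a, hold_b), rep_config, classifier_factory
            )
            record("passive", name_a, trace_p.auprc[name_a][-1])
            record("passive", name_b, trace_p.auprc[name_b][-1])
            record_audit("passive", trace_p, [name_a, name_b])

        if "self-training" in strategies:
            for state, hold, name in zip(fresh_views(), (hold_a, hold_b), view_names):
                _, trace_s = run_selftraining(state, hold, rep_config, classifier_factory)
                record("self-training", name, trace_s.auprc[name][-1])
                record_audit("self-training", trace_s, [name])

        if "co-training" in strategies:
            va, vb = fresh_views()
            models, trace_c = run_cotraining(
                va, vb, (hold_a, hold_b), rep_config, classifier_factory
            )
            record("co-training", name_a, trace_c.auprc[name_a][-1])
            record("co-training", name_b, trace_c.auprc[name_b][-1])
            record_audit("co-training", trace_c, [name_a, name_b])
            record(
                "co-training",
                "combined",
                _combined_auprc(models, holdouts, view_names),
            )

    return ExperimentResult(
        frame=pd.DataFrame(rows),
        audit=pd.DataFrame(audit_rows),
        skipped=skipped,
        metadata={
            "n_reps": n_reps,
            "rng_seed": config.rng_seed,
            "iterations": config.iterations,
            "view_names": list(view_names),
        },
    )


# ---------------------------------------------------------------------------
# statistical comparisons
# ---------------------------------------------------------------------------

def compare_methods(
    result: ExperimentResult,
    alpha: float = 0.01,
    reference: str = "co-training",
) -> dict:
    """ANOVA + Tukey HSD across strategies, paired t of combined vs views.

    Per view: a one-way ANOVA over the final AUPRCs of all strategies,
    followed by Tukey HSD contrasts of the reference strategy against each
    other strategy at significance level ``alpha``. The combined classifier
    is compared with each single view by a paired t-test, paired by
    repetition. Zero-variance degenerate cases are flagged instead of
    raising.
    """
    report: dict = {"alpha": alpha, "views": {}, "combined_vs_view": {}}
    frame = result.frame
    views = [v for v in frame["view"].unique() if v != "combined"]
    for view in views:
        sub = frame[frame.view == view]
        strategies = sorted(sub["strategy"].unique())
        groups = [
            sub[sub.strategy == s]["auprc"].to_numpy() for s in strategies
        ]
        entry: dict = {"strategies": strategies}
        flat = np.concatenate(groups)
        if np.allclose(flat, flat[0]):
            entry.update({"F": 0.0, "p": 1.0, "degenerate": True, "tukey": {}})
        else:
            f_stat, p_val = stats.f_oneway(*groups)
            tukey = stats.tukey_hsd(*groups)
            ref_idx = strategies.index(reference)
            pairwise = {}
            for j, strat in enumerate(strategies):
                if strat == reference:
                    continue
                p_pair = float(tukey.pvalue[ref_idx, j])
                pairwise[strat] = {
                    "p": p_pair,
                    "significant": bool(p_pair < alpha),
                }
            entry.update(
                {
                    "F": float(f_stat),
                    "p": float(p_val),
                    "degenerate": False,
                    "tukey": pairwise,
                }
            )
        report["views"][view] = entry

    combined = frame[(frame.view == "combined")]
    if not combined.empty:
        for view in views:
            piv = frame[frame.strategy == "co-training"].pivot(
                index="repetition", columns="view", values="auprc"
            )
            piv = piv.dropna(subset=["combined", view])
            diffs = piv["combined"].to_numpy() - piv[view].to_numpy()
            if np.allclose(diffs, 0.0):
                report["combined_vs_view"][view] = {
                    "t": 0.0, "p": 1.0, "degenerate": True, "significant": False,
                }
            else:
                t_stat, p_val = stats.ttest_rel(
                    piv["combined"].to_numpy(), piv[view].to_numpy()
                )
                report["combined_vs_view"][view] = {
                    "t": float(t_stat),
                    "p": float(p_val),
                    "degenerate": False,
                    "significant": bool(p_val < alpha),
                }
    return report
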