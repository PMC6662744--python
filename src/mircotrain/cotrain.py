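"""Iterative learning strategies over two views of one instance universe.

Four strategies are implemented over a pluggable probabilistic classifier
(default: a 500-tree random forest):

* **co-training** — each view's classifier scores its own unlabelled pool;
  the single most confident positive and negative predictions are removed
  from *both* views' pools and appended, with the donor's predicted labels,
  to the *other* view's training set;
* **self-training** — a single view feeds its own most confident predictions
  back into its own training set;
* **passive learning** — a control for training-set size: one instance is
  drawn uniformly from the >50%-score stratum (labelled positive) and one
  from the <50% stratum (labelled negative) per view per iteration, and
  transferred cross-view;
* **no learning** — the classifier trained on the seed set only
  (equivalently, any strategy with ``iterations=0``).

Removing transfers from both pools is an interpretation: it prevents an
instance from simultaneously serving as training data for one view and
unlabelled data for the other, and rules out label ping-pong.

Every run records a :class:`TrainingTrace` — per-iteration transferred ids,
assigned labels, donor confidences, hidden-truth correctness flags (when the
pool carries audited true labels) and the per-view holdout AUPRC learning
curve. Runs are deterministic given ``CoTrainConfig.rng_seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .datatypes import NEGATIVE, POSITIVE, UNLABELLED, ViewDataset


class ProbabilisticClassifier(Protocol):
    """Contract for the pluggable classifier: fit + positive-class scores."""

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "ProbabilisticClassifier": ...

    def score(self, features: np.ndarray) -> np.ndarray: ...


class ForestClassifier:
    """Default classifier: random forest with 500 trees."""

    def __init__(self, n_estimators: int = 500, random_state: int = 0):
        self._clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=random_state, n_jobs=1
        )

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "ForestClassifier":
        if len(set(labels.tolist())) < 2:
            raise ValueError("training set must contain both classes")
        self._clf.fit(features, labels)
        return self

    def score(self, features: np.ndarray) -> np.ndarray:
        pos_col = list(self._clf.classes_).index(POSITIVE)
        return self._clf.predict_proba(features)[:, pos_col]


ClassifierFactory = Callable[[int], ProbabilisticClassifier]


def default_classifier_factory(random_state: int) -> ForestClassifier:
    return ForestClassifier(n_estimators=500, random_state=random_state)


def make_forest_factory(n_estimators: int) -> ClassifierFactory:
    return lambda random_state: ForestClassifier(
        n_estimators=n_estimators, random_state=random_state
    )


@dataclass
class ViewState:
    """One view's evolving labelled train set, unlabelled pool and model."""

    view_name: str
    train: ViewDataset
    pool: ViewDataset
    model: Optional[ProbabilisticClassifier] = None

    def __post_init__(self) -> None:
        overlap = set(self.train.instance_ids) & set(self.pool.instance_ids)
        if overlap:
            raise ValueError(f"train/pool overlap in view {self.view_name!r}: {sorted(overlap)[:3]}")
        if self.train.labels is None or not np.isin(
            self.train.labels, [POSITIVE, NEGATIVE]
        ).all():
            raise ValueError(f"view {self.view_name!r}: train labels must be positive/negative")


@dataclass(frozen=True)
class CoTrainConfig:
    """Iteration budget, stopping rule and randomness for a learning run.

    ``iterations`` defaults to 11 (with 1 positive + 1 negative transferred
    per view per iteration). ``stop_rule`` is ``"fixed"`` or ``"plateau"``;
    the plateau rule stops once the per-step AUPRC gain over the last
    ``plateau_window`` iterations stays below ``plateau_epsilon`` for every
    view.
    """

    iterations: int = 11
    rng_seed: int = 0
    stop_rule: str = "fixed"
    plateau_window: int = 2
    plateau_epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.stop_rule not in ("fixed", "plateau"):
            raise ValueError("stop_rule must be 'fixed' or 'plateau'")


@dataclass(frozen=True)
class TransferRecord:
    iteration: int
    view: str  # donor view
    transferred_id: str
    assigned_label: int
    confidence: float
    correct: Optional[bool]
    fallback: bool = False


@dataclass
class TrainingTrace:
    """Per-iteration record of transfers and holdout learning curves."""

    transfers: list[TransferRecord] = field(default_factory=list)
    auprc: dict[str, list[float]] = field(default_factory=dict)
    status: str = "completed"

    def curve(self, view: str) -> list[float]:
        return self.auprc[view]

    def n_incorrect(self, view: Optional[str] = None) -> int:
        """Count of audited transfers whose assigned label was wrong."""
        return sum(
            1
            for t in self.transfers
            if t.correct is False and (view is None or t.view == view)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "iteration": t.iteration,
                "view": t.view,
                "transferred_id": t.transferred_id,
                "assigned_label": t.assigned_label,
                "confidence": t.confidence,
                "correct": t.correct,
                "fallback": t.fallback,
                **{
                    f"auprc_{v}": (curve[t.iteration] if t.iteration < len(curve) else np.nan)
                    for v, curve in self.auprc.items()
                },
            }
            for t in self.transfers
        ]
        return pd.DataFrame(rows)


def select_top_confident(scores: Mapping[str, float]) -> tuple[str, str]:
    """Most confident positive (argmax score) and negative (argmin score).

    Ties break lexicographically by instance id; the two returned ids are
    always distinct. No 0.5 threshold is applied: in a degenerate pool where
    every score is below 0.5 the argmax still serves as the positive pick.
    """
    if len(scores) < 2:
        raise ValueError("pool exhausted: need at least 2 scored instances")
    top_pos = min(scores, key=lambda i: (-scores[i], i))
    top_neg = min(
        (i for i in scores if i != top_pos), key=lambda i: (scores[i], i)
    )
    return top_pos, top_neg


def plateau_stop(
    trace: TrainingTrace | Mapping[str, Sequence[float]],
    window: int,
    epsilon: float,
) -> bool:
    """True iff every view's AUPRC gain stayed below ``epsilon`` over the
    last ``window`` iterations."""
    curves = trace.auprc if isinstance(trace, TrainingTrace) else trace
    for curve in curves.values():
        if len(curve) < window + 1:
            raise ValueError("insufficient history for plateau check")
        recent = list(curve[-(window + 1):])
        gains = [b - a for a, b in zip(recent, recent[1:])]
        if max(gains) >= epsilon:
            return False
    return True


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def _holdout_auprc(model: ProbabilisticClassifier, holdout: ViewDataset) -> float:
    from .evaluate import auprc  # local import to avoid a cycle

    return auprc(model.score(holdout.values), holdout.labels)


def _audit(pool: ViewDataset, iid: str, assigned: int) -> Optional[bool]:
    if pool.true_labels is None:
        return None
    truth = int(pool.true_labels[pool.index_of([iid])[0]])
    if truth == UNLABELLED:
        return None
    return truth == assigned


def _append_to_train(view: ViewState, donor_pool: ViewDataset, iid: str, label: int) -> None:
    """Move one instance (features taken from the recipient view's pool) into
    a view's training set with an assigned label."""
    row = view.pool.values[view.pool.index_of([iid])[0]]
    view.train = ViewDataset(
        instance_ids=view.train.instance_ids + [iid],
        feature_names=view.train.feature_names,
        values=np.vstack([view.train.values, row[None, :]]),
        labels=np.append(view.train.labels, label),
        true_labels=None,
    )


def _remove_from_pool(view: ViewState, ids: set[str]) -> None:
    keep = [i for i in view.pool.instance_ids if i not in ids]
    view.pool = view.pool.subset(keep)


def _derived_seed(rng_seed: int, iteration: int, view_name: str, stream: int) -> int:
    """Deterministic sub-seed per (view, iteration, purpose).

    Independent of strategy and of the other view, so that e.g. the
    iteration-0 model of every strategy is bit-identical for a given
    ``rng_seed``. Stream 0 seeds the classifier, stream 1 the passive draws.
    """
    key = zlib.crc32(view_name.encode())
    seq = np.random.SeedSequence([rng_seed, iteration, key, stream])
    return int(seq.generate_state(1)[0] % (2**31))


def _fit(view: ViewState, factory: ClassifierFactory, seed: int) -> None:
    view.model = factory(seed).fit(view.train.values, view.train.labels)


def _pool_scores(view: ViewState) -> dict[str, float]:
    scores = view.model.score(view.pool.values)
    return dict(zip(view.pool.instance_ids, scores.tolist()))


def _check_universe(views: Sequence[ViewState]) -> None:
    if set(views[0].pool.instance_ids) != set(views[1].pool.instance_ids):
        raise ValueError("the two views must share one unlabelled pool id set")


def _iterate(
    views: list[ViewState],
    holdouts: list[ViewDataset],
    config: CoTrainConfig,
    factory: ClassifierFactory,
    select: Callable[
        [ViewState, set[str], np.random.Generator],
        list[tuple[str, int, float, bool]],
    ],
    cross_view: bool,
) -> TrainingTrace:
    """Shared iteration loop for co-, self- and passive training.

    ``select`` returns, for a donor view, the list of
    ``(instance_id, assigned_label, confidence, fallback)`` picks, never
    touching the already-claimed ids it is given.
    ``cross_view`` routes picks to the other view's train set (and removes
    them from every pool); otherwise they stay within the donor view.
    """
    trace = TrainingTrace(auprc={v.view_name: [] for v in views})

    for iteration in range(config.iterations + 1):
        for view, holdout in zip(views, holdouts):
            _fit(view, factory, _derived_seed(config.rng_seed, iteration, view.view_name, 0))
            trace.auprc[view.view_name].append(_holdout_auprc(view.model, holdout))
        if iteration == config.iterations:
            break
        if (
            config.stop_rule == "plateau"
            and iteration >= config.plateau_window
            and plateau_stop(trace, config.plateau_window, config.plateau_epsilon)
        ):
            trace.status = "plateau"
            break

        if any(len(v.pool) < 2 for v in views):
            trace.status = "pool_exhausted"
            break
        # donors pick sequentially; ids claimed earlier in the iteration are
        # excluded so no instance is transferred twice (cross-pool property)
        claimed: set[str] = set()
        picks: dict[str, list[tuple[str, int, float, bool]]] = {}
        exhausted = False
        for v in views:
            available = len(v.pool) - sum(
                1 for i in claimed if i in set(v.pool.instance_ids)
            )
            if available < 2:
                exhausted = True
                break
            picks[v.view_name] = select(
                v,
                claimed,
                np.random.default_rng(
                    _derived_seed(config.rng_seed, iteration, v.view_name, 1)
                ),
            )
            claimed.update(iid for iid, *_ in picks[v.view_name])
        if exhausted:
            trace.status = "pool_exhausted"
            break
        transferred: set[str] = set()
        for donor_idx, donor in enumerate(views):
            recipient = (
                views[(donor_idx + 1) % len(views)] if cross_view else donor
            )
            for iid, label, conf, fallback in picks[donor.view_name]:
                trace.transfers.append(
                    TransferRecord(
                        iteration=iteration,
                        view=donor.view_name,
                        transferred_id=iid,
                        assigned_label=label,
                        confidence=conf,
                        correct=_audit(donor.pool, iid, label),
                        fallback=fallback,
                    )
                )
                if iid not in set(recipient.train.instance_ids):
                    _append_to_train(recipient, donor.pool, iid, label)
                transferred.add(iid)
        for view in views:
            _remove_from_pool(view, transferred)
    return trace


def _confident_picks(
    view: ViewState, exclude: set[str], rng: np.random.Generator
) -> list[tuple[str, int, float, bool]]:
    scores = {i: s for i, s in _pool_scores(view).items() if i not in exclude}
    top_pos, top_neg = select_top_confident(scores)
    return [
        (top_pos, POSITIVE, scores[top_pos], False),
        (top_neg, NEGATIVE, 1.0 - scores[top_neg], False),
    ]


def _passive_picks(
    view: ViewState, exclude: set[str], rng: np.random.Generator
) -> list[tuple[str, int, float, bool]]:
    scores = {i: s for i, s in _pool_scores(view).items() if i not in exclude}
    ids = sorted(scores)
    pos_stratum = [i for i in ids if scores[i] > 0.5]
    if pos_stratum:
        pos_pick, pos_fb = pos_stratum[int(rng.integers(len(pos_stratum)))], False
    else:  # no confident positive: fall back to the extreme score
        pos_pick, pos_fb = max(ids, key=lambda i: (scores[i], i)), True
    neg_stratum = [i for i in ids if scores[i] < 0.5 and i != pos_pick]
    if neg_stratum:
        neg_pick, neg_fb = neg_stratum[int(rng.integers(len(neg_stratum)))], False
    else:
        neg_pick, neg_fb = (
            min((i for i in ids if i != pos_pick), key=lambda i: (scores[i], i)),
            True,
        )
    return [
        (pos_pick, POSITIVE, scores[pos_pick], pos_fb),
        (neg_pick, NEGATIVE, 1.0 - scores[neg_pick], neg_fb),
    ]


# ---------------------------------------------------------------------------
# public strategies
# ---------------------------------------------------------------------------

def run_cotraining(
    view_a: ViewState,
    view_b: ViewState,
    holdout: tuple[ViewDataset, ViewDataset],
    config: CoTrainConfig,
    classifier_factory: ClassifierFactory = default_classifier_factory,
) -> tuple[dict[str, ProbabilisticClassifier], TrainingTrace]:
    """Multi-view co-training (cross-pool variant).

    Per iteration each view is fit on its training set and scores its own
    pool; its most confident positive and negative picks are removed from
    both pools and appended, with the predicted labels, to the *other*
    view's training set. The per-view holdout AUPRC is recorded before every
    transfer round and once after the final one.
    """
    views = [view_a, view_b]
    _check_universe(views)
    trace = _iterate(
        views, list(holdout), config, classifier_factory,
        _confident_picks, cross_view=True,
    )
    return {v.view_name: v.model for v in views}, trace


def run_selftraining(
    view: ViewState,
    holdout: ViewDataset,
    config: CoTrainConfig,
    classifier_factory: ClassifierFactory = default_classifier_factory,
) -> tuple[ProbabilisticClassifier, TrainingTrace]:
    """Single-view self-training: top picks move from own pool to own train."""
    trace = _iterate(
        [view], [holdout], config, classifier_factory,
        _confident_picks, cross_view=False,
    )
    return view.model, trace


def run_passive(
    view_a: ViewState,
    view_b: ViewState,
    holdout: tuple[ViewDataset, ViewDataset],
    config: CoTrainConfig,
    classifier_factory: ClassifierFactory = default_classifier_factory,
) -> tuple[dict[str, ProbabilisticClassifier], TrainingTrace]:
    """Passive cross-view learning: transfers are drawn uniformly from the
    >50% (positive) and <50% (negative) score strata rather than by rank;
    an empty stratum falls back to the extreme score and is flagged."""
    views = [view_a, view_b]
    _check_universe(views)
    trace = _iterate(
        views, list(holdout), config, classifier_factory,
        _passive_picks, cross_view=True,
    )
    return {v.view_name: v.model for v in views}, trace
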