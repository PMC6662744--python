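"""Synthetic data generators.

Two simulators make the whole pipeline exercisable without any external
download:

* :func:`gen_two_view` draws a two-view feature-space dataset with
  class-conditional Gaussian features. Informative dimensions have class
  means at +/- sep/2 (in units of the within-class standard deviation) and
  the views are conditionally independent given the class — the premise
  co-training relies on. A view with ``sep = 0`` carries no class signal.

* :func:`gen_hairpins` builds hairpin candidates with read stacks whose
  Dicer-processing consistency differs by class: positives are perfect
  complementary stems with reads anchored at the mature and star 5' cut
  sites; negatives are composition-matched shuffles (so the sequence view is
  not trivially solvable from GC content) with reads scattered uniformly.

Generator ground truth travels on ``ViewDataset.true_labels`` /
returned label vectors; no learning strategy ever reads it — only the
trace-audit layer does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    NEGATIVE,
    POSITIVE,
    HairpinCandidate,
    Interval,
    ReadStack,
    RegionAnnotation,
    SequenceRecord,
    ViewDataset,
)
from .expression_features import star_from_mature
from .fold import fold_baseline, pair_table

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class TwoViewSimConfig:
    """Two-view Gaussian simulator settings.

    Defaults describe the evaluation conditions used throughout: 375
    instances per class (so an 80% training split holds 600 instances), one
    informative dimension per view with a class-mean separation of 2
    within-class standard deviations — ``sep`` *is* the view's class
    separation — plus 5 pure-noise dimensions per view.
    """

    n_pos: int = 375
    n_neg: int = 375
    dims_a: int = 1
    dims_b: int = 1
    sep_a: float = 2.0
    sep_b: float = 2.0
    noise_dims_a: int = 5
    noise_dims_b: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pos, self.n_neg, self.dims_a, self.dims_b,
               self.noise_dims_a, self.noise_dims_b) < 0:
            raise ValueError("all counts must be >= 0")
        if self.sep_a < 0 or self.sep_b < 0:
            raise ValueError("separations must be >= 0")


@dataclass(frozen=True)
class HairpinSimConfig:
    """Hairpin/read-stack simulator settings.

    Defaults give pre-miRNA-sized candidates (2 x 25 nt stem + 8 nt loop =
    58 nt), 100 reads per candidate from a million-read library, and a strong
    class contrast in Dicer consistency (90% of positive reads at the
    annotated cut sites vs 10% for negatives).
    """

    n_pos: int = 40
    n_neg: int = 40
    stem_len: int = 25
    loop_len: int = 8
    reads_per_candidate: int = 100
    pos_consistency: float = 0.9
    neg_consistency: float = 0.1
    library_size: int = 1_000_000
    rng_seed: int = 0
    mature_len: int = 22
    read_len: int = 22

    def __post_init__(self) -> None:
        if self.stem_len < 4:
            raise ValueError("stem_len must be >= 4")
        if self.loop_len < 3:
            raise ValueError("loop_len must be >= 3")
        for name in ("pos_consistency", "neg_consistency"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


def gen_two_view(
    config: TwoViewSimConfig,
) -> tuple[ViewDataset, ViewDataset, np.ndarray]:
    """Class-conditional Gaussian two-view dataset.

    Returns ``(view_a, view_b, labels)``; both views carry the labels (and
    the same vector as ``true_labels`` for auditing after labels are hidden).
    Deterministic given ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_pos + config.n_neg
    labels = np.concatenate(
        [np.full(config.n_pos, POSITIVE), np.full(config.n_neg, NEGATIVE)]
    )
    ids = [f"s{k:05d}" for k in range(n)]
    signs = np.where(labels == POSITIVE, 0.5, -0.5)

    def one_view(tag: str, dims: int, noise_dims: int, sep: float) -> ViewDataset:
        informative = rng.normal(size=(n, dims)) + signs[:, None] * sep
        noise = rng.normal(size=(n, noise_dims))
        values = np.hstack([informative, noise])
        names = [f"{tag}_inf{j}" for j in range(dims)] + [
            f"{tag}_noise{j}" for j in range(noise_dims)
        ]
        return ViewDataset(
            instance_ids=list(ids),
            feature_names=names,
            values=values,
            labels=labels.copy(),
            true_labels=labels.copy(),
        )

    view_a = one_view("a", config.dims_a, config.noise_dims_a, config.sep_a)
    view_b = one_view("b", config.dims_b, config.noise_dims_b, config.sep_b)
    return view_a, view_b, labels


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def _scatter_starts(
    rng: np.random.Generator,
    n_stacks: int,
    length: int,
    read_len: int,
    forbidden: list[int],
    margin: int = 2,
) -> list[int]:
    """Random stack starts at least ``margin`` nt away from every anchor.

    Reads near the 3' end are simply clipped, so starts range over most of
    the precursor; if the margin leaves no room (tiny hairpins) it is
    relaxed one nt at a time so generation always terminates.
    """
    starts: list[int] = []
    hi = max(2, length - 5)
    while margin >= -1:  # margin -1 accepts any start: guaranteed exit
        attempts = 0
        while len(starts) < n_stacks and attempts < 200:
            s = int(rng.integers(0, hi))
            attempts += 1
            if all(abs(s - a) > margin for a in forbidden):
                starts.append(s)
        if len(starts) == n_stacks:
            return starts
        margin -= 1
    raise AssertionError("unreachable: margin -1 accepts any start")


def _split_counts(total: int, weights: list[float]) -> list[int]:
    """Deterministic integer split of ``total`` proportional to weights."""
    norm = sum(weights)
    raw = [int(np.floor(total * w / norm)) for w in weights]
    remainder = total - sum(raw)
    for k in range(remainder):
        raw[k % len(raw)] += 1
    return raw


def gen_hairpins(
    config: HairpinSimConfig,
) -> tuple[list[HairpinCandidate], np.ndarray]:
    """Hairpin candidates with class-dependent Dicer consistency.

    Positives: a perfectly complementary ``stem_len`` stem around a random
    loop, folded with the baseline folder; the mature arm occupies the 5'
    stem and the star interval is derived from the fold's pair table (2-nt
    3' overhang), exactly as the annotation heuristic would. A
    ``pos_consistency`` share of reads is stacked at the two anchor starts
    (mature-heavy, 60/40), the rest scattered away from them.

    Negatives: composition-matched shuffles of positive-style sequences with
    arbitrary anchor annotations; a ``neg_consistency`` share of reads sits
    at those anchors, the rest is scattered uniformly.
    """
    rng = np.random.default_rng(config.rng_seed)
    candidates: list[HairpinCandidate] = []
    labels: list[int] = []
    mature_len = min(config.mature_len, config.stem_len)

    for k in range(config.n_pos):
        stem5 = _random_seq(rng, config.stem_len)
        loop = _random_seq(rng, config.loop_len)
        seq = stem5 + loop + _revcomp(stem5)
        fold = fold_baseline(seq)
        mature = Interval(0, mature_len)
        try:
            star = star_from_mature(pair_table(fold.structure), mature)
        except ValueError:
            # fold paired the mature arm in an unusable way; canonical guess
            star = Interval(
                config.stem_len + config.loop_len + 2, len(seq)
            )
        regions = RegionAnnotation(
            mature=mature,
            star=star,
            loop=Interval(mature.end, star.start),
            lower_stem_limit=mature.start,
        )
        stacks = _make_stacks(
            rng, config, len(seq),
            anchors=[(mature.start, len(mature)), (star.start, len(star))],
            consistency=config.pos_consistency,
        )
        candidates.append(
            HairpinCandidate(
                record=SequenceRecord(id=f"pos{k:04d}", residues=seq),
                structure=fold.structure,
                stacks=stacks,
                regions=regions,
                library_size=config.library_size,
            )
        )
        labels.append(POSITIVE)

    length = 2 * config.stem_len + config.loop_len
    for k in range(config.n_neg):
        pool = list(
            _random_seq(rng, config.stem_len)
            + _random_seq(rng, config.loop_len)
        )
        pool += [_COMPLEMENT[b] for b in pool[: config.stem_len]]
        rng.shuffle(pool)
        seq = "".join(pool)
        fold = fold_baseline(seq)
        m0 = int(rng.integers(0, max(1, length // 2 - mature_len)))
        mature = Interval(m0, m0 + mature_len)
        s_lo = max(mature.end + 1, length // 2)
        s0 = int(rng.integers(s_lo, max(s_lo + 1, length - mature_len)))
        star = Interval(s0, min(s0 + mature_len, length))
        regions = RegionAnnotation(
            mature=mature,
            star=star,
            loop=Interval(mature.end, star.start),
            lower_stem_limit=mature.start,
        )
        stacks = _make_stacks(
            rng, config, length,
            anchors=[(mature.start, len(mature)), (star.start, len(star))],
            consistency=config.neg_consistency,
        )
        candidates.append(
            HairpinCandidate(
                record=SequenceRecord(id=f"neg{k:04d}", residues=seq),
                structure=fold.structure,
                stacks=stacks,
                regions=regions,
                library_size=config.library_size,
            )
        )
        labels.append(NEGATIVE)

    return candidates, np.array(labels, dtype=int)


def _make_stacks(
    rng: np.random.Generator,
    config: HairpinSimConfig,
    length: int,
    anchors: list[tuple[int, int]],
    consistency: float,
) -> list[ReadStack]:
    total = config.reads_per_candidate
    n_consistent = int(round(consistency * total))
    n_scattered = total - n_consistent
    stacks: list[ReadStack] = []
    if n_consistent > 0:
        # mature anchor carries the majority of Dicer-consistent reads
        counts = _split_counts(n_consistent, [0.6, 0.4])
        for (start, span), count in zip(anchors, counts):
            if count > 0:
                stacks.append(
                    ReadStack(start=start, end=min(start + span, length), count=count)
                )
    if n_scattered > 0:
        n_stacks = min(5, n_scattered)
        starts = _scatter_starts(
            rng, n_stacks, length, config.read_len,
            forbidden=[a for a, _ in anchors],
        )
        for start, count in zip(starts, _split_counts(n_scattered, [1.0] * n_stacks)):
            if count > 0:
                end = min(start + config.read_len, length)
                stacks.append(ReadStack(start=start, end=end, count=count))
    return stacks
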