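"""Core data types shared across the package.

Conventions
-----------
* All coordinates are 0-based, half-open ``[start, end)``.
* RNA residues are uppercase over the alphabet ``{A, C, G, U}``; ``T`` is
  accepted on input and normalized to ``U``.
* Class labels are small integers: :data:`POSITIVE` (1), :data:`NEGATIVE` (0)
  and :data:`UNLABELLED` (-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

RNA_ALPHABET = frozenset("ACGU")

POSITIVE: int = 1
NEGATIVE: int = 0
UNLABELLED: int = -1


def normalize_residues(raw: str, *, record_id: str = "<sequence>") -> str:
    """Uppercase, map T->U and validate against the RNA alphabet.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a residue outside {A,C,G,U,T}
        (reported with its 1-based position).
    """
    residues = raw.strip().upper().replace("T", "U")
    if not residues:
        raise ValueError(f"record {record_id!r}: empty sequence")
    for pos, ch in enumerate(residues, start=1):
        if ch not in RNA_ALPHABET:
            raise ValueError(
                f"record {record_id!r}: invalid residue {ch!r} at position {pos}"
            )
    return residues


@dataclass(frozen=True)
class SequenceRecord:
    """An identified RNA sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "residues", normalize_residues(self.residues, record_id=self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReadStack:
    """A pile-up of identical reads mapped to ``[start, end)`` of a candidate."""

    start: int
    end: int
    count: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"read stack requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.count < 0:
            raise ValueError(f"read stack count must be >= 0, got {self.count}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Interval:
    """Half-open interval ``[start, end)``; ``start == end`` is the empty interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end or self.start < 0:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class RegionAnnotation:
    """Mature/star/loop annotation of a hairpin.

    ``lower_stem_limit`` is the leftmost position of the mature/star duplex;
    base pairs whose 5' partner lies strictly below it (and whose 3' partner
    lies beyond the duplex) belong to the lower stem.
    """

    mature: Interval
    star: Interval
    loop: Interval
    lower_stem_limit: int

    def __post_init__(self) -> None:
        if self.mature.overlap(self.star.start, self.star.end) > 0:
            raise ValueError("mature and star regions must be disjoint")


@dataclass
class HairpinCandidate:
    """A candidate pre-miRNA: sequence, structure, annotation and read stacks."""

    record: SequenceRecord
    structure: str
    stacks: list[ReadStack] = field(default_factory=list)
    regions: Optional[RegionAnnotation] = None
    library_size: int = 1

    def __post_init__(self) -> None:
        if len(self.structure) != len(self.record.residues):
            raise ValueError(
                f"candidate {self.record.id!r}: structure length "
                f"{len(self.structure)} != sequence length {len(self.record.residues)}"
            )
        depth = 0
        for i, ch in enumerate(self.structure):
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            elif ch != ".":
                raise ValueError(
                    f"candidate {self.record.id!r}: invalid structure symbol "
                    f"{ch!r} at position {i + 1}"
                )
            if depth < 0:
                raise ValueError(
                    f"candidate {self.record.id!r}: unbalanced structure "
                    f"(unmatched ')' at position {i + 1})"
                )
        if depth != 0:
            raise ValueError(
                f"candidate {self.record.id!r}: unbalanced structure "
                f"({depth} unmatched '(')"
            )
        if self.library_size <= 0:
            raise ValueError(
                f"candidate {self.record.id!r}: library_size must be positive"
            )

    @property
    def id(self) -> str:
        return self.record.id


@dataclass
class ViewDataset:
    """A feature matrix over named instances for one view.

    ``labels`` carries the labels visible to a learner (may include
    :data:`UNLABELLED`); ``true_labels``, when present, is generator or
    curator ground truth retained for trace auditing only — no learning
    strategy reads it.
    """

    instance_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: Optional[np.ndarray] = None
    true_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n != len(self.instance_ids):
            raise ValueError(
                f"{len(self.instance_ids)} ids but {n} rows in the value matrix"
            )
        if d != len(self.feature_names):
            raise ValueError(
                f"{len(self.feature_names)} feature names but {d} columns"
            )
        if len(set(self.instance_ids)) != len(self.instance_ids):
            raise ValueError("instance_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("value matrix contains non-finite entries")
        for attr in ("labels", "true_labels"):
            vec = getattr(self, attr)
            if vec is not None:
                vec = np.asarray(vec, dtype=int)
                if vec.shape != (n,):
                    raise ValueError(f"{attr} must have one entry per instance")
                if not np.isin(vec, [POSITIVE, NEGATIVE, UNLABELLED]).all():
                    raise ValueError(f"{attr} must be over {{1, 0, -1}}")
                setattr(self, attr, vec)

    def __len__(self) -> int:
        return len(self.instance_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {iid: k for k, iid in enumerate(self.instance_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown instance id {exc.args[0]!r}") from exc

    def subset(self, ids: Sequence[str]) -> "ViewDataset":
        """New dataset restricted to ``ids`` (in the given order)."""
        idx = self.index_of(ids)
        return ViewDataset(
            instance_ids=[self.instance_ids[k] for k in idx],
            feature_names=list(self.feature_names),
            values=self.values[idx],
            labels=None if self.labels is None else self.labels[idx],
            true_labels=None if self.true_labels is None else self.true_labels[idx],
        )

    def with_labels(self, labels: Optional[np.ndarray]) -> "ViewDataset":
        return replace(self, labels=labels)


@dataclass(frozen=True)
class SplitSpec:
    """Holdout / seed-training split parameters.

    Defaults follow the evaluation protocol: a stratified 20% holdout and a
    seed training set of 5 positives + 5 negatives drawn from the remaining
    80%; everything else becomes the unlabelled pool.
    """

    holdout_fraction: float = 0.2
    seed_pos: int = 5
    seed_neg: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.seed_pos < 0 or self.seed_neg < 0:
            raise ValueError("seed counts must be non-negative")
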