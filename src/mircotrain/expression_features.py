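"""Expression-view featurizer.

Eight features summarize how well a candidate's mapped read stacks agree
with Dicer processing of a genuine pre-miRNA hairpin:

1. percentage of paired nucleotides within the mature region;
2. number of base pairs in the lower stem (both partners outside
   mature/star/loop);
3. percentage of reads inconsistent with Dicer processing;
4. percentage of loop-region reads consistent with Dicer processing;
5. percentage of all reads consistent with Dicer processing;
6. percentage of mature-region reads consistent with Dicer processing;
7. percentage of star-region reads consistent with Dicer processing;
8. total reads in the precursor region, normalized to library size
   (reads per million).

A read stack is *Dicer-consistent* when its 5' start falls within
``tolerance`` nucleotides of the annotated mature or star 5' end — Dicer
cuts the duplex at well-defined sites, so reads from genuine biogenesis pile
up there, whereas degradation products scatter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    HairpinCandidate,
    Interval,
    ReadStack,
    RegionAnnotation,
    ViewDataset,
)
from .fold import pair_table

logger = logging.getLogger(__name__)

EXPRESSION_FEATURE_NAMES = [
    "pct_mature_paired",
    "lower_stem_pairs",
    "pct_reads_inconsistent",
    "pct_loop_reads_consistent",
    "pct_reads_consistent",
    "pct_mature_reads_consistent",
    "pct_star_reads_consistent",
    "normalized_read_count",
]

#: canonical 2-nt 3' overhang Dicer leaves on each strand of the duplex
DICER_OVERHANG = 2


def star_from_mature(table: Sequence[int], mature: Interval) -> Interval:
    """Star-arm interval implied by the mature interval and the pair table.

    The raw star span is the range of partners of the mature region's paired
    positions; it is then shifted 2 nt toward the 3' end of the star arm to
    account for the staggered Dicer cut, and clamped to the sequence and away
    from the mature region.
    """
    partners = [table[p] for p in range(mature.start, mature.end) if table[p] >= 0]
    if not partners:
        raise ValueError("mature region contains no paired position")
    lo, hi = min(partners), max(partners)
    n = len(table)
    if lo >= mature.end:  # star on the 3' arm
        start = min(lo + DICER_OVERHANG, n - 1)
        end = min(hi + 1 + DICER_OVERHANG, n)
        start = max(start, mature.end)
    else:  # star on the 5' arm
        start = max(lo - DICER_OVERHANG, 0)
        end = max(hi + 1 - DICER_OVERHANG, start + 1)
        end = min(end, mature.start)
    if start >= end:
        raise ValueError("degenerate star region implied by pair table")
    return Interval(start, end)


def annotate_regions(candidate: HairpinCandidate) -> RegionAnnotation:
    """Infer mature/star/loop regions from read stacks and the structure.

    The mature arm is the span of the highest-count stack (ties: earliest
    start, then shortest span); the star arm is its base-paired partner span
    shifted by the canonical 2-nt 3' overhang; the loop lies between the
    arm-proximal ends of the two.
    """
    if not candidate.stacks:
        raise ValueError(
            f"candidate {candidate.id!r}: cannot annotate without reads"
        )
    n = len(candidate.record.residues)
    top = max(candidate.stacks, key=lambda s: (s.count, -s.start, -(s.end - s.start)))
    mature = Interval(top.start, min(top.end, n))
    table = pair_table(candidate.structure)
    star = star_from_mature(table, mature)
    if star.start >= mature.end:
        loop = Interval(mature.end, star.start)
    else:
        loop = Interval(star.end, mature.start)
    return RegionAnnotation(
        mature=mature,
        star=star,
        loop=loop,
        lower_stem_limit=min(mature.start, star.start),
    )


@dataclass
class DicerPartition:
    """Read counts partitioned by Dicer consistency, overall and per region."""

    consistent: int = 0
    inconsistent: int = 0
    by_region: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            r: {"consistent": 0, "inconsistent": 0} for r in ("mature", "star", "loop")
        }
    )

    @property
    def total(self) -> int:
        return self.consistent + self.inconsistent


def _stack_region(stack: ReadStack, regions: RegionAnnotation) -> Optional[str]:
    """Region holding the majority of a stack's span; ties favour
    mature > star > loop; no overlap at all -> None."""
    overlaps = [
        ("mature", regions.mature.overlap(stack.start, stack.end)),
        ("star", regions.star.overlap(stack.start, stack.end)),
        ("loop", regions.loop.overlap(stack.start, stack.end)),
    ]
    name, best = max(overlaps, key=lambda t: t[1])  # max is stable: first wins ties
    return name if best > 0 else None


def dicer_consistency(
    stacks: Sequence[ReadStack],
    regions: RegionAnnotation,
    tolerance: int = 1,
) -> DicerPartition:
    """Partition reads into Dicer-consistent/inconsistent, overall and per region."""
    part = DicerPartition()
    anchors = (regions.mature.start, regions.star.start)
    for stack in stacks:
        ok = any(abs(stack.start - a) <= tolerance for a in anchors)
        key = "consistent" if ok else "inconsistent"
        setattr(part, key, getattr(part, key) + stack.count)
        region = _stack_region(stack, regions)
        if region is not None:
            part.by_region[region][key] += stack.count
    return part


def _pct(numer: float, denom: float) -> float:
    return 100.0 * numer / denom if denom > 0 else 0.0


def compute_expression_features(
    candidate: HairpinCandidate, tolerance: int = 1
) -> dict[str, float]:
    """The 8 expression-view features for one candidate.

    Uses the candidate's region annotation when present, otherwise derives
    one with :func:`annotate_regions`. Requires ``library_size > 0`` (already
    enforced by the candidate type).
    """
    regions = candidate.regions or annotate_regions(candidate)
    table = pair_table(candidate.structure)
    mature = regions.mature

    paired_in_mature = sum(
        1 for p in range(mature.start, mature.end) if table[p] >= 0
    )
    pct_mature_paired = _pct(paired_in_mature, len(mature))

    excluded = (regions.mature, regions.star, regions.loop)
    lower_stem_pairs = sum(
        1
        for i, j in enumerate(table)
        if j > i and not any(i in r or j in r for r in excluded)
    )

    part = dicer_consistency(candidate.stacks, regions, tolerance=tolerance)
    total_reads = part.total
    if total_reads == 0:
        logger.warning(
            "candidate %r has no reads in the precursor region; "
            "read-percentage features set to 0",
            candidate.id,
        )
    mature_counts = part.by_region["mature"]
    star_counts = part.by_region["star"]
    loop_counts = part.by_region["loop"]

    pct_consistent = _pct(part.consistent, total_reads)
    # complement, not a second division: consistent + inconsistent == 100 exactly
    pct_inconsistent = 100.0 - pct_consistent if total_reads > 0 else 0.0

    return {
        "pct_mature_paired": pct_mature_paired,
        "lower_stem_pairs": float(lower_stem_pairs),
        "pct_reads_inconsistent": pct_inconsistent,
        "pct_loop_reads_consistent": _pct(
            loop_counts["consistent"], sum(loop_counts.values())
        ),
        "pct_reads_consistent": pct_consistent,
        "pct_mature_reads_consistent": _pct(
            mature_counts["consistent"], sum(mature_counts.values())
        ),
        "pct_star_reads_consistent": _pct(
            star_counts["consistent"], sum(star_counts.values())
        ),
        "normalized_read_count": 1e6 * total_reads / candidate.library_size,
    }


def expression_feature_table(
    candidates: Sequence[HairpinCandidate],
    tolerance: int = 1,
    labels: Optional[Sequence[int]] = None,
) -> ViewDataset:
    """Expression-view feature matrix for a collection of candidates."""
    rows = [
        [compute_expression_features(c, tolerance=tolerance)[n]
         for n in EXPRESSION_FEATURE_NAMES]
        for c in candidates
    ]
    return ViewDataset(
        instance_ids=[c.id for c in candidates],
        feature_names=list(EXPRESSION_FEATURE_NAMES),
        values=np.array(rows, dtype=float).reshape(
            len(candidates), len(EXPRESSION_FEATURE_NAMES)
        ),
        labels=None if labels is None else np.asarray(labels, dtype=int),
    )
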