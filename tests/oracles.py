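"""Independent brute-force oracles used only by the tests.

These deliberately avoid the implementation's code paths: the folding oracle
enumerates nestings recursively instead of filling a DP table, and the
precision-recall oracle sweeps explicit thresholds with naive counting.
"""

from __future__ import annotations

from functools import lru_cache

PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def max_pairs_bruteforce(seq: str, min_loop: int = 3) -> int:
    """Maximum number of pairs over all valid nested structures, by
    recursive enumeration of the pairing of the first free position."""

    @lru_cache(maxsize=None)
    def best(positions: tuple[int, ...]) -> int:
        if len(positions) < 2:
            return 0
        first, rest = positions[0], positions[1:]
        score = best(rest)  # first unpaired
        for j in rest:
            if j - first > min_loop and (seq[first], seq[j]) in PAIRS:
                inside = tuple(p for p in rest if p < j)
                outside = tuple(p for p in rest if p > j)
                score = max(score, 1 + best(inside) + best(outside))
        return score

    return best(tuple(range(len(seq))))


def auprc_bruteforce(scores, labels) -> float:
    """Exhaustive-threshold precision-recall step area.

    One operating point per distinct score value (predict positive when
    score >= threshold), swept in descending order; area accumulates
    (recall_i - recall_{i-1}) * precision_i.
    """
    scores = list(map(float, scores))
    labels = [int(l) for l in labels]
    n_pos = sum(1 for l in labels if l == 1)
    assert 0 < n_pos < len(labels), "need both classes"
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        tp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= t and l != 1)
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def singleton_merits(values, labels) -> list[float]:
    """CFS merit of each single-feature subset: |pearson(feature, label)|."""
    import numpy as np

    y = np.asarray(labels, dtype=float)
    merits = []
    for j in range(values.shape[1]):
        x = values[:, j]
        if x.std() == 0 or y.std() == 0:
            merits.append(0.0)
        else:
            merits.append(abs(float(np.corrcoef(x, y)[0, 1])))
    return merits
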