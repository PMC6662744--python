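"""Sequence-view featurizer.

Computes four feature families for a hairpin candidate from its sequence and
secondary structure:

* minimum-free-energy indices — MFE, AMFE (MFE per 100 nt), MFEI
  (AMFE / GC%), and GC content in percent;
* 32 sequence/structure triplet elements — for every window of three
  consecutive positions, the middle nucleotide combined with the
  paired/unpaired pattern of the window (both brackets collapse to ``(``);
* 16 overlapping dinucleotide frequencies;
* a structural-robustness score — the mean base-pair distance between the
  wild-type fold and the folds of all 3L single-point mutants, scaled by
  sequence length (lower = more robust).

``cfs_select`` implements correlation-based feature subset selection: a
greedy forward search over the merit
``k * mean|r_cf| / sqrt(k + k*(k-1) * mean|r_ff|)`` where ``r_cf`` is the
feature-label Pearson correlation and ``r_ff`` the feature-feature one.
"""

from __future__ import annotations

import logging
from itertools import product
from typing import Callable, Optional, Sequence

import numpy as np

from .datatypes import NEGATIVE, POSITIVE, HairpinCandidate, ViewDataset
from .fold import FoldResult, fold_baseline, pair_set

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGU"
TRIPLET_PATTERNS = ["".join(p) for p in product(".(", repeat=3)]
TRIPLET_KEYS = [f"{nt}{pat}" for nt in NUCLEOTIDES for pat in TRIPLET_PATTERNS]
DINUCLEOTIDES = [a + b for a in NUCLEOTIDES for b in NUCLEOTIDES]

MFE_NAMES = ["MFE", "AMFE", "MFEI", "GC_content"]
SEQUENCE_FEATURE_NAMES = (
    MFE_NAMES
    + [f"triplet_{k}" for k in TRIPLET_KEYS]
    + [f"dinuc_{d}" for d in DINUCLEOTIDES]
    + ["robustness"]
)


def gc_content(residues: str) -> float:
    """GC content in percent."""
    if not residues:
        return 0.0
    return 100.0 * sum(residues.count(b) for b in "GC") / len(residues)


def mfe_features(residues: str, fold: FoldResult) -> dict[str, float]:
    """MFE, AMFE (= MFE/L*100), MFEI (= AMFE/GC%), GC_content (%)."""
    length = len(residues)
    if length == 0:
        raise ValueError("empty sequence")
    mfe = fold.energy
    amfe = mfe / length * 100.0
    gc = gc_content(residues)
    if gc == 0.0:
        if amfe != 0.0:
            logger.warning("GC content is zero; reporting MFEI = 0 by convention")
        mfei = 0.0
    else:
        mfei = amfe / gc
    return {"MFE": mfe, "AMFE": amfe, "MFEI": mfei, "GC_content": gc}


def triplet_features(residues: str, structure: str) -> dict[str, float]:
    """32 sequence/structure triplet frequencies (middle nt x 3-mer pattern)."""
    if len(residues) != len(structure):
        raise ValueError("sequence/structure length mismatch")
    values = dict.fromkeys(TRIPLET_KEYS, 0.0)
    n = len(residues)
    if n < 3:
        logger.warning("sequence shorter than 3 nt: triplet features all zero")
        return values
    collapsed = structure.replace(")", "(")
    for i in range(n - 2):
        key = residues[i + 1] + collapsed[i : i + 3]
        values[key] += 1.0
    total = float(n - 2)
    return {k: v / total for k, v in values.items()}


def dinucleotide_features(residues: str) -> dict[str, float]:
    """16 overlapping dinucleotide frequencies."""
    values = dict.fromkeys(DINUCLEOTIDES, 0.0)
    n = len(residues)
    if n < 2:
        logger.warning("sequence shorter than 2 nt: dinucleotide features all zero")
        return values
    for i in range(n - 1):
        values[residues[i : i + 2]] += 1.0
    total = float(n - 1)
    return {k: v / total for k, v in values.items()}


def robustness_feature(
    residues: str, folder: Callable[[str], FoldResult] = fold_baseline
) -> float:
    """Mean base-pair distance to all 3L single-point mutants, over L.

    The base-pair distance between two structures is the size of the
    symmetric difference of their pair sets. A structurally robust hairpin
    (small value) keeps its fold under point mutation — a hallmark of
    genuine pre-miRNA.
    """
    n = len(residues)
    if n == 0:
        raise ValueError("empty sequence")
    wild = pair_set(folder(residues).structure)
    total = 0.0
    n_mut = 0
    for pos in range(n):
        for base in NUCLEOTIDES:
            if base == residues[pos]:
                continue
            mutant = residues[:pos] + base + residues[pos + 1 :]
            mut_pairs = pair_set(folder(mutant).structure)
            total += len(wild ^ mut_pairs)
            n_mut += 1
    return (total / n_mut) / n


def sequence_feature_vector(
    candidate: HairpinCandidate,
    folder: Callable[[str], FoldResult] = fold_baseline,
    *,
    include_robustness: bool = True,
) -> dict[str, float]:
    """All sequence-view features for one candidate.

    Uses the candidate's stored structure for the structure-dependent
    families; the folder is used for the MFE pseudo-energy (when the stored
    structure came from the same backend the two agree) and for the
    robustness mutants.
    """
    residues = candidate.record.residues
    fold = folder(residues)
    feats = mfe_features(residues, fold)
    feats.update(
        {f"triplet_{k}": v for k, v in triplet_features(residues, candidate.structure).items()}
    )
    feats.update(
        {f"dinuc_{k}": v for k, v in dinucleotide_features(residues).items()}
    )
    if include_robustness:
        feats["robustness"] = robustness_feature(residues, folder)
    return feats


def sequence_feature_table(
    candidates: Sequence[HairpinCandidate],
    folder: Callable[[str], FoldResult] = fold_baseline,
    *,
    include_robustness: bool = True,
    labels: Optional[Sequence[int]] = None,
) -> ViewDataset:
    """Sequence-view feature matrix for a collection of candidates."""
    names = [
        n for n in SEQUENCE_FEATURE_NAMES if include_robustness or n != "robustness"
    ]
    rows = []
    for cand in candidates:
        feats = sequence_feature_vector(
            cand, folder, include_robustness=include_robustness
        )
        rows.append([feats[n] for n in names])
    return ViewDataset(
        instance_ids=[c.id for c in candidates],
        feature_names=names,
        values=np.array(rows, dtype=float).reshape(len(candidates), len(names)),
        labels=None if labels is None else np.asarray(labels, dtype=int),
    )


# ---------------------------------------------------------------------------
# Correlation-based feature subset selection (CFS)
# ---------------------------------------------------------------------------

def cfs_merit(mean_rcf: float, mean_rff: float, k: int) -> float:
    """CFS merit of a k-feature subset from its mean |correlations|."""
    if k == 0:
        return 0.0
    return k * mean_rcf / np.sqrt(k + k * (k - 1) * mean_rff)


def cfs_select(dataset: ViewDataset) -> list[str]:
    """Greedy forward CFS: grow the subset while the merit increases.

    Features are standardized internally; a constant feature has all its
    correlations treated as 0. Ties are broken by feature-name order, making
    the selection deterministic. Returns the selected names in the order
    they were added.
    """
    if dataset.labels is None:
        raise ValueError("cfs_select requires labels")
    if dataset.n_features < 2:
        raise ValueError("cfs_select requires at least 2 features")
    mask = np.isin(dataset.labels, [POSITIVE, NEGATIVE])
    X = dataset.values[mask]
    y = dataset.labels[mask].astype(float)

    def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
        if a.std() == 0.0 or b.std() == 0.0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    names = dataset.feature_names
    d = len(names)
    rcf = np.array([abs(_safe_corr(X[:, j], y)) for j in range(d)])
    rff = np.zeros((d, d))
    for i in range(d):
        for j in range(i + 1, d):
            rff[i, j] = rff[j, i] = abs(_safe_corr(X[:, i], X[:, j]))

    order = sorted(range(d), key=lambda j: names[j])

    def merit_of(subset: list[int]) -> float:
        k = len(subset)
        mean_rcf = float(rcf[subset].mean())
        if k == 1:
            mean_rff = 0.0
        else:
            sub = rff[np.ix_(subset, subset)]
            mean_rff = float(sub[np.triu_indices(k, 1)].mean())
        return cfs_merit(mean_rcf, mean_rff, k)

    selected: list[int] = []
    current_merit = 0.0
    remaining = list(order)
    while remaining:
        best_j, best_merit = None, current_merit
        for j in remaining:  # name order => deterministic tie-break
            m = merit_of(selected + [j])
            if m > best_merit + 1e-12:
                best_j, best_merit = j, m
        if best_j is None:
            break
        selected.append(best_j)
        remaining.remove(best_j)
        current_merit = best_merit
    return [names[j] for j in selected]
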