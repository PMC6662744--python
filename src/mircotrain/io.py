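"""Readers/writers for the plain-text formats touched, dataset labelling
rules, and split/seed construction.

Formats
-------
FASTA             sequences (via Biopython); ``T`` normalized to ``U``.
structures file   FASTA-like: ``>id`` header followed by one dot-bracket
                  line per record (Vienna convention).
stacks TSV        first line ``#library_size=<int>``, then a header
                  ``candidate_id<TAB>start<TAB>end<TAB>count`` and one row
                  per read stack.
feature TSV       ``instance_id`` column + one column per feature; an
                  optional ``label`` column carries 1/0/-1.

All writers round-trip bit-exactly with their readers.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datatypes import (
    NEGATIVE,
    POSITIVE,
    UNLABELLED,
    HairpinCandidate,
    ReadStack,
    SequenceRecord,
    SplitSpec,
    ViewDataset,
)


# ---------------------------------------------------------------------------
# FASTA and structure files
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and T->U normalized; invalid residues or empty
    sequences raise ``ValueError`` naming the offending record and position.
    Duplicate ids raise as well.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for k, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise ValueError(f"{path}: record {k} has an empty header")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


def read_structures(path: str | os.PathLike) -> dict[str, str]:
    """Read a dot-bracket structure file (``>id`` + one structure line each)."""
    structures: dict[str, str] = {}
    current: Optional[str] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if not current:
                    raise ValueError(f"{path}:{lineno}: empty structure header")
                if current in structures:
                    raise ValueError(f"{path}:{lineno}: duplicate id {current!r}")
                structures[current] = ""
            else:
                if current is None:
                    raise ValueError(f"{path}:{lineno}: structure line before header")
                if structures[current]:
                    raise ValueError(
                        f"{path}:{lineno}: second structure line for {current!r}"
                    )
                if set(line) - set("().") :
                    raise ValueError(
                        f"{path}:{lineno}: invalid dot-bracket symbols in {line!r}"
                    )
                structures[current] = line
    empty = [i for i, s in structures.items() if not s]
    if empty:
        raise ValueError(f"{path}: no structure line for {empty[0]!r}")
    return structures


def write_structures(structures: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iid, struct in structures.items():
            fh.write(f">{iid}\n{struct}\n")


# ---------------------------------------------------------------------------
# Read-stack tables
# ---------------------------------------------------------------------------

def read_stacks_table(
    path: str | os.PathLike,
) -> tuple[dict[str, list[ReadStack]], int]:
    """Parse a read-stack TSV; returns (candidate_id -> stacks, library_size)."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#library_size="):
            raise ValueError(f"{path}:1: expected '#library_size=<int>' line")
        try:
            library_size = int(first.split("=", 1)[1])
        except ValueError as exc:
            raise ValueError(f"{path}:1: unparseable library size") from exc
        if library_size <= 0:
            raise ValueError(f"{path}:1: library_size must be positive")
        header = fh.readline().strip().split("\t")
        if header != ["candidate_id", "start", "end", "count"]:
            raise ValueError(f"{path}:2: unexpected header {header}")
        stacks: dict[str, list[ReadStack]] = {}
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            cid, start_s, end_s, count_s = parts
            try:
                start, end, count = int(start_s), int(end_s), int(count_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field") from exc
            try:
                stack = ReadStack(start=start, end=end, count=count)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            stacks.setdefault(cid, []).append(stack)
    return stacks, library_size


def write_stacks_table(
    stacks: Mapping[str, Sequence[ReadStack]],
    library_size: int,
    path: str | os.PathLike,
) -> None:
    with open(path, "w") as fh:
        fh.write(f"#library_size={library_size}\n")
        fh.write("candidate_id\tstart\tend\tcount\n")
        for cid, group in stacks.items():
            for st in group:
                fh.write(f"{cid}\t{st.start}\t{st.end}\t{st.count}\n")


# ---------------------------------------------------------------------------
# Feature tables / label files
# ---------------------------------------------------------------------------

def write_view_dataset(dataset: ViewDataset, path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        dataset.values, columns=dataset.feature_names, index=dataset.instance_ids
    )
    frame.index.name = "instance_id"
    if dataset.labels is not None:
        frame["label"] = dataset.labels
    frame.to_csv(path, sep="\t")  # default float repr round-trips exactly


def read_view_dataset(path: str | os.PathLike) -> ViewDataset:
    frame = pd.read_csv(
        path, sep="\t", index_col="instance_id", float_precision="round_trip"
    )
    labels = None
    if "label" in frame.columns:
        labels = frame.pop("label").to_numpy(dtype=int)
    return ViewDataset(
        instance_ids=[str(i) for i in frame.index],
        feature_names=list(frame.columns),
        values=frame.to_numpy(dtype=float),
        labels=labels,
    )


def write_labels(
    ids: Sequence[str], labels: Sequence[int], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("instance_id\tlabel\n")
        for iid, lab in zip(ids, labels):
            fh.write(f"{iid}\t{int(lab)}\n")


def read_labels(path: str | os.PathLike) -> dict[str, int]:
    frame = pd.read_csv(path, sep="\t")
    return {str(r.instance_id): int(r.label) for r in frame.itertuples()}


# ---------------------------------------------------------------------------
# Dataset labelling rules
# ---------------------------------------------------------------------------

def _matches_known(residues: str, known: Sequence[str]) -> bool:
    # exact-substring containment in either direction, post T->U normalization
    return any(residues in k or k in residues for k in known)


def build_labelled_sets(
    candidates: Sequence[HairpinCandidate],
    known_mirna: Sequence[SequenceRecord],
    coding_hits: Mapping[str, int],
    ncrna_set: Sequence[SequenceRecord] = (),
    *,
    max_mismatches: int = 2,
) -> tuple[list[HairpinCandidate], list[HairpinCandidate | SequenceRecord]]:
    """Partition candidates into labelled positive and negative sets.

    A candidate whose sequence matches a known miRNA (exact substring in
    either direction) is a positive. A non-matching candidate whose best
    coding-region alignment has at most ``max_mismatches`` mismatches is a
    negative (a sequence producing mRNA is assumed not to also produce a
    miRNA). Functional non-coding RNAs (``ncrna_set``) are appended to the
    negatives so a classifier cannot succeed by separating coding from
    non-coding sequence alone. Candidates matching neither rule are
    discarded. Inputs are assumed pre-deduplicated.
    """
    ids = [c.id for c in candidates]
    if len(set(ids)) != len(ids):
        raise ValueError("candidate ids must be unique")
    collisions = set(ids) & {r.id for r in ncrna_set}
    if collisions:
        raise ValueError(
            f"id collision between candidates and ncRNA set: {sorted(collisions)[:3]}"
        )
    known = [r.residues for r in known_mirna]
    positives: list[HairpinCandidate] = []
    negatives: list[HairpinCandidate | SequenceRecord] = []
    for cand in candidates:
        if _matches_known(cand.record.residues, known):
            positives.append(cand)
        elif cand.id in coding_hits and coding_hits[cand.id] <= max_mismatches:
            negatives.append(cand)
    negatives.extend(ncrna_set)
    return positives, negatives


# ---------------------------------------------------------------------------
# Split / seed construction
# ---------------------------------------------------------------------------

def split_and_seed(
    dataset: ViewDataset, spec: SplitSpec
) -> tuple[ViewDataset, ViewDataset, ViewDataset]:
    """Stratified holdout split plus seed-training draw.

    Returns ``(seed_train, unlabelled_pool, holdout_test)``. The holdout is a
    class-stratified ``spec.holdout_fraction`` share of the data; the seed
    training set is ``spec.seed_pos`` positives + ``spec.seed_neg`` negatives
    drawn uniformly without replacement from the remaining 80%; everything
    else becomes the pool with labels hidden (true labels are retained on the
    pool's ``true_labels`` for audit purposes only).

    Deterministic given ``spec.rng_seed``: the same seed yields the same
    partition of instance ids regardless of the feature matrix, so applying
    the same spec to two views of one instance universe produces aligned
    splits.
    """
    if dataset.labels is None:
        raise ValueError("split_and_seed requires a labelled dataset")
    labels = dataset.labels
    if not np.isin(labels, [POSITIVE, NEGATIVE]).all():
        raise ValueError("all labels must be positive/negative for splitting")
    # order by id so the partition depends only on (ids, labels, seed)
    order = sorted(range(len(dataset)), key=lambda k: dataset.instance_ids[k])
    rng = np.random.default_rng(spec.rng_seed)

    holdout_idx: list[int] = []
    rest_by_class: dict[int, list[int]] = {POSITIVE: [], NEGATIVE: []}
    for cls in (POSITIVE, NEGATIVE):
        members = [k for k in order if labels[k] == cls]
        n_hold = int(round(spec.holdout_fraction * len(members)))
        chosen = rng.choice(len(members), size=n_hold, replace=False)
        chosen_set = set(chosen.tolist())
        for j, k in enumerate(members):
            (holdout_idx if j in chosen_set else rest_by_class[cls]).append(k)

    seed_idx: list[int] = []
    pool_idx: list[int] = []
    for cls, n_seed, name in (
        (POSITIVE, spec.seed_pos, "positive"),
        (NEGATIVE, spec.seed_neg, "negative"),
    ):
        members = rest_by_class[cls]
        if len(members) < n_seed:
            raise ValueError(
                f"not enough {name} instances for the seed training set: "
                f"need {n_seed}, have {len(members)} after the holdout split"
            )
        chosen = rng.choice(len(members), size=n_seed, replace=False)
        chosen_set = set(chosen.tolist())
        for j, k in enumerate(members):
            (seed_idx if j in chosen_set else pool_idx).append(k)

    def _take(idx: list[int]) -> ViewDataset:
        return dataset.subset([dataset.instance_ids[k] for k in sorted(idx)])

    seed_train = _take(seed_idx)
    holdout = _take(holdout_idx)
    pool = _take(pool_idx)
    pool.true_labels = pool.labels
    pool.labels = np.full(len(pool), UNLABELLED, dtype=int)
    return seed_train, pool, holdout
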