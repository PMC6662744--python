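"""RNA secondary-structure backends.

The baseline backend is a Nussinov-style base-pair-maximizing dynamic
program: it returns the nested structure with the largest number of
Watson-Crick/wobble pairs (AU, GC, GU) subject to a minimum hairpin-loop
length, and reports a pseudo-energy of minus the pair count. It exists so the
whole pipeline runs with no external thermodynamic dependency; a
thermodynamic backend that shells out to ViennaRNA's ``RNAfold`` is provided
for users who have it installed.

Traceback tie-breaking (documented, deterministic): when leaving the last
position unpaired scores as well as pairing it, the position is left
unpaired; among equally scoring pairing partners the smallest index wins.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Callable, Protocol

from .datatypes import RNA_ALPHABET

CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


@dataclass(frozen=True)
class FoldResult:
    """A dot-bracket structure with its (pseudo-)energy.

    ``energy`` is in kcal/mol for thermodynamic backends and ``-(pair
    count)`` for the baseline backend.
    """

    structure: str
    energy: float

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


class Folder(Protocol):
    def __call__(self, residues: str) -> FoldResult: ...


def can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 where unpaired) from dot-bracket."""
    table = [-1] * len(structure)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced structure: unmatched ')' at {i}")
            j = stack.pop()
            table[i], table[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid structure symbol {ch!r} at {i}")
    if stack:
        raise ValueError(f"unbalanced structure: unmatched '(' at {stack[-1]}")
    return table


def pair_set(structure: str) -> frozenset[tuple[int, int]]:
    """The set of (i, j) pairs, i < j, encoded by a dot-bracket string."""
    table = pair_table(structure)
    return frozenset((i, j) for i, j in enumerate(table) if j > i)


def fold_baseline(residues: str, min_loop: int = 3) -> FoldResult:
    """Base-pair-maximizing nested fold (Nussinov DP).

    Hairpin loops keep at least ``min_loop`` unpaired residues, i.e. a pair
    (i, j) requires j - i > min_loop.
    """
    bad = set(residues) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid residues for folding: {sorted(bad)}")
    n = len(residues)
    # dp[i][j] = max pairs in residues[i..j]
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if can_pair(residues[k], residues[j]):
                    left = dp[i][k - 1] if k > i else 0
                    inner = dp[k + 1][j - 1]
                    best = max(best, left + 1 + inner)
            dp[i][j] = best

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while j - i > min_loop:
            if dp[i][j] == dp[i][j - 1]:  # prefer j unpaired
                j -= 1
                continue
            for k in range(i, j - min_loop):  # smallest partner wins ties
                if can_pair(residues[k], residues[j]):
                    left = dp[i][k - 1] if k > i else 0
                    if left + 1 + dp[k + 1][j - 1] == dp[i][j]:
                        structure[k], structure[j] = "(", ")"
                        if k > i:
                            traceback(i, k - 1)
                        i, j = k + 1, j - 1
                        break
            else:  # pragma: no cover - dp table guarantees a branch
                raise AssertionError("traceback failed")

    if n:
        traceback(0, n - 1)
    struct = "".join(structure)
    return FoldResult(structure=struct, energy=-float(struct.count("(")))


def fold_vienna(residues: str) -> FoldResult:
    """Thermodynamic MFE fold via the ``RNAfold`` executable (ViennaRNA)."""
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold executable not found on PATH")
    proc = subprocess.run(
        [exe, "--noPS"], input=residues + "\n", capture_output=True, text=True,
        check=True,
    )
    lines = [l for l in proc.stdout.splitlines() if l.strip()]
    # last line: "((...)). ( -1.20)"
    struct_line = lines[-1]
    structure = struct_line.split(None, 1)[0]
    energy = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    return FoldResult(structure=structure, energy=energy)


BACKENDS: dict[str, Callable[[str], FoldResult]] = {
    "baseline": fold_baseline,
    "vienna": fold_vienna,
}


def get_folder(name: str) -> Callable[[str], FoldResult]:
    try:
        return BACKENDS[name]
    except KeyError:
        raise ValueError(
            f"unknown folding backend {name!r}; choose from {sorted(BACKENDS)}"
        ) from None
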