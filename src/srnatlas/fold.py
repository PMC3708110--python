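"""Minimum-free-energy RNA secondary structure by dynamic programming.

A self-contained, simplified thermodynamic model: legal pairs are AU, GC
and GU wobbles; the energy of a structure is the sum of nearest-neighbor
stacking energies over adjacent base pairs plus a helix-nucleation penalty
per maximal helix.  Loop-length terms beyond the minimum hairpin size (3)
are ignored.  The model is deliberately simple — it is a stem-detector for
candidate pre-miRNA hairpins, not a general folding server — but it is
exactly solvable, and an exhaustive structure-enumeration oracle certifies
the DP on short sequences.  An adapter hook allows an external
thermodynamic folder (e.g. the ViennaRNA ``RNAfold`` binary) to be swapped
in without changing any candidate logic.

Energy parameters (kcal/mol): see ``STACK_TABLE`` below; ``HELIX_INIT`` is
+3.5 per helix, so isolated pairs are never favorable.
"""

from __future__ import annotations

import re
import subprocess
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HairpinFold",
    "fold_hairpin",
    "score_structure",
    "enumerate_structures",
    "optimal_by_enumeration",
    "RNAfoldAdapter",
    "HELIX_INIT",
    "MIN_LOOP",
]

MIN_LOOP = 3
HELIX_INIT = 3.5

# nearest-neighbor stacking energies, kcal/mol, keyed (outer pair, inner pair)
# where a pair "XY" means X on the 5' side paired to Y (DNA alphabet, T==U)
STACK_TABLE: dict[tuple[str, str], float] = {
    ("AT", "AT"): -0.9, ("AT", "TA"): -1.1, ("AT", "GC"): -2.1,
    ("AT", "CG"): -2.2, ("AT", "GT"): -0.6, ("AT", "TG"): -1.4,
    ("TA", "AT"): -1.3, ("TA", "TA"): -0.9, ("TA", "GC"): -2.4,
    ("TA", "CG"): -2.1, ("TA", "GT"): -1.0, ("TA", "TG"): -0.3,
    ("GC", "AT"): -2.2, ("GC", "TA"): -2.4, ("GC", "GC"): -3.3,
    ("GC", "CG"): -2.4, ("GC", "GT"): -1.4, ("GC", "TG"): -2.1,
    ("CG", "AT"): -2.1, ("CG", "TA"): -2.1, ("CG", "GC"): -3.4,
    ("CG", "CG"): -3.3, ("CG", "GT"): -1.5, ("CG", "TG"): -2.5,
    ("GT", "AT"): -1.3, ("GT", "TA"): -1.0, ("GT", "GC"): -2.5,
    ("GT", "CG"): -1.5, ("GT", "GT"): -0.5, ("GT", "TG"): -0.4,
    ("TG", "AT"): -0.6, ("TG", "TA"): -1.4, ("TG", "GC"): -2.1,
    ("TG", "CG"): -1.4, ("TG", "GT"): -0.4, ("TG", "TG"): -0.5,
}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_LEGAL = {(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)}  # AU, GC, GU

# 4x4 -> pair string for table lookup
_PAIR_STR = {(a, b): x + y for x, a in (("A", 0), ("C", 1), ("G", 2), ("T", 3))
             for y, b in (("A", 0), ("C", 1), ("G", 2), ("T", 3))}

# dense arrays for the DP kernel
_LEGAL_ARR = np.zeros((4, 4), dtype=np.bool_)
for _p in _LEGAL:
    _LEGAL_ARR[_p] = True
_STACK_ARR = np.zeros((4, 4, 4, 4), dtype=np.float64)
for (_o, _i), _e in STACK_TABLE.items():
    _STACK_ARR[_CODE[_o[0]], _CODE[_o[1]], _CODE[_i[0]], _CODE[_i[1]]] = _e

_INF = 1e9


def _encode(seq: str) -> np.ndarray:
    s = seq.upper().replace("U", "T")
    if not re.fullmatch(r"[ACGT]+", s):
        raise ValueError("sequence must contain only A/C/G/U(T)")
    return np.array([_CODE[c] for c in s], dtype=np.int64)


@dataclass(frozen=True)
class HairpinFold:
    """An MFE structure: dot-bracket, energy, loop count, pair map."""

    sequence: str
    dot_bracket: str
    mfe: float
    n_hairpin_loops: int
    pairs: tuple[tuple[int, int], ...]

    @property
    def partner(self) -> dict[int, int]:
        d = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    def pairing_fraction(self, start: int, end: int, opposite_only: bool = True) -> float:
        """Fraction of bases in [start, end) that are paired.

        With ``opposite_only`` the partner must lie wholly outside the
        interval (binding to the other arm rather than internally).
        """
        if end <= start:
            return 0.0
        part = self.partner
        n = 0
        for i in range(start, end):
            j = part.get(i)
            if j is None:
                continue
            if opposite_only and start <= j < end:
                continue
            n += 1
        return n / (end - start)

    def one_arm(self, start: int, end: int) -> bool:
        """True if all partners of [start, end) fall on a single side."""
        part = self.partner
        partners = [part[i] for i in range(start, end) if i in part and not start <= part[i] < end]
        if not partners:
            return False
        return all(j >= end for j in partners) or all(j < start for j in partners)


# ---------------------------------------------------------------------------
# DP kernel


def _fill_py(code: np.ndarray):
    n = len(code)
    V = np.full((n, n), _INF)
    W = np.zeros((n, n + 1))  # W[i, j+1] covers [i, j]; W[i, i] == empty
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            a, b = code[i], code[j]
            if _LEGAL_ARR[a, b]:
                best = W[i + 1, j]
                if j - 1 - (i + 1) > MIN_LOOP and _LEGAL_ARR[code[i + 1], code[j - 1]]:
                    s = _STACK_ARR[a, b, code[i + 1], code[j - 1]] + V[i + 1, j - 1]
                    if s < best:
                        best = s
                V[i, j] = best
            # W over [i, j]
            best = W[i, j]  # j unpaired
            for k in range(i, j - MIN_LOOP):
                if V[k, j] < _INF / 2:
                    cand = W[i, k] + HELIX_INIT + V[k, j]
                    if cand < best:
                        best = cand
            W[i, j + 1] = best
    return V, W


try:  # accelerate the O(n^3) fill; the pure-python kernel is the fallback
    from numba import njit

    _fill_numba = njit(cache=False)(_fill_py)

    def _fill(code: np.ndarray):
        return _fill_numba(code)

except Exception:  # pragma: no cover

    def _fill(code: np.ndarray):
        return _fill_py(code)


def _traceback(code: np.ndarray, V: np.ndarray, W: np.ndarray) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    stack = [("W", 0, len(code) - 1)]
    eps = 1e-7
    while stack:
        kind, i, j = stack.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if kind == "W":
            if abs(W[i, j + 1] - W[i, j]) < eps:
                stack.append(("W", i, j - 1))
                continue
            for k in range(i, j - MIN_LOOP):
                if V[k, j] < _INF / 2 and abs(W[i, j + 1] - (W[i, k] + HELIX_INIT + V[k, j])) < eps:
                    stack.append(("V", k, j))
                    stack.append(("W", i, k - 1))
                    break
        else:  # V: (i, j) paired
            pairs.append((i, j))
            a, b = code[i], code[j]
            if (
                j - 1 - (i + 1) > MIN_LOOP
                and _LEGAL_ARR[code[i + 1], code[j - 1]]
                and abs(V[i, j] - (_STACK_ARR[a, b, code[i + 1], code[j - 1]] + V[i + 1, j - 1])) < eps
            ):
                stack.append(("V", i + 1, j - 1))
            else:
                stack.append(("W", i + 1, j - 1))
    return sorted(pairs)


def _dot_bracket(n: int, pairs: list[tuple[int, int]]) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def count_hairpin_loops(dot_bracket: str) -> int:
    """Number of terminal loops: '(' followed only by dots then ')'."""
    return len(re.findall(r"\(\.*\)", dot_bracket))


def fold_hairpin(sequence: str) -> HairpinFold:
    """MFE structure of ``sequence`` under the simplified stacking model.

    Returns energy 0 and an all-dot structure when no negative-energy
    structure exists (the open chain is then optimal).
    """
    code = _encode(sequence)
    n = len(code)
    if n < MIN_LOOP + 2:
        return HairpinFold(sequence, "." * n, 0.0, 0, ())
    V, W = _fill(code)
    mfe = float(W[0, n])
    if mfe >= -1e-9:
        return HairpinFold(sequence, "." * n, 0.0, 0, ())
    pairs = _traceback(code, V, W)
    db = _dot_bracket(n, pairs)
    return HairpinFold(sequence, db, round(mfe, 6), count_hairpin_loops(db), tuple(pairs))


# ---------------------------------------------------------------------------
# enumeration oracle (independent scoring + explicit structure generation)


def score_structure(sequence: str, pairs) -> float:
    """Energy of an explicit pair set under the same parameter table.

    Sum of stacking terms for adjacent pairs plus HELIX_INIT per maximal
    helix; written against the pair set directly, independent of the DP.
    """
    code = _encode(sequence)
    pairset = set(map(tuple, pairs))
    e = 0.0
    for i, j in pairset:
        if (i + 1, j - 1) in pairset:
            e += float(_STACK_ARR[code[i], code[j], code[i + 1], code[j - 1]])
        if (i - 1, j + 1) not in pairset:
            e += HELIX_INIT
    return e


def enumerate_structures(sequence: str):
    """Yield every legal pair set (min loop 3) of a short sequence.

    Exhaustive recursion on the first position; intended for sequences of
    ~25 nt or less, where the structure space is fully enumerable.
    """
    code = _encode(sequence)
    n = len(code)
    if n > 32:
        raise ValueError("enumeration oracle restricted to short sequences")

    def rec(i: int, j: int):
        if j - i < MIN_LOOP + 1:
            yield ()
            return
        # i unpaired
        yield from rec(i + 1, j)
        for k in range(i + MIN_LOOP + 1, j + 1):
            if _LEGAL_ARR[code[i], code[k]]:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        yield ((i, k),) + inner + outer

    yield from rec(0, n - 1)


def optimal_by_enumeration(sequence: str) -> float:
    """Minimum score over all enumerated structures (0 = open chain)."""
    best = 0.0
    for pairs in enumerate_structures(sequence):
        s = score_structure(sequence, pairs)
        if s < best:
            best = s
    return best


# ---------------------------------------------------------------------------
# external folder adapter


class RNAfoldAdapter:
    """Fold via an external ``RNAfold`` executable (thermodynamic parity).

    Drop-in alternative to :func:`fold_hairpin`; candidate-filter logic is
    agnostic to which folder produced the :class:`HairpinFold`.
    """

    def __init__(self, executable: str = "RNAfold"):
        self.executable = executable

    def __call__(self, sequence: str) -> HairpinFold:
        out = subprocess.run(
            [self.executable, "--noPS"],
            input=sequence + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout.splitlines()
        db, energy = out[1].rsplit(" ", 1)
        db = db.strip()
        mfe = float(energy.strip("()"))
        stack, pairs = [], []
        for i, c in enumerate(db):
            if c == "(":
                stack.append(i)
            elif c == ")":
                pairs.append((stack.pop(), i))
        return HairpinFold(sequence, db, mfe, count_hairpin_loops(db), tuple(sorted(pairs)))
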