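"""RNA secondary-structure folding for hairpin evaluation.

miRNA precursor screening only needs fold-back (stem-loop) structures, so
the built-in baseline folder maximises base pairing under a no-multibranch
restriction: pairs are fully nested along a single stem with bulges and
internal loops, minimum hairpin loop of 3 nt.  That restriction turns the
classic cubic maximum-pairing recursion into a quadratic one.

Baseline energies are simple additive pseudo-energies (per pair and per
stacked pair), NOT thermodynamic free energies; they are calibrated only
so that long, well-paired stems score far below short or sloppy ones.  A
thermodynamic engine (the RNAfold executable, if installed) can be plugged
in via :class:`RNAfoldEngine`; the energy gate used in miRNA screening is
meaningful in kcal/mol only with such an engine.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
          ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}

# pseudo-energy increments (arbitrary units reported as kcal/mol-like numbers)
_E_PAIR = -1.0
_E_STACK = -2.0

MIN_LOOP = 3


@dataclass
class FoldResult:
    sequence: str
    structure: str          # dot-bracket, same length as sequence
    energy: float           # kcal/mol (thermodynamic engines) or pseudo-energy
    thermodynamic: bool = False

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")

    def pair_table(self) -> List[int]:
        """1-based pair table: pt[i] = partner of position i, 0 if unpaired.

        Index 0 is unused (kept 0) so positions match the package's 1-based
        coordinate convention.
        """
        pt = [0] * (len(self.structure) + 1)
        stack: List[int] = []
        for i, c in enumerate(self.structure, start=1):
            if c == "(":
                stack.append(i)
            elif c == ")":
                j = stack.pop()
                pt[i], pt[j] = j, i
        if stack:
            raise ValueError("unbalanced dot-bracket structure")
        return pt


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def fold(sequence: str, engine: Optional["RNAfoldEngine"] = None) -> FoldResult:
    """Fold a sequence into its best stem-loop structure.

    Uses the configured thermodynamic engine when given, otherwise the
    baseline maximum-pairing folder.  Raises on non-nucleotide characters
    or sequences longer than 1000 nt.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) > 1000:
        raise ValueError("fold() supports sequences up to 1000 nt")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"cannot fold sequence with characters {sorted(bad)}")
    if engine is not None:
        return engine.fold(sequence)
    return _baseline_fold(seq)


def _baseline_fold(seq: str) -> FoldResult:
    """Quadratic no-multibranch stacking-aware DP with traceback.

    Maximises pairs + 2 * stacked pairs, so contiguous helices dominate
    scattered isolated pairs; the reported pseudo-energy is the negated
    objective.
    """
    n = len(seq)
    if n < MIN_LOOP + 2:
        return FoldResult(seq, "." * n, 0.0, False)
    STACK_BONUS = 2
    # P[i][j]: best score in i..j given (i, j) paired; M[i][j]: best overall
    M = np.zeros((n + 1, n + 1), dtype=np.int32)
    P = np.full((n + 1, n + 1), -(10 ** 6), dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if _can_pair(seq[i], seq[j]):
                inner = M[i + 1][j - 1]
                if P[i + 1][j - 1] >= 0:
                    inner = max(inner, P[i + 1][j - 1] + STACK_BONUS)
                P[i][j] = 1 + inner
            M[i][j] = max(M[i + 1][j], M[i][j - 1], P[i][j])
    struct = ["."] * n
    pairs: List[Tuple[int, int]] = []
    stack = [(0, n - 1, False)]
    while stack:
        i, j, paired = stack.pop()
        if i >= j:
            continue
        if paired:
            struct[i], struct[j] = "(", ")"
            pairs.append((i, j))
            if P[i + 1][j - 1] >= 0 and P[i][j] == 1 + STACK_BONUS + P[i + 1][j - 1]:
                stack.append((i + 1, j - 1, True))
            else:
                stack.append((i + 1, j - 1, False))
        elif M[i][j] == P[i][j]:
            stack.append((i, j, True))
        elif M[i][j] == M[i + 1][j]:
            stack.append((i + 1, j, False))
        else:
            stack.append((i, j - 1, False))
    energy = _pseudo_energy(pairs)
    return FoldResult(seq, "".join(struct), energy, False)


def _pseudo_energy(pairs: List[Tuple[int, int]]) -> float:
    if not pairs:
        return 0.0
    pairset = set(pairs)
    e = _E_PAIR * len(pairs)
    for (i, j) in pairs:
        if (i + 1, j - 1) in pairset:
            e += _E_STACK
    return round(e, 2)


class RNAfoldEngine:
    """Thermodynamic MFE folding via the RNAfold executable (if installed)."""

    def __init__(self, executable: str = "RNAfold"):
        path = shutil.which(executable)
        if path is None:
            raise RuntimeError(f"{executable} not found on PATH")
        self.executable = path

    def fold(self, sequence: str) -> FoldResult:
        seq = sequence.upper().replace("T", "U")
        proc = subprocess.run(
            [self.executable, "--noPS"],
            input=seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        lines = proc.stdout.strip().splitlines()
        struct_line = lines[-1]
        structure = struct_line.split(None, 1)[0]
        energy = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
        return FoldResult(sequence.upper().replace("U", "T"), structure, energy, True)


def default_engine() -> Optional[RNAfoldEngine]:
    """The RNAfold engine when the executable is installed, else None."""
    try:
        return RNAfoldEngine()
    except RuntimeError:
        return None
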