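"""RNA secondary-structure prediction by base-pair maximization.

The folder is a Nussinov-style dynamic program over nested (pseudoknot-free)
structures with Watson-Crick plus G:U wobble pairs and a minimum hairpin
loop of 3 nt.  It maximizes the number of base pairs, which is sufficient
to verify stem-loop precursor criteria; it is not a thermodynamic
minimum-free-energy model.  A plug-in hook (``external_folder``) accepts
any callable returning a dot-bracket string for users who want MFE parity
with Vienna-style folders.

Tie-breaking in the traceback is deterministic: when several partners for
the closing base achieve the optimum, the partner with the smallest index
is chosen, so identical inputs always give identical structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import AlphabetError, canonical, to_rna

MIN_LOOP = 3
MAX_FOLD_LEN = 600

# canonical DNA alphabet internally: A-T, G-C and the G-T wobble
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


@dataclass
class SecondaryStructure:
    """A nested structure over one sequence.

    ``pairs`` maps each paired position to its partner (both directions);
    ``loop_positions`` lists the hairpin loops as 0-based half-open spans
    (maximal unpaired runs directly closed by a pair).
    """

    sequence: str
    dot_bracket: str
    pair_count: int
    pairs: dict[int, int]
    loop_positions: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dot_bracket):
            raise ValueError("dot_bracket length must equal sequence length")

    @property
    def rna(self) -> str:
        return to_rna(self.sequence)

    def vienna(self) -> str:
        """Two-line Vienna-style display (RNA alphabet + dot-bracket)."""
        return f"{self.rna}\n{self.dot_bracket}"


def _fill_dp_python(dp: np.ndarray, pairable: np.ndarray, min_loop: int) -> None:
    """Nussinov recurrence: dp[i, j] = max pairs in s[i..j] (inclusive)."""
    n = dp.shape[0]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if pairable[k, j]:
                    left = dp[i, k - 1] if k > i else 0
                    v = left + dp[k + 1, j - 1] + 1
                    if v > best:
                        best = v
            dp[i, j] = best


try:  # JIT the O(n^3) fill; results are identical to the Python fill
    from numba import njit

    _fill_dp = njit(cache=True)(_fill_dp_python)
except ImportError:  # pragma: no cover
    _fill_dp = _fill_dp_python


def _pair_matrix(s: str) -> np.ndarray:
    codes = np.frombuffer(s.encode(), dtype=np.uint8)
    n = len(s)
    mat = np.zeros((n, n), dtype=bool)
    for (a, b) in _PAIRS:
        mat |= (codes[:, None] == ord(a)) & (codes[None, :] == ord(b))
    return mat


def fold(
    sequence: str,
    min_loop: int = MIN_LOOP,
    external_folder: Callable[[str], str] | None = None,
) -> SecondaryStructure:
    """Fold a sequence into its maximum-base-pair nested structure.

    ``external_folder``, if given, must map an RNA string to a dot-bracket
    string of equal length; it replaces the internal dynamic program.
    """
    s = canonical(sequence)
    n = len(s)
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence length {n} exceeds folding limit {MAX_FOLD_LEN}")
    if external_folder is not None:
        db = external_folder(to_rna(s))
        return structure_from_dot_bracket(s, db)
    if n == 0:
        return SecondaryStructure(s, "", 0, {}, [])

    pairable = _pair_matrix(s)
    dp = np.zeros((n, n), dtype=np.int32)
    _fill_dp(dp, pairable, min_loop)
    # partners_of[j]: ascending candidate partner indices k with pairable[k, j]
    partners_of = [np.flatnonzero(pairable[:, j]) for j in range(n)]

    # deterministic traceback: smallest partner index first
    pairs: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = dp[i, j]
        ks = partners_of[j]
        ks = ks[(ks >= i) & (ks <= j - min_loop - 1)]
        chosen = -1
        for k in ks:
            left = dp[i, k - 1] if k > i else 0
            if left + dp[k + 1, j - 1] + 1 == target:
                chosen = int(k)
                break
        if chosen >= 0:
            pairs[chosen] = j
            pairs[j] = chosen
            if chosen > i:
                stack.append((i, chosen - 1))
            stack.append((chosen + 1, j - 1))
        else:
            stack.append((i, j - 1))

    db = "".join(
        "(" if i in pairs and pairs[i] > i else ")" if i in pairs else "."
        for i in range(n)
    )
    return SecondaryStructure(s, db, len(pairs) // 2, pairs, _hairpin_loops(pairs, n))


def structure_from_dot_bracket(sequence: str, dot_bracket: str) -> SecondaryStructure:
    """Build a :class:`SecondaryStructure` from an existing dot-bracket string."""
    s = canonical(sequence)
    if len(s) != len(dot_bracket):
        raise ValueError("dot_bracket length must equal sequence length")
    pairs: dict[int, int] = {}
    opens: list[int] = []
    for i, c in enumerate(dot_bracket):
        if c == "(":
            opens.append(i)
        elif c == ")":
            if not opens:
                raise ValueError("unbalanced dot-bracket string")
            k = opens.pop()
            pairs[k] = i
            pairs[i] = k
        elif c != ".":
            raise ValueError(f"illegal dot-bracket character {c!r}")
    if opens:
        raise ValueError("unbalanced dot-bracket string")
    return SecondaryStructure(s, dot_bracket, len(pairs) // 2, pairs, _hairpin_loops(pairs, len(s)))


def _hairpin_loops(pairs: dict[int, int], n: int) -> list[tuple[int, int]]:
    """Hairpin loops: spans (i+1, j) with (i, j) paired and nothing paired inside."""
    loops = []
    for i, j in pairs.items():
        if j <= i:
            continue
        if all(k not in pairs for k in range(i + 1, j)):
            loops.append((i + 1, j))
    return sorted(loops)


# ---------------------------------------------------------------------------
# Hairpin metrics for miRNA precursor criteria
# ---------------------------------------------------------------------------


class NotHairpinError(ValueError):
    """The putative mature sequence does not sit on a hairpin stem."""


@dataclass
class HairpinMetrics:
    mature_paired_fraction: float
    duplex_mismatches: int
    max_asym_bulge: int
    star_interval: tuple[int, int]  # 0-based half-open within the precursor
    loop_size: int
    precursor_length: int


def hairpin_metrics(
    structure: SecondaryStructure, mature_interval: tuple[int, int]
) -> HairpinMetrics:
    """Compute duplex metrics for a mature miRNA placed on a folded precursor.

    ``mature_interval`` is 0-based half-open within the precursor.  The
    star interval is the region pairing with the mature duplex shifted by
    the canonical 2-nt 3' overhang.  Raises :class:`NotHairpinError` when
    the mature lies wholly in a terminal loop (no paired position).
    """
    ms, me = mature_interval
    n = len(structure.sequence)
    if not (0 <= ms < me <= n):
        raise ValueError("mature_interval outside the precursor")
    mature_len = me - ms
    paired_positions = [p for p in range(ms, me) if p in structure.pairs]
    if not paired_positions:
        raise NotHairpinError("mature sequence maps entirely to an unpaired region")

    partners = [structure.pairs[p] for p in paired_positions]
    p_lo, p_hi = min(partners), max(partners)
    if ms <= p_lo <= me - 1 or ms <= p_hi <= me - 1:
        raise NotHairpinError("mature sequence pairs with itself (terminal loop)")

    # star: partner span shifted 2 nt toward the precursor 3' end when the
    # star arm lies 3' of the mature, and toward 5' otherwise (DCL geometry:
    # both duplex strands leave a 2-nt 3' overhang)
    shift = 2 if p_lo > me - 1 else -2
    star_lo = max(0, p_lo + shift)
    star_hi = min(n, p_hi + 1 + shift)
    star_interval = (star_lo, star_hi)

    # duplex mismatches: unpaired mature positions (their partner region is
    # present because at least part of the mature is in the duplex)
    duplex_mismatches = mature_len - len(paired_positions)

    # largest asymmetry between opposing unpaired runs within the duplex
    max_asym = 0
    for a, b in zip(paired_positions, paired_positions[1:]):
        gap_m = b - a - 1
        gap_s = abs(structure.pairs[a] - structure.pairs[b]) - 1
        max_asym = max(max_asym, abs(gap_m - gap_s))

    loop_size = _loop_between_arms(structure, (ms, me), star_interval)

    return HairpinMetrics(
        mature_paired_fraction=len(paired_positions) / mature_len,
        duplex_mismatches=duplex_mismatches,
        max_asym_bulge=max_asym,
        star_interval=star_interval,
        loop_size=loop_size,
        precursor_length=n,
    )


def _loop_between_arms(
    structure: SecondaryStructure,
    mature: tuple[int, int],
    star: tuple[int, int],
) -> int:
    """Size of the hairpin loop between the mature and star arms.

    Picks the hairpin loop lying between the two arms; falls back to the
    largest hairpin loop when the structure has no loop strictly between
    them (e.g. a branched fold).
    """
    lo = min(mature[1], star[1])
    hi = max(mature[0], star[0])
    between = [
        (a, b) for a, b in structure.loop_positions if a >= lo - 1 and b <= hi + 1
    ]
    if between:
        return max(b - a for a, b in between)
    if structure.loop_positions:
        return max(b - a for a, b in structure.loop_positions)
    return 0


def mature_in_loop(structure: SecondaryStructure, mature_interval: tuple[int, int]) -> bool:
    """True when the mature interval sits wholly inside a hairpin loop."""
    ms, me = mature_interval
    if any(p in structure.pairs for p in range(ms, me)):
        return False
    return any(a <= ms and me <= b for a, b in structure.loop_positions)
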