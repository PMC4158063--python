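"""Independent reference implementations used only to check the package.

These deliberately avoid the production code paths: the folding oracle
enumerates nested structures by exhaustive recursion (no dynamic-program
table), and the SSR oracle is a direct quadratic scan.
"""

from __future__ import annotations

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def brute_force_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum base pairs over all nested structures, by exhaustive
    recursion over every pairing choice (feasible for len <= ~16)."""

    def rec(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        best = rec(i, j - 1)  # j unpaired
        for k in range(i, j - min_loop):
            if (seq[k], seq[j]) in _PAIRS:
                inside = rec(k + 1, j - 1)
                outside = rec(i, k - 1) if k > i else 0
                best = max(best, outside + inside + 1)
        return best

    return rec(0, len(seq) - 1) if seq else 0


def brute_force_ssrs(
    sequence: str, thresholds: dict[int, int]
) -> set[tuple[int, int, str, int]]:
    """All maximal tandem repeats as (start0, end0, unit, reps), with
    smallest-unit nested suppression, by direct scanning."""
    n = len(sequence)
    accepted: list[tuple[int, int, str, int]] = []
    for u in sorted(thresholds):
        jump_end = 0  # leftmost phase of a run wins within one unit length
        for i in range(n - u + 1):
            if i < jump_end:
                continue
            unit = sequence[i:i + u]
            if "N" in unit:
                continue
            if unit in (unit + unit)[1:-1]:  # periodic unit -> smaller period exists
                continue
            if i >= u and sequence[i - u:i] == unit:  # not left-maximal
                continue
            reps = 1
            while sequence[i + reps * u:i + (reps + 1) * u] == unit:
                reps += 1
            if reps < thresholds[u]:
                continue
            span = (i, i + reps * u)
            jump_end = span[1]
            if any(a <= span[0] and span[1] <= b for a, b, _, _ in accepted):
                continue  # nested inside a smaller-unit report
            accepted.append((span[0], span[1], unit, reps))
    return set(accepted)


def naive_alignment_penalty(mirna: str, site: str) -> float:
    """Position-by-position recomputation of the target penalty score."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    wobble = {("G", "T"), ("T", "G")}
    total = 0.0
    for p in range(1, len(mirna) + 1):
        m = mirna[p - 1]
        t = site[len(site) - p]  # antiparallel partner
        if comp.get(m) == t:
            cost = 0.0
        elif (m, t) in wobble:
            cost = 0.5
        else:
            cost = 1.0
        if 2 <= p <= 13:
            cost *= 2.0
        total += cost
    return total


def naive_substring_hits(query: str, genome: dict[str, str]) -> int:
    """O(n*m) substring scan counting exact hits of query on both strands."""
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = query.translate(comp)[::-1]
    hits = 0
    for seq in genome.values():
        for q in (query, rc):
            hits += sum(
                1 for i in range(len(seq) - len(q) + 1) if seq[i:i + len(q)] == q
            )
    return hits
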