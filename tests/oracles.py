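"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and libraries) they check:
alignment identity is computed by exhaustive enumeration of every alignment
of two short sequences, and interval operations are checked against explicit
position sets.
"""
from __future__ import annotations

from fractions import Fraction

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2
GAP_EXTEND = -1

# ops: "M" consumes one base of each; "D" consumes target only (gap in the
# query row); "I" consumes query only (gap in the target row).


def _enumerate_ops(m: int, n: int):
    """Yield every alignment of a length-m target and length-n query."""
    stack = [(0, 0, [])]
    while stack:
        i, j, ops = stack.pop()
        if i == m and j == n:
            yield ops
            continue
        if i < m and j < n:
            stack.append((i + 1, j + 1, ops + ["M"]))
        if i < m:
            stack.append((i + 1, j, ops + ["D"]))
        if j < n:
            stack.append((i, j + 1, ops + ["I"]))


def _score_and_identity(target: str, query: str, ops: list[str]):
    """Score one alignment (free terminal query-row gaps) and its identity.

    Returns (score, matches, columns) where columns span the first to last
    aligned base pair, matching the package's identity convention.
    """
    # runs of identical ops, with their start index in the op list
    runs: list[tuple[str, int, int]] = []
    for idx, op in enumerate(ops):
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1], runs[-1][2] + 1)
        else:
            runs.append((op, idx, 1))
    score = 0
    i = j = 0
    matches = 0
    first_m = last_m = None
    col = 0
    for op in ops:
        if op == "M":
            score += MATCH if target[i] == query[j] else MISMATCH
            if target[i] == query[j]:
                matches += 1
            if first_m is None:
                first_m = col
            last_m = col
            i += 1
            j += 1
        elif op == "D":
            i += 1
        else:
            j += 1
        col += 1
    for op, start, length in runs:
        if op == "M":
            continue
        terminal_d = op == "D" and (start == 0 or start + length == len(ops))
        if not terminal_d:
            score += GAP_OPEN + (length - 1) * GAP_EXTEND
    if first_m is None:
        return score, 0, 0
    # columns between first and last aligned pair inclusive; matches counted
    # only at M ops, gap ops inside the core are non-matching columns
    columns = last_m - first_m + 1
    # subtract matches outside the core: impossible (core defined by M ops)
    return score, matches, columns


def semi_global_identity_set(seq_a: str, seq_b: str) -> tuple[int, set[Fraction]]:
    """(optimal score, set of identities over all optimal alignments).

    Mirrors the package convention for role assignment: the longer sequence
    (lexicographic order breaking ties) is the target whose terminal
    overhangs are free.
    """
    x, y = sorted((seq_a, seq_b), key=lambda s: (len(s), s))
    target, query = y, x
    best = None
    identities: set[Fraction] = set()
    for ops in _enumerate_ops(len(target), len(query)):
        score, matches, columns = _score_and_identity(target, query, ops)
        identity = Fraction(int(matches), int(columns)) if columns else Fraction(0)
        if best is None or score > best:
            best = score
            identities = {identity}
        elif score == best:
            identities.add(identity)
    return best, identities


def covered_positions(intervals) -> set[int]:
    return {p for s, e in intervals for p in range(s, e)}


def merge_proximal_bruteforce(intervals, max_gap: int) -> list[tuple[int, int]]:
    """Interval decomposition of the gap-chained position set.

    A position belongs to the merged set iff it is covered or lies in a gap
    of <= max_gap uncovered positions between covered positions; chains of
    such gaps collapse transitively.
    """
    pos = covered_positions(intervals)
    if not pos:
        return []
    filled = set(pos)
    ordered = sorted(pos)
    for a, b in zip(ordered, ordered[1:]):
        if 0 < b - a - 1 <= max_gap:
            filled.update(range(a + 1, b))
    out: list[tuple[int, int]] = []
    for p in sorted(filled):
        if out and p == out[-1][1]:
            out[-1] = (out[-1][0], p + 1)
        else:
            out.append((p, p + 1))
    return out


def union_intervals_bruteforce(intervals) -> list[tuple[int, int]]:
    """Union of intervals where touching counts as overlapping."""
    return merge_proximal_bruteforce(intervals, 0)
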