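"""Independent reference implementations used as test oracles.

These deliberately avoid the package's own code paths: alignment scores by
exhaustive enumeration of every monotone alignment, period scores by a
character-by-character loop, GOR calls by naive re-summation of the raw
table file.
"""

from __future__ import annotations

from itertools import product

import pandas as pd

GAP = "-"


def _move_strings(n: int, m: int):
    """All monotone alignments of lengths (n, m) as strings over D/U/L."""
    # D consumes one of each, U consumes from a, L consumes from b
    def rec(i, j, acc):
        if i == n and j == m:
            yield acc
            return
        if i < n and j < m:
            yield from rec(i + 1, j + 1, acc + "D")
        if i < n:
            yield from rec(i + 1, j, acc + "U")
        if j < m:
            yield from rec(i, j + 1, acc + "L")

    yield from rec(0, 0, "")


def _score_moves(
    a: str, b: str, moves: str, score_pair, gap_open: float, gap_extend: float
) -> float:
    """Affine score of one alignment: a gap run of length g costs
    open + (g - 1) * extend."""
    total = 0.0
    i = j = 0
    prev = "D"
    for mv in moves:
        if mv == "D":
            total += score_pair(a[i], b[j])
            i += 1
            j += 1
        else:
            total += gap_extend if mv == prev else gap_open
            if mv == "U":
                i += 1
            else:
                j += 1
        prev = mv
    return total


def exhaustive_global_score(
    a: str, b: str, score_pair, gap_open: float = -10.0, gap_extend: float = -1.0
) -> float:
    """Optimal global affine-gap score by enumerating every alignment."""
    return max(
        _score_moves(a, b, mv, score_pair, gap_open, gap_extend)
        for mv in _move_strings(len(a), len(b))
    )


def exhaustive_local_score(
    a: str, b: str, score_pair, gap_open: float = -10.0, gap_extend: float = -1.0
) -> float:
    """Optimal local score: best global score over all substring pairs."""
    best = 0.0
    for i1, i2 in product(range(len(a) + 1), repeat=2):
        if i2 <= i1:
            continue
        for j1, j2 in product(range(len(b) + 1), repeat=2):
            if j2 <= j1:
                continue
            s = exhaustive_global_score(
                a[i1:i2], b[j1:j2], score_pair, gap_open, gap_extend
            )
            best = max(best, s)
    return best


def identity_pair(x: str, y: str) -> float:
    return 1.0 if x == y else 0.0


def blosum62_pair():
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    return lambda x, y: float(m[x, y])


def naive_period_scores(region: str, min_period: int, max_period: int) -> dict[int, float]:
    out = {}
    for p in range(min_period, max_period + 1):
        matches = sum(1 for i in range(len(region) - p) if region[i] == region[i + p])
        out[p] = 100.0 * matches / (len(region) - p)
    return out


def naive_gor_calls(seq: str, table_path) -> str:
    """Re-sum the raw GOR table file position by position and argmax."""
    df = pd.read_csv(table_path, sep="\t")
    states = ["helix", "sheet", "turn", "coil"]
    code = {"helix": "H", "sheet": "E", "turn": "T", "coil": "C"}
    values: dict[tuple[str, str, int], float] = {}
    for _, row in df.iterrows():
        for d in range(-8, 9):
            values[(row["state"], row["residue"], d)] = float(row[f"d{d:+d}"])
    calls = []
    for i in range(len(seq)):
        best_state, best_score = None, None
        for s in states:  # fixed priority order: first strict maximum wins
            score = 0.0
            for d in range(-8, 9):
                j = i + d
                if 0 <= j < len(seq) and (s, seq[j], d) in values:
                    score += values[(s, seq[j], d)]
            if best_score is None or score > best_score:
                best_state, best_score = s, score
        calls.append(code[best_state])
    return "".join(calls)
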