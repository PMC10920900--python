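"""Independent brute-force oracles used to validate the implementation.

These deliberately re-derive expected results by different algorithms
than the package uses: exhaustive column-path enumeration and a 3-state
dynamic program for alignments, a closed-form run-product construction
for splice-path enumeration, and exhaustive subset enumeration for the
hypergeometric tail.
"""

from __future__ import annotations

from itertools import combinations, groupby, product
from math import comb

MATCH, MISMATCH, GAP_OPEN = 1.0, -1.0, -3.0
NEG = float("-inf")


# ---------------------------------------------------------------------------
# Alignment oracles.  Scoring scheme: match +1, mismatch -1, each maximal
# gap run costs -3 (opening; extension free) except the run containing the
# final alignment column, which is free.
# ---------------------------------------------------------------------------

def _score_columns(cols: list[tuple[str, str]]) -> float:
    score = 0.0
    runs = []
    k, n = 0, len(cols)
    while k < n:
        tc, qc = cols[k]
        if tc == "-" or qc == "-":
            which = 0 if tc == "-" else 1
            k2 = k
            while k2 < n and cols[k2][which] == "-":
                k2 += 1
            runs.append((k, k2))
            k = k2
        else:
            score += MATCH if tc == qc else MISMATCH
            k += 1
    for _, end in runs:
        if end != n:
            score += GAP_OPEN
    return score


def _events_from_columns(cols: list[tuple[str, str]], target: str):
    """(events, mismatches) with the anchor convention of align_proteins."""
    events: list[tuple[str, int, int]] = []
    mismatches: list[int] = []
    ti = 0
    last_aligned_t = -1
    k, n = 0, len(cols)
    while k < n:
        tc, qc = cols[k]
        if tc == "-":  # insertion (gap in target)
            k2 = k
            while k2 < n and cols[k2][0] == "-":
                k2 += 1
            events.append(("insertion", max(last_aligned_t, 0), k2 - k))
            k = k2
        elif qc == "-":  # deletion (gap in query)
            k2 = k
            length = 0
            while k2 < n and cols[k2][0] != "-" and cols[k2][1] == "-":
                k2 += 1
                length += 1
            events.append(("deletion", ti, length))
            ti += length
            k = k2
        else:
            if tc != qc:
                mismatches.append(ti)
            last_aligned_t = ti
            ti += 1
            k += 1
    return tuple(sorted(events)), tuple(mismatches)


def enumerate_optimal_alignments(target: str, query: str):
    """All optimal (events, mismatches) extractions, by full enumeration.

    Exponential: use only for sequences of length <= ~6.
    """
    best = [NEG]
    optimal: set = set()

    def rec(i: int, j: int, cols: list[tuple[str, str]]) -> None:
        if i == len(target) and j == len(query):
            s = _score_columns(cols)
            if s > best[0] + 1e-9:
                best[0] = s
                optimal.clear()
            if abs(s - best[0]) <= 1e-9:
                optimal.add(_events_from_columns(cols, target))
            return
        if i < len(target) and j < len(query):
            rec(i + 1, j + 1, cols + [(target[i], query[j])])
        if i < len(target):
            rec(i + 1, j, cols + [(target[i], "-")])
        if j < len(query):
            rec(i, j + 1, cols + [("-", query[j])])

    rec(0, 0, [])
    return best[0], optimal


def dp_alignment(target: str, query: str, max_paths: int = 20000):
    """3-state affine DP: optimal score and all optimal event extractions.

    States: M (diagonal), D (gap in query), I (gap in target).  The final
    gap run's opening cost is refunded, matching free right-end gaps.
    """
    n, m = len(target), len(query)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = GAP_OPEN
    for j in range(1, m + 1):
        I[0][j] = GAP_OPEN
    for i in range(n + 1):
        for j in range(m + 1):
            if i >= 1 and j >= 1:
                s = MATCH if target[i - 1] == query[j - 1] else MISMATCH
                M[i][j] = s + max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            if i >= 1:
                D[i][j] = max(
                    D[i][j],
                    M[i - 1][j] + GAP_OPEN if M[i - 1][j] > NEG else NEG,
                    D[i - 1][j],
                    I[i - 1][j] + GAP_OPEN if I[i - 1][j] > NEG else NEG,
                )
            if j >= 1:
                I[i][j] = max(
                    I[i][j],
                    M[i][j - 1] + GAP_OPEN if M[i][j - 1] > NEG else NEG,
                    I[i][j - 1],
                    D[i][j - 1] + GAP_OPEN if D[i][j - 1] > NEG else NEG,
                )
    best = max(M[n][m], D[n][m] - GAP_OPEN, I[n][m] - GAP_OPEN)

    # enumerate optimal paths backwards; states recorded forward afterwards
    paths: list[list[str]] = []

    def back(i: int, j: int, state: str, need: float, moves: list[str]) -> None:
        if len(paths) >= max_paths:
            return
        if i == 0 and j == 0:
            if state == "M" and abs(need) < 1e-9:
                paths.append(moves[::-1])
            return
        eps = 1e-9
        if state == "M":
            if i == 0 or j == 0:
                return
            s = MATCH if target[i - 1] == query[j - 1] else MISMATCH
            for prev in ("M", "D", "I"):
                val = {"M": M, "D": D, "I": I}[prev][i - 1][j - 1]
                if val > NEG and abs(s + val - need) < eps:
                    back(i - 1, j - 1, prev, val, moves + ["M"])
        elif state == "D":
            if i == 0:
                return
            for prev, cost in (("M", GAP_OPEN), ("D", 0.0), ("I", GAP_OPEN)):
                val = {"M": M, "D": D, "I": I}[prev][i - 1][j]
                if val > NEG and abs(val + cost - need) < eps:
                    back(i - 1, j, prev, val, moves + ["D"])
        else:
            if j == 0:
                return
            for prev, cost in (("M", GAP_OPEN), ("I", 0.0), ("D", GAP_OPEN)):
                val = {"M": M, "D": D, "I": I}[prev][i][j - 1]
                if val > NEG and abs(val + cost - need) < eps:
                    back(i, j - 1, prev, val, moves + ["I"])

    eps = 1e-9
    if abs(M[n][m] - best) < eps:
        back(n, m, "M", M[n][m], [])
    if abs(D[n][m] - GAP_OPEN - best) < eps:
        back(n, m, "D", D[n][m], [])
    if abs(I[n][m] - GAP_OPEN - best) < eps:
        back(n, m, "I", I[n][m], [])

    extractions = set()
    for moves in paths:
        cols = []
        i = j = 0
        for mv in moves:
            if mv == "M":
                cols.append((target[i], query[j])); i += 1; j += 1
            elif mv == "D":
                cols.append((target[i], "-")); i += 1
            else:
                cols.append(("-", query[j])); j += 1
        extractions.add(_events_from_columns(cols, target))
    capped = len(paths) >= max_paths
    return best, extractions, capped


# ---------------------------------------------------------------------------
# Splice-path enumeration oracle: closed-form run-product construction.
# ---------------------------------------------------------------------------

def chain_oracle(sites: list[tuple[int, str]]) -> set[tuple[tuple[int, int], ...]]:
    """All legal alternating donor→acceptor chains for a sorted site pool.

    Runs of same-kind sites strictly alternate; a chain picks exactly one
    member per run, skipping a leading acceptor run and a trailing
    unpaired donor run.  Returns the set of intron tuples.
    """
    runs = [
        (kind, [p for p, _ in grp])
        for kind, grp in ((k, list(g)) for k, g in groupby(sites, key=lambda s: s[1]))
    ]
    if runs and runs[0][0] == "acceptor":
        runs = runs[1:]
    if len(runs) % 2:
        runs = runs[:-1]
    if not runs:
        return {()}
    choices = [positions for _, positions in runs]
    out = set()
    for combo in product(*choices):
        out.add(tuple(zip(combo[::2], combo[1::2])))
    return out


# ---------------------------------------------------------------------------
# Hypergeometric lower tail by exhaustive subset enumeration.
# ---------------------------------------------------------------------------

def hypergeom_lower_oracle(N: int, K: int, n: int, k: int) -> float:
    """P(|subset ∩ flagged| <= k) over all C(N, n) subsets, flagged = first K."""
    flagged = set(range(K))
    hits = sum(
        1 for subset in combinations(range(N), n)
        if len(flagged.intersection(subset)) <= k
    )
    return hits / comb(N, n)
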