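"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or exact arithmetic,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, inf


# --- off-target scanning ----------------------------------------------------

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq: str) -> str:
    return "".join(_RC.get(b, "N") for b in reversed(seq))


def brute_force_offtargets(genome, spacer, max_mm):
    """Test every window on both strands; returns a set of site tuples.

    Tuples are (chrom, start, strand, protospacer, pam, down4, n_mm) with
    start = leftmost reference coordinate of the protospacer.
    """
    hits = set()
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else _revcomp(seq)
            for p in range(n - 27 + 1):
                window = s[p : p + 27]
                if any(b not in "ACGT" for b in window):
                    continue
                proto, pam, down4 = window[:20], window[20:23], window[23:]
                if pam[1] != "G" or pam[2] != "G":
                    continue
                mm = sum(a != b for a, b in zip(proto, spacer))
                if mm <= max_mm:
                    start = p if strand == "+" else n - p - 20
                    hits.add((chrom, start, strand, proto, pam, down4, mm))
    return hits


# --- Fisher's exact test ----------------------------------------------------

def exact_fisher_two_sided(a, b, c, d):
    """Two-sided Fisher p by exact integer enumeration over the support."""
    r1, r2, c1 = a + b, c + d, a + c
    total = r1 + r2
    if total == 0 or c1 == 0 or c1 == total or r1 == 0 or r2 == 0:
        return 1.0
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(kmin, kmax + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(num, comb(total, c1)))


# --- Benjamini-Hochberg -----------------------------------------------------

def bh_definitional(pvalues):
    """adj_i = min_{j: p_(j) >= p_(i)} (m / rank_j) * p_(j), capped at 1."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = inf
    for rank_index in range(m - 1, -1, -1):
        i = order[rank_index]
        running_min = min(running_min, m / (rank_index + 1) * pvalues[i])
        adjusted[i] = min(running_min, 1.0)
    return adjusted


# --- hypergeometric tails ---------------------------------------------------

def exact_hypergeom_tails(k, M, K, n):
    """(P(X >= k), P(X <= k), P(X == k)) by exact summation."""
    denom = comb(M, n)
    lo = max(0, n - (M - K))
    hi = min(K, n)
    upper = sum(comb(K, x) * comb(M - K, n - x) for x in range(max(k, lo), hi + 1))
    lower = sum(comb(K, x) * comb(M - K, n - x) for x in range(lo, min(k, hi) + 1))
    point = comb(K, k) * comb(M - K, n - k) if lo <= k <= hi else 0
    return (
        float(Fraction(upper, denom)),
        float(Fraction(lower, denom)),
        float(Fraction(point, denom)),
    )


# --- exhaustive alignment ---------------------------------------------------

def _gotoh_matrices(ref, obs, match, mismatch, gap_open, gap_extend):
    n, m = len(ref), len(obs)
    NEG = float("-inf")
    g1 = gap_open + gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = gap_open + gap_extend * i
    for j in range(1, m + 1):
        I[0][j] = gap_open + gap_extend * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == obs[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1]) + s
            D[i][j] = max(M[i - 1][j] + g1, D[i - 1][j] + gap_extend,
                          I[i - 1][j] + g1)
            I[i][j] = max(M[i][j - 1] + g1, I[i][j - 1] + gap_extend,
                          D[i][j - 1] + g1)
    return M, D, I


def _normalize_events(ops, ref, obs):
    """Convert an op string (list of 'M','D','I' with payload) to leftmost
    per-gap events [(start, op, length), ...]."""
    events = []
    i = j = 0  # consumed ref / obs
    idx = 0
    while idx < len(ops):
        op = ops[idx]
        if op == "M":
            i += 1
            j += 1
            idx += 1
            continue
        length = 0
        start_i, start_j = i, j
        while idx < len(ops) and ops[idx] == op:
            length += 1
            if op == "D":
                i += 1
            else:
                j += 1
            idx += 1
        if op == "D":
            a, b = start_i + 1, start_i + length  # 1-based deleted interval
            while a > 1 and ref[a - 2] == ref[b - 1]:
                a -= 1
                b -= 1
            events.append((a, "del", length, b))
        else:
            block = obs[start_j : start_j + length]
            anchor = start_i
            while anchor >= 1 and ref[anchor - 1] == block[-1]:
                block = block[-1] + block[:-1]
                anchor -= 1
            events.append((anchor, "ins", length, anchor))
    return tuple(events)


def exhaustive_optimal_indel_calls(
    ref, obs, match=2.0, mismatch=-4.0, gap_open=-6.0, gap_extend=-1.0,
    limit=20000,
):
    """All distinct leftmost-normalised gap-call tuples over every optimal
    global alignment, plus the canonical (lexicographically smallest) one.
    """
    M, D, I = _gotoh_matrices(ref, obs, match, mismatch, gap_open, gap_extend)
    n, m = len(ref), len(obs)
    g1 = gap_open + gap_extend
    eps = 1e-9
    results = set()
    stack = []
    best = max(M[n][m], D[n][m], I[n][m])
    for state, mat in (("M", M), ("D", D), ("I", I)):
        if mat[n][m] >= best - eps:
            stack.append((n, m, state, []))
    while stack and len(results) < limit:
        i, j, state, ops = stack.pop()
        if i == 0 and j == 0:
            results.add(_normalize_events(list(reversed(ops)), ref, obs))
            continue
        if state == "M":
            s = match if ref[i - 1] == obs[j - 1] else mismatch
            target = M[i][j] - s
            for prev, mat in (("M", M), ("D", D), ("I", I)):
                if abs(mat[i - 1][j - 1] - target) < eps:
                    stack.append((i - 1, j - 1, prev, ops + ["M"]))
        elif state == "D":
            score = D[i][j]
            if abs(M[i - 1][j] + g1 - score) < eps:
                stack.append((i - 1, j, "M", ops + ["D"]))
            if abs(D[i - 1][j] + gap_extend - score) < eps:
                stack.append((i - 1, j, "D", ops + ["D"]))
            if abs(I[i - 1][j] + g1 - score) < eps:
                stack.append((i - 1, j, "I", ops + ["D"]))
        else:
            score = I[i][j]
            if abs(M[i][j - 1] + g1 - score) < eps:
                stack.append((i, j - 1, "M", ops + ["I"]))
            if abs(I[i][j - 1] + gap_extend - score) < eps:
                stack.append((i, j - 1, "I", ops + ["I"]))
            if abs(D[i][j - 1] + g1 - score) < eps:
                stack.append((i, j - 1, "D", ops + ["I"]))
    canonical = min(results) if results else tuple()
    return results, canonical
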