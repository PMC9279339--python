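"""Global alignment and indel calling for the 27-nt surrogate region.

The observed surrogate segment of each read is aligned end-to-end against the
27-nt reference (Needleman-Wunsch with affine gaps, Gotoh recursion) and only
gaps are reported as edits; substitutions are never indels.  Events are given
in reference N-coordinates N1..N27: a deletion reports the interval of deleted
reference bases, an insertion reports the reference base it follows (anchor 0
means before N1).  Each gap is normalised to its leftmost equivalent placement
so calls are deterministic within repeat runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG_INF = -1e18
_EPS = 1e-9


@dataclass(frozen=True)
class AlignScoring:
    """Alignment scores; a gap of length L costs ``gap_open + L * gap_extend``."""

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -6.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class IndelEvent:
    """One gap in the alignment, in 1-based reference coordinates.

    ``op`` is "del" or "ins".  For deletions, [start, end] is the deleted
    reference interval; for insertions start == end == the anchor position
    (the reference base the inserted sequence follows; 0 = before N1).
    """

    op: str
    length: int
    start: int
    end: int

    def overlaps(self, lo: int, hi: int) -> bool:
        """Interval-overlap test against reference window [lo, hi].

        Insertions are points at their anchor; the anchor position decides
        boundary cases.
        """
        if self.op == "ins":
            return lo <= self.start <= hi
        return self.start <= hi and self.end >= lo


def align_indels(
    observed: str, reference: str, scoring: AlignScoring | None = None
) -> list[IndelEvent]:
    """Call indels in ``observed`` relative to ``reference``.

    Returns an empty list when the optimal global alignment is gap-free
    (substitutions alone are not edits).  Gap placement ties are broken to the
    leftmost representation: the traceback prefers diagonal moves, and every
    gap is then shifted left through equal-scoring repeat placements.
    """
    if not observed or not reference:
        raise ValueError("both sequences must be nonempty")
    if observed == reference:
        return []
    sc = scoring or AlignScoring()
    n, m = len(reference), len(observed)
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    obs = np.frombuffer(observed.encode(), dtype=np.uint8)

    # M = match/mismatch state, D = gap in observed (deleted reference bases),
    # I = gap in reference (inserted observed bases).
    M = np.full((n + 1, m + 1), NEG_INF)
    D = np.full((n + 1, m + 1), NEG_INF)
    I = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    gap1 = sc.gap_open + sc.gap_extend
    for i in range(1, n + 1):
        D[i, 0] = sc.gap_open + sc.gap_extend * i
    for j in range(1, m + 1):
        I[0, j] = sc.gap_open + sc.gap_extend * j
    for i in range(1, n + 1):
        sub = np.where(obs == ref[i - 1], sc.match, sc.mismatch)
        Mi1, Di1, Ii1 = M[i - 1], D[i - 1], I[i - 1]
        Mi, Di, Ii = M[i], D[i], I[i]
        for j in range(1, m + 1):
            Mi[j] = max(Mi1[j - 1], Di1[j - 1], Ii1[j - 1]) + sub[j - 1]
            Di[j] = max(Mi1[j] + gap1, Di1[j] + sc.gap_extend, Ii1[j] + gap1)
            Ii[j] = max(Mi[j - 1] + gap1, Ii[j - 1] + sc.gap_extend,
                        Di[j - 1] + gap1)

    mats = {"M": M, "D": D, "I": I}
    i, j = n, m
    state = "M"
    best = max(M[i, j], D[i, j], I[i, j])
    for s in ("M", "D", "I"):
        if mats[s][i, j] >= best - _EPS:
            state = s
            break

    # raw gaps as (is_del, ref_end, obs_end, length), found end-first
    raw: list[list[int]] = []
    cur: list[int] | None = None
    while i > 0 or j > 0:
        if state == "M":
            cur = None
            prev = M[i, j] - (sc.match if ref[i - 1] == obs[j - 1] else sc.mismatch)
            i, j = i - 1, j - 1
            for s in ("M", "D", "I"):
                if abs(mats[s][i, j] - prev) < _EPS:
                    state = s
                    break
        elif state == "D":
            if cur is None or not cur[0]:
                cur = [True, i, j, 0]
                raw.append(cur)
            cur[3] += 1
            score = D[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] + gap1 - score) < _EPS:
                state = "M"
            elif abs(D[i, j] + sc.gap_extend - score) < _EPS:
                state = "D"
            else:
                state = "I"
        else:
            if cur is None or cur[0]:
                cur = [False, i, j, 0]
                raw.append(cur)
            cur[3] += 1
            score = I[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] + gap1 - score) < _EPS:
                state = "M"
            elif abs(I[i, j] + sc.gap_extend - score) < _EPS:
                state = "I"
            else:
                state = "D"
    raw.reverse()

    events: list[IndelEvent] = []
    for is_del, ref_end, obs_end, length in raw:
        if is_del:
            a, b = ref_end - length + 1, ref_end
            # shift left while the flanking reference base repeats the run
            while a > 1 and reference[a - 2] == reference[b - 1]:
                a -= 1
                b -= 1
            events.append(IndelEvent("del", length, a, b))
        else:
            k = obs_end
            block = observed[k - length : k]
            anchor = ref_end
            while anchor >= 1 and reference[anchor - 1] == block[-1]:
                block = block[-1] + block[:-1]
                anchor -= 1
            events.append(IndelEvent("ins", length, anchor, anchor))
    events.sort(key=lambda e: (e.start, e.op, e.length))
    return events
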