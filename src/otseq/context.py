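"""Mismatch position/type determinants of off-target activity.

Mismatches are annotated as (spacer base, protospacer base) pairs read on the
non-target strand, giving 12 ordered types (a "GA" mismatch is spacer G
against protospacer A, the pairing that forms the well-tolerated rG:dT wobble
with the target strand).  Profiles count mismatch occurrences per spacer
position N1..N20 and per type within a call group (ALL, NSOT, Sig, LIOT,
HIOT); enrichment of the significant group against a background is scored
with two-tailed hypergeometric tests, and guide GC content is compared
between high- and low-efficiency guides with a rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu

from .design import SPACER_LENGTH, parse_mismatches

MISMATCH_TYPES = tuple(
    g + p for g in "ACGT" for p in "ACGT" if g != p
)  # 12 ordered (spacer, protospacer) types

GROUPS = ("ALL", "NSOT", "Sig", "LIOT", "HIOT")


@dataclass
class MismatchProfile:
    group: str
    position_counts: np.ndarray  # length 20, N1..N20
    type_counts: dict[str, int]
    n_sites: int

    @property
    def n_mismatches_total(self) -> int:
        return int(self.position_counts.sum())

    def position_fractions(self) -> np.ndarray:
        total = self.n_mismatches_total
        if total == 0:
            return np.full(SPACER_LENGTH, np.nan)
        return self.position_counts / total

    def type_fractions(self) -> dict[str, float]:
        total = self.n_mismatches_total
        return {
            t: (n / total if total else float("nan"))
            for t, n in self.type_counts.items()
        }


def _select_group(
    manifest: pd.DataFrame,
    calls: pd.DataFrame | None,
    group: str,
    mm_range: tuple[int, int],
    exclude: set[str] | None,
) -> pd.DataFrame:
    lo, hi = mm_range
    sel = manifest[
        (manifest["n_mismatches"] >= lo) & (manifest["n_mismatches"] <= hi)
    ]
    if exclude:
        sel = sel[~sel["construct_id"].isin(exclude)]
    if group == "ALL":
        return sel
    if calls is None:
        raise ValueError(f"group {group!r} requires a calls table")
    by_call = dict(zip(calls["construct_id"], calls["call"]))
    if group == "Sig":
        wanted = {"LIOT", "HIOT"}
    elif group in ("NSOT", "LIOT", "HIOT"):
        wanted = {group}
    else:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    return sel[sel["construct_id"].map(lambda c: by_call.get(c) in wanted)]


def profile_mismatches(
    manifest: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    group: str = "ALL",
    mm_range: tuple[int, int] = (3, 4),
    exclude: set[str] | None = None,
) -> MismatchProfile:
    """Count mismatch positions and types over one call group.

    ``mm_range`` restricts sites by their total mismatch number (default 3-4,
    the classes where position effects are informative).  ``exclude`` drops
    constructs (e.g. growth-confounded, enrichment/depletion-flagged ones).
    The position and type marginals both sum to the total mismatch count, and
    the profile does not depend on site order.
    """
    sel = _select_group(manifest, calls, group, mm_range, exclude)
    position_counts = np.zeros(SPACER_LENGTH, dtype=int)
    type_counts = {t: 0 for t in MISMATCH_TYPES}
    for text in sel["mismatches"]:
        for pos, g, p in parse_mismatches(text):
            position_counts[pos - 1] += 1
            type_counts[g + p] += 1
    return MismatchProfile(
        group=group,
        position_counts=position_counts,
        type_counts=type_counts,
        n_sites=len(sel),
    )


def hypergeom_enrichment(
    sig: MismatchProfile,
    background: MismatchProfile,
    sig_subset_of_background: bool = True,
) -> pd.DataFrame:
    """Per-position and per-type hypergeometric enrichment of ``sig``.

    Mismatches of the significant group are modelled as a draw (without
    replacement) from the background mismatch pool: for each position/type
    with k observed among n drawn, K in the background of size M, the
    over-representation p is the upper tail P(X >= k) and the
    under-representation p the lower tail P(X <= k).

    When the background is the ALL group the significant counts must be a
    componentwise subset of it; set ``sig_subset_of_background=False`` for a
    disjoint background such as NSOT.
    """
    M = background.n_mismatches_total
    n = sig.n_mismatches_total
    rows = []
    items: list[tuple[str, str, int, int]] = [
        (
            "position", f"N{i + 1}",
            int(sig.position_counts[i]), int(background.position_counts[i]),
        )
        for i in range(SPACER_LENGTH)
    ] + [
        ("type", t, sig.type_counts[t], background.type_counts[t])
        for t in MISMATCH_TYPES
    ]
    for kind, label, k, K in items:
        if sig_subset_of_background and k > K:
            raise ValueError(
                f"significant counts are not a subset of the background at {label}"
            )
        over = float(hypergeom.sf(k - 1, M, K, n)) if M else float("nan")
        under = float(hypergeom.cdf(k, M, K, n)) if M else float("nan")
        rows.append(
            {
                "kind": kind, "label": label,
                "sig_count": k, "background_count": K,
                "over_p": min(over, 1.0), "under_p": min(under, 1.0),
            }
        )
    return pd.DataFrame(rows)


def gc_percent(spacer: str) -> float:
    return (spacer.count("G") + spacer.count("C")) / len(spacer) * 100.0


def gc_content_compare(
    guides: pd.DataFrame, threshold: float = 80.0
) -> dict:
    """Compare spacer GC% between high- and low-efficiency guides.

    ``guides`` needs columns ``spacer`` and ``on_target_if`` (percent).  The
    split is at ``threshold`` (default 80%, separating highly efficient
    guides); groups are compared with a two-sided Mann-Whitney rank-sum test.
    The p-value is NaN when either group is empty or all values coincide.
    """
    gc = guides["spacer"].map(gc_percent)
    high = gc[guides["on_target_if"] > threshold]
    low = gc[guides["on_target_if"] <= threshold]
    result = {
        "threshold": threshold,
        "n_high": int(high.size),
        "n_low": int(low.size),
        "mean_gc_high": float(high.mean()) if high.size else float("nan"),
        "mean_gc_low": float(low.mean()) if low.size else float("nan"),
        "p_value": float("nan"),
    }
    if high.size and low.size and not (
        high.nunique() == 1 and low.nunique() == 1 and high.iloc[0] == low.iloc[0]
    ):
        result["p_value"] = float(
            mannwhitneyu(low, high, alternative="two-sided").pvalue
        )
    return result


def profiles_to_frame(profiles: list[MismatchProfile]) -> pd.DataFrame:
    """Long-form table of position/type counts and fractions per group."""
    rows = []
    for pr in profiles:
        total = pr.n_mismatches_total
        for i in range(SPACER_LENGTH):
            rows.append(
                {
                    "group": pr.group, "kind": "position", "label": f"N{i + 1}",
                    "count": int(pr.position_counts[i]),
                    "fraction": pr.position_counts[i] / total if total else float("nan"),
                }
            )
        for t in MISMATCH_TYPES:
            rows.append(
                {
                    "group": pr.group, "kind": "type", "label": t,
                    "count": pr.type_counts[t],
                    "fraction": pr.type_counts[t] / total if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)
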