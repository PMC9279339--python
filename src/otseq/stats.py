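"""Significance calling for paired MOCK / SpCas9 site counts.

For every construct the indel and non-indel clean-read counts of the two
samples form a 2x2 table tested with a two-sided Fisher's exact test;
p-values are Benjamini-Hochberg adjusted across all testable constructs of
the run.  A site has significantly detectable indels when the adjusted p is
below alpha AND the indel-frequency fold change SpCas9/MOCK is at least 2,
with a minimum indel-read support in the SpCas9 sample.  Significant sites
are split at 3% SpCas9 indel frequency into low (LIOT) and high (HIOT)
indel classes; everything else is NSOT.  Sites failing read-depth, synthesis
or WT background-quality filters are reported as FILTERED with reasons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

_REL_TOL = 1e-12


def indel_frequency(indel: int, total: int) -> float:
    """Indel frequency in percent: indel reads / total reads x 100.

    Returns NaN when total is 0 (the site cannot be quantified and will be
    filtered downstream).
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    if indel > total:
        raise ValueError(f"indel count {indel} exceeds total {total}")
    if total == 0:
        return float("nan")
    return indel / total * 100.0


def fisher_test(
    indel_cas9: int, nonindel_cas9: int, indel_mock: int, nonindel_mock: int
) -> float:
    """Two-sided Fisher's exact p for the 2x2 indel/non-indel table.

    Computed by summing, over the hypergeometric support at fixed margins,
    the probabilities of all tables no more likely than the observed one
    (relative tolerance 1e-12 on the comparison).  An all-zero table has
    p = 1.
    """
    a, b, c, d = indel_cas9, nonindel_cas9, indel_mock, nonindel_mock
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    total = r1 + r2
    if total == 0 or c1 == 0 or c1 == total or r1 == 0 or r2 == 0:
        return 1.0
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    k = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(k, total, r1, c1)
    p_obs = pmf[a - kmin]
    mask = pmf <= p_obs * (1.0 + _REL_TOL)
    if mask.all():
        return 1.0
    return min(float(pmf[mask].sum()), 1.0)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class CallThresholds:
    """Thresholds of the calling recipe; echoed into output metadata."""

    alpha: float = 0.05
    min_fold_change: float = 2.0
    hiot_if: float = 3.0          # percent; LIOT/HIOT split on SpCas9 IF
    min_total: int = 32           # clean reads required in each sample
    min_indel: int = 5            # SpCas9 indel reads required for significance
    max_wt_if: float = 25.0       # percent; MOCK IF above this is unusable
    max_mock_if: float = 4.0      # percent; synthesis-quality gate (MOCK IF)
    fc_continuity: str = "half_read"   # or "raw" (infinite FC allowed)
    min_indel_policy: str = "demote"   # or "filter"

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def fold_change(
    indel_cas9: int, total_cas9: int, indel_mock: int, total_mock: int,
    continuity: str = "half_read",
) -> float:
    """Indel-frequency fold change FC = IF(SpCas9) / IF(MOCK).

    When the MOCK sample has zero indel reads the ratio is undefined; the
    default adds a 0.5-read continuity correction to the MOCK numerator only,
    while ``continuity="raw"`` returns +inf.
    """
    if_cas9 = indel_frequency(indel_cas9, total_cas9)
    if indel_mock == 0:
        if continuity == "raw":
            return math.inf if if_cas9 > 0 else 0.0
        if_mock = 0.5 / total_mock * 100.0
    else:
        if_mock = indel_frequency(indel_mock, total_mock)
    return if_cas9 / if_mock


def call_sites(
    counts: pd.DataFrame, thresholds: CallThresholds | None = None
) -> pd.DataFrame:
    """Produce one SiteCall row per construct from a paired counts table.

    ``counts`` is the long-form table from :func:`otseq.reads.tabulate`
    (columns construct_id, sample in {MOCK, SpCas9}, total_clean, indel).
    BH adjustment spans all constructs that pass the read-quality and
    background filters in this run.
    """
    th = thresholds or CallThresholds()
    pivot: dict[str, dict[str, tuple[int, int]]] = {}
    for _, row in counts.iterrows():
        pivot.setdefault(row["construct_id"], {})[row["sample"]] = (
            int(row["total_clean"]), int(row["indel"])
        )
    rows = []
    for cid in pivot:
        entry = {
            "construct_id": cid,
            "total_mock": 0, "indel_mock": 0,
            "total_cas9": 0, "indel_cas9": 0,
            "if_mock": float("nan"), "if_cas9": float("nan"),
            "fisher_p": float("nan"), "adj_p": float("nan"),
            "fold_change": float("nan"),
            "call": "FILTERED", "filter_reasons": "",
        }
        reasons = []
        samples = pivot[cid]
        if "MOCK" not in samples or "SpCas9" not in samples:
            reasons.append("unpaired")
        else:
            tm, im = samples["MOCK"]
            tc, ic = samples["SpCas9"]
            entry.update(
                total_mock=tm, indel_mock=im, total_cas9=tc, indel_cas9=ic
            )
            if tm < th.min_total or tc < th.min_total:
                reasons.append("read_quality")
            if tm == 0 or tc == 0:
                reasons.append("no_reads")
            if tm > 0 and tc > 0:
                if_mock = indel_frequency(im, tm)
                if_cas9 = indel_frequency(ic, tc)
                entry.update(if_mock=if_mock, if_cas9=if_cas9)
                if if_mock > th.max_mock_if:
                    reasons.append("synthesis")
                if if_mock > th.max_wt_if:
                    reasons.append("wt_if")
            if th.min_indel_policy == "filter" and ic < th.min_indel:
                reasons.append("indel_support")
        entry["filter_reasons"] = ",".join(reasons)
        rows.append((entry, not reasons))

    testable = [entry for entry, ok in rows if ok]
    if testable:
        pvals = [
            fisher_test(
                e["indel_cas9"], e["total_cas9"] - e["indel_cas9"],
                e["indel_mock"], e["total_mock"] - e["indel_mock"],
            )
            for e in testable
        ]
        adj = bh_adjust(pvals)
        for e, p, q in zip(testable, pvals, adj):
            e["fisher_p"] = p
            e["adj_p"] = float(q)
            e["fold_change"] = fold_change(
                e["indel_cas9"], e["total_cas9"],
                e["indel_mock"], e["total_mock"],
                continuity=th.fc_continuity,
            )
            significant = (
                e["adj_p"] < th.alpha
                and e["fold_change"] >= th.min_fold_change
                and e["indel_cas9"] >= th.min_indel
            )
            if significant:
                e["call"] = "HIOT" if e["if_cas9"] >= th.hiot_if else "LIOT"
            else:
                e["call"] = "NSOT"
    out = pd.DataFrame([entry for entry, _ in rows])
    out.attrs["thresholds"] = th.as_dict()
    return out


def enrichment_depletion(
    counts: pd.DataFrame, min_ratio: float = 2.0
) -> pd.DataFrame:
    """Flag constructs whose read share shifted between samples.

    Total clean reads per construct are normalised to reads-per-million
    within each sample; a construct whose normalised SpCas9/MOCK ratio is at
    least ``min_ratio`` (either direction) is flagged enriched or depleted.
    Flagged constructs are excluded from downstream sequence-context
    analyses, since growth effects confound their indel frequencies.
    """
    piv = counts.pivot_table(
        index="construct_id", columns="sample", values="total_clean",
        aggfunc="sum",
    ).fillna(0)
    for sample in ("MOCK", "SpCas9"):
        if sample not in piv or piv[sample].sum() == 0:
            raise ValueError(f"zero library size for sample {sample}")
    rpm_mock = piv["MOCK"] / piv["MOCK"].sum() * 1e6
    rpm_cas9 = piv["SpCas9"] / piv["SpCas9"].sum() * 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.asarray(rpm_cas9) / np.asarray(rpm_mock)
    flags = []
    for r, m, c in zip(ratio, rpm_mock, rpm_cas9):
        if m == 0 and c == 0:
            flags.append("none")
        elif (m == 0 and c > 0) or r >= min_ratio:
            flags.append("enriched")
        elif (c == 0 and m > 0) or (1.0 / r) >= min_ratio:
            flags.append("depleted")
        else:
            flags.append("none")
    return pd.DataFrame(
        {
            "construct_id": piv.index,
            "rpm_mock": np.asarray(rpm_mock),
            "rpm_cas9": np.asarray(rpm_cas9),
            "enrichment_flag": flags,
        }
    ).reset_index(drop=True)
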