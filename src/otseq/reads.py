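"""Paired-end amplicon read processing: merge, demultiplex, filter, count.

The pipeline turns raw MOCK / SpCas9 FASTQ pairs into per-construct read
tallies in four stages:

1. overlap merging of mate pairs into full-length amplicon sequences;
2. barcode demultiplexing against the library manifest (the 10-nt barcode is
   read immediately downstream of a constant scaffold anchor; orientation is
   auto-detected);
3. a structural filter requiring the invariant ``g + spacer + scaffold +
   barcode`` prefix and the ``GTTT`` downstream anchor to match the reference
   exactly, extracting the observed surrogate region in between;
4. indel calling on the extracted segment (see :mod:`otseq.align`), with two
   background-removal rules: reads whose only events are 1-bp indels outside
   the cut-proximal window N15-N21 are reclassified as non-indel, and alleles
   also observed in the MOCK sample are subtracted from the SpCas9 tallies as
   oligo-synthesis artifacts.

Counts obey: ``indel <= total_clean`` and ``assigned reads == total_clean +
sum(filtered by reason)`` for every construct and sample.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import design
from .align import AlignScoring, IndelEvent, align_indels

logger = logging.getLogger(__name__)

SUFFIX_ANCHOR = design.DOWNSTREAM_LINKER + design.BSMBI_SITE  # GTTTGCGTCTC
RETAIN_WINDOW = (15, 21)  # cut-proximal surrogate positions kept as true edits
DEFAULT_LENGTH_BOUND = 24  # max |len(observed) - 27| before a read is dropped


class ReadProcessingError(RuntimeError):
    pass


@dataclass
class MergedRead:
    read_id: str
    sequence: str
    qualities: np.ndarray
    reverse_complemented: bool = False

    @property
    def mean_quality(self) -> float:
        return float(self.qualities.mean())


@dataclass
class SiteCounts:
    """Per-construct, per-sample tallies after filtering."""

    construct_id: str
    sample: str
    total_clean: int = 0
    indel: int = 0
    allele_table: Counter = field(default_factory=Counter)
    filtered_counts: Counter = field(default_factory=Counter)

    @property
    def assigned(self) -> int:
        return self.total_clean + sum(self.filtered_counts.values())


# --- FASTQ IO --------------------------------------------------------------

def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield (read_id, seq1, qual1, seq2, qual2); mates must stay in sync."""
    with _open_text(r1_path) as fh1, _open_text(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (id1, s1, q1), (id2, s2, q2) in zip(it1, it2, strict=True):
            base1 = id1.split()[0].rsplit("/", 1)[0]
            base2 = id2.split()[0].rsplit("/", 1)[0]
            if base1 != base2:
                raise ReadProcessingError(
                    f"desynchronized mates: {id1!r} vs {id2!r}"
                )
            yield base1, s1, q1, s2, q2


def _quals(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33


# --- pair merging ----------------------------------------------------------

class PairMerger:
    """Overlap-merge mate pairs into single amplicon sequences.

    The best overlap is the one with the fewest mismatches (ties broken by the
    longest overlap); it is accepted when its mismatch fraction is at most
    ``max_mismatch_frac``.  Disagreeing bases are resolved toward the
    higher-quality base (equal quality: mate 1 wins).  Unmergeable pairs are
    counted and dropped.
    """

    def __init__(self, min_overlap: int = 10, max_mismatch_frac: float = 0.25):
        self.min_overlap = min_overlap
        self.max_mismatch_frac = max_mismatch_frac
        self.n_merged = 0
        self.n_unmerged = 0

    def merge(
        self, read_id: str, seq1: str, qual1: str, seq2: str, qual2: str
    ) -> MergedRead | None:
        s1 = np.frombuffer(seq1.encode(), dtype=np.uint8)
        s2 = np.frombuffer(design.revcomp(seq2).encode(), dtype=np.uint8)
        q1 = _quals(qual1)
        q2 = _quals(qual2)[::-1]
        max_ov = min(len(s1), len(s2))
        best_ov, best_mm = 0, None
        for ov in range(max_ov, self.min_overlap - 1, -1):
            mm = int((s1[-ov:] != s2[:ov]).sum())
            if best_mm is None or mm < best_mm:
                best_ov, best_mm = ov, mm
                if mm == 0:
                    break
        if best_mm is None or best_mm > self.max_mismatch_frac * best_ov:
            self.n_unmerged += 1
            return None
        ov = best_ov
        head_s, head_q = s1[:-ov] if ov else s1, q1[:-ov] if ov else q1
        o1, o2 = s1[-ov:], s2[:ov]
        oq1, oq2 = q1[-ov:], q2[:ov]
        take2 = (o1 != o2) & (oq2 > oq1)
        cons = np.where(take2, o2, o1)
        cons_q = np.maximum(oq1, oq2)
        seq = (
            head_s.tobytes().decode()
            + cons.tobytes().decode()
            + s2[ov:].tobytes().decode()
        )
        quals = np.concatenate([head_q, cons_q, q2[ov:]])
        self.n_merged += 1
        return MergedRead(read_id, seq, quals)


def merge_pairs(
    r1_path: str | Path,
    r2_path: str | Path,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> Iterator[MergedRead]:
    merger = PairMerger(min_overlap, max_mismatch_frac)
    for read_id, s1, q1, s2, q2 in read_fastq_pairs(r1_path, r2_path):
        merged = merger.merge(read_id, s1, q1, s2, q2)
        if merged is not None:
            yield merged


# --- demultiplexing --------------------------------------------------------

class Demultiplexer:
    """Assign merged reads to constructs by exact barcode match.

    The barcode is located immediately downstream of the last
    ``anchor_length`` bases of the configured scaffold; if the anchor is not
    found, the reverse complement of the read is tried.
    """

    def __init__(
        self,
        manifest: pd.DataFrame,
        scaffold: str = design.SPCAS9_SCAFFOLD,
        anchor_length: int = 12,
    ):
        barcodes = manifest["barcode"]
        if barcodes.duplicated().any():
            raise ReadProcessingError("manifest barcodes are not unique")
        self.anchor = scaffold[-anchor_length:]
        self.barcode_to_construct = dict(zip(barcodes, manifest["construct_id"]))
        self.counters: Counter = Counter()

    def assign(self, sequence: str) -> tuple[str | None, str]:
        """Return (construct_id or None, oriented sequence)."""
        seq = sequence
        pos = seq.find(self.anchor)
        if pos == -1:
            seq = design.revcomp(sequence)
            pos = seq.find(self.anchor)
        if pos == -1:
            self.counters["unassigned_no_anchor"] += 1
            return None, sequence
        start = pos + len(self.anchor)
        barcode = seq[start : start + design.BARCODE_LENGTH]
        construct = self.barcode_to_construct.get(barcode)
        if construct is None:
            self.counters["unassigned_unknown_barcode"] += 1
            return None, seq
        self.counters["assigned"] += 1
        return construct, seq


# --- structural filter -----------------------------------------------------

@dataclass(frozen=True)
class ConstructRef:
    """Reference segments needed to filter reads of one construct."""

    construct_id: str
    prefix: str      # g + spacer + scaffold + barcode
    surrogate27: str

    @classmethod
    def from_manifest_row(
        cls, row: pd.Series, scaffold: str = design.SPCAS9_SCAFFOLD
    ) -> "ConstructRef":
        prefix = (
            design.TRANSCRIPTION_G + row["spacer"] + scaffold + row["barcode"]
        )
        return cls(row["construct_id"], prefix, row["surrogate27"])


def structural_filter(
    sequence: str,
    ref: ConstructRef,
    length_bound: int = DEFAULT_LENGTH_BOUND,
) -> tuple[str | None, str]:
    """Check the invariant read structure and extract the surrogate segment.

    Returns (observed segment, "pass") when the ``g+spacer+scaffold+barcode``
    prefix and the downstream ``GTTTG`` + BsmBI anchor are both present and
    exact; otherwise (None, reason) with reason "structure" or "length".
    """
    p = sequence.find(ref.prefix)
    if p == -1:
        return None, "structure"
    start = p + len(ref.prefix)
    q = sequence.find(SUFFIX_ANCHOR, start)
    if q == -1:
        return None, "structure"
    observed = sequence[start:q]
    if not observed or abs(len(observed) - len(ref.surrogate27)) > length_bound:
        return None, "length"
    return observed, "pass"


# --- indel classification --------------------------------------------------

def positional_indel_filter(
    events: Iterable[IndelEvent], window: tuple[int, int] = RETAIN_WINDOW
) -> bool:
    """Decide whether a read's called events count as a true edit.

    1-bp events lying entirely outside the cut-proximal window (reference
    positions N15-N21 of the 27-nt surrogate) are treated as PCR/sequencing
    noise; any event of length >= 2, or any event overlapping the window,
    marks the read as edited.  Insertion boundary cases are decided by the
    anchor position of the leftmost-normalised event.
    """
    lo, hi = window
    return any(ev.length >= 2 or ev.overlaps(lo, hi) for ev in events)


class AlleleClassifier:
    """Cache indel decisions per (reference, observed allele) pair."""

    def __init__(self, scoring: AlignScoring | None = None,
                 window: tuple[int, int] = RETAIN_WINDOW):
        self.scoring = scoring or AlignScoring()
        self.window = window
        self._cache: dict[tuple[str, str], bool] = {}

    def is_indel(self, observed: str, reference: str) -> bool:
        key = (reference, observed)
        hit = self._cache.get(key)
        if hit is None:
            events = align_indels(observed, reference, self.scoring)
            hit = positional_indel_filter(events, self.window)
            self._cache[key] = hit
        return hit


# --- WT pseudo-edit subtraction --------------------------------------------

def wt_pseudoedit_subtraction(
    cas9: SiteCounts, mock: SiteCounts, classifier: AlleleClassifier,
    reference: str,
    min_mock_frac: float = 0.01,
    min_mock_reads: int = 2,
) -> SiteCounts:
    """Remove oligo-synthesis artifact alleles from the SpCas9 tallies.

    Non-reference allele sequences found in the MOCK sample are removed from
    the SpCas9 table: both samples carry the same synthesis and PCR
    artifacts, so a shared allele cannot be attributed to Cas9 editing.
    Removed reads are tallied under filter reason "wt_pseudoedit".

    Synthesis artifacts are template-level and therefore recur in MOCK at a
    substantial frequency, whereas stray sequencing errors are read-level
    singletons; an allele must reach ``min_mock_frac`` of the MOCK clean
    reads (and ``min_mock_reads`` reads) to count as a pseudo-edit, so that
    one chance MOCK error matching a genuine edit allele does not delete the
    corresponding SpCas9 evidence.  Set both to 0 to remove any shared
    allele unconditionally.
    """
    floor = max(min_mock_reads, min_mock_frac * mock.total_clean)
    shared = [
        a for a in cas9.allele_table
        if a != reference and mock.allele_table.get(a, 0) >= max(floor, 1)
    ]
    if not shared:
        return cas9
    out = SiteCounts(
        cas9.construct_id, cas9.sample, cas9.total_clean, cas9.indel,
        Counter(cas9.allele_table), Counter(cas9.filtered_counts),
    )
    for allele in shared:
        n = out.allele_table.pop(allele)
        out.total_clean -= n
        if classifier.is_indel(allele, reference):
            out.indel -= n
        out.filtered_counts["wt_pseudoedit"] += n
    return out


# --- full tabulation -------------------------------------------------------

@dataclass
class TabulateConfig:
    min_overlap: int = 10
    max_mismatch_frac: float = 0.25
    length_bound: int = DEFAULT_LENGTH_BOUND
    scaffold: str = design.SPCAS9_SCAFFOLD
    scoring: AlignScoring = field(default_factory=AlignScoring)
    retain_window: tuple[int, int] = RETAIN_WINDOW
    min_mean_quality: float | None = None  # optional QC gate, off by default
    subtract_wt_pseudoedits: bool = True
    min_mock_allele_frac: float = 0.01
    min_mock_allele_reads: int = 2


def _process_sample(
    sample: str,
    r1_path: str | Path,
    r2_path: str | Path,
    refs: dict[str, ConstructRef],
    demux: Demultiplexer,
    classifier: AlleleClassifier,
    cfg: TabulateConfig,
) -> dict[str, SiteCounts]:
    counts = {
        cid: SiteCounts(cid, sample) for cid in refs
    }
    merger = PairMerger(cfg.min_overlap, cfg.max_mismatch_frac)
    for read_id, s1, q1, s2, q2 in read_fastq_pairs(r1_path, r2_path):
        merged = merger.merge(read_id, s1, q1, s2, q2)
        if merged is None:
            continue
        if (
            cfg.min_mean_quality is not None
            and merged.mean_quality < cfg.min_mean_quality
        ):
            demux.counters["low_quality"] += 1
            continue
        construct, oriented = demux.assign(merged.sequence)
        if construct is None:
            continue
        ref = refs[construct]
        sc = counts[construct]
        observed, reason = structural_filter(oriented, ref, cfg.length_bound)
        if observed is None:
            sc.filtered_counts[reason] += 1
            continue
        sc.total_clean += 1
        sc.allele_table[observed] += 1
        if observed != ref.surrogate27 and classifier.is_indel(
            observed, ref.surrogate27
        ):
            sc.indel += 1
    demux.counters[f"{sample}_unmerged_pairs"] = merger.n_unmerged
    demux.counters[f"{sample}_merged_pairs"] = merger.n_merged
    return counts


def tabulate(
    manifest: pd.DataFrame,
    mock_fastqs: tuple[str | Path, str | Path],
    cas9_fastqs: tuple[str | Path, str | Path],
    config: TabulateConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, SiteCounts], dict[str, SiteCounts]]:
    """Run the full counting pipeline for a MOCK / SpCas9 sample pair.

    Returns (counts table, MOCK SiteCounts by construct, SpCas9 SiteCounts by
    construct).  The counts table has one row per construct and sample with
    total_clean, indel and per-reason filtered counts; processing order of
    reads does not affect it.
    """
    cfg = config or TabulateConfig()
    refs = {
        row["construct_id"]: ConstructRef.from_manifest_row(row, cfg.scaffold)
        for _, row in manifest.iterrows()
    }
    classifier = AlleleClassifier(cfg.scoring, cfg.retain_window)
    demux = Demultiplexer(manifest, cfg.scaffold)
    mock = _process_sample(
        "MOCK", *mock_fastqs, refs=refs, demux=demux,
        classifier=classifier, cfg=cfg,
    )
    cas9 = _process_sample(
        "SpCas9", *cas9_fastqs, refs=refs, demux=demux,
        classifier=classifier, cfg=cfg,
    )
    if cfg.subtract_wt_pseudoedits:
        for cid, ref in refs.items():
            cas9[cid] = wt_pseudoedit_subtraction(
                cas9[cid], mock[cid], classifier, ref.surrogate27,
                cfg.min_mock_allele_frac, cfg.min_mock_allele_reads,
            )
    if demux.counters["assigned"] == 0:
        logger.warning("no reads matched any manifest barcode; table is empty")
    rows = []
    for sample, table in (("MOCK", mock), ("SpCas9", cas9)):
        for cid in manifest["construct_id"]:
            sc = table[cid]
            rows.append(
                {
                    "construct_id": cid,
                    "sample": sample,
                    "total_clean": sc.total_clean,
                    "indel": sc.indel,
                    "filtered_structure": sc.filtered_counts.get("structure", 0),
                    "filtered_length": sc.filtered_counts.get("length", 0),
                    "filtered_wt_pseudoedit": sc.filtered_counts.get(
                        "wt_pseudoedit", 0
                    ),
                }
            )
    counts_df = pd.DataFrame(rows)
    return counts_df, mock, cas9


def write_counts(counts_df: pd.DataFrame, path: str | Path) -> None:
    counts_df.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_allele_tables(
    tables: dict[str, SiteCounts], path: str | Path
) -> None:
    rows = []
    for cid in sorted(tables):
        sc = tables[cid]
        for allele, n in sorted(sc.allele_table.items()):
            rows.append(
                {"construct_id": cid, "sample": sc.sample,
                 "allele": allele, "count": n}
            )
    pd.DataFrame(
        rows, columns=["construct_id", "sample", "allele", "count"]
    ).to_csv(path, sep="\t", index=False)
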