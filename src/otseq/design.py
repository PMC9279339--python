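"""Design of barcoded surrogate off-target reporter libraries.

A library is built around a set of 20-nt SpCas9 spacers.  For each guide, every
genomic window of 20 nt followed by an NGG PAM and within a configurable
Hamming distance of the spacer is a candidate off-target site.  Each retained
site becomes one synthetic construct: a single 170-nt oligo carrying the guide
expression cassette (U6-initiating ``g`` + spacer + sgRNA scaffold) and, on the
same molecule, a 37-bp surrogate insert made of a 10-nt construct barcode
("AC" + 8 random bases) followed by the 27-nt surrogate copy of the site
(protospacer + PAM + 4 nt of genomic downstream context).  Both ends of the
oligo carry BsmBI sites for Golden Gate cloning, so any construct with an
internal BsmBI recognition sequence is rejected.

Spacer positions are numbered N1 (most PAM-distal) to N20 (PAM-proximal).
Genomic coordinates are 0-based half-open; ``start`` is the leftmost reference
coordinate of the 20-nt protospacer, and ``strand`` gives the protospacer
orientation (sequences are reported on the protospacer strand).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

# --- fixed oligo segments (uppercase throughout) ---------------------------
UPSTREAM_FLANK = "ACCA"        # 4 nt synthesis flank
BSMBI_SITE = "CGTCTC"          # BsmBI recognition sequence
BSMBI_SITE_RC = "GAGACG"
GGA_LINKER = "ACACC"           # Golden Gate cloning linker
TRANSCRIPTION_G = "G"          # extra base initiating U6 transcription
DOWNSTREAM_LINKER = "GTTTG"
DOWNSTREAM_FLANK = "ACGG"      # 4 nt synthesis flank after the trailing BsmBI

# Canonical SpCas9 sgRNA scaffold (76 nt) plus the TTTTTT pol-III terminator;
# 82 nt in total.  Configurable: every length check derives from the value
# actually passed around, never from the literal 82.
SPCAS9_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCC"
    "GTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
    "TTTTTT"
)

SPACER_LENGTH = 20
PAM_LENGTH = 3
DOWNSTREAM4_LENGTH = 4
SURROGATE_LENGTH = SPACER_LENGTH + PAM_LENGTH + DOWNSTREAM4_LENGTH  # 27
BARCODE_LENGTH = 10
BARCODE_PREFIX = "AC"
SITE_SPAN = SURROGATE_LENGTH  # genomic footprint needed per candidate window

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


class DesignError(ValueError):
    """Raised when a construct or barcode cannot satisfy the design rules."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def has_bsmbi(seq: str) -> bool:
    """True if ``seq`` contains a BsmBI recognition site in either orientation."""
    return BSMBI_SITE in seq or BSMBI_SITE_RC in seq


def oligo_length(scaffold: str = SPCAS9_SCAFFOLD) -> int:
    """Total oligo length implied by the configured scaffold (170 by default)."""
    return (
        len(UPSTREAM_FLANK) + len(BSMBI_SITE) + len(GGA_LINKER)
        + len(TRANSCRIPTION_G) + SPACER_LENGTH + len(scaffold)
        + BARCODE_LENGTH + SURROGATE_LENGTH
        + len(DOWNSTREAM_LINKER) + len(BSMBI_SITE) + len(DOWNSTREAM_FLANK)
    )


# --- domain types ----------------------------------------------------------

@dataclass(frozen=True)
class GuideRNA:
    """A 20-nt SpCas9 spacer with an identifier."""

    guide_id: str
    spacer: str

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LENGTH:
            raise ValueError(
                f"spacer must be {SPACER_LENGTH} nt, got {len(self.spacer)}"
            )
        if set(self.spacer) - set("ACGT"):
            raise ValueError(f"spacer contains non-ACGT bases: {self.spacer}")


@dataclass(frozen=True)
class OffTargetSite:
    """A genomic candidate site annotated against one guide.

    ``mismatches`` lists (position, spacer_base, protospacer_base) with
    position in N-coordinates 1..20 (N1 = PAM-distal).
    """

    site_id: str
    guide_id: str
    chrom: str
    start: int
    strand: str
    protospacer: str
    pam: str
    downstream4: str
    n_mismatches: int
    mismatches: tuple[tuple[int, str, str], ...]

    @property
    def surrogate27(self) -> str:
        return self.protospacer + self.pam + self.downstream4


@dataclass(frozen=True)
class SurrogateConstruct:
    construct_id: str
    guide_id: str
    site: OffTargetSite
    barcode: str
    scaffold: str
    oligo: str

    @property
    def spacer_cassette(self) -> str:
        """g + spacer + scaffold, the invariant 5' block of every read."""
        i = len(UPSTREAM_FLANK) + len(BSMBI_SITE) + len(GGA_LINKER)
        j = i + 1 + SPACER_LENGTH + len(self.scaffold)
        return self.oligo[i:j]

    @property
    def surrogate27(self) -> str:
        return self.site.surrogate27

    @property
    def surrogate37(self) -> str:
        return self.barcode + self.site.surrogate27


# --- off-target enumeration ------------------------------------------------

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scan_one_strand(
    codes: np.ndarray, spacer_codes: np.ndarray, max_mismatches: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Window starts and mismatch counts for NGG-adjacent windows on one strand.

    Returns (starts, n_mismatches, n_ambiguous_skipped); ``starts`` index the
    protospacer within ``codes``.
    """
    n = len(codes)
    if n < SITE_SPAN:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), 0
    n_windows = n - SITE_SPAN + 1
    windows = sliding_window_view(codes, SPACER_LENGTH)[:n_windows]
    # PAM check: positions +21/+22 must be G (the +20 "N" is free)
    pam_ok = (codes[SPACER_LENGTH + 1 : SPACER_LENGTH + 1 + n_windows] == 2) & (
        codes[SPACER_LENGTH + 2 : SPACER_LENGTH + 2 + n_windows] == 2
    )
    # ambiguity: any non-ACGT base anywhere in the 27-nt footprint
    ambiguous = sliding_window_view(codes == 4, SITE_SPAN)[:n_windows].any(axis=1)
    mm = (windows != spacer_codes).sum(axis=1)
    hits = pam_ok & ~ambiguous & (mm <= max_mismatches)
    n_skipped = int((pam_ok & ambiguous).sum())
    starts = np.nonzero(hits)[0]
    return starts, mm[starts], n_skipped


def enumerate_offtargets(
    genome: Mapping[str, str],
    guide: GuideRNA,
    max_mismatches: int = 4,
) -> list[OffTargetSite]:
    """Scan a genome for NGG-adjacent windows within Hamming distance of a spacer.

    Every 20-nt window on either strand that is followed by an NGG PAM plus
    4 nt of downstream sequence and differs from ``guide.spacer`` in at most
    ``max_mismatches`` positions is returned.  Windows too close to a sequence
    end to provide the PAM and downstream context are skipped, as are windows
    whose 27-nt footprint contains ambiguity codes (counted and logged).
    Output order is deterministic: (chrom, start, strand).
    """
    if not 0 <= max_mismatches <= 6:
        raise ValueError("max_mismatches must be in 0..6")
    spacer_codes = _encode(guide.spacer)
    sites: list[OffTargetSite] = []
    n_ambiguous = 0
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        length = len(seq)
        for strand in "+-":
            oriented = seq if strand == "+" else revcomp(seq)
            codes = _encode(oriented)
            starts, mms, skipped = _scan_one_strand(
                codes, spacer_codes, max_mismatches
            )
            n_ambiguous += skipped
            for p, n_mm in zip(starts.tolist(), mms.tolist()):
                proto = oriented[p : p + SPACER_LENGTH]
                pam = oriented[p + SPACER_LENGTH : p + SPACER_LENGTH + PAM_LENGTH]
                down4 = oriented[p + SPACER_LENGTH + PAM_LENGTH : p + SITE_SPAN]
                start = p if strand == "+" else length - p - SPACER_LENGTH
                mismatches = tuple(
                    (i + 1, guide.spacer[i], proto[i])
                    for i in range(SPACER_LENGTH)
                    if guide.spacer[i] != proto[i]
                )
                sites.append(
                    OffTargetSite(
                        site_id=f"{guide.guide_id}|{chrom}:{start}:{strand}",
                        guide_id=guide.guide_id,
                        chrom=chrom,
                        start=start,
                        strand=strand,
                        protospacer=proto,
                        pam=pam,
                        downstream4=down4,
                        n_mismatches=int(n_mm),
                        mismatches=mismatches,
                    )
                )
    if n_ambiguous:
        logger.info(
            "guide %s: skipped %d NGG windows containing ambiguity codes",
            guide.guide_id,
            n_ambiguous,
        )
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


# --- barcodes --------------------------------------------------------------

def _barcode_in_context_ok(barcode: str, protospacer: str, scaffold: str) -> bool:
    """Reject barcodes that would create a BsmBI site at either junction."""
    context = scaffold[-(len(BSMBI_SITE) - 1):] + barcode + protospacer[: len(BSMBI_SITE) - 1]
    return not has_bsmbi(context)


def assign_barcodes(
    sites: Sequence[OffTargetSite],
    seed: int,
    min_hamming: int = 1,
    scaffold: str = SPCAS9_SCAFFOLD,
    max_attempts: int = 10_000,
) -> dict[str, str]:
    """Draw one unique 10-nt barcode ("AC" + 8 random bases) per site.

    Barcodes are redrawn when they collide with an already assigned barcode
    (exact match by default; ``min_hamming`` > 1 enforces a minimum pairwise
    Hamming distance greedily) or would create a BsmBI recognition site at the
    scaffold/barcode or barcode/protospacer junction.  Reproducible under
    ``seed``.
    """
    n_random = BARCODE_LENGTH - len(BARCODE_PREFIX)
    if len(sites) > 4 ** n_random:
        raise DesignError(
            f"cannot assign {len(sites)} unique barcodes from 4^{n_random} candidates"
        )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    assigned: dict[str, str] = {}
    chosen: list[str] = []
    for site in sites:
        for _ in range(max_attempts):
            barcode = BARCODE_PREFIX + "".join(rng.choice(bases, size=n_random))
            if has_bsmbi(barcode):
                continue
            if not _barcode_in_context_ok(barcode, site.protospacer, scaffold):
                continue
            if min_hamming <= 1:
                if barcode in assigned.values():
                    continue
            else:
                if any(
                    sum(a != b for a, b in zip(barcode, other)) < min_hamming
                    for other in chosen
                ):
                    continue
            assigned[site.site_id] = barcode
            chosen.append(barcode)
            break
        else:
            raise DesignError(
                "barcode assignment exhausted: could not satisfy "
                f"uniqueness (min Hamming distance {min_hamming}) and BsmBI "
                f"constraints for site {site.site_id} after {max_attempts} draws"
            )
    return assigned


# --- oligo assembly --------------------------------------------------------

def assemble_oligo(
    guide: GuideRNA,
    site: OffTargetSite,
    barcode: str,
    scaffold: str = SPCAS9_SCAFFOLD,
    construct_id: str | None = None,
) -> SurrogateConstruct:
    """Assemble the full synthesis oligo for one site.

    Layout (170 nt with the default 82-nt scaffold)::

        ACCA | CGTCTC | ACACC | g | spacer(20) | scaffold(82)
             | barcode(10) + surrogate27(27) | GTTTG | CGTCTC | ACGG

    Raises :class:`DesignError` with reason "BsmBI" when the variable interior
    (spacer, scaffold, barcode + surrogate) contains a BsmBI recognition site
    in either orientation: such constructs cannot be Golden Gate cloned and
    are discarded from the library.
    """
    if len(barcode) != BARCODE_LENGTH or not barcode.startswith(BARCODE_PREFIX):
        raise DesignError(f"invalid barcode {barcode!r}")
    surrogate37 = barcode + site.surrogate27
    interior = TRANSCRIPTION_G + guide.spacer + scaffold + surrogate37
    if has_bsmbi(interior):
        raise DesignError(
            f"BsmBI: internal recognition site in construct for {site.site_id}"
        )
    oligo = (
        UPSTREAM_FLANK + BSMBI_SITE + GGA_LINKER + interior
        + DOWNSTREAM_LINKER + BSMBI_SITE + DOWNSTREAM_FLANK
    )
    # the junctions must not create extra sites either
    if oligo.count(BSMBI_SITE) != 2 or BSMBI_SITE_RC in oligo:
        raise DesignError(
            f"BsmBI: junction creates an unintended recognition site in {site.site_id}"
        )
    assert len(oligo) == oligo_length(scaffold)
    return SurrogateConstruct(
        construct_id=construct_id or site.site_id,
        guide_id=guide.guide_id,
        site=site,
        barcode=barcode,
        scaffold=scaffold,
        oligo=oligo,
    )


def design_library(
    genome: Mapping[str, str],
    guides: Sequence[GuideRNA],
    max_mismatches: int = 4,
    seed: int = 0,
    min_hamming: int = 1,
    scaffold: str = SPCAS9_SCAFFOLD,
) -> tuple[list[SurrogateConstruct], list[tuple[str, str]]]:
    """Enumerate, barcode, and assemble constructs for a set of guides.

    Returns (constructs, rejected) where ``rejected`` lists
    (site_id, reason) for sites discarded by the BsmBI exclusion rule.
    """
    ids = [g.guide_id for g in guides]
    if len(set(ids)) != len(ids):
        raise DesignError("guide_id values must be unique within a design run")
    all_sites: list[tuple[GuideRNA, OffTargetSite]] = []
    for guide in guides:
        for site in enumerate_offtargets(genome, guide, max_mismatches):
            all_sites.append((guide, site))
    # pre-drop sites whose own sequence carries BsmBI (barcode-independent)
    keep: list[tuple[GuideRNA, OffTargetSite]] = []
    rejected: list[tuple[str, str]] = []
    for guide, site in all_sites:
        if has_bsmbi(TRANSCRIPTION_G + guide.spacer + scaffold + site.surrogate27):
            rejected.append((site.site_id, "BsmBI"))
        else:
            keep.append((guide, site))
    barcodes = assign_barcodes(
        [s for _, s in keep], seed=seed, min_hamming=min_hamming, scaffold=scaffold
    )
    constructs = []
    for guide, site in keep:
        try:
            constructs.append(
                assemble_oligo(guide, site, barcodes[site.site_id], scaffold)
            )
        except DesignError:
            rejected.append((site.site_id, "BsmBI"))
    return constructs, rejected


# --- library export / import ----------------------------------------------

MANIFEST_COLUMNS = [
    "construct_id", "guide_id", "spacer", "chrom", "start", "end", "strand",
    "barcode", "surrogate27", "n_mismatches", "mismatches",
]


def format_mismatches(mismatches: Iterable[tuple[int, str, str]]) -> str:
    parts = [f"N{pos}:{g}>{p}" for pos, g, p in mismatches]
    return ",".join(parts) if parts else "."


def parse_mismatches(text: str) -> tuple[tuple[int, str, str], ...]:
    if not text or text == ".":
        return ()
    out = []
    for part in text.split(","):
        pos, change = part.split(":")
        g, p = change.split(">")
        out.append((int(pos.lstrip("N")), g, p))
    return tuple(out)


def constructs_to_manifest(constructs: Sequence[SurrogateConstruct]) -> pd.DataFrame:
    rows = []
    for c in constructs:
        s = c.site
        rows.append(
            {
                "construct_id": c.construct_id,
                "guide_id": c.guide_id,
                "spacer": c.oligo[
                    len(UPSTREAM_FLANK) + len(BSMBI_SITE) + len(GGA_LINKER) + 1 :
                ][:SPACER_LENGTH],
                "chrom": s.chrom,
                "start": s.start,
                "end": s.start + SPACER_LENGTH,
                "strand": s.strand,
                "barcode": c.barcode,
                "surrogate27": s.surrogate27,
                "n_mismatches": s.n_mismatches,
                "mismatches": format_mismatches(s.mismatches),
            }
        )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def export_library(
    constructs: Sequence[SurrogateConstruct], outdir: str | Path
) -> dict[str, Path]:
    """Write oligo FASTA, manifest TSV and per-guide mismatch spectrum.

    Coordinates in the manifest are 0-based half-open over the protospacer.
    """
    if not constructs:
        raise DesignError("refusing to export an empty library")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "oligos.fasta",
        "manifest": outdir / "manifest.tsv",
        "spectrum": outdir / "mismatch_spectrum.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for c in constructs:
            fh.write(f">{c.construct_id}\n{c.oligo}\n")
    manifest = constructs_to_manifest(constructs)
    manifest.to_csv(paths["manifest"], sep="\t", index=False)
    spectrum = Counter((c.guide_id, c.site.n_mismatches) for c in constructs)
    rows = [
        {"guide_id": g, "n_mismatches": mm, "n_sites": n}
        for (g, mm), n in sorted(spectrum.items())
    ]
    pd.DataFrame(rows, columns=["guide_id", "n_mismatches", "n_sites"]).to_csv(
        paths["spectrum"], sep="\t", index=False
    )
    return paths


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["n_mismatches"] = df["n_mismatches"].astype(int)
    return df[MANIFEST_COLUMNS]


def mismatch_spectrum(constructs: Sequence[SurrogateConstruct]) -> dict[int, int]:
    """Counts of constructs per mismatch number, library-wide."""
    return dict(sorted(Counter(c.site.n_mismatches for c in constructs).items()))
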