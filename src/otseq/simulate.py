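"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the pooled surrogate-reporter experiment end to end:
a random genome with planted off-target sites at chosen mismatch distances,
the designed construct library, and paired 150-nt amplicon reads for a MOCK
(no nuclease) and an SpCas9 sample, with truth tables sufficient to score
read assignment, indel-frequency recovery, significance calls and
enrichment flags.

Default conditions mirror the experiment the pipeline targets: per-construct
sequencing depth 2000 (the per-construct PCR coverage of the pooled assay),
paired 150-nt reads over a 210-nt amplicon, a 1% per-read PCR/sequencing
1-bp-indel background in the surrogate region (the 1-2% background indel
rate observed in unedited cells), 0.1% per-base substitution error, a 2%
per-construct oligo-synthesis error rate, and Cas9 edits as short indels at
the blunt cut between surrogate positions N17/N18 (3 bp upstream of the
PAM).  Every random choice flows from a single seed; identical configs give
byte-identical outputs.

A counts-level generator (:func:`simulate_counts`) draws indel/total read
counts directly from the same binomial read-sampling model, for calibrating
the statistical caller at depths where per-read simulation adds nothing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import design
from .design import GuideRNA, SurrogateConstruct, revcomp

# primer-binding flanks around the oligo in the sequenced amplicon
LEFT_FLANK = "TCTTGTGGAAAGGACGAAAC"
RIGHT_FLANK = "GTCTTCTCGAAGACCCGGTG"

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 20_000
    n_guides: int = 2
    # planted sites per guide: mismatch count -> number of sites
    planted_per_guide: Mapping[int, int] = field(
        default_factory=lambda: {0: 1, 2: 2, 3: 2, 4: 2}
    )
    # per-site true editing rate: zero-inflated log-uniform for off-targets,
    # high for on-targets (most guides cut their perfect site efficiently)
    p_inactive_offtarget: float = 0.85
    offtarget_if_range: tuple[float, float] = (0.005, 0.5)
    ontarget_if_range: tuple[float, float] = (0.8, 0.95)
    # indel model at the cut between N17/N18
    deletion_geom_p: float = 0.5
    max_deletion: int = 6
    insertion_fraction: float = 0.2
    # error model
    # per-construct probability of a synthesis-error allele; its template
    # fraction sits below the 4% MOCK-IF synthesis filter (higher-fraction
    # artifacts would remove the whole construct from analysis)
    synthesis_error_rate: float = 0.02
    synthesis_allele_fraction: float = 0.03
    substitution_rate: float = 0.001       # per sequenced base
    seq_indel_rate: float = 0.01           # per read, 1-bp indel in surrogate
    seq_indel_exclude_window: bool = False  # place errors outside N15-N21 only
    # sampling
    depth: int = 2000                      # read pairs per construct per sample
    read_length: int = 150
    dropout_fraction: float = 0.02         # constructs with growth dropout
    dropout_factor: float = 0.25           # SpCas9 depth multiplier for those

    def validate(self) -> None:
        rates = [
            self.p_inactive_offtarget, self.synthesis_error_rate,
            self.synthesis_allele_fraction, self.substitution_rate,
            self.seq_indel_rate, self.dropout_fraction,
        ]
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if self.depth < 0 or self.read_length < 20:
            raise ValueError("invalid depth or read length")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _random_spacer(rng: np.random.Generator) -> str:
    while True:
        spacer = _random_seq(rng, design.SPACER_LENGTH)
        if not design.has_bsmbi(spacer):
            return spacer


def _mutate_positions(
    rng: np.random.Generator, spacer: str, n_mm: int
) -> str:
    positions = rng.choice(design.SPACER_LENGTH, size=n_mm, replace=False)
    out = list(spacer)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(3)]
    return "".join(out)


def simulate_genome_and_guides(
    cfg: SimConfig,
) -> tuple[dict[str, str], list[GuideRNA], pd.DataFrame]:
    """Random genome with planted perfect and mismatched sites per guide.

    Returns (genome, guides, truth) where ``truth`` records every planted
    site (guide_id, chrom, start, strand, n_mismatches, protospacer).  All
    plants carry an NGG PAM and 4 nt of downstream context and are placed on
    the + strand in non-overlapping slots.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_slots = sum(cfg.planted_per_guide.values()) * cfg.n_guides
    slot_span = design.SITE_SPAN + 13  # spacing buffer between plants
    if n_slots * slot_span + 100 > cfg.genome_length:
        raise ValueError("genome too short for the requested plants")
    genome_arr = rng.choice(_BASES, size=cfg.genome_length)
    # evenly spaced slots with a small random offset
    anchors = np.linspace(
        50, cfg.genome_length - slot_span - 50, n_slots
    ).astype(int)
    guides = [
        GuideRNA(f"g{i + 1}", _random_spacer(rng)) for i in range(cfg.n_guides)
    ]
    truth_rows = []
    slot = 0
    for guide in guides:
        for n_mm in sorted(cfg.planted_per_guide):
            for _ in range(cfg.planted_per_guide[n_mm]):
                while True:
                    proto = (
                        guide.spacer if n_mm == 0
                        else _mutate_positions(rng, guide.spacer, n_mm)
                    )
                    pam = rng.choice(_BASES) + "GG"
                    down4 = _random_seq(rng, 4)
                    if not design.has_bsmbi(proto + pam + down4):
                        break
                start = int(anchors[slot]) + int(rng.integers(0, 8))
                site27 = proto + pam + down4
                genome_arr[start : start + design.SITE_SPAN] = list(site27)
                truth_rows.append(
                    {
                        "guide_id": guide.guide_id,
                        "chrom": "chrS",
                        "start": start,
                        "strand": "+",
                        "n_mismatches": n_mm,
                        "protospacer": proto,
                    }
                )
                slot += 1
    genome = {"chrS": "".join(genome_arr)}
    truth = pd.DataFrame(truth_rows)
    return genome, guides, truth


# --- read-level simulation --------------------------------------------------

def _apply_cut_indel(
    rng: np.random.Generator, surrogate: str, cfg: SimConfig
) -> str:
    """Apply one Cas9-induced indel at the blunt cut between N17 and N18."""
    cut = 17  # bases N1..N17 left of the cut
    if rng.random() < cfg.insertion_fraction:
        length = min(int(rng.geometric(cfg.deletion_geom_p)), 4)
        ins = _random_seq(rng, length)
        return surrogate[:cut] + ins + surrogate[cut:]
    length = min(int(rng.geometric(cfg.deletion_geom_p)), cfg.max_deletion)
    # the deleted interval covers the cut; keep it inside N10..N25 so the
    # read structure (barcode / GTTT anchors) stays intact
    lo = max(cut - length + 1, 10)
    hi = min(cut + 1, 26 - length)
    start = int(rng.integers(lo, max(hi + 1, lo + 1)))  # 1-based deletion start
    return surrogate[: start - 1] + surrogate[start - 1 + length :]


def _cut_deletion_alleles(surrogate: str, cfg: SimConfig) -> set[str]:
    """Every deletion allele the cut model can emit for this surrogate."""
    cut = 17
    out = set()
    for length in range(1, cfg.max_deletion + 1):
        lo = max(cut - length + 1, 10)
        hi = min(cut + 1, 26 - length)
        for start in range(lo, max(hi, lo) + 1):
            out.add(surrogate[: start - 1] + surrogate[start - 1 + length :])
    return out


def _synthesis_allele(
    rng: np.random.Generator, surrogate: str, cfg: SimConfig
) -> str:
    """A fixed synthesis-error allele: 1-bp deletion inside N15-N21.

    The position is redrawn so the allele string differs from every allele
    the cut model can produce; otherwise artifact and edit reads would be
    indistinguishable by construction and the truth table could not score
    the background-subtraction step.  If every window position collides
    (repeat-dense surrogates), a PAM-distal substitution is added instead.
    """
    edits = _cut_deletion_alleles(surrogate, cfg)
    positions = list(rng.permutation(np.arange(15, 22)))
    for pos in positions:
        allele = surrogate[: pos - 1] + surrogate[pos:]
        if allele not in edits:
            return allele
    pos = int(positions[0])
    allele = surrogate[: pos - 1] + surrogate[pos:]
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}[allele[0]]
    return swap + allele[1:]


def _sequencing_indel(
    rng: np.random.Generator, molecule: str, surr_start: int, surr_len: int,
    cfg: SimConfig,
) -> str:
    positions = list(range(1, surr_len + 1))
    if cfg.seq_indel_exclude_window:
        positions = [p for p in positions if not 15 <= p <= 21]
    pos = positions[rng.integers(len(positions))]
    i = surr_start + pos - 1
    if rng.random() < 0.5 and surr_len > 1:
        return molecule[:i] + molecule[i + 1 :]
    return molecule[:i] + _random_seq(rng, 1) + molecule[i:]


def _substitutions(
    rng: np.random.Generator, seq: str, rate: float
) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(3)]
    return "".join(out)


def _rebuild_oligo(row: pd.Series, scaffold: str) -> str:
    return (
        design.UPSTREAM_FLANK + design.BSMBI_SITE + design.GGA_LINKER
        + design.TRANSCRIPTION_G + row["spacer"] + scaffold
        + row["barcode"] + row["surrogate27"]
        + design.DOWNSTREAM_LINKER + design.BSMBI_SITE + design.DOWNSTREAM_FLANK
    )


def simulate_reads(
    manifest: pd.DataFrame,
    cfg: SimConfig,
    scaffold: str = design.SPCAS9_SCAFFOLD,
    true_if: Mapping[str, float] | None = None,
) -> tuple[list, list, pd.DataFrame]:
    """Paired reads for a MOCK and an SpCas9 sample over a designed library.

    Per construct, the SpCas9 true indel fraction is drawn from the
    configured per-site editing model (or taken from ``true_if``); the MOCK
    true fraction is always zero.  Both samples share the synthesis-error
    and sequencing-error processes.  Returns (mock_records, cas9_records,
    truth) where records are (read_id, seq1, qual1, seq2, qual2) tuples and
    ``truth`` holds per-construct true rates, allele bookkeeping and dropout
    flags.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    mock_records: list[tuple] = []
    cas9_records: list[tuple] = []
    truth_rows = []
    for _, row in manifest.iterrows():
        cid = row["construct_id"]
        oligo = _rebuild_oligo(row, scaffold)
        amplicon = LEFT_FLANK + oligo + RIGHT_FLANK
        surr_start = len(LEFT_FLANK) + len(oligo) - (
            len(design.DOWNSTREAM_LINKER) + len(design.BSMBI_SITE)
            + len(design.DOWNSTREAM_FLANK) + design.SURROGATE_LENGTH
        )
        surrogate = row["surrogate27"]
        if true_if is not None:
            p_edit = float(true_if.get(cid, 0.0))
        elif row["n_mismatches"] == 0:
            p_edit = float(rng.uniform(*cfg.ontarget_if_range))
        elif rng.random() < cfg.p_inactive_offtarget:
            p_edit = 0.0
        else:
            lo, hi = cfg.offtarget_if_range
            p_edit = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        has_synth = rng.random() < cfg.synthesis_error_rate
        synth_allele = _synthesis_allele(rng, surrogate, cfg) if has_synth else ""
        dropped = rng.random() < cfg.dropout_fraction
        depth_cas9 = int(round(cfg.depth * (cfg.dropout_factor if dropped else 1)))
        n_edited = 0
        for sample, records, depth in (
            ("MOCK", mock_records, cfg.depth),
            ("SpCas9", cas9_records, depth_cas9),
        ):
            for r in range(depth):
                surr = surrogate
                edited = sample == "SpCas9" and rng.random() < p_edit
                if edited:
                    surr = _apply_cut_indel(rng, surrogate, cfg)
                    n_edited += 1
                elif has_synth and rng.random() < cfg.synthesis_allele_fraction:
                    surr = synth_allele
                molecule = (
                    amplicon[:surr_start] + surr
                    + amplicon[surr_start + design.SURROGATE_LENGTH :]
                )
                if rng.random() < cfg.seq_indel_rate:
                    molecule = _sequencing_indel(
                        rng, molecule, surr_start, len(surr), cfg
                    )
                s1 = molecule[: cfg.read_length]
                s2 = revcomp(molecule)[: cfg.read_length]
                s1 = _substitutions(rng, s1, cfg.substitution_rate)
                s2 = _substitutions(rng, s2, cfg.substitution_rate)
                q = "I" * len(s1)
                records.append((f"{cid}:{sample}:{r}", s1, q, s2, "I" * len(s2)))
        truth_rows.append(
            {
                "construct_id": cid,
                "true_if": p_edit * 100.0,
                "n_reads_mock": cfg.depth,
                "n_reads_cas9": depth_cas9,
                "n_edited_reads": n_edited,
                "synthesis_error": has_synth,
                "synthesis_allele": synth_allele if has_synth else ".",
                "dropout": dropped,
            }
        )
    return mock_records, cas9_records, pd.DataFrame(truth_rows)


def write_fastq_pair(
    records: Sequence[tuple], r1_path: str | Path, r2_path: str | Path
) -> None:
    import gzip

    def _open(path):
        path = str(path)
        if path.endswith(".gz"):
            return gzip.open(path, "wt")
        return open(path, "w")

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for read_id, s1, q1, s2, q2 in records:
            f1.write(f"@{read_id}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{read_id}/2\n{s2}\n+\n{q2}\n")


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_guides(guides: Sequence[GuideRNA], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("guide_id\tspacer\n")
        for g in guides:
            fh.write(f"{g.guide_id}\t{g.spacer}\n")


def read_guides(path: str | Path) -> list[GuideRNA]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [GuideRNA(r["guide_id"], r["spacer"]) for _, r in df.iterrows()]


# --- counts-level simulation ------------------------------------------------

def simulate_counts(
    n_sites: int,
    depth: int,
    background_rate: float,
    true_if: Sequence[float] | float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-site indel/total counts directly from the read-sampling model.

    Each site's MOCK indel count is Binomial(depth, background) and its
    SpCas9 count Binomial(depth, 1 - (1-background)(1-true_if)); this is the
    marginal distribution the read-level simulator induces after filtering,
    and is the generator of choice for calibrating the statistical caller at
    large site numbers.  ``true_if`` is a fraction in [0, 1], scalar or
    per-site.
    """
    rng = np.random.default_rng(seed)
    tif = np.broadcast_to(np.asarray(true_if, dtype=float), (n_sites,))
    p_cas9 = 1.0 - (1.0 - background_rate) * (1.0 - tif)
    rows = []
    for i in range(n_sites):
        cid = f"s{i + 1}"
        rows.append(
            {
                "construct_id": cid, "sample": "MOCK",
                "total_clean": depth,
                "indel": int(rng.binomial(depth, background_rate)),
            }
        )
        rows.append(
            {
                "construct_id": cid, "sample": "SpCas9",
                "total_clean": depth,
                "indel": int(rng.binomial(depth, p_cas9[i])),
            }
        )
    return pd.DataFrame(rows)


def simulate_mismatch_annotations(
    n_sites: int,
    n_mismatches: int = 3,
    type_weights: Mapping[str, float] | None = None,
    position_weights: Sequence[float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-site mismatch annotations with controllable biases.

    Produces a manifest-like table (construct_id, n_mismatches, mismatches)
    whose mismatch positions and (spacer, protospacer) types are drawn from
    the given weight vectors — uniform by default.  Used to plant known
    position/type excesses for the enrichment analysis.
    """
    from .context import MISMATCH_TYPES
    from .design import format_mismatches

    rng = np.random.default_rng(seed)
    tw = np.array(
        [type_weights.get(t, 1.0) if type_weights else 1.0 for t in MISMATCH_TYPES]
    )
    tw = tw / tw.sum()
    pw = np.asarray(
        position_weights if position_weights is not None
        else np.ones(design.SPACER_LENGTH)
    , dtype=float)
    pw = pw / pw.sum()
    rows = []
    for i in range(n_sites):
        positions = rng.choice(
            design.SPACER_LENGTH, size=n_mismatches, replace=False, p=pw
        )
        mismatches = []
        for pos in sorted(positions.tolist()):
            t = MISMATCH_TYPES[rng.choice(len(MISMATCH_TYPES), p=tw)]
            mismatches.append((pos + 1, t[0], t[1]))
        rows.append(
            {
                "construct_id": f"s{i + 1}",
                "n_mismatches": n_mismatches,
                "mismatches": format_mismatches(mismatches),
            }
        )
    return pd.DataFrame(rows)
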