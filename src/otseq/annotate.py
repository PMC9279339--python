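"""Genomic feature annotation of off-target sites.

Each site (the 20-nt protospacer interval) is placed into exactly one
category — 5'UTR, 3'UTR, exon, intron, 2-kb upstream, 2-kb downstream or
intergenic (IGR) — by interval overlap against gene models, using the most
specific overlapped feature: UTRs outrank exon, exon outranks intron, gene
flanks come last before IGR.  Up/downstream are defined by the gene's strand.
Ties between genes are broken alphabetically by gene id so the output is
deterministic.  Sites can additionally be intersected with a user-supplied
gene list (one symbol per line), e.g. cancer- or essential-gene panels.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

CATEGORIES = (
    "5'UTR", "3'UTR", "exon", "intron", "upstream2kb", "downstream2kb", "IGR"
)
_PRECEDENCE = {cat: i for i, cat in enumerate(CATEGORIES)}

_UTR5_TYPES = {"five_prime_UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "three_prime_utr"}


class GeneModels:
    """Interval indexes over a GFF3 file, one tree per (chrom, category)."""

    def __init__(self, gff3_path: str | Path, flank: int = 2000):
        self.flank = flank
        db = gffutils.create_db(
            str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._gene_exons: dict[str, IntervalTree] = {}
        for gene in db.features_of_type("gene"):
            gene_id = gene.attributes.get("ID", [gene.id])[0]
            start, end = gene.start - 1, gene.end  # GFF3 is 1-based inclusive
            self._add(gene.seqid, "gene", start, end, gene_id)
            if gene.strand == "-":
                up = (end, end + flank)
                down = (max(0, start - flank), start)
            else:
                up = (max(0, start - flank), start)
                down = (end, end + flank)
            if up[0] < up[1]:
                self._add(gene.seqid, "upstream2kb", up[0], up[1], gene_id)
            if down[0] < down[1]:
                self._add(gene.seqid, "downstream2kb", down[0], down[1], gene_id)
        for ftype, cat in (
            ("exon", "exon"),
            *((t, "5'UTR") for t in _UTR5_TYPES),
            *((t, "3'UTR") for t in _UTR3_TYPES),
        ):
            try:
                features = list(db.features_of_type(ftype))
            except Exception:
                continue
            for feat in features:
                gene_id = self._owning_gene(db, feat)
                self._add(feat.seqid, cat, feat.start - 1, feat.end, gene_id)
                if cat == "exon":
                    self._gene_exons.setdefault(gene_id, IntervalTree()).addi(
                        feat.start - 1, feat.end, gene_id
                    )
        self.chroms = {chrom for chrom, _ in self._trees}

    @staticmethod
    def _owning_gene(db, feat) -> str:
        node = feat
        for _ in range(4):
            parents = list(db.parents(node, featuretype="gene"))
            if parents:
                return parents[0].attributes.get("ID", [parents[0].id])[0]
            up = list(db.parents(node))
            if not up:
                break
            node = up[0]
        return feat.attributes.get("gene_id", [feat.id])[0]

    def _add(self, chrom: str, cat: str, start: int, end: int, gene_id: str):
        self._trees.setdefault((chrom, cat), IntervalTree()).addi(
            start, end, gene_id
        )

    def _overlapping(self, chrom: str, cat: str, start: int, end: int):
        tree = self._trees.get((chrom, cat))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})

    def classify(self, chrom: str, start: int, end: int) -> tuple[str, str | None]:
        """Most specific (category, gene_id) for an interval; IGR when none."""
        if chrom not in self.chroms:
            return "IGR", None
        for cat in ("5'UTR", "3'UTR", "exon"):
            genes = self._overlapping(chrom, cat, start, end)
            if genes:
                return cat, genes[0]
        for gene_id in self._overlapping(chrom, "gene", start, end):
            exons = self._gene_exons.get(gene_id)
            if exons is None or not exons.overlap(start, end):
                return "intron", gene_id
        for cat in ("upstream2kb", "downstream2kb"):
            genes = self._overlapping(chrom, cat, start, end)
            if genes:
                return cat, genes[0]
        return "IGR", None


def annotate_sites(
    sites: pd.DataFrame,
    gff3_path: str | Path,
    gene_list: set[str] | None = None,
    flank: int = 2000,
) -> pd.DataFrame:
    """Annotate site intervals with a feature category and gene membership.

    ``sites`` needs columns construct_id (or site_id), chrom, start, end
    (0-based half-open protospacer interval).  Sites on chromosomes absent
    from the gene models fall back to IGR with a warning.  The categories
    partition the input: every site receives exactly one.
    """
    models = GeneModels(gff3_path, flank=flank)
    id_col = "construct_id" if "construct_id" in sites else "site_id"
    missing = set(sites["chrom"]) - models.chroms
    if missing:
        logger.warning(
            "chromosomes absent from gene models (sites -> IGR): %s",
            ",".join(sorted(missing)),
        )
    rows = []
    for _, row in sites.iterrows():
        cat, gene_id = models.classify(
            row["chrom"], int(row["start"]), int(row["end"])
        )
        rows.append(
            {
                "site_id": row[id_col],
                "category": cat,
                "gene_id": gene_id if gene_id is not None else ".",
                "in_user_list": bool(gene_list and gene_id in gene_list),
            }
        )
    return pd.DataFrame(rows)


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
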