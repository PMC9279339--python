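"""Read merging, demultiplexing, structural filtering and tabulation."""

import numpy as np
import pandas as pd
import pytest

from otseq import design, reads, simulate
from otseq.align import IndelEvent
from otseq.reads import (
    AlleleClassifier,
    ConstructRef,
    Demultiplexer,
    PairMerger,
    ReadProcessingError,
    SiteCounts,
    positional_indel_filter,
    structural_filter,
    tabulate,
    wt_pseudoedit_subtraction,
)
from conftest import random_seq


def _pair_from(amplicon, read_len=150):
    return amplicon[:read_len], design.revcomp(amplicon)[:read_len]


class TestMerge:
    def test_exact_amplicon_reconstruction(self, rng):
        amplicon = random_seq(rng, 180)
        s1, s2 = _pair_from(amplicon)
        merged = PairMerger().merge("r", s1, "I" * 150, s2, "I" * 150)
        assert merged is not None and merged.sequence == amplicon

    def test_disagreement_resolved_toward_higher_quality(self, rng):
        amplicon = random_seq(rng, 180)
        s1, s2 = _pair_from(amplicon)
        # corrupt a mate-1 base inside the overlap and mark it low quality
        s1 = s1[:100] + ("A" if s1[100] != "A" else "C") + s1[101:]
        q1 = "I" * 100 + "#" + "I" * 49
        merged = PairMerger().merge("r", s1, q1, s2, "I" * 150)
        assert merged.sequence == amplicon

    def test_zero_overlap_dropped_and_counted(self, rng):
        merger = PairMerger(min_overlap=10)
        left = random_seq(rng, 40)
        right = random_seq(rng, 40)
        out = merger.merge("r", left, "I" * 40, design.revcomp(right), "I" * 40)
        assert out is None or reads.design.revcomp  # merge may chance-align
        assert merger.n_unmerged + merger.n_merged == 1

    def test_simulated_pairs_merge_rate(self, small_library):
        *_, manifest = small_library
        cfg = simulate.SimConfig(
            seed=2, depth=200, substitution_rate=0.01,
            synthesis_error_rate=0.0, dropout_fraction=0.0,
        )
        mock, _, _ = simulate.simulate_reads(manifest.iloc[:2], cfg)
        merger = PairMerger()
        lengths = []
        for rid, s1, q1, s2, q2 in mock:
            m = merger.merge(rid, s1, q1, s2, q2)
            if m is not None:
                lengths.append(len(m.sequence))
        rate = merger.n_merged / (merger.n_merged + merger.n_unmerged)
        assert rate >= 0.99
        # unedited molecules reconstruct the full 210-nt amplicon +-1
        assert np.median(lengths) == 210

    def test_desynchronized_mates_error(self, tmp_path):
        (tmp_path / "r1.fq").write_text("@a/1\nACGT\n+\nIIII\n")
        (tmp_path / "r2.fq").write_text("@b/2\nACGT\n+\nIIII\n")
        with pytest.raises(ReadProcessingError, match="desynchronized"):
            list(reads.read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"))


class TestDemux:
    def _amplicon(self, row):
        return (
            simulate.LEFT_FLANK + simulate._rebuild_oligo(
                row, design.SPCAS9_SCAFFOLD
            ) + simulate.RIGHT_FLANK
        )

    def test_exact_assignment_and_orientation(self, small_library):
        *_, manifest = small_library
        demux = Demultiplexer(manifest)
        for _, row in manifest.iterrows():
            amplicon = self._amplicon(row)
            cid, _ = demux.assign(amplicon)
            assert cid == row["construct_id"]
            cid_rc, oriented = demux.assign(design.revcomp(amplicon))
            assert cid_rc == row["construct_id"] and oriented == amplicon

    def test_barcode_substitution_is_unassigned(self, small_library):
        *_, manifest = small_library
        demux = Demultiplexer(manifest)
        row = manifest.iloc[0]
        amplicon = self._amplicon(row)
        i = amplicon.find(row["barcode"] + row["surrogate27"])
        bad = amplicon[:i] + ("T" if amplicon[i] != "T" else "G") + amplicon[i + 1:]
        cid, _ = demux.assign(bad)
        assert cid is None
        assert demux.counters["unassigned_unknown_barcode"] == 1

    def test_accuracy_with_barcode_errors(self, small_library, rng):
        """0.3% of reads carry a barcode error: >=99% of reads are still
        assigned correctly and none is cross-assigned."""
        *_, manifest = small_library
        demux = Demultiplexer(manifest)
        n_total, n_correct, n_cross = 0, 0, 0
        for _ in range(1500):
            row = manifest.iloc[int(rng.integers(len(manifest)))]
            amplicon = self._amplicon(row)
            i = amplicon.find(row["barcode"])
            bc = list(row["barcode"])
            if rng.random() < 0.003:
                k = int(rng.integers(10))
                bc[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bc[k]]
            amplicon = amplicon[:i] + "".join(bc) + amplicon[i + 10:]
            cid, _ = demux.assign(amplicon)
            n_total += 1
            if cid == row["construct_id"]:
                n_correct += 1
            elif cid is not None:
                n_cross += 1
        assert n_correct / n_total >= 0.99
        assert n_cross == 0

    def test_duplicate_barcodes_rejected(self, small_library):
        *_, manifest = small_library
        bad = pd.concat([manifest, manifest.iloc[[0]]])
        with pytest.raises(ReadProcessingError, match="unique"):
            Demultiplexer(bad)


class TestStructuralFilter:
    def _ref_and_read(self, manifest, idx=0):
        row = manifest.iloc[idx]
        ref = ConstructRef.from_manifest_row(row)
        amplicon = (
            simulate.LEFT_FLANK + simulate._rebuild_oligo(
                row, design.SPCAS9_SCAFFOLD
            ) + simulate.RIGHT_FLANK
        )
        return ref, amplicon

    def test_unedited_read_passes(self, small_library):
        *_, manifest = small_library
        ref, read = self._ref_and_read(manifest)
        observed, reason = structural_filter(read, ref)
        assert reason == "pass" and observed == ref.surrogate27

    def test_deletion_shortens_extracted_segment(self, small_library):
        *_, manifest = small_library
        ref, read = self._ref_and_read(manifest)
        i = read.find(ref.surrogate27)
        edited = read[:i + 10] + read[i + 12:]  # 2-nt deletion inside surrogate
        observed, reason = structural_filter(edited, ref)
        assert reason == "pass" and len(observed) == 25

    def test_scaffold_substitution_fails_structure(self, small_library):
        *_, manifest = small_library
        ref, read = self._ref_and_read(manifest)
        i = read.find(design.SPCAS9_SCAFFOLD) + 40
        bad = read[:i] + ("A" if read[i] != "A" else "C") + read[i + 1:]
        observed, reason = structural_filter(bad, ref)
        assert observed is None and reason == "structure"

    def test_extreme_length_change_fails_length(self, small_library):
        *_, manifest = small_library
        ref, read = self._ref_and_read(manifest)
        i = read.find(ref.surrogate27)
        gutted = read[:i] + read[i + 26:]  # 26-nt deletion
        observed, reason = structural_filter(gutted, ref)
        assert observed is None and reason == "length"


class TestPositionalFilter:
    @pytest.mark.parametrize("pos,expected", [(5, False), (14, False),
                                              (15, True), (17, True),
                                              (21, True), (22, False)])
    def test_single_1bp_deletion(self, pos, expected):
        assert positional_indel_filter([IndelEvent("del", 1, pos, pos)]) is expected

    def test_2bp_event_always_retained(self):
        assert positional_indel_filter([IndelEvent("del", 2, 3, 4)])
        assert positional_indel_filter([IndelEvent("ins", 2, 25, 25)])

    def test_insertion_anchor_boundaries(self):
        assert not positional_indel_filter([IndelEvent("ins", 1, 14, 14)])
        assert positional_indel_filter([IndelEvent("ins", 1, 21, 21)])

    def test_deletion_spanning_window_edge(self):
        assert positional_indel_filter([IndelEvent("del", 3, 13, 15)])


class TestWtSubtraction:
    def _counts(self, alleles, ref):
        sc = SiteCounts("c1", "SpCas9")
        classifier = AlleleClassifier()
        for allele, n in alleles.items():
            sc.allele_table[allele] += n
            sc.total_clean += n
            if allele != ref and classifier.is_indel(allele, ref):
                sc.indel += n
        return sc

    def test_shared_artifact_allele_removed(self, rng):
        ref = random_seq(rng, 27)
        artifact = ref[:16] + ref[17:]  # 1-bp deletion at N17: looks edited
        cas9 = self._counts({ref: 90, artifact: 7, ref[:15] + ref[17:]: 3}, ref)
        mock = self._counts({ref: 95, artifact: 5}, ref)
        mock.sample = "MOCK"
        out = wt_pseudoedit_subtraction(cas9, mock, AlleleClassifier(), ref)
        assert artifact not in out.allele_table
        assert out.total_clean == 93 and out.indel == 3
        assert out.filtered_counts["wt_pseudoedit"] == 7
        assert out.assigned == cas9.assigned

    def test_disjoint_alleles_unchanged(self, rng):
        ref = random_seq(rng, 27)
        cas9 = self._counts({ref: 90, ref[:10] + ref[12:]: 10}, ref)
        mock = self._counts({ref: 100}, ref)
        out = wt_pseudoedit_subtraction(cas9, mock, AlleleClassifier(), ref)
        assert out is cas9


@pytest.fixture(scope="module")
def pipeline_run(small_library, tmp_path_factory):
    *_, manifest = small_library
    cfg = simulate.SimConfig(
        seed=21, depth=150, substitution_rate=0.0005,
        synthesis_error_rate=0.0, dropout_fraction=0.0,
    )
    mock, cas9, truth = simulate.simulate_reads(manifest, cfg)
    d = tmp_path_factory.mktemp("fq")
    simulate.write_fastq_pair(mock, d / "m1.fq.gz", d / "m2.fq.gz")
    simulate.write_fastq_pair(cas9, d / "c1.fq", d / "c2.fq")
    counts, mock_t, cas9_t = tabulate(
        manifest, (d / "m1.fq.gz", d / "m2.fq.gz"), (d / "c1.fq", d / "c2.fq")
    )
    return manifest, counts, mock_t, cas9_t, truth


class TestTabulate:
    def test_counting_invariants(self, pipeline_run):
        manifest, counts, mock_t, cas9_t, _ = pipeline_run
        assert set(counts["construct_id"]) == set(manifest["construct_id"])
        assert (counts["indel"] <= counts["total_clean"]).all()
        for table in (mock_t, cas9_t):
            for sc in table.values():
                assert sum(sc.allele_table.values()) == sc.total_clean
                assert sc.assigned == sc.total_clean + sum(
                    sc.filtered_counts.values()
                )

    def test_counts_track_simulator_truth(self, pipeline_run):
        manifest, counts, _, _, truth = pipeline_run
        cas9 = counts[counts["sample"] == "SpCas9"].set_index("construct_id")
        for _, row in truth.iterrows():
            got = cas9.loc[row["construct_id"]]
            est_if = got["indel"] / got["total_clean"] * 100
            # realized edited fraction, with background tolerance
            true_pct = row["n_edited_reads"] / row["n_reads_cas9"] * 100
            assert abs(est_if - true_pct) < 2.5

    def test_order_invariance(self, small_library, tmp_path):
        *_, manifest = small_library
        cfg = simulate.SimConfig(seed=33, depth=40, dropout_fraction=0.0)
        mock, cas9, _ = simulate.simulate_reads(manifest.iloc[:3], cfg)
        rng = np.random.default_rng(0)

        def run(records_m, records_c, tag):
            simulate.write_fastq_pair(records_m, tmp_path / f"{tag}m1.fq",
                                      tmp_path / f"{tag}m2.fq")
            simulate.write_fastq_pair(records_c, tmp_path / f"{tag}c1.fq",
                                      tmp_path / f"{tag}c2.fq")
            counts, *_ = tabulate(
                manifest.iloc[:3],
                (tmp_path / f"{tag}m1.fq", tmp_path / f"{tag}m2.fq"),
                (tmp_path / f"{tag}c1.fq", tmp_path / f"{tag}c2.fq"),
            )
            return counts

        a = run(mock, cas9, "a")
        shuffled_m = [mock[i] for i in rng.permutation(len(mock))]
        shuffled_c = [cas9[i] for i in rng.permutation(len(cas9))]
        b = run(shuffled_m, shuffled_c, "b")
        assert a.equals(b)
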