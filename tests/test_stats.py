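"""Fisher testing, BH adjustment, site calling and enrichment flags."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

from otseq import simulate
from otseq.stats import (
    CallThresholds,
    bh_adjust,
    call_sites,
    enrichment_depletion,
    fisher_test,
    fold_change,
    indel_frequency,
)
from oracles import bh_definitional, exact_fisher_two_sided


class TestIndelFrequency:
    @pytest.mark.parametrize(
        "indel,total,expected", [(0, 100, 0.0), (25, 100, 25.0), (5, 32, 15.625)]
    )
    def test_direct_formula(self, indel, total, expected):
        assert indel_frequency(indel, total) == expected

    def test_zero_total_is_undefined(self):
        assert np.isnan(indel_frequency(0, 0))

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError):
            indel_frequency(5, 4)


class TestFisher:
    def test_symmetric_table(self):
        assert fisher_test(5, 5, 5, 5) == 1.0

    @pytest.mark.parametrize("n", [0, 1, 7, 100])
    def test_no_indels_anywhere(self, n):
        assert fisher_test(0, n, 0, n) == 1.0

    def test_matches_exact_enumeration(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            expect = exact_fisher_two_sided(a, b, c, d)
            assert fisher_test(a, b, c, d) == pytest.approx(expect, abs=1e-12)

    def test_matches_scipy_cross_check(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 60, size=4))
            if (a + b) == 0 or (c + d) == 0:
                continue
            ours = fisher_test(a, b, c, d)
            ref = fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12)

    def test_monotone_in_cas9_indels_past_symmetry(self):
        """With fixed totals and MOCK counts, p is non-increasing as the
        SpCas9 indel count grows beyond the MOCK-matched point."""
        prev = None
        for a in range(10, 400):
            p = fisher_test(a, 1000 - a, 10, 990)
            if prev is not None:
                assert p <= prev + 1e-12
            prev = p


class TestBH:
    def test_single_value(self):
        assert bh_adjust([0.01]).tolist() == [0.01]

    def test_hand_computed_example(self):
        # ranks 1..4: min over j>=rank of (4/j) p_(j) = 0.04 for all
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04] * 4
        )

    def test_matches_definitional_formula(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert bh_adjust(p).tolist() == pytest.approx(bh_definitional(p))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_permutation_invariance(self, pvals, rnd):
        base = bh_adjust(pvals)
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        permuted = bh_adjust([pvals[i] for i in perm])
        for k, i in enumerate(perm):
            assert permuted[k] == pytest.approx(base[i])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def _counts_df(entries):
    rows = []
    for cid, (tm, im, tc, ic) in entries.items():
        rows.append({"construct_id": cid, "sample": "MOCK",
                     "total_clean": tm, "indel": im})
        rows.append({"construct_id": cid, "sample": "SpCas9",
                     "total_clean": tc, "indel": ic})
    return pd.DataFrame(rows)


class TestCallSites:
    def test_strong_site_is_hiot(self):
        calls = call_sites(_counts_df({"s": (1000, 10, 1000, 400)}))
        row = calls.iloc[0]
        assert row["call"] == "HIOT"
        assert row["fold_change"] == pytest.approx(40.0)
        assert row["adj_p"] < 1e-50

    def test_low_if_significant_site_is_liot(self):
        calls = call_sites(_counts_df({"s": (1000, 5, 1000, 20)}))
        row = calls.iloc[0]
        assert row["adj_p"] < 0.05 and row["if_cas9"] == 2.0
        assert row["call"] == "LIOT"

    def test_three_percent_boundary(self):
        calls = call_sites(
            _counts_df({"lo": (2000, 2, 2000, 59), "hi": (2000, 2, 2000, 60)})
        ).set_index("construct_id")
        assert calls.loc["lo", "call"] == "LIOT"   # 2.95% < 3
        assert calls.loc["hi", "call"] == "HIOT"   # 3.0% >= 3

    def test_min_indel_support_demotes(self):
        calls = call_sites(_counts_df({"s": (1000, 0, 1000, 4)}))
        assert calls.iloc[0]["call"] == "NSOT"

    def test_filters_and_reasons(self):
        calls = call_sites(
            _counts_df(
                {
                    "shallow": (10, 0, 1000, 100),
                    "synth": (1000, 60, 1000, 300),   # MOCK IF 6% > 4
                    "dirty": (1000, 300, 1000, 600),  # MOCK IF 30% > 25
                    "empty": (0, 0, 0, 0),
                }
            )
        ).set_index("construct_id")
        assert (calls["call"] == "FILTERED").all()
        assert "read_quality" in calls.loc["shallow", "filter_reasons"]
        assert "synthesis" in calls.loc["synth", "filter_reasons"]
        assert "wt_if" in calls.loc["dirty", "filter_reasons"]
        assert "no_reads" in calls.loc["empty", "filter_reasons"]

    def test_unpaired_site_filtered(self):
        df = _counts_df({"s": (1000, 10, 1000, 100)})
        calls = call_sites(df[df["sample"] == "MOCK"])
        assert calls.iloc[0]["call"] == "FILTERED"
        assert "unpaired" in calls.iloc[0]["filter_reasons"]

    def test_bh_family_is_all_testable_sites(self):
        entries = {f"s{i}": (1000, 10, 1000, 12 + i) for i in range(20)}
        calls = call_sites(_counts_df(entries))
        tested = calls[calls["call"] != "FILTERED"]
        assert bh_adjust(tested["fisher_p"]).tolist() == pytest.approx(
            tested["adj_p"].tolist()
        )

    def test_fc_continuity_modes(self):
        assert fold_change(40, 1000, 0, 1000) == pytest.approx(80.0)
        assert fold_change(40, 1000, 0, 1000, continuity="raw") == np.inf

    def test_thresholds_echoed(self):
        th = CallThresholds(alpha=0.01)
        calls = call_sites(_counts_df({"s": (100, 1, 100, 50)}), th)
        assert calls.attrs["thresholds"]["alpha"] == 0.01


class TestNullCalibration:
    def test_no_editing_yields_almost_no_significant_calls(self):
        """Both samples at 1% background, depth 1000: the joint FC >= 2 and
        adjusted p < 0.05 requirement keeps significant calls at ~0."""
        frac = []
        for seed in range(5):
            counts = simulate.simulate_counts(
                n_sites=200, depth=1000, background_rate=0.01, seed=seed
            )
            calls = call_sites(counts)
            sig = calls["call"].isin(["LIOT", "HIOT"]).mean()
            frac.append(sig)
        assert np.mean(frac) <= 0.05


class TestEnrichmentDepletion:
    def test_equal_counts_unflagged(self):
        df = _counts_df({"a": (1000, 0, 1000, 0), "b": (500, 0, 500, 0)})
        flags = enrichment_depletion(df)
        assert (flags["enrichment_flag"] == "none").all()

    def test_depletion_flagged(self):
        df = _counts_df({"a": (1000, 0, 1000, 0), "b": (900, 0, 300, 0)})
        flags = enrichment_depletion(df).set_index("construct_id")
        assert flags.loc["b", "enrichment_flag"] == "depleted"

    def test_dropout_constructs_recovered_from_simulation(self):
        rng = np.random.default_rng(3)
        rows = {}
        dropped = set()
        for i in range(100):
            cid = f"s{i}"
            depth = 1000
            if rng.random() < 0.05:
                dropped.add(cid)
                rows[cid] = (depth, 0, depth // 4, 0)
            else:
                rows[cid] = (depth, 0, depth, 0)
        flags = enrichment_depletion(_counts_df(rows)).set_index("construct_id")
        called = set(flags.index[flags["enrichment_flag"] == "depleted"])
        assert called == dropped

    def test_zero_library_size_rejected(self):
        df = _counts_df({"a": (0, 0, 1000, 0)})
        with pytest.raises(ValueError, match="zero library size"):
            enrichment_depletion(df)
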