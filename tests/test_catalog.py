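"""Catalog construction, context frequencies and the detection-power filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import platsig as ps
from platsig.catalog import assign_channels


def _table(rows, columns=("sample", "chrom", "pos", "ref", "alt", "context5", "context3")):
    return pd.DataFrame(rows, columns=list(columns))


class TestBuildCatalog:
    def test_single_snv_lands_in_its_channel(self):
        df = _table([("T1", "chr1", 5, "C", "A", "A", "A")])
        catalog, qc = ps.build_catalog(df)
        assert catalog.total == 1
        assert catalog.counts[0, 0] == 1  # A[C>A]A is channel 0
        assert qc.n_retained == 1

    def test_empty_table_gives_zero_catalog_with_requested_columns(self):
        df = _table([])
        catalog, _ = ps.build_catalog(df, samples=["T1", "T2"])
        assert catalog.samples == ["T1", "T2"]
        assert catalog.total == 0

    def test_counts_conserved_on_simulated_cohort(self, small_cohort):
        catalog, qc = ps.build_catalog(small_cohort.post)
        assert catalog.total == len(small_cohort.post) == qc.n_retained
        # per-sample column sums match per-sample record counts
        per_sample = small_cohort.post.groupby("sample").size()
        for j, s in enumerate(catalog.samples):
            assert catalog.counts[:, j].sum() == per_sample[s]

    def test_purine_spelling_collapses_to_truth_channel(self, small_cohort):
        """Records written on the purine strand land in the same channel."""
        annotated = assign_channels(small_cohort.post.copy())
        assert (annotated["channel"] == annotated["channel_truth"]).all()

    def test_indels_and_ambiguous_contexts_excluded_and_counted(self):
        df = _table([
            ("T1", "chr1", 5, "C", "A", "A", "A"),
            ("T1", "chr1", 9, "CT", "C", "A", "A"),   # indel
            ("T1", "chr1", 12, "C", "A", "N", "A"),   # ambiguous flank
        ])
        catalog, qc = ps.build_catalog(df)
        assert catalog.total == 1
        assert qc.n_indel == 1
        assert qc.n_ambiguous_context == 1

    def test_reference_context_extraction_and_mismatch_exclusion(self, tiny_fasta):
        # chr1: ACATGGCTAGCTT; pos 2 (1-based) = C with flanks A,A
        df = _table(
            [("T1", "chr1", 2, "C", "G"), ("T1", "chr1", 3, "G", "T")],
            columns=("sample", "chrom", "pos", "ref", "alt"),
        )
        catalog, qc = ps.build_catalog(df, reference=tiny_fasta)
        assert catalog.total == 1  # second record: reference has A at pos 3
        assert qc.n_ref_mismatch == 1
        assert catalog.counts[ps.CHANNELS_96.index("A[C>G]A"), 0] == 1


class TestStrandedCatalog:
    def test_single_coding_mutation(self):
        df = _table(
            [("T1", "chr1", 5, "C", "A", "A", "A", "coding")],
            columns=("sample", "chrom", "pos", "ref", "alt", "context5", "context3", "strand"),
        )
        catalog, _ = ps.build_stranded_catalog(df)
        assert catalog.counts[ps.CHANNELS_192.index("A[C>A]A|+"), 0] == 1
        assert catalog.total == 1

    def test_marginalizes_to_unstranded_catalog(self, small_cohort):
        stranded, _ = ps.build_stranded_catalog(small_cohort.post)
        plain, _ = ps.build_catalog(small_cohort.post)
        collapsed = stranded.collapse_strands()
        assert collapsed.samples == plain.samples
        np.testing.assert_array_equal(collapsed.counts, plain.counts)

    def test_all_unassigned_is_an_error(self):
        df = _table(
            [("T1", "chr1", 5, "C", "A", "A", "A", "?")],
            columns=("sample", "chrom", "pos", "ref", "alt", "context5", "context3", "strand"),
        )
        with pytest.raises(ValueError, match="strand"):
            ps.build_stranded_catalog(df)


class TestContextFrequencies:
    def test_single_window(self):
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [1], "end": [2]})
        table = ps.compute_context_frequencies({"chr1": "ACA"}, bed)
        assert table.frequency[ps.CONTEXTS_32.index("ACA")] == 1.0

    def test_purine_centered_window_collapses(self):
        # "ACAC": windows ACA (pyrimidine center) and CAC -> recorded as GTG
        table = ps.compute_context_frequencies({"chr1": "ACAC"})
        freqs = table.to_series()
        assert freqs["ACA"] == pytest.approx(0.5)
        assert freqs["GTG"] == pytest.approx(0.5)
        assert freqs.sum() == pytest.approx(1.0)

    def test_interval_edges_use_reference_flanks(self):
        # interval covers only position 2 (0-based), flanks come from outside
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [2], "end": [3]})
        table = ps.compute_context_frequencies({"chr1": "GGCGG"}, bed)
        assert table.frequency[ps.CONTEXTS_32.index("GCG")] == 1.0

    def test_uniform_random_sequence_matches_multinomial_expectation(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=1_000_000))
        table = ps.compute_context_frequencies({"chr1": seq})
        n = len(seq) - 2
        # each pyrimidine-centered context collects 2 of the 64 raw
        # trinucleotides, each with probability 1/64
        p = 2 / 64
        se = math.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(table.frequency - p) < 3.5 * se)

    def test_empty_territory_is_an_error(self):
        with pytest.raises(ValueError, match="countable"):
            ps.compute_context_frequencies({"chr1": "NNNNN"})


class TestDetectionPower:
    def test_degenerate_inputs(self):
        assert ps.detection_power(0, 0.3) == 0.0
        assert ps.detection_power(1000, 0.5) == pytest.approx(1.0, abs=1e-9)
        assert ps.detection_power(50, 0.0) == 0.0

    def test_matches_exact_binomial_sum(self):
        expected = 1.0 - sum(
            math.comb(30, k) * 0.1**k * 0.9 ** (30 - k) for k in range(3)
        )
        assert ps.detection_power(30, 0.1) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_oracle_for_small_depths(self):
        model = ps.PowerModel(min_alt_reads=3)
        rng = np.random.default_rng(11)
        for depth in range(0, 51, 5):
            for vaf in rng.uniform(0.01, 0.9, size=3):
                exact = sum(
                    math.comb(depth, k) * vaf**k * (1 - vaf) ** (depth - k)
                    for k in range(3, depth + 1)
                )
                assert ps.detection_power(depth, vaf, model) == pytest.approx(exact, abs=1e-10)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        depth=st.integers(min_value=0, max_value=500),
        vaf=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_monotone_in_depth_and_vaf(self, depth, vaf):
        p = ps.detection_power(depth, vaf)
        assert ps.detection_power(depth + 25, vaf) >= p - 1e-12
        assert ps.detection_power(depth, min(1.0, vaf + 0.05)) >= p - 1e-12


class TestClassifySharedPrivate:
    @staticmethod
    def _pair():
        cols = ("sample", "chrom", "pos", "ref", "alt", "mate_depth", "mate_vaf")
        pre = pd.DataFrame([
            ("P1_pre", "chr1", 100, "C", "A", np.nan, np.nan),  # shared
            ("P1_pre", "chr1", 200, "C", "T", 200.0, 0.25),     # powered -> pre_only
            ("P1_pre", "chr1", 300, "T", "G", 5.0, 0.10),       # underpowered
        ], columns=cols)
        post = pd.DataFrame([
            ("P1_post", "chr1", 100, "C", "A", np.nan, np.nan),  # shared
            ("P1_post", "chr1", 400, "T", "C", 150.0, 0.30),     # powered -> post_only
        ], columns=cols)
        return pre, post

    def test_timing_labels(self):
        pre, post = self._pair()
        out = ps.classify_shared_private(pre, post)
        timing = out.set_index("pos")["timing"]
        assert timing[100].eq("shared").all()
        assert timing[200] == "pre_only"
        assert timing[300] == "unpowered"
        assert timing[400] == "post_only"

    def test_cohort_pairing_error_on_unmatched_patients(self):
        pre, post = self._pair()
        pre["patient"] = "P1"
        post["patient"] = "P2"
        with pytest.raises(ValueError, match="unmatched patient"):
            ps.classify_cohort(pre, post)

    def test_cohort_roundtrip_recovers_truth_timing(self, small_cohort):
        """Power-filter classification agrees with generator truth except
        where the mate tumor is genuinely underpowered."""
        out = ps.classify_cohort(small_cohort.pre, small_cohort.post)
        resolved = out[out["timing"] != "unpowered"]
        assert (resolved["timing"] == resolved["timing_truth"]).all()
        # shared sites are always resolved as shared
        truth_shared = out[out["timing_truth"] == "shared"]
        assert (truth_shared["timing"] == "shared").all()
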