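"""Clonality-weighted signature attribution and subclonal enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import platsig as ps
from platsig.attribution import clonality_from_ccf


def _two_sig_set() -> ps.SignatureSet:
    """K=2 set with channel 0 activities (0.05, 0.01)."""
    W = np.full((96, 2), np.nan)
    W[:, 0] = (1 - 0.05) / 95
    W[0, 0] = 0.05
    W[:, 1] = (1 - 0.01) / 95
    W[0, 1] = 0.01
    return ps.SignatureSet(ps.CHANNELS_96, ["S1", "S2"], W)


class TestAttributeMutation:
    def test_worked_two_signature_example(self):
        """Activities (10, 90), channel activities (0.05, 0.01):
        c = 10*0.05 / (10*0.05 + 90*0.01)."""
        credit = ps.attribute_mutation(0, _two_sig_set(), np.array([10.0, 90.0]))
        expected = 10 * 0.05 / (10 * 0.05 + 90 * 0.01)
        assert credit[0] == pytest.approx(expected, abs=1e-12)
        assert credit[1] == pytest.approx(1 - expected, abs=1e-12)

    def test_uniform_case_splits_evenly(self, three_sigs):
        W = np.full((96, 3), 1 / 96)
        sigs = ps.SignatureSet(ps.CHANNELS_96, list("abc"), W)
        credit = ps.attribute_mutation(42, sigs, np.full(3, 7.0))
        np.testing.assert_allclose(credit, 1 / 3)

    def test_zero_channel_activity_gets_zero_credit(self):
        W = np.zeros((96, 2))
        W[0, 0] = 1.0
        W[1:, 1] = 1 / 95
        sigs = ps.SignatureSet(ps.CHANNELS_96, ["a", "b"], W)
        credit = ps.attribute_mutation(0, sigs, np.array([5.0, 5.0]))
        assert credit[1] == 0.0
        assert credit[0] == 1.0

    def test_unattributable_channel_raises(self):
        W = np.zeros((96, 2))
        W[0, :] = 1.0
        sigs = ps.SignatureSet(ps.CHANNELS_96, ["a", "b"], W)
        with pytest.raises(ValueError, match="unattributable"):
            ps.attribute_mutation(5, sigs, np.array([1.0, 1.0]))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    def test_invariant_to_activity_rescaling(self, scale):
        h = np.array([10.0, 90.0])
        base = ps.attribute_mutation(0, _two_sig_set(), h)
        scaled = ps.attribute_mutation(0, _two_sig_set(), h * scale)
        np.testing.assert_allclose(scaled, base, atol=1e-9)


class TestAggregate:
    @staticmethod
    def _mutations(rows):
        return pd.DataFrame(rows, columns=["sample", "channel96", "clonality"])

    def test_credit_conservation(self, small_cohort):
        catalog, _ = ps.build_catalog(small_cohort.post)
        refit = ps.infer_activities(catalog, small_cohort.signatures, ps.RefitConfig(seed=2))
        muts = small_cohort.post.rename(columns={"channel_truth": "channel"}).copy()
        muts["channel96"] = muts["channel"].map(
            {c: i for i, c in enumerate(ps.CHANNELS_96)}
        )
        res = ps.aggregate_attributions(muts, small_cohort.signatures, refit.activities)
        total_credit = (
            res.table["clonal_credit"].sum() + res.table["subclonal_credit"].sum()
        )
        assert total_credit == pytest.approx(res.n_attributed, abs=1e-6)
        assert res.n_excluded_clonality == 0

    def test_all_clonal_gives_zero_subclonal_fraction(self):
        muts = self._mutations([("s", 0, "clonal")] * 10)
        acts = ps.ActivityMatrix(["S1", "S2"], ["s"], np.array([[10.0], [90.0]]))
        res = ps.aggregate_attributions(muts, _two_sig_set(), acts)
        assert (res.table["subclonal_fraction"] == 0).all()
        assert res.overall_subclonal_fraction == 0.0

    def test_single_subclonal_mutation_reproduces_worked_example(self):
        muts = self._mutations([("s", 0, "subclonal")])
        acts = ps.ActivityMatrix(["S1", "S2"], ["s"], np.array([[10.0], [90.0]]))
        res = ps.aggregate_attributions(muts, _two_sig_set(), acts)
        np.testing.assert_allclose(
            res.table["subclonal_credit"], [0.357142857142857, 0.642857142857143],
            atol=1e-9,
        )

    def test_unknown_clonality_excluded_and_counted(self):
        muts = self._mutations([("s", 0, "clonal"), ("s", 0, "unknown")])
        acts = ps.ActivityMatrix(["S1", "S2"], ["s"], np.array([[10.0], [90.0]]))
        res = ps.aggregate_attributions(muts, _two_sig_set(), acts)
        assert res.n_attributed == 1
        assert res.n_excluded_clonality == 1

    def test_planted_subclonal_signature_ranks_most_subclonal(self):
        """The treatment signature, confined to subclonal mutations by the
        generator, has the highest subclonal credit fraction in almost
        every replicate."""
        wins = 0
        n_reps = 50
        chan_idx = {c: i for i, c in enumerate(ps.CHANNELS_96)}
        for rep in range(n_reps):
            cohort = ps.generate_paired_cohort(
                ps.SimulationConfig(n_patients=6, mutations_per_tumor=300, seed=3000 + rep)
            )
            catalog, _ = ps.build_catalog(cohort.post)
            refit = ps.infer_activities(
                catalog, cohort.signatures, ps.RefitConfig(seed=rep)
            )
            muts = cohort.post.copy()
            muts["channel96"] = muts["channel_truth"].map(chan_idx)
            res = ps.aggregate_attributions(muts, cohort.signatures, refit.activities)
            table = res.table.set_index("signature")
            if table["subclonal_fraction"].idxmax() == ps.TREATMENT:
                wins += 1
        assert wins >= 0.95 * n_reps


class TestEnrichmentTest:
    def test_identical_proportions_give_zero_statistic(self):
        table = pd.DataFrame({
            "signature": ["a", "b"],
            "clonal_credit": [50.0, 100.0],
            "subclonal_credit": [50.0, 100.0],
        })
        res = ps.subclonal_enrichment_test(table)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_degrees_of_freedom_is_k_minus_one(self):
        table = pd.DataFrame({
            "signature": list("abcd"),
            "clonal_credit": [50.0, 60.0, 70.0, 80.0],
            "subclonal_credit": [10.0, 30.0, 20.0, 40.0],
        })
        assert ps.subclonal_enrichment_test(table).df == 3

    def test_matches_textbook_pearson_chi_squared(self):
        """(50,50) vs (90,10): statistic checked against the hand-computed
        Pearson chi-squared of the 2x2 table."""
        table = pd.DataFrame({
            "signature": ["a", "b"],
            "clonal_credit": [50.0, 90.0],
            "subclonal_credit": [50.0, 10.0],
        })
        res = ps.subclonal_enrichment_test(table)
        # expected counts from margins: rows (100, 100), cols (140, 60)
        expected = np.array([[70.0, 30.0], [70.0, 30.0]])
        observed = np.array([[50.0, 50.0], [90.0, 10.0]])
        stat = ((observed - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.df == 1

    def test_zero_credit_signature_dropped_with_warning(self):
        table = pd.DataFrame({
            "signature": ["a", "b", "empty"],
            "clonal_credit": [50.0, 90.0, 0.0],
            "subclonal_credit": [50.0, 10.0, 0.0],
        })
        with pytest.warns(UserWarning, match="zero-credit"):
            res = ps.subclonal_enrichment_test(table)
        assert res.df == 1
        assert res.dropped == ["empty"]

    def test_type_one_error_calibrated_without_association(self):
        """Credits drawn with one shared subclonal proportion reject at
        ~alpha across replicates."""
        rng = np.random.default_rng(99)
        alpha, n_sims, rejections = 0.05, 1000, 0
        for _ in range(n_sims):
            totals = rng.integers(200, 800, size=3)
            sub = rng.binomial(totals, 0.3)
            table = pd.DataFrame({
                "signature": list("abc"),
                "clonal_credit": (totals - sub).astype(float),
                "subclonal_credit": sub.astype(float),
            })
            if ps.subclonal_enrichment_test(table).p_value < alpha:
                rejections += 1
        se = np.sqrt(alpha * (1 - alpha) / n_sims)
        assert abs(rejections / n_sims - alpha) < 4 * se


class TestClonalityFromCCF:
    def test_threshold_and_missing(self):
        labels = clonality_from_ccf(np.array([1.0, 0.9995, 0.5, np.nan]))
        assert list(labels) == ["clonal", "clonal", "subclonal", "unknown"]
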