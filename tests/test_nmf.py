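"""Signature discovery: multi-run NMF, rank diagnostics, cosine matching."""

import numpy as np
import pandas as pd
import pytest

import platsig as ps
from platsig import nmf


def _best_cosines(discovered: ps.SignatureSet, truth: ps.SignatureSet) -> dict:
    return {
        t: max(
            ps.cosine_similarity(discovered.W[:, i], truth[t])
            for i in range(discovered.k)
        )
        for t in truth.names
    }


class TestDiscovery:
    def test_exact_rank_one_catalog_recovered(self, three_sigs):
        sig = three_sigs.W[:, 0]
        loadings = np.array([100.0, 250.0, 60.0, 400.0])
        V = np.rint(np.outer(sig, loadings) * 10)  # scale up to reduce rounding
        catalog = ps.MutationCatalog(ps.CHANNELS_96, list("abcd"), V.astype(int))
        res = ps.discover_signatures(catalog, rank=1, n_runs=3, seed=0)
        assert ps.cosine_similarity(res.signatures.W[:, 0], sig) >= 0.999
        assert res.residual <= 0.01 * np.linalg.norm(V)

    def test_same_seed_reproduces_identical_factors(self, mixture_catalog):
        catalog, _ = mixture_catalog
        a = ps.discover_signatures(catalog, rank=3, n_runs=4, seed=9)
        b = ps.discover_signatures(catalog, rank=3, n_runs=4, seed=9)
        np.testing.assert_array_equal(a.signatures.W, b.signatures.W)
        np.testing.assert_array_equal(a.activities.H, b.activities.H)

    def test_planted_signatures_recovered(self, mixture_catalog, three_sigs):
        catalog, H_true = mixture_catalog
        res = ps.discover_signatures(catalog, rank=3, n_runs=20, seed=1)
        best = _best_cosines(res.signatures, three_sigs)
        assert all(v >= 0.95 for v in best.values()), best

    def test_activity_recovery_correlates_with_truth(self, mixture_catalog, three_sigs):
        catalog, H_true = mixture_catalog
        res = ps.discover_signatures(catalog, rank=3, n_runs=20, seed=1)
        # align discovered to truth by cosine, then check activities
        for k, name in enumerate(three_sigs.names):
            sims = [
                ps.cosine_similarity(res.signatures.W[:, i], three_sigs.W[:, k])
                for i in range(3)
            ]
            i = int(np.argmax(sims))
            r = np.corrcoef(res.activities.H[i], H_true[k])[0, 1]
            assert r >= 0.9

    def test_error_trace_is_non_increasing(self, mixture_catalog):
        catalog, _ = mixture_catalog
        res = ps.discover_signatures(catalog, rank=2, n_runs=2, seed=3)
        assert np.all(np.diff(res.error_trace) <= 1e-9)

    def test_factor_normalization_preserves_product(self, mixture_catalog):
        catalog, _ = mixture_catalog
        res = ps.discover_signatures(catalog, rank=3, n_runs=2, seed=5)
        np.testing.assert_allclose(res.signatures.W.sum(axis=0), 1.0, atol=1e-9)
        # reconstruction from normalized factors matches the residual
        recon_err = np.linalg.norm(catalog.counts - res.signatures.W @ res.activities.H)
        assert recon_err == pytest.approx(res.residual, rel=1e-9)

    def test_invalid_rank_and_empty_catalog_rejected(self):
        zero = ps.MutationCatalog(ps.CHANNELS_96, ["a", "b"], np.zeros((96, 2), dtype=int))
        with pytest.raises(ValueError, match="rank"):
            ps.discover_signatures(zero, rank=2, n_runs=1, seed=0)
        with pytest.raises(ValueError, match="no mutations"):
            ps.discover_signatures(zero, rank=1, n_runs=1, seed=0)

    def test_residual_competitive_with_sklearn_oracle(self, mixture_catalog):
        """Final residual within 1% of scikit-learn's NMF at equal rank."""
        from sklearn.decomposition import NMF

        catalog, _ = mixture_catalog
        V = catalog.counts.astype(float)
        ours = ps.discover_signatures(catalog, rank=3, n_runs=10, seed=2, max_iter=2000)
        best_sk = np.inf
        for rs in range(10):
            model = NMF(
                n_components=3, init="random", solver="mu", beta_loss="frobenius",
                max_iter=2000, tol=1e-6, random_state=rs,
            )
            Wsk = model.fit_transform(V)
            best_sk = min(best_sk, np.linalg.norm(V - Wsk @ model.components_))
        assert ours.residual <= 1.01 * best_sk


@pytest.fixture(scope="module")
def rank2_catalog():
    """Exact two-signature catalog with two well-separated sample groups."""
    rng = np.random.default_rng(31)
    sigs = ps.generate_signatures(2, 0.3, seed=41)
    H = np.zeros((2, 10))
    H[0, :5] = rng.uniform(300, 500, 5)
    H[1, 5:] = rng.uniform(300, 500, 5)
    H[0, 5:] = rng.uniform(10, 30, 5)
    H[1, :5] = rng.uniform(10, 30, 5)
    V = np.rint(sigs.W @ H).astype(int)
    return ps.MutationCatalog(ps.CHANNELS_96, [f"s{j}" for j in range(10)], V)


class TestRankSurvey:
    def test_planted_rank_detected_by_diagnostics(self, rank2_catalog):
        survey = ps.rank_survey(rank2_catalog, ranks=[2, 3, 4], n_runs=10, seed=7)
        assert list(survey["rank"]) == [2, 3, 4]
        r2 = survey.set_index("rank")
        norm = np.linalg.norm(rank2_catalog.counts)
        # the true rank already explains the catalog: adding components
        # buys almost nothing
        assert r2.loc[2, "residual"] - r2.loc[3, "residual"] <= 0.01 * norm
        assert r2.loc[2, "cophenetic"] >= r2.loc[3, "cophenetic"] - 1e-9

    def test_single_rank_gives_single_row(self, rank2_catalog):
        survey = ps.rank_survey(rank2_catalog, ranks=[2], n_runs=3, seed=0)
        assert len(survey) == 1

    def test_duplicated_samples_have_perfect_consensus_at_rank_one(self, three_sigs):
        V = np.tile(np.rint(three_sigs.W[:, 0] * 1000).astype(int)[:, None], (1, 6))
        catalog = ps.MutationCatalog(ps.CHANNELS_96, [f"d{j}" for j in range(6)], V)
        survey = ps.rank_survey(catalog, ranks=[1], n_runs=5, seed=3)
        assert survey.loc[0, "cophenetic"] == 1.0


class TestCosineAndMatching:
    def test_cosine_examples(self):
        v = np.array([1.0, 1.0, 0.0])
        assert ps.cosine_similarity(v, v) == pytest.approx(1.0)
        assert ps.cosine_similarity(np.array([1, 0, 0.0]), np.array([0, 1, 0.0])) == 0.0
        assert ps.cosine_similarity(
            np.array([1, 1, 0.0]), np.array([1, 0, 1.0])
        ) == pytest.approx(0.5)
        with pytest.raises(ValueError, match="zero vector"):
            ps.cosine_similarity(np.zeros(3), v)

    def test_match_exact_and_unmatched(self, three_sigs):
        discovered = ps.SignatureSet(
            three_sigs.channels, ["d1"], three_sigs.W[:, [1]]
        )
        res = ps.match_signatures(discovered, three_sigs)
        row = res.table.iloc[0]
        assert row["best_match"] == three_sigs.names[1]
        assert row["cosine"] == pytest.approx(1.0)
        assert bool(row["matched"])
        # orthogonal-ish discovered signature: below the 0.85 threshold
        lone = np.zeros(96)
        lone[np.argmin(three_sigs.W.sum(axis=1))] = 1.0
        res2 = ps.match_signatures(
            ps.SignatureSet(three_sigs.channels, ["x"], lone[:, None]), three_sigs
        )
        assert res2.table.iloc[0]["best_match"] == "UNK"
        assert not bool(res2.table.iloc[0]["matched"])

    def test_pair_mean_similarity_beats_members_for_blended_signature(self, three_sigs):
        blend = 0.5 * (three_sigs.W[:, 0] + three_sigs.W[:, 2])
        discovered = ps.SignatureSet(three_sigs.channels, ["mix"], blend[:, None])
        res = ps.match_signatures(
            discovered, three_sigs, pairs=[(three_sigs.names[0], three_sigs.names[2])]
        )
        pair_sim = res.pair_similarities.iloc[0, 0]
        member_sims = [
            ps.cosine_similarity(blend, three_sigs.W[:, 0]),
            ps.cosine_similarity(blend, three_sigs.W[:, 2]),
        ]
        assert pair_sim > max(member_sims)

    def test_channel_order_mismatch_rejected(self, three_sigs):
        shuffled = ps.SignatureSet(
            tuple(reversed(three_sigs.channels)), three_sigs.names, three_sigs.W
        )
        with pytest.raises(ValueError, match="channel orderings"):
            ps.match_signatures(three_sigs, shuffled)


class TestParameterRecovery:
    def test_median_recovery_over_replicates(self):
        """Across seeded two-signature cohorts the median recovered cosine
        and the median activity correlation stay high."""
        cosines, activity_r = [], []
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            sigs = ps.generate_signatures(2, 0.5, seed=700 + rep)
            H_true = rng.dirichlet([1.0, 1.0], size=20).T * 1000
            V = np.zeros((96, 20), dtype=np.int64)
            for s_ in range(20):
                for k in range(2):
                    V[:, s_] += rng.multinomial(int(round(H_true[k, s_])), sigs.W[:, k])
            catalog = ps.MutationCatalog(ps.CHANNELS_96, [f"s{j}" for j in range(20)], V)
            res = ps.discover_signatures(catalog, rank=2, n_runs=5, seed=rep)
            for k in range(2):
                sims = [
                    ps.cosine_similarity(res.signatures.W[:, i], sigs.W[:, k])
                    for i in range(2)
                ]
                i = int(np.argmax(sims))
                cosines.append(sims[i])
                activity_r.append(np.corrcoef(res.activities.H[i], H_true[k])[0, 1])
        assert np.median(cosines) >= 0.95
        assert np.median(activity_r) >= 0.9
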