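"""Cross-modal PLS: pseudo-replicates, NIPALS, LOO prediction, VIP."""

import numpy as np
import pandas as pd
import pytest

import ramanxome as rx
from ramanxome import crossmodal as xm
from ramanxome import spectral as sp
from ramanxome import synthetic as syn


def _planted_link(n_cells=30, n_features=400, n_informative=25, seed=0, rep_seed=3):
    """Noiseless rank-2 planted linkage: cell scores, LD model, pseudo-reps,
    continuous log-scale features, responses."""
    scores, labels = syn.planted_cell_scores(n_cells, n_cells, seed=seed)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ldm = sp.fit_lda(scores, labels)
    reps = xm.make_pseudoreplicates(scores, labels, n_groups=3, seed=rep_seed)
    mu, informative, B = syn.linked_log_means(n_features, n_informative,
                                              reps.group_means, seed=seed)
    features = mu.T  # samples x transcripts, noiseless log2 means
    return scores, labels, ldm, reps, features, informative, B


class TestPseudoReplicates:
    def test_six_cells_split_into_three_pairs_deterministically(self):
        scores = np.arange(24, dtype=float).reshape(12, 2)
        labels = np.array(["D0"] * 6 + ["D4"] * 6)
        a = xm.make_pseudoreplicates(scores, labels, seed=4)
        b = xm.make_pseudoreplicates(scores, labels, seed=4)
        assert a.assignment == b.assignment
        sizes = pd.Series(list(a.assignment.values())).value_counts()
        assert set(sizes) == {2}
        assert set(a.group_means.index) == {"D0-1", "D0-2", "D0-3", "D4-1", "D4-2", "D4-3"}

    def test_58_cells_split_20_19_19(self):
        scores = np.zeros((58 + 60, 3))
        labels = np.array(["D0"] * 58 + ["D4"] * 60)
        reps = xm.make_pseudoreplicates(scores, labels, seed=0)
        counts = pd.Series(list(reps.assignment.values())).value_counts()
        assert sorted(counts[g] for g in ("D0-1", "D0-2", "D0-3")) == [19, 19, 20]
        assert sorted(counts[g] for g in ("D4-1", "D4-2", "D4-3")) == [20, 20, 20]

    def test_group_mean_is_member_mean(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 1, (20, 4))
        labels = np.array(["D0"] * 10 + ["D4"] * 10)
        reps = xm.make_pseudoreplicates(scores, labels, seed=1, cell_ids=np.arange(20))
        for gid in reps.sample_ids:
            members = [c for c, g in reps.assignment.items() if g == gid]
            np.testing.assert_allclose(
                reps.group_means.loc[gid].to_numpy(), scores[members].mean(0), rtol=1e-12
            )

    def test_identical_cells_give_identical_means(self):
        scores = np.ones((12, 2))
        labels = np.array(["D0"] * 6 + ["D4"] * 6)
        reps = xm.make_pseudoreplicates(scores, labels, seed=2)
        assert (reps.group_means.to_numpy() == 1.0).all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            xm.make_pseudoreplicates(np.zeros((4, 2)),
                                     np.array(["D0", "D0", "D4", "D4"]), n_groups=3)


class TestPreprocessCounts:
    def _cm(self, data, samples):
        df = pd.DataFrame(data, columns=samples)
        df.index = [f"T{i}" for i in range(len(df))]
        conds = {s: s.rsplit("-", 1)[0] for s in samples}
        return rx.io.CountMatrix(counts=df, conditions=conds)

    def test_counts_one_and_three_center_to_half(self):
        cm = self._cm([[1, 3]], ["D0-1", "D0-2"])
        feats, _ = xm.preprocess_counts(cm, ["D0-1", "D0-2"])
        np.testing.assert_allclose(feats.to_numpy().ravel(), [-0.5, 0.5])

    def test_zero_count_feature_is_minus_mean(self):
        cm = self._cm([[0, 15]], ["D0-1", "D0-2"])
        feats, _ = xm.preprocess_counts(cm, ["D0-1", "D0-2"])
        assert feats.iloc[0, 0] == pytest.approx(-np.log2(16) / 2)

    def test_held_out_sample_centered_with_training_means(self):
        cm = self._cm([[1, 3, 63, 63]], ["D0-1", "D0-2", "D4-1", "D4-2"])
        _, transform = xm.preprocess_counts(cm, ["D0-1", "D0-2"])
        held = transform.apply(cm.counts, ["D4-1"])
        assert held.iloc[0, 0] == pytest.approx(np.log2(64) - 1.5)  # not centered on itself


class TestFitPLS:
    def test_rank_one_noiseless_link_recovered_with_one_component(self):
        """Exact-recovery limit: a rank-1 design with a rank-1 planted map is
        fit exactly by a single PLS component."""
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, 8)
        v = rng.normal(0, 1, 40)
        X = np.outer(s, v)
        B = rng.normal(0, 1, (40, 2))
        Y = X @ B
        pls = xm.fit_pls(X, Y, A=1)
        np.testing.assert_allclose(pls.predict(X), Y, atol=1e-8)

    def test_zero_components_predict_training_mean(self):
        rng = np.random.default_rng(1)
        X, Y = rng.normal(0, 1, (6, 10)), rng.normal(0, 1, (6, 3))
        pls = xm.fit_pls(X, Y, A=0)
        np.testing.assert_allclose(pls.predict(X), np.tile(Y.mean(0), (6, 1)), rtol=1e-12)

    def test_univariate_case_matches_least_squares_slope(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (12, 1))
        y = 3.0 * x[:, 0] + rng.normal(0, 0.1, 12)
        pls = xm.fit_pls(x, y[:, None], A=1)
        xc, yc = x[:, 0] - x.mean(), y - y.mean()
        slope = (xc @ yc) / (xc @ xc)
        assert pls.B[0, 0] == pytest.approx(slope, rel=1e-10)

    def test_full_rank_pls_reproduces_least_squares(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (10, 4))
        Y = rng.normal(0, 1, (10, 2))
        pls = xm.fit_pls(X, Y, A=4)
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        B_ls, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        np.testing.assert_allclose(pls.predict(X), Xc @ B_ls + Y.mean(0), atol=1e-8)

    def test_x_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(4)
        pls = xm.fit_pls(rng.normal(0, 1, (12, 30)), rng.normal(0, 1, (12, 3)), A=4)
        G = pls.T_scores.T @ pls.T_scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.diag(G).max()

    def test_matches_sklearn_pls_predictions(self):
        """Independent cross-check against sklearn's NIPALS PLSRegression."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (15, 25))
        Y = rng.normal(0, 1, (15, 4)) + (X[:, :4] * 0.5)
        ours = xm.fit_pls(X, Y, A=3)
        # sklearn stops its power iteration on an internal criterion, so the
        # two solvers agree only to ~1e-4 on predictions ...
        ref = PLSRegression(n_components=3, scale=False, tol=1e-12, max_iter=10000).fit(X, Y)
        np.testing.assert_allclose(ours.predict(X), ref.predict(X), atol=1e-4)
        # ... while the exact oracle for the first weight vector is the
        # dominant eigenvector of Xc' Yc Yc' Xc
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Yc @ Yc.T @ Xc)
        w_true = evecs[:, -1]
        w_ours = ours.W[:, 0] if ours.W[:, 0] @ w_true > 0 else -ours.W[:, 0]
        np.testing.assert_allclose(w_ours, w_true, atol=1e-8)

    def test_zero_variance_response_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="zero variance"):
            xm.fit_pls(rng.normal(0, 1, (6, 10)), np.ones((6, 2)), A=1)


class TestLOOPredict:
    def test_noiseless_planted_link_predicts_exactly(self):
        """Rank-2 link with A >= rank: exact LOO predictions and all six
        group calls correct."""
        _, _, ldm, reps, features, _, _ = _planted_link()
        preds = xm.loo_predict_features(features, reps.group_means, A=2, ld_model=ldm)
        assert len(preds) == 6
        for p in preds:
            assert p.residual < 1e-6
            assert p.group_call == p.condition

    def test_duplicated_training_sample_predicted_exactly(self):
        _, _, ldm, reps, features, _, _ = _planted_link(rep_seed=8)
        dup_feats = features.copy()
        dup_feats.iloc[0] = features.iloc[1]
        responses = reps.group_means.copy()
        responses.iloc[0] = responses.iloc[1]
        preds = xm.loo_predict_features(dup_feats, responses, A=2)
        assert preds[0].residual < 1e-6

    def test_permuted_link_falls_to_chance(self):
        """Breaking the sample pairing drops group calls to chance level."""
        _, _, ldm, reps, features, _, _ = _planted_link()
        rng = np.random.default_rng(77)
        at_chance = 0
        for _ in range(20):
            perm = rng.permutation(6)
            shuffled = features.copy()
            shuffled.iloc[:] = features.to_numpy()[perm]
            preds = xm.loo_predict_features(shuffled, reps.group_means, A=2, ld_model=ldm)
            correct = sum(p.group_call == p.condition for p in preds)
            if correct <= 4:
                at_chance += 1
        assert at_chance >= 10

    def test_counts_route_calls_match_conditions(self, nucleus_analysis, linked_counts):
        preds = xm.loo_predict(
            linked_counts["counts"], nucleus_analysis["reps"].group_means,
            A=2, ld_model=nucleus_analysis["ldm"],
        )
        correct = sum(p.group_call == p.condition for p in preds)
        assert correct >= 5

    def test_fold_losing_a_condition_rejected(self):
        rng = np.random.default_rng(9)
        features = pd.DataFrame(rng.normal(0, 1, (3, 5)), index=["D0-1", "D0-2", "D4-1"])
        responses = pd.DataFrame(rng.normal(0, 1, (3, 2)), index=features.index)
        with pytest.raises(ValueError, match="lost a condition"):
            xm.loo_predict_features(features, responses, A=1)


class TestVIP:
    def test_symmetric_two_feature_model_gives_equal_vip(self):
        t = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        X = np.column_stack([t, t])
        Y = t[:, None]
        pls = xm.fit_pls(X, Y, A=1)
        vip = xm.vip_scores(pls)
        np.testing.assert_allclose(vip.to_numpy(), [1.0, 1.0], rtol=1e-10)

    def test_mean_square_vip_is_one_for_any_model(self):
        rng = np.random.default_rng(10)
        for a in (1, 2, 3):
            X = rng.normal(0, 1, (10, 50))
            Y = rng.normal(0, 1, (10, 4))
            vip = xm.vip_scores(xm.fit_pls(X, Y, A=a))
            assert float((vip**2).mean()) == pytest.approx(1.0, abs=1e-6)

    def test_vip_of_zero_component_model_rejected(self):
        rng = np.random.default_rng(11)
        pls = xm.fit_pls(rng.normal(0, 1, (6, 10)), rng.normal(0, 1, (6, 2)), A=0)
        with pytest.raises(ValueError, match="component"):
            xm.vip_scores(pls)

    def test_planted_informative_recovery_over_seeds(self):
        """>= 80% of the top-30 VIP transcripts are planted (10-seed median)."""
        recoveries = []
        for s in range(10):
            scores, labels = syn.planted_cell_scores(30, 30, seed=300 + s)
            reps = xm.make_pseudoreplicates(scores, labels, n_groups=3, seed=s)
            cm, truth = syn.simulate_transcriptome(2000, 30, reps.group_means,
                                                   dispersion=0.05, seed=600 + s)
            feats, _ = xm.preprocess_counts(cm, list(reps.group_means.index))
            pls = xm.fit_pls(feats, reps.group_means, A=2)
            vip = xm.vip_scores(pls)
            recoveries.append(xm.vip_recovery(vip, truth.informative_ids, n=30))
        assert np.median(recoveries) >= 0.8

    def test_informative_vs_noise_vip_auc(self, nucleus_analysis, linked_counts):
        """Informative transcripts rank above noise (AUC >= 0.95)."""
        reps = nucleus_analysis["reps"]
        feats, _ = xm.preprocess_counts(linked_counts["counts"], list(reps.group_means.index))
        vip = xm.vip_scores(xm.fit_pls(feats, reps.group_means, A=2))
        informative = set(linked_counts["truth"].informative_ids)
        is_inf = np.array([t in informative for t in vip.index])
        ranks = pd.Series(vip.to_numpy()).rank().to_numpy()
        n1, n0 = is_inf.sum(), (~is_inf).sum()
        auc = (ranks[is_inf].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        assert auc >= 0.95

    def test_recovery_of_perfect_and_random_rankings(self):
        informative = [f"T{i}" for i in range(30)]
        perfect = pd.Series(np.linspace(2, 1, 30), index=informative)
        assert xm.vip_recovery(perfect, informative, n=30) == 1.0
        # hypergeometric expectation for a random ranking: K/M
        from scipy.stats import hypergeom

        expected = hypergeom(2000, 30, 30).mean() / 30
        assert expected == pytest.approx(0.015, abs=1e-9)
        rng = np.random.default_rng(12)
        ids = [f"T{i}" for i in range(2000)]
        rec = [
            xm.vip_recovery(pd.Series(1.0, index=rng.permutation(ids)), informative[:30], 30)
            for _ in range(50)
        ]
        assert np.mean(rec) < 0.1


class TestCompartmentRobustness:
    def test_nucleus_and_whole_cell_vip_lists_nearly_identical(
        self, default_cohort, nucleus_analysis, linked_counts
    ):
        """Top-20 VIP lists from nucleus- and whole-cell-based models share
        >= 17/20 transcripts (the compartments see the same activation
        signal through correlated spectra)."""
        seg = default_cohort["segmentation"]
        cm = linked_counts["counts"]
        vips = {}
        for comp in ("nucleus", "whole_cell", "cytoplasm"):
            X, labels, _ = seg.spectra_matrix(comp)
            pcm = sp.fit_pca(X, n_keep=9)
            res = xm.crossmodal_analysis(pcm.kept_scores, labels, cm, A=2, seed=7)
            vips[comp] = set(res.vip.index[:20])
        assert len(vips["nucleus"] & vips["whole_cell"]) >= 17
        assert len(vips["nucleus"] & vips["cytoplasm"]) >= 17
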