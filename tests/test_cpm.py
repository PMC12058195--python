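"""Feature selection, SVR prediction, cross-validation and accuracy summaries."""

import numpy as np
import pytest

import arousalcpm as ac
from arousalcpm.cpm import NoFeaturesError


@pytest.fixture(scope="module")
def planted_edge_ids(coupled, coupled_fc):
    return {coupled_fc.edges.lookup(i, j) for i, j in coupled.truth.planted_edges}


@pytest.fixture(scope="module")
def loso(coupled_fc, coupled_target):
    return ac.run_loso(coupled_fc, coupled_target, alpha=0.01, train_stride=2)


class TestSelectFeatures:
    def test_planted_edges_selected_positive(self, coupled_fc, coupled_target,
                                             planted_edge_ids):
        mask = ac.select_features(coupled_fc.z, coupled_target, alpha=0.01)
        selected = set(mask.edges.tolist())
        assert planted_edge_ids <= selected
        for e in planted_edge_ids:
            assert mask.signs[np.searchsorted(mask.edges, e)] == 1

    def test_anticorrelated_edge_selected_negative(self, coupled_target):
        rng = np.random.default_rng(0)
        n_sub, T = 6, len(coupled_target)
        z = rng.standard_normal((n_sub, 4, T))
        z[:, 2, :] = -coupled_target + 0.1 * rng.standard_normal((n_sub, T))
        mask = ac.select_features(z, coupled_target, alpha=0.01)
        assert 2 in mask.edges
        assert mask.signs[np.searchsorted(mask.edges, 2)] == -1

    def test_single_subject_rejected(self, coupled_target):
        z = np.random.default_rng(1).standard_normal((1, 5, len(coupled_target)))
        with pytest.raises(ValueError):
            ac.select_features(z, coupled_target)


class TestFitPredict:
    def test_constant_target_constant_prediction(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((3, 6, 80))
        mask = ac.FeatureMask(edges=np.arange(3), signs=np.ones(3, dtype=int), alpha=0.01)
        pred = ac.fit_predict(z, np.full(80, 1.7), mask, z[0])
        np.testing.assert_allclose(pred, 1.7, atol=1e-3)

    def test_training_subject_refit_consistency(self, coupled_fc, coupled_target):
        """A held-in subject is predicted at least as well as a held-out one."""
        z = coupled_fc.z
        mask = ac.select_features(z[:-1], coupled_target, alpha=0.01)
        fit = ac.fit_cpm(z[:-1], coupled_target, mask, train_stride=2)
        r_in, _ = ac.score_prediction(ac.predict_cpm(fit, z[0]), coupled_target)
        r_out, _ = ac.score_prediction(ac.predict_cpm(fit, z[-1]), coupled_target)
        assert r_in > 0.3
        assert r_in >= r_out - 0.15

    def test_empty_mask_rejected(self, coupled_fc, coupled_target):
        empty = ac.FeatureMask(edges=np.array([], dtype=int),
                               signs=np.array([], dtype=int), alpha=0.01)
        with pytest.raises(NoFeaturesError):
            ac.fit_cpm(coupled_fc.z, coupled_target, empty)


class TestScorePrediction:
    def test_identity_and_antiphase(self):
        tgt = ac.zscore(np.sin(np.arange(200) / 9))
        r, rmse = ac.score_prediction(tgt, tgt)
        assert r == pytest.approx(1.0)
        assert rmse == pytest.approx(0.0, abs=1e-12)
        r, rmse = ac.score_prediction(-tgt, tgt)
        assert r == pytest.approx(-1.0)
        assert rmse == pytest.approx(2.0, rel=0.01)

    def test_unit_noise_rmse_closed_forms(self):
        rng = np.random.default_rng(3)
        tgt = ac.zscore(rng.standard_normal(5000))
        pred = tgt + rng.standard_normal(5000)
        # raw scale: E[(pred - tgt)^2] = 1
        _, rmse_raw = ac.score_prediction(pred, tgt, standardize=False)
        assert rmse_raw == pytest.approx(1.0, abs=0.05)
        # standardized prediction has sd 1, correlation 1/sqrt(2) with the
        # target, so E[(z_pred - tgt)^2] = 2 - 2/sqrt(2) = 2 - sqrt(2)
        _, rmse_std = ac.score_prediction(pred, tgt)
        assert rmse_std == pytest.approx(np.sqrt(2 - np.sqrt(2)), abs=0.05)

    def test_constant_prediction_flagged_zero(self):
        tgt = ac.zscore(np.arange(10.0))
        with pytest.warns(UserWarning, match="constant"):
            r, rmse = ac.score_prediction(np.full(10, 2.0), tgt)
        assert r == 0.0
        assert rmse == pytest.approx(np.sqrt(np.mean(tgt**2)))


class TestRunLoso:
    def test_recovers_planted_signal(self, loso, planted_edge_ids):
        assert loso.summary.mean_r > 0.3
        consensus = set(loso.consensus.edges.tolist())
        assert len(consensus & planted_edge_ids) >= 0.5 * len(planted_edge_ids)

    def test_consensus_subset_of_every_fold(self, loso):
        consensus = set(loso.consensus.edges.tolist())
        for mask in loso.fold_masks:
            assert consensus <= set(mask.edges.tolist())

    def test_no_leakage_from_held_out_subject(self, coupled_fc, coupled_target):
        """Corrupting a held-out subject's data must not change its fold's mask."""
        z = coupled_fc.z[:5].copy()
        res_a = ac.run_loso(z, coupled_target, train_stride=4)
        z2 = z.copy()
        z2[0] = np.random.default_rng(9).standard_normal(z2[0].shape)
        res_b = ac.run_loso(z2, coupled_target, train_stride=4)
        np.testing.assert_array_equal(res_a.fold_masks[0].edges, res_b.fold_masks[0].edges)
        np.testing.assert_array_equal(res_a.fold_masks[0].signs, res_b.fold_masks[0].signs)

    def test_fisher_summary_symmetric_lists_vanish(self):
        from arousalcpm.behavior import fisher_mean

        assert fisher_mean(np.array([0.4, -0.4, 0.2, -0.2])) == pytest.approx(0.0)

    def test_too_few_subjects(self, coupled_fc, coupled_target):
        with pytest.raises(ValueError):
            ac.run_loso(coupled_fc.z[:2], coupled_target)


class TestCrossDataset:
    def test_half_split_generalizes(self, coupled_fc, coupled_target, loso):
        z = coupled_fc.z
        summ, folds = ac.run_cross_dataset(z[:4], coupled_target, loso.consensus,
                                           z[4:], coupled_target, train_stride=2)
        assert summ.mean_r > 0.2
        assert summ.n_folds == 4

    def test_empty_features_rejected(self, coupled_fc, coupled_target):
        empty = ac.FeatureMask(edges=np.array([], dtype=int),
                               signs=np.array([], dtype=int), alpha=0.01)
        with pytest.raises(NoFeaturesError):
            ac.run_cross_dataset(coupled_fc.z[:4], coupled_target, empty,
                                 coupled_fc.z[4:], coupled_target)

    def test_edge_hash_mismatch_rejected(self, coupled, coupled_target, spec400, loso):
        fc_a = ac.compute_dynfc_set(coupled.bold[:3], spec400)
        fc_b = ac.compute_dynfc_set(coupled.bold[3:, :-1], spec400)  # fewer ROIs
        mask = ac.FeatureMask(edges=np.array([0, 1]), signs=np.array([1, 1]), alpha=0.01)
        with pytest.raises(ValueError, match="hash"):
            ac.run_cross_dataset(fc_a, coupled_target, mask, fc_b, coupled_target)


class TestGroupAveragePrediction:
    def test_identical_predictions(self, coupled_target):
        preds = np.tile(coupled_target, (3, 1))
        assert ac.group_average_prediction(preds, coupled_target) == pytest.approx(1.0)

    def test_averaging_beats_individuals(self, coupled_target):
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            preds = coupled_target + rng.standard_normal((6, len(coupled_target)))
            group_r = ac.group_average_prediction(preds, coupled_target)
            indiv = np.median([np.corrcoef(p, coupled_target)[0, 1] for p in preds])
            wins += group_r >= indiv
        assert wins >= 18

    def test_cancelling_predictions_flagged(self, coupled_target):
        preds = np.vstack([coupled_target, -coupled_target])
        with pytest.warns(UserWarning, match="constant"):
            assert ac.group_average_prediction(preds, coupled_target) == 0.0


class TestPairedComparison:
    def test_identical_lists(self):
        t, p, df = ac.paired_fold_comparison([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert (t, p, df) == (0.0, 1.0, 2)

    def test_hand_computed_example(self):
        a, b = [0.5, 0.6, 0.7], [0.4, 0.5, 0.6]
        d = np.arctanh(a) - np.arctanh(b)
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        t, p, df = ac.paired_fold_comparison(a, b)
        assert t == pytest.approx(t_oracle)
        assert t == pytest.approx(10.5, abs=0.5)
        assert df == 2

    def test_symmetric_reversal_gives_zero(self):
        a = [0.2, 0.4, 0.6]
        t, p, df = ac.paired_fold_comparison(a, a[::-1])
        assert t == pytest.approx(0.0, abs=1e-12)
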