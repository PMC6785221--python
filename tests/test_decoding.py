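"""Decoder identities, PLS behaviour, PC regression, the hemisphere
shuffle test, perturbation controls, and wrong-arm generalization."""

import numpy as np
import pandas as pd
import pytest

from hemicycle import (RateTensor, cross_hemisphere_muscle_decode,
                       fit_muscle_decoder, hemisphere_shuffle_test,
                       pc_regression_predict, population_r2,
                       signal_perturbation_controls,
                       wrong_arm_generalization)
from hemicycle.conditions import ALL_CONDITIONS
from hemicycle.decoding import _pls_weights


class TestPopulationR2:
    def test_perfect_prediction(self, rng):
        Y = rng.standard_normal((30, 4))
        assert population_r2(Y, Y) == 1.0

    def test_zero_prediction_scores_zero(self, rng):
        Y = rng.standard_normal((30, 4))
        assert population_r2(Y, np.zeros_like(Y)) == pytest.approx(0.0)

    def test_hand_computed_small_instance(self):
        Y = np.array([[1.0, 0.0], [0.0, 2.0], [-1.0, 1.0], [2.0, -1.0]])
        Yp = np.array([[0.5, 0.0], [0.0, 1.5], [-0.5, 1.0], [1.5, -1.0]])
        # ||Y-Yp||_F^2 = 0.25*3 + 0.25 = 1.0 ; ||Y||_F^2 = 12
        assert population_r2(Y, Yp) == pytest.approx(1.0 - 1.0 / 12.0)

    def test_all_zero_target_rejected(self):
        with pytest.raises(ValueError):
            population_r2(np.zeros((5, 2)), np.ones((5, 2)))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            population_r2(rng.standard_normal((5, 2)),
                          rng.standard_normal((5, 3)))


class TestPLS:
    def test_full_rank_matches_ols(self, rng):
        """On a well-conditioned problem, full-rank PLS equals ordinary
        least squares to high precision."""
        X = rng.standard_normal((200, 8))
        B_true = rng.standard_normal((8, 3))
        Y = X @ B_true + 0.01 * rng.standard_normal((200, 3))
        X, Y = X - X.mean(0), Y - Y.mean(0)  # decoder contract: centered
        B_pls = _pls_weights(X, Y, rank=8)
        B_ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
        pred_pls, pred_ols = X @ B_pls, X @ B_ols
        rel = np.linalg.norm(pred_pls - pred_ols) / np.linalg.norm(pred_ols)
        assert rel < 1e-6

    def test_noiseless_low_rank_recovered(self, rng):
        """Y an exact rank-2 linear readout of X: near-perfect held-out
        prediction at low rank."""
        latent = rng.standard_normal((120, 2))
        X = latent @ rng.standard_normal((2, 20))
        Y = latent @ rng.standard_normal((2, 4))
        model = fit_muscle_decoder(X[:60], Y[:60], X[60:90], Y[60:90],
                                   rank_candidates=range(1, 8))
        r2 = population_r2(Y[90:], model.predict(X[90:]))
        assert r2 > 0.999
        assert model.rank <= 3

    def test_shuffled_target_not_predictable(self, rng):
        X = rng.standard_normal((120, 20))
        Y = rng.standard_normal((120, 4))
        model = fit_muscle_decoder(X[:60], Y[:60], X[60:90], Y[60:90])
        r2 = population_r2(Y[90:], model.predict(X[90:]))
        assert r2 < 0.1

    def test_validation_curve_and_trimming(self, rng):
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal((40, 2))
        with pytest.warns(UserWarning, match="trimmed"):
            model = fit_muscle_decoder(X, Y, X, Y,
                                       rank_candidates=range(1, 30))
        assert list(model.validation_curve["rank"]) == list(range(1, 6))
        assert model.provenance["method"].startswith("PLS2")


class TestPCRegression:
    def test_self_prediction_full_rank(self, rng):
        X = rng.standard_normal((80, 6))
        res = pc_regression_predict(X, X, X, X, ranks=[6], mode="cross")
        assert res["r2"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_shared_latents_close_cross_and_self(self, rng):
        """Two populations driven by the same latents: cross-prediction at
        rank 10 nearly matches leave-one-out self-prediction."""
        z_tr = rng.standard_normal((200, 10))
        z_te = rng.standard_normal((200, 10))
        A = rng.standard_normal((10, 40))
        B = rng.standard_normal((10, 30))
        res_cross = pc_regression_predict(z_tr @ A, z_tr @ B,
                                          z_te @ A, z_te @ B,
                                          ranks=[10], mode="cross")
        res_self = pc_regression_predict(z_tr @ B, z_tr @ B,
                                         z_te @ B, z_te @ B,
                                         ranks=[10],
                                         mode="leave_one_out_self")
        assert abs(res_cross["r2"].iloc[0] - res_self["r2"].iloc[0]) < 0.05

    def test_private_latent_creates_matching_deficit(self, rng):
        """A latent private to the target carrying ~30% of its variance
        caps cross-prediction R^2 ~0.3 below self-prediction."""
        z_shared_tr = rng.standard_normal((300, 6))
        z_shared_te = rng.standard_normal((300, 6))
        z_priv_tr = rng.standard_normal((300, 2))
        z_priv_te = rng.standard_normal((300, 2))
        A = rng.standard_normal((6, 40))
        B_shared = rng.standard_normal((6, 30))
        B_priv = rng.standard_normal((2, 30))
        # scale the private part to ~30% of target variance
        scale = np.sqrt(0.3 / 0.7) * np.linalg.norm(B_shared) / np.linalg.norm(B_priv) * np.sqrt(2 / 6)
        target_tr = z_shared_tr @ B_shared + scale * np.sqrt(3) * (z_priv_tr @ B_priv)
        target_te = z_shared_te @ B_shared + scale * np.sqrt(3) * (z_priv_te @ B_priv)
        priv_share = (np.var(scale * np.sqrt(3) * (z_priv_te @ B_priv))
                      / np.var(target_te))
        res_cross = pc_regression_predict(z_shared_tr @ A, target_tr,
                                          z_shared_te @ A, target_te,
                                          ranks=[6], mode="cross")
        deficit = 1.0 - res_cross["r2"].iloc[0]
        assert deficit == pytest.approx(priv_share, abs=0.06)

    def test_excessive_rank_rejected(self, rng):
        X = rng.standard_normal((20, 4))
        with pytest.raises(ValueError, match="rank"):
            pc_regression_predict(X, X, X, X, ranks=[5], mode="cross")


class TestHemisphereShuffle:
    def test_null_size_contract(self, neural):
        res = hemisphere_shuffle_test(neural, rank=8, n_resamples=7, seed=0)
        assert res["null"].shape == (7,)

    def test_mixed_generator_not_significant(self, neural):
        """The generator mixes both arms' signals into both hemispheres,
        so hemisphere labels carry no private signal."""
        res = hemisphere_shuffle_test(neural, rank=8, n_resamples=20, seed=1)
        assert not res["significant"]

    def test_private_hemisphere_signal_detected(self, rng):
        """Give the left hemisphere a private high-variance latent: the
        self-vs-cross gap becomes significant."""
        T, n = 300, 30
        t = np.arange(T) * 10.0
        conditions = [c.label for c in ALL_CONDITIONS]
        values = np.zeros((T, 2 * n, 8))
        for k in range(8):
            z = np.column_stack([np.sin(2 * np.pi * t / 500 + p)
                                 for p in rng.uniform(0, 2 * np.pi, 4)])
            shared = z @ rng.standard_normal((4, 2 * n))
            private = np.column_stack(
                [np.sin(2 * np.pi * t / 250 + p)
                 for p in rng.uniform(0, 2 * np.pi, 3)])
            priv = private @ rng.standard_normal((3, n))
            values[:, :, k] = shared + 10.0
            values[:, :n, k] += 3.0 * priv
        channels = pd.DataFrame({
            "channel_id": [f"u{i}" for i in range(2 * n)],
            "kind": "unit",
            "hemisphere": ["left"] * n + ["right"] * n})
        tensor = RateTensor(values=values, sem=np.zeros_like(values),
                            time_ms=t, channels=channels,
                            conditions=conditions)
        res = hemisphere_shuffle_test(tensor, rank=4, n_resamples=20, seed=2)
        assert res["significant"]


class TestPerturbationControls:
    def test_full_reconstruction_exact(self, rng):
        X = rng.standard_normal((60, 9))
        ctl = signal_perturbation_controls(X)
        np.testing.assert_allclose(ctl.reconstructed, X, atol=1e-10)

    def test_pc1_removal_drops_exactly_its_share(self, rng):
        X = rng.standard_normal((60, 9)) @ np.diag(np.linspace(3, 0.5, 9))
        ctl = signal_perturbation_controls(X)
        Xc = X - X.mean(0)
        from hemicycle import fit_condition_subspace
        space = fit_condition_subspace(X)
        removed = ctl.remove_pc1 - ctl.remove_pc1.mean(0)
        drop = np.sum(Xc**2) - np.sum(removed**2)
        assert drop == pytest.approx(space.eigenvalues[0], rel=1e-9)

    def test_rescale_needs_four_pcs(self, rng):
        with pytest.raises(ValueError, match="4 PCs"):
            signal_perturbation_controls(rng.standard_normal((10, 3)))

    def test_removing_dominant_signal_hurts_cross_prediction(self, rng):
        """Mirrors the signal-removal control: hiding PC1 of the source
        lowers cross-prediction of a shared-latent target."""
        z = rng.standard_normal((200, 5)) @ np.diag([4, 2, 1, 0.7, 0.5])
        z_te = rng.standard_normal((200, 5)) @ np.diag([4, 2, 1, 0.7, 0.5])
        A, B = rng.standard_normal((5, 30)), rng.standard_normal((5, 25))
        src_tr, src_te = z @ A, z_te @ A
        tgt_tr, tgt_te = z @ B, z_te @ B
        base = pc_regression_predict(src_tr, tgt_tr, src_te, tgt_te,
                                     ranks=[5], mode="cross")["r2"].iloc[0]
        ctl_tr = signal_perturbation_controls(src_tr).remove_pc1
        ctl_te = signal_perturbation_controls(src_te).remove_pc1
        hurt = pc_regression_predict(ctl_tr, tgt_tr, ctl_te, tgt_te,
                                     ranks=[5], mode="cross")["r2"].iloc[0]
        assert hurt < base - 0.1


class TestCrossHemisphereDecode:
    def test_output_shape_and_quality(self, neural, emg):
        table = cross_hemisphere_muscle_decode(neural, emg)
        assert len(table) == 16  # 8 conditions x 2 sources
        assert set(table["source"]) == {"driving", "non_driving"}
        med = table.groupby("source")["r2"].median()
        # both hemispheres carry the muscle-potent latents
        assert med["driving"] > 0.6
        assert med["non_driving"] > 0.6
        assert abs(med["driving"] - med["non_driving"]) < 0.15

    def test_empty_hemisphere_rejected(self, neural, emg):
        mask = (neural.channels["hemisphere"] == "left").to_numpy()
        with pytest.raises(ValueError, match="hemisphere"):
            cross_hemisphere_muscle_decode(neural.select_channels(mask), emg)


class TestWrongArm:
    def test_bookkeeping_and_api_shift(self, neural, emg):
        res = wrong_arm_generalization(neural, emg, "train_performing")
        n_muscles = emg.values.shape[1] // 2
        assert len(res.modulation) == 2 * 2 * n_muscles  # arm x direction
        assert set(res.weight_magnitudes) == {"left", "right"}
        # decoded output is more lateralized than the units it reads from
        assert res.arm_preference["decoded_api"].median() > 0.3

    def test_unknown_strategy_rejected(self, neural, emg):
        with pytest.raises(ValueError, match="strategy"):
            wrong_arm_generalization(neural, emg, "train_everything")

    def test_missing_condition_rejected(self, neural, emg):
        partial = RateTensor(values=neural.values[:, :, :6],
                             sem=neural.sem[:, :, :6],
                             time_ms=neural.time_ms,
                             channels=neural.channels,
                             conditions=neural.conditions[:6])
        with pytest.raises(ValueError):
            wrong_arm_generalization(partial, emg, "train_performing")

    def test_balanced_mixing_gives_balanced_weights(self, neural, emg):
        """lateralization is mild in the fixture: decoder weight
        magnitudes are comparable across hemispheres."""
        res = wrong_arm_generalization(neural, emg, "train_performing")
        med_l = np.median(res.weight_magnitudes["left"])
        med_r = np.median(res.weight_magnitudes["right"])
        assert 0.5 < med_l / med_r < 2.0
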