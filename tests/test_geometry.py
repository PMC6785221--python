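"""Normalization, subspace fitting, variance capture, contribution
weights, and trajectory tangling (including the brute-force oracle)."""

import numpy as np
import pandas as pd
import pytest

from hemicycle import (GeneratorConfig, RateTensor, TanglingParams,
                       compute_rate_tensors, contribution_weight_distributions,
                       fit_condition_subspace, generate_session,
                       neuron_count_sweep, soft_normalize, subspace_contribution_weights,
                       tangling, tangling_comparison, triplet_sweep,
                       variance_capture_curve)
from hemicycle.conditions import ALL_CONDITIONS
from hemicycle.geometry import _derivatives


def _tensor_from_values(values, hemispheres=None):
    T, n, C = values.shape
    channels = pd.DataFrame({
        "channel_id": [f"u{i}" for i in range(n)],
        "kind": "unit",
        "hemisphere": hemispheres or ["left"] * (n // 2) + ["right"] * (n - n // 2),
    })
    return RateTensor(values=values, sem=np.zeros_like(values),
                      time_ms=np.arange(T) * 10.0, channels=channels,
                      conditions=[c.label for c in ALL_CONDITIONS[:C]])


class TestSoftNormalize:
    def test_formula_case(self):
        values = np.zeros((4, 1, 1))
        values[:, 0, 0] = [0.0, 30.0, 60.0, 95.0]
        tensor = _tensor_from_values(values, hemispheres=["left"])
        out = soft_normalize(tensor, c=5.0)
        assert out.values[3, 0, 0] == pytest.approx(0.95)

    def test_zero_range_unit_maps_to_zero(self):
        values = np.full((4, 1, 1), 12.0)
        out = soft_normalize(_tensor_from_values(values, ["left"]), c=0.0)
        assert np.all(out.values == 0.0)

    def test_compresses_dynamic_range_across_units(self):
        """A 100-range unit carries 25x the variance of a 20-range unit
        before normalization; soft-norm pulls the ratio toward parity."""
        T = 100
        t = np.linspace(0, 2 * np.pi, T)
        values = np.zeros((T, 2, 1))
        values[:, 0, 0] = 50 * np.sin(t) + 50
        values[:, 1, 0] = 10 * np.sin(t) + 10
        tensor = _tensor_from_values(values, ["left", "right"])
        out = soft_normalize(tensor, c=5.0)
        var_ratio_raw = values[:, 0, 0].var() / values[:, 1, 0].var()
        var_ratio_norm = out.values[:, 0, 0].var() / out.values[:, 1, 0].var()
        assert var_ratio_raw == pytest.approx(25.0)
        assert 1.0 < var_ratio_norm < 2.0

    def test_negative_offset_rejected(self, neural):
        with pytest.raises(ValueError):
            soft_normalize(neural, c=-1.0)


class TestFitConditionSubspace:
    def test_planar_data_fully_captured_by_two_pcs(self, rng):
        plane = rng.standard_normal((2, 10))
        X = rng.standard_normal((50, 2)) @ plane
        space = fit_condition_subspace(X)
        frac = space.eigenvalues[:2].sum() / space.eigenvalues.sum()
        assert frac == pytest.approx(1.0, abs=1e-12)

    def test_basis_orthonormal(self, rng):
        space = fit_condition_subspace(rng.standard_normal((40, 12)))
        gram = space.basis.T @ space.basis
        np.testing.assert_allclose(gram, np.eye(space.rank), atol=1e-10)

    def test_training_data_capture_reaches_one(self, rng):
        X = rng.standard_normal((30, 8))
        space = fit_condition_subspace(X)
        curve = variance_capture_curve(space, X)
        assert curve[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(curve) >= -1e-15)

    def test_isotropic_noise_has_flat_spectrum(self, rng):
        X = rng.standard_normal((5000, 10))
        space = fit_condition_subspace(X)
        ev = space.eigenvalues / space.eigenvalues.mean()
        assert ev.max() < 1.25 and ev.min() > 0.8

    def test_excessive_rank_rejected(self, rng):
        with pytest.raises(ValueError, match="rank"):
            fit_condition_subspace(rng.standard_normal((10, 4)), rank=5)


class TestVarianceCapture:
    def test_unit_mismatch_rejected(self, rng):
        space = fit_condition_subspace(rng.standard_normal((20, 6)))
        with pytest.raises(ValueError, match="unit"):
            variance_capture_curve(space, rng.standard_normal((20, 7)))

    def test_training_condition_dominates_pointwise(self, rng):
        shared = rng.standard_normal((3, 10))
        train = rng.standard_normal((40, 3)) @ shared
        other = rng.standard_normal((40, 10))
        space = fit_condition_subspace(train)
        c_train = variance_capture_curve(space, train)
        c_other = variance_capture_curve(space, other)
        assert np.all(c_train[:5] >= c_other[:5] - 1e-12)


class TestTripletSweep:
    def test_bookkeeping_eight_triplets(self, neural):
        sweep = triplet_sweep(neural)
        n_units = neural.values.shape[1]
        for relation in ("same_arm", "opposite_arm"):
            sel = sweep.curves[sweep.curves["relation"] == relation]
            assert sel["train"].nunique() == 8
            assert len(sel) == 8 * min(200, n_units)
        assert set(sweep.summary["relation"]) == {"same_arm", "opposite_arm"}

    def test_missing_condition_rejected(self, neural):
        partial = RateTensor(values=neural.values[:, :, :6],
                             sem=neural.sem[:, :, :6],
                             time_ms=neural.time_ms, channels=neural.channels,
                             conditions=neural.conditions[:6])
        with pytest.raises(ValueError, match="missing"):
            triplet_sweep(partial)

    def test_orthogonal_generator_separates_arms(self, neural):
        """subspace_overlap=0 (fixture): the same-arm capture at 5 PCs far
        exceeds the opposite-arm capture."""
        sweep = triplet_sweep(neural)
        same = sweep.capture_at("same_arm").mean()
        opp = sweep.capture_at("opposite_arm").mean()
        assert same > 0.5
        assert opp < 0.12
        assert same > opp + 0.3


class TestContributionWeights:
    def test_full_lateralization_silences_nondriving_weights(self):
        cfg = GeneratorConfig(n_units_per_hemisphere=12, n_muscles_per_arm=2,
                              n_trials_per_condition=16, lateralization=1.0,
                              seed=21)
        session, _ = generate_session(cfg)
        neural, _ = compute_rate_tensors(session)
        # left-arm subspace: driving hemisphere is the right one.  Only 4
        # PCs carry signal (latent_dim_per_arm), so compare within those;
        # residual Poisson noise keeps silent-hemisphere weights above zero.
        dists, medians = contribution_weight_distributions(neural, "left",
                                                           n_pcs=4)
        assert medians["right"] > 2 * medians["left"]

    def test_weights_invariant_to_unit_order(self, rng):
        X = rng.standard_normal((50, 10))
        space = fit_condition_subspace(X)
        hems = np.array(["left"] * 5 + ["right"] * 5)
        ref = subspace_contribution_weights(space, hems, n_pcs=3)
        perm = rng.permutation(10)
        space_p = fit_condition_subspace(X[:, perm])
        got = subspace_contribution_weights(space_p, hems[perm], n_pcs=3)
        for h in ("left", "right"):
            np.testing.assert_allclose(np.sort(got[h]), np.sort(ref[h]),
                                       atol=1e-10)


class TestNeuronCountSweep:
    def test_full_count_matches_unsubsampled(self, neural):
        n = neural.values.shape[1]
        sweep = neuron_count_sweep(neural, [n], n_draws=3, seed=0)
        full = triplet_sweep(neural)
        got = sweep[sweep["relation"] == "opposite_arm"]["capture"].iloc[0]
        assert got == pytest.approx(full.capture_at("opposite_arm").mean())

    def test_fixed_seed_reproducible(self, neural):
        a = neuron_count_sweep(neural, [10], n_draws=2, seed=7)
        b = neuron_count_sweep(neural, [10], n_draws=2, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_capture_bias_shrinks_with_count(self, neural):
        """Small populations overestimate cross-arm capture; the estimate
        falls toward its asymptote as units are added."""
        n = neural.values.shape[1]
        sweep = neuron_count_sweep(neural, [8, n], n_draws=5, seed=1)
        opp = sweep[sweep["relation"] == "opposite_arm"].set_index("count")
        assert opp.loc[8, "capture"] > opp.loc[n, "capture"]

    def test_oversized_count_rejected(self, neural):
        with pytest.raises(ValueError, match="exceeds"):
            neuron_count_sweep(neural, [neural.values.shape[1] + 1])


def brute_force_tangling(trajectories, params):
    """O(T^2) double-loop oracle with the same arithmetic as the fast path."""
    labels = list(trajectories)
    mats = [np.asarray(trajectories[k], float) for k in labels]
    X = np.vstack(mats)
    Xdot = np.vstack([_derivatives(m, params.dt_s) for m in mats])
    centered = X - X.mean(axis=0)
    eps = params.epsilon_fraction * float(np.mean(np.sum(centered**2, axis=1)))
    M = X.shape[0]
    Q = np.empty(M)
    for t in range(M):
        best = -np.inf
        num = np.sum((Xdot - Xdot[t]) ** 2, axis=1)
        den = np.sum((X - X[t]) ** 2, axis=1) + eps
        for tp in range(M):
            best = max(best, num[tp] / den[tp])
        Q[t] = best
    out, start = {}, 0
    for k, m in zip(labels, mats):
        out[k] = Q[start:start + m.shape[0]]
        start += m.shape[0]
    return out


class TestTangling:
    def _circle(self, T=200, R=1.0, omega=2 * np.pi, phase=0.0, sign=1.0):
        t = np.arange(T) * 0.01
        return np.column_stack([R * np.cos(sign * omega * t + phase),
                                R * np.sin(sign * omega * t + phase)])

    def test_constant_for_uniform_circle(self):
        params = TanglingParams(n_dims=2, dt_s=0.01)
        q = tangling({"c": self._circle(T=500)}, params)["c"]
        interior = q[5:-5]  # one-sided derivative endpoints differ
        assert interior.std() / interior.mean() < 0.02

    def test_matches_bruteforce_exactly(self, rng):
        params = TanglingParams(n_dims=8, dt_s=0.01)
        trajs = {f"c{i}": rng.standard_normal((130, 8)).cumsum(axis=0)
                 for i in range(4)}
        fast = tangling(trajs, params)
        slow = brute_force_tangling(trajs, params)
        for k in trajs:
            np.testing.assert_array_equal(fast[k], slow[k])

    def test_counterrotating_circles_raise_tangling(self):
        params = TanglingParams(n_dims=2, dt_s=0.01)
        one = tangling({"f": self._circle()}, params)["f"]
        both = tangling({"f": self._circle(),
                         "b": self._circle(sign=-1.0)}, params)
        assert both["f"].mean() > 5 * one.mean()

    def test_rotation_invariance(self, rng):
        params = TanglingParams(n_dims=4, dt_s=0.01)
        trajs = {f"c{i}": rng.standard_normal((80, 4)).cumsum(axis=0)
                 for i in range(2)}
        R, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        rotated = {k: v @ R for k, v in trajs.items()}
        q0 = tangling(trajs, params)
        q1 = tangling(rotated, params)
        for k in trajs:
            np.testing.assert_allclose(q1[k], q0[k], rtol=1e-10)

    def test_uniform_scaling_invariance(self, rng):
        params = TanglingParams(n_dims=3, dt_s=0.01)
        trajs = {"a": rng.standard_normal((90, 3)).cumsum(axis=0)}
        scaled = {"a": 37.5 * trajs["a"]}
        q0 = tangling(trajs, params)["a"]
        q1 = tangling(scaled, params)["a"]
        np.testing.assert_allclose(q1, q0, rtol=1e-10)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            tangling({"a": np.zeros((1, 3))}, TanglingParams(n_dims=3))


class TestTanglingComparison:
    def test_distribution_sizes(self, neural, emg):
        comp = tangling_comparison(neural, emg)
        T = 200  # middle cycles at 10 ms
        # per hemisphere x per arm-set: 4 conditions x T, pooled over 2 hemis
        assert comp.distributions["driving"].size == 2 * 4 * T
        assert comp.distributions["non_driving"].size == 2 * 4 * T
        assert comp.distributions["muscle"].size == 2 * 4 * T

    def test_identical_hemispheres_give_identical_distributions(self, neural, emg):
        mirrored = neural.values.copy()
        n = mirrored.shape[1] // 2
        mirrored[:, n:, :] = mirrored[:, :n, :]
        twin = RateTensor(values=mirrored, sem=neural.sem.copy(),
                          time_ms=neural.time_ms, channels=neural.channels,
                          conditions=list(neural.conditions))
        comp = tangling_comparison(twin, emg)
        np.testing.assert_allclose(np.sort(comp.distributions["driving"]),
                                   np.sort(comp.distributions["non_driving"]))

    def test_rectified_muscles_tangle_more_than_neurons(self, study_scale_tensors):
        """Rectified muscle readouts of rotational latents tangle more
        than the neural trajectories that drive them.  Needs the
        study-scale session: at small scale, Poisson noise inflates the
        neural derivative terms and with them neural tangling."""
        neural, emg, _ = study_scale_tensors
        comp = tangling_comparison(neural, emg)
        assert comp.mean("muscle") > comp.mean("driving")
        assert comp.mean("muscle") > comp.mean("non_driving")
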