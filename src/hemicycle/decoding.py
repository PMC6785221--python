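"""Reduced-rank linear decoding of muscle activity and cross-hemisphere
prediction.

Muscle decoders are rank-r partial-least-squares (PLS) regressions from
soft-normalized, per-condition-centered firing rates to range-normalized,
per-condition-centered EMG intensities.  The rank is selected on one
held-out validation cycle of the test condition; generalization is scored
with the population variance-explained

    R^2 = 1 - ||Y - Ypred||_F^2 / ||Y||_F^2 .

Cross-hemisphere structure is probed with principal-components regression
(predict one hemisphere's population from the other's top PC projections,
versus a leave-one-out self-prediction), a hemisphere-label shuffle test,
and signal-removal / PC-rescaling controls.  The wrong-arm analysis asks
whether decoders trained only on performing-arm conditions predict the
near-silence of muscles when the other arm performs the task.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .conditions import (ALL_CONDITIONS, Condition, conditions_for_arm,
                         driving_hemisphere, other_arm)
from .preprocess import RateTensor, extract_middle_cycles
from .geometry import soft_normalize, fit_condition_subspace

SAMPLES_PER_CYCLE = 50  # canonical 500 ms cycle at 10 ms resolution


def population_r2(Y: np.ndarray, Ypred: np.ndarray) -> float:
    """Population percent-variance-explained (as a fraction, can be < 0)."""
    Y = np.asarray(Y, dtype=float)
    Ypred = np.asarray(Ypred, dtype=float)
    if Y.shape != Ypred.shape:
        raise ValueError("Y and Ypred must have matching shapes")
    total = np.sum(Y**2)
    if total == 0:
        raise ValueError("Y has zero variance")
    return float(1.0 - np.sum((Y - Ypred) ** 2) / total)


@dataclass
class DecoderModel:
    """Rank-r linear map from centered, normalized rates to muscle intensity."""

    weights: np.ndarray  # units x muscles
    rank: int
    train_conditions: list
    validation_curve: pd.DataFrame  # rank, validation_r2
    provenance: dict = field(default_factory=dict)

    def predict(self, X_centered: np.ndarray) -> np.ndarray:
        return np.asarray(X_centered, dtype=float) @ self.weights


def _pls_weights(X: np.ndarray, Y: np.ndarray, rank: int) -> np.ndarray:
    """Weight matrix (features x targets) of a rank-r PLS2 fit."""
    pls = PLSRegression(n_components=rank, scale=False)
    with warnings.catch_warnings():
        # rank search intentionally probes past the informative components
        warnings.filterwarnings("ignore", message="y residual is constant")
        pls.fit(X, Y)
    B = pls.coef_
    if B.shape == (X.shape[1], Y.shape[1]):
        return B
    return B.T  # older scikit-learn orientation


def fit_muscle_decoder(X_train, Y_train, X_val, Y_val,
                       rank_candidates=None,
                       train_conditions=None) -> DecoderModel:
    """Fit PLS decoders over candidate ranks and keep the one with maximal
    validation R^2.

    All matrices must already be normalized and per-condition centered.
    ``(X_val, Y_val)`` is the single held-out validation cycle of the test
    condition.  Candidate ranks exceeding the data dimensions are trimmed
    with a warning.
    """
    X_train = np.asarray(X_train, dtype=float)
    Y_train = np.asarray(Y_train, dtype=float)
    max_rank = min(X_train.shape[0] - 1, X_train.shape[1])
    if rank_candidates is None:
        rank_candidates = range(1, min(20, max_rank,
                                       4 * Y_train.shape[1]) + 1)
    ranks = [r for r in rank_candidates if 1 <= r <= max_rank]
    if len(ranks) < len(list(rank_candidates)):
        warnings.warn("rank candidates exceeding data dimensions were trimmed")
    if not ranks:
        raise ValueError("no feasible rank candidates")
    records = []
    best = None
    for r in ranks:
        B = _pls_weights(X_train, Y_train, r)
        r2 = population_r2(Y_val, np.asarray(X_val) @ B)
        records.append({"rank": r, "validation_r2": r2})
        if best is None or r2 > best[1]:
            best = (r, r2, B)
    return DecoderModel(
        weights=best[2], rank=best[0], train_conditions=list(train_conditions or []),
        validation_curve=pd.DataFrame(records),
        provenance={"method": "PLS2 (NIPALS, scikit-learn PLSRegression)",
                    "normalization": "neural soft-norm c=5; EMG range-norm",
                    "centering": "per-condition temporal mean",
                    "validation": "cycle 2 of the test condition"})


# ---------------------------------------------------------------------------
# Shared data preparation


def _centered(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def prepare_decoding_matrices(neural: RateTensor, emg: RateTensor,
                              softnorm_c: float = 5.0):
    """Middle-cycle, normalized (not yet centered) matrices per condition.

    Returns ``(X, Y, channels)`` where ``X[label]`` is time x units
    (soft-normalized), ``Y[arm][label]`` is time x muscles-of-arm
    (range-normalized), and ``channels`` the neural channel metadata.
    """
    n_mid = extract_middle_cycles(soft_normalize(neural, c=softnorm_c))
    e_mid = extract_middle_cycles(soft_normalize(emg, c=0.0))
    X = {lab: n_mid.matrix(lab) for lab in n_mid.conditions}
    Y = {}
    for arm in ("left", "right"):
        mask = (e_mid.channels["arm"] == arm).to_numpy()
        sub = e_mid.select_channels(mask)
        Y[arm] = {lab: sub.matrix(lab) for lab in sub.conditions}
    return X, Y, n_mid.channels


def _split_validation(M: np.ndarray):
    """(validation cycle, remaining test cycles) of a middle-cycle matrix."""
    return M[:SAMPLES_PER_CYCLE], M[SAMPLES_PER_CYCLE:]


def cross_hemisphere_muscle_decode(neural: RateTensor, emg: RateTensor,
                                   rank_candidates=None) -> pd.DataFrame:
    """Generalization R^2 for performing-arm muscles decoded from the
    driving versus the non-driving cortex, for each of the 8 conditions.

    Training uses the same arm/direction condition with the opposite start
    position; rank is selected on cycle 2 of the test condition; R^2 is
    reported on the remaining cycles.
    """
    X, Y, channels = prepare_decoding_matrices(neural, emg)
    hems = channels["hemisphere"].to_numpy()
    for hemi in ("left", "right"):
        if not np.any(hems == hemi):
            raise ValueError(f"no units in {hemi} hemisphere")
    rows = []
    for test in ALL_CONDITIONS:
        train = test.with_other_start()
        drive_h = driving_hemisphere(test.arm)
        for source, hemi in (("driving", drive_h),
                             ("non_driving", other_arm(drive_h))):
            mask = hems == hemi
            Xtr = _centered(X[train.label][:, mask])
            Ytr = _centered(Y[test.arm][train.label])
            Xv_full = _centered(X[test.label][:, mask])
            Yv_full = _centered(Y[test.arm][test.label])
            Xval, Xtest = _split_validation(Xv_full)
            Yval, Ytest = _split_validation(Yv_full)
            model = fit_muscle_decoder(Xtr, Ytr, Xval, Yval,
                                       rank_candidates,
                                       train_conditions=[train.label])
            r2 = population_r2(Ytest, model.predict(Xtest))
            rows.append({"condition": test.label, "source": source,
                         "rank": model.rank, "r2": r2})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Principal-components regression across hemispheres


@dataclass
class CrossHemisphereModel:
    pc_basis: np.ndarray  # source units x rank, orthonormal
    regression: np.ndarray  # rank x target units
    rank: int

    def predict(self, X_centered: np.ndarray) -> np.ndarray:
        return X_centered @ self.pc_basis @ self.regression


def pc_regression_predict(source_train, target_train, source_test,
                          target_test, ranks=range(1, 11),
                          mode: str = "cross") -> pd.DataFrame:
    """R^2 per rank for principal-components regression.

    ``cross`` predicts the target population from the source population's
    top PC projections.  ``leave_one_out_self`` predicts each target unit
    from the PCs of all *other* target units (source matrices are ignored
    and the target population predicts itself).  All matrices are centered
    by their own temporal means internally.
    """
    St, Tt = np.asarray(source_train, float), np.asarray(target_train, float)
    Se, Te = np.asarray(source_test, float), np.asarray(target_test, float)
    ranks = list(ranks)
    rows = []
    if mode == "cross":
        max_rank = min(St.shape)
        if max(ranks) > max_rank:
            raise ValueError(f"rank {max(ranks)} exceeds source dimension {max_rank}")
        space = fit_condition_subspace(St)
        Stc, Ttc = _centered(St), _centered(Tt)
        Sec, Tec = _centered(Se), _centered(Te)
        for r in ranks:
            Wr = space.basis[:, :r]
            beta, *_ = np.linalg.lstsq(Stc @ Wr, Ttc, rcond=None)
            pred = Sec @ Wr @ beta
            rows.append({"rank": r, "mode": mode,
                         "r2": population_r2(Tec, pred)})
    elif mode == "leave_one_out_self":
        n = Tt.shape[1]
        if max(ranks) > n - 1:
            raise ValueError(f"rank {max(ranks)} exceeds leave-one-out "
                             f"source dimension {n - 1}")
        Ttc, Tec = _centered(Tt), _centered(Te)
        preds = {r: np.empty_like(Tec) for r in ranks}
        for p in range(n):
            others = np.arange(n) != p
            space = fit_condition_subspace(Ttc[:, others])
            Xtr = Ttc[:, others]
            Xte = Tec[:, others]
            for r in ranks:
                Wr = space.basis[:, :r]
                beta, *_ = np.linalg.lstsq(Xtr @ Wr, Ttc[:, p], rcond=None)
                preds[r][:, p] = Xte @ Wr @ beta
        for r in ranks:
            rows.append({"rank": r, "mode": mode,
                         "r2": population_r2(Tec, preds[r])})
    else:
        raise ValueError("mode must be 'cross' or 'leave_one_out_self'")
    return pd.DataFrame(rows)


def _self_vs_cross_gap(X: dict, hems: np.ndarray, rank: int) -> float:
    """Mean over conditions of (self LOO R^2 - cross R^2) at one rank."""
    gaps = []
    for test in ALL_CONDITIONS:
        train = test.with_other_start()
        drive = hems == driving_hemisphere(test.arm)
        Ytr, Yte = X[train.label][:, drive], X[test.label][:, drive]
        Str, Ste = X[train.label][:, ~drive], X[test.label][:, ~drive]
        r_cross = pc_regression_predict(Str, Ytr, Ste, Yte, [rank],
                                        mode="cross")["r2"].iloc[0]
        r_self = pc_regression_predict(Ytr, Ytr, Yte, Yte, [rank],
                                       mode="leave_one_out_self")["r2"].iloc[0]
        gaps.append(r_self - r_cross)
    return float(np.mean(gaps))


def hemisphere_shuffle_test(neural: RateTensor, rank: int = 10,
                            n_resamples: int = 100, seed: int = 0):
    """Is the self-vs-cross prediction gap larger than hemisphere labels
    being arbitrary would produce?

    The observed gap (mean over the 8 conditions of leave-one-out
    self-prediction R^2 minus cross-hemisphere R^2 at ``rank``) is compared
    with the gaps obtained after randomly permuting the hemisphere labels.
    Significant when the observed gap exceeds 95% of the resampled gaps.
    """
    mid = extract_middle_cycles(soft_normalize(neural))
    X = {lab: mid.matrix(lab) for lab in mid.conditions}
    hems = mid.channels["hemisphere"].to_numpy()
    if not (np.any(hems == "left") and np.any(hems == "right")):
        raise ValueError("both hemispheres must be populated")
    n_min = min(int(np.sum(hems == "left")), int(np.sum(hems == "right")))
    if rank > n_min - 1:
        warnings.warn(f"rank trimmed from {rank} to {n_min - 1} "
                      "(small hemisphere population)")
        rank = n_min - 1
    observed = _self_vs_cross_gap(X, hems, rank)
    rng = np.random.default_rng(seed)
    null = np.array([
        _self_vs_cross_gap(X, rng.permutation(hems), rank)
        for _ in range(n_resamples)])
    significant = bool(observed > np.quantile(null, 0.95))
    p = float(np.mean(null >= observed))
    return {"observed_gap": observed, "null": null, "p": p,
            "significant": significant}


# ---------------------------------------------------------------------------
# Signal perturbation controls


@dataclass
class PerturbationControls:
    reconstructed: np.ndarray  # full-rank reconstruction (sanity: == input)
    remove_pc1: np.ndarray
    rescale_pcs: np.ndarray


def signal_perturbation_controls(matrix: np.ndarray) -> PerturbationControls:
    """Controls that hide or rescale signals in a population response.

    ``remove_pc1`` reconstructs the response from all PCs except the first;
    ``rescale_pcs`` halves the projections on PCs 1-2 and doubles those on
    PCs 3-4 before reconstructing.
    """
    X = np.asarray(matrix, dtype=float)
    space = fit_condition_subspace(X)
    if space.rank < 4:
        raise ValueError("rescale control needs at least 4 PCs")
    W = space.basis
    Xc = X - space.mean
    pc = Xc @ W
    recon = pc @ W.T + space.mean
    no1 = pc.copy()
    no1[:, 0] = 0.0
    remove_pc1 = no1 @ W.T + space.mean
    scaled = pc.copy()
    scaled[:, :2] /= 2.0
    scaled[:, 2:4] *= 2.0
    rescale = scaled @ W.T + space.mean
    return PerturbationControls(reconstructed=recon, remove_pc1=remove_pc1,
                                rescale_pcs=rescale)


# ---------------------------------------------------------------------------
# Wrong-arm generalization


@dataclass
class WrongArmResult:
    strategy: str
    decoded_traces: dict  # (arm, direction, 'performing'|'non_performing') -> T x muscles
    modulation: pd.DataFrame  # muscle, arm, direction, decoded/actual perf & non-perf
    arm_preference: pd.DataFrame  # muscle, arm, direction, decoded_api, actual_api
    weight_magnitudes: dict  # hemisphere -> |weight| samples

    def median_wrong_arm_ratio(self) -> float:
        """Median over muscles/directions of decoded non-performing
        modulation relative to decoded performing modulation."""
        m = self.modulation
        return float(np.median(m["decoded_non_performing"]
                               / m["decoded_performing"]))


def wrong_arm_generalization(neural: RateTensor, emg: RateTensor,
                             strategy: str = "train_performing",
                             rank_candidates=None) -> WrongArmResult:
    """Can a muscle decoder ignore activity related to the wrong arm?

    For each arm and cycling direction: train on the top-start condition
    (performing only, or both arms' top-start conditions for
    ``train_both``), select rank on cycle 2 of the bottom-start performing
    condition, then decode the remaining cycles of the bottom-start
    condition performed by each arm.  Decoded modulation should collapse
    when the muscle's arm is not performing.
    """
    if strategy not in ("train_performing", "train_both"):
        raise ValueError("strategy must be 'train_performing' or 'train_both'")
    X, Y, channels = prepare_decoding_matrices(neural, emg)
    hems = channels["hemisphere"].to_numpy()
    traces = {}
    mod_rows = []
    api_rows = []
    weights = {"left": [], "right": []}
    for arm in ("left", "right"):
        muscle_ids = [f"m{k}" for k in range(next(iter(Y[arm].values())).shape[1])]
        for direction in ("forward", "backward"):
            train_perf = Condition(arm, direction, "top")
            val_cond = Condition(arm, direction, "bottom")
            test_other = Condition(other_arm(arm), direction, "bottom")
            required = [train_perf.label, val_cond.label, test_other.label]
            if strategy == "train_both":
                required.append(train_perf.with_other_arm().label)
            for lab in required:
                if lab not in X:
                    raise ValueError(f"missing condition {lab}")
            Xtr = _centered(X[train_perf.label])
            Ytr = _centered(Y[arm][train_perf.label])
            if strategy == "train_both":
                twin = train_perf.with_other_arm()
                Xtr = np.vstack([Xtr, _centered(X[twin.label])])
                Ytr = np.vstack([Ytr, _centered(Y[arm][twin.label])])
            Xval, Xtest_p = _split_validation(_centered(X[val_cond.label]))
            Yval, Ytest_p = _split_validation(_centered(Y[arm][val_cond.label]))
            _, Xtest_n = _split_validation(_centered(X[test_other.label]))
            _, Ytest_n = _split_validation(_centered(Y[arm][test_other.label]))
            model = fit_muscle_decoder(Xtr, Ytr, Xval, Yval, rank_candidates,
                                       train_conditions=[train_perf.label])
            pred_p = model.predict(Xtest_p)
            pred_n = model.predict(Xtest_n)
            traces[(arm, direction, "performing")] = pred_p
            traces[(arm, direction, "non_performing")] = pred_n
            for h in ("left", "right"):
                weights[h].append(np.abs(model.weights[hems == h]).ravel())
            for m, mid_ in enumerate(muscle_ids):
                dm_p, dm_n = float(pred_p[:, m].std()), float(pred_n[:, m].std())
                am_p, am_n = float(Ytest_p[:, m].std()), float(Ytest_n[:, m].std())
                mod_rows.append({
                    "muscle": f"{arm}_{mid_}", "arm": arm, "direction": direction,
                    "decoded_performing": dm_p, "decoded_non_performing": dm_n,
                    "actual_performing": am_p, "actual_non_performing": am_n})
                api_rows.append({
                    "muscle": f"{arm}_{mid_}", "arm": arm, "direction": direction,
                    "decoded_api": (dm_p - dm_n) / (dm_p + dm_n)
                    if dm_p + dm_n > 0 else np.nan,
                    "actual_api": (am_p - am_n) / (am_p + am_n)
                    if am_p + am_n > 0 else np.nan})
    return WrongArmResult(
        strategy=strategy, decoded_traces=traces,
        modulation=pd.DataFrame(mod_rows),
        arm_preference=pd.DataFrame(api_rows),
        weight_magnitudes={h: np.concatenate(v) for h, v in weights.items()})
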