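"""Population geometry: normalization, condition subspaces, cross-arm
variance capture, contribution weights, neuron-count sweep, and trajectory
tangling.

The central analysis asks whether population activity during left-arm and
right-arm conditions occupies a shared or orthogonal subspace: PCA is fit
on one condition's (time x unit) response, held-out conditions are
projected onto those PCs, and the cumulative fraction of their variance
captured is compared between same-arm and opposite-arm tests.

Trajectory tangling Q(t) measures whether similar population states ever
have dissimilar derivatives:

    Q(t) = max_{t'} ||xdot(t) - xdot(t')||^2 / (||x(t) - x(t')||^2 + eps)

with t' ranging over all times of all conditions in the set and eps a
small constant (a fraction of the total variance across the retained
dimensions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import (ALL_CONDITIONS, Condition, conditions_for_arm,
                         driven_arm, driving_hemisphere, other_arm)
from .preprocess import RateTensor, extract_middle_cycles

DEFAULT_SOFTNORM_C = 5.0


@dataclass
class SoftNormParams:
    offset: float = DEFAULT_SOFTNORM_C

    def __post_init__(self):
        if self.offset < 0:
            raise ValueError("soft-normalization offset must be >= 0")


def soft_normalize(tensor: RateTensor, c: float = DEFAULT_SOFTNORM_C) -> RateTensor:
    """Divide each channel by (its range across all times/conditions + c).

    c = 5 on the spikes/s scale balances high- and low-rate units without
    magnifying near-silent ones; c = 0 gives plain range normalization
    (used for EMG, whose absolute scale is arbitrary).
    """
    SoftNormParams(c)
    rng = tensor.values.max(axis=(0, 2)) - tensor.values.min(axis=(0, 2))
    denom = rng + c
    safe = np.where(denom > 0, denom, 1.0)
    scale = np.where(denom > 0, 1.0 / safe, 0.0)
    return RateTensor(values=tensor.values * scale[None, :, None],
                      sem=tensor.sem * scale[None, :, None],
                      time_ms=tensor.time_ms, channels=tensor.channels,
                      conditions=list(tensor.conditions))


@dataclass
class Subspace:
    """Orthonormal PCA basis fit to one condition's population response."""

    basis: np.ndarray  # units x rank, orthonormal columns
    mean: np.ndarray  # temporal mean used for centering (units,)
    eigenvalues: np.ndarray  # sum-of-squares captured per PC, descending
    train_condition: str = ""

    @property
    def rank(self) -> int:
        return self.basis.shape[1]


def fit_condition_subspace(matrix: np.ndarray, rank: int | None = None,
                           train_condition: str = "") -> Subspace:
    """PCA of a (time x unit) response; components ordered by variance."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be time x unit")
    max_rank = min(X.shape)
    if rank is None:
        rank = max_rank
    if rank < 1 or rank > max_rank:
        raise ValueError(f"rank must be in [1, {max_rank}], got {rank}")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    return Subspace(basis=vt[:rank].T, mean=mean, eigenvalues=s[:rank] ** 2,
                    train_condition=train_condition)


def variance_capture_curve(space: Subspace, test_matrix: np.ndarray,
                           center: str = "own") -> np.ndarray:
    """Cumulative fraction of a test response's variance captured per PC.

    The test matrix is centered by its own temporal mean (default) or by
    the training mean (``center='train'``).  Capture is the sum of squared
    projections onto the leading PCs divided by the total centered sum of
    squares, so curves from different subspaces are directly comparable.
    """
    X = np.asarray(test_matrix, dtype=float)
    if X.shape[1] != space.basis.shape[0]:
        raise ValueError("test matrix and subspace have different unit sets")
    if center == "own":
        Xc = X - X.mean(axis=0)
    elif center == "train":
        Xc = X - space.mean
    else:
        raise ValueError("center must be 'own' or 'train'")
    total = np.sum(Xc**2)
    if total == 0:
        raise ValueError("test matrix has zero variance")
    proj = Xc @ space.basis
    per_pc = np.sum(proj**2, axis=0)
    return np.cumsum(per_pc) / total


@dataclass
class TripletSweepResult:
    curves: pd.DataFrame  # train, test, relation, pc (1-based), capture
    n_pcs: int
    summary: pd.DataFrame  # relation, mean, sd of capture at n_pcs

    def capture_at(self, relation: str, n_pcs: int | None = None) -> np.ndarray:
        k = n_pcs or self.n_pcs
        sel = self.curves[(self.curves["relation"] == relation)
                          & (self.curves["pc"] == k)]
        return sel["capture"].to_numpy()


def triplet_sweep(neural: RateTensor, n_pcs: int = 5,
                  softnorm_c: float = DEFAULT_SOFTNORM_C,
                  center: str = "own") -> TripletSweepResult:
    """Variance-capture sweep over all condition triplets.

    Every condition serves as the training condition once.  Its same-arm
    test shares arm and direction but not start position; its opposite-arm
    test is the identical condition performed by the other arm.  Inputs are
    soft-normalized and centered per condition.
    """
    missing = [c.label for c in ALL_CONDITIONS if c.label not in neural.conditions]
    if missing:
        raise ValueError(f"missing conditions: {missing}")
    mid = extract_middle_cycles(soft_normalize(neural, c=softnorm_c))
    rows = []
    for train in ALL_CONDITIONS:
        space = fit_condition_subspace(mid.matrix(train),
                                       train_condition=train.label)
        tests = {"same_arm": train.with_other_start(),
                 "opposite_arm": train.with_other_arm()}
        for relation, test in tests.items():
            curve = variance_capture_curve(space, mid.matrix(test), center=center)
            for k, cap in enumerate(curve, start=1):
                rows.append({"train": train.label, "test": test.label,
                             "relation": relation, "pc": k, "capture": cap})
    curves = pd.DataFrame(rows)
    at_k = curves[curves["pc"] == n_pcs]
    summary = (at_k.groupby("relation")["capture"].agg(["mean", "std"])
               .reset_index().rename(columns={"std": "sd"}))
    return TripletSweepResult(curves=curves, n_pcs=n_pcs, summary=summary)


def subspace_contribution_weights(space: Subspace, hemispheres,
                                  n_pcs: int = 5) -> dict:
    """|weight| distributions in the top PCs, grouped by hemisphere."""
    hems = np.asarray(hemispheres)
    if hems.size != space.basis.shape[0]:
        raise ValueError("hemisphere labels must match subspace units")
    W = np.abs(space.basis[:, :min(n_pcs, space.rank)])
    return {h: W[hems == h].ravel() for h in ("left", "right")}


def contribution_weight_distributions(neural: RateTensor, arm: str,
                                      n_pcs: int = 5,
                                      softnorm_c: float = DEFAULT_SOFTNORM_C):
    """Per-hemisphere |weight| samples for one arm's subspaces.

    Pools the top-``n_pcs`` PC weights over the four training conditions
    performed with ``arm`` (each unit contributes 4 x n_pcs weights), and
    reports medians.  The driving hemisphere for that arm is expected to
    contribute modestly more when responses are lateralized.
    """
    mid = extract_middle_cycles(soft_normalize(neural, c=softnorm_c))
    hems = neural.channels["hemisphere"].to_numpy()
    pooled = {"left": [], "right": []}
    for cond in conditions_for_arm(arm):
        space = fit_condition_subspace(mid.matrix(cond),
                                       train_condition=cond.label)
        for h, w in subspace_contribution_weights(space, hems, n_pcs).items():
            pooled[h].append(w)
    dists = {h: np.concatenate(v) for h, v in pooled.items()}
    medians = {h: float(np.median(v)) for h, v in dists.items()}
    return dists, medians


def neuron_count_sweep(neural: RateTensor, counts, n_draws: int = 10,
                       seed: int = 0, n_pcs: int = 5) -> pd.DataFrame:
    """Opposite-arm capture versus sampled neuron count.

    Small populations bias subspace-overlap estimates away from
    orthogonality; the mean opposite-arm capture should fall toward its
    asymptote as the unit count grows.
    """
    n_units = neural.values.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for count in counts:
        if count > n_units:
            raise ValueError(f"count {count} exceeds population size {n_units}")
        draws = 1 if count == n_units else n_draws
        for d in range(draws):
            if count == n_units:
                idx = np.arange(n_units)
            else:
                idx = rng.choice(n_units, size=count, replace=False)
            mask = np.zeros(n_units, dtype=bool)
            mask[idx] = True
            sweep = triplet_sweep(neural.select_channels(mask), n_pcs=n_pcs)
            for relation in ("same_arm", "opposite_arm"):
                rows.append({
                    "count": count, "draw": d, "relation": relation,
                    "capture": float(sweep.capture_at(relation).mean())})
    out = pd.DataFrame(rows)
    return (out.groupby(["count", "relation"])["capture"].mean()
            .reset_index())


# ---------------------------------------------------------------------------
# Trajectory tangling


@dataclass
class TanglingParams:
    n_dims: int = 8
    epsilon_fraction: float = 0.10
    dt_s: float = 0.010  # sampling step of the state trajectories

    def __post_init__(self):
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")
        if self.epsilon_fraction <= 0:
            raise ValueError("epsilon_fraction must be > 0")


def _derivatives(X: np.ndarray, dt_s: float) -> np.ndarray:
    """Central differences, one-sided at the edges (second-order interior)."""
    return np.gradient(X, dt_s, axis=0)


def tangling(trajectories, params: TanglingParams | None = None):
    """Tangling Q(t) for a set of state trajectories.

    ``trajectories`` maps a condition label to a (time x dim) state matrix
    (already reduced to the retained dimensions).  The max over t' pools
    all times of all conditions.  eps = epsilon_fraction x total variance
    across dimensions of the pooled states.  Returns a dict mapping each
    label to its (T,) array of Q values.
    """
    params = params or TanglingParams()
    labels = list(trajectories)
    mats = [np.asarray(trajectories[k], dtype=float) for k in labels]
    for m in mats:
        if m.ndim != 2 or m.shape[0] < 2:
            raise ValueError("each trajectory needs >= 2 time points")
    X = np.vstack(mats)
    Xdot = np.vstack([_derivatives(m, params.dt_s) for m in mats])
    centered = X - X.mean(axis=0)
    total_var = float(np.mean(np.sum(centered**2, axis=1)))
    eps = params.epsilon_fraction * total_var
    M = X.shape[0]
    Q = np.empty(M)
    for t in range(M):
        num = np.sum((Xdot - Xdot[t]) ** 2, axis=1)
        den = np.sum((X - X[t]) ** 2, axis=1) + eps
        Q[t] = np.max(num / den)
    out = {}
    start = 0
    for k, m in zip(labels, mats):
        out[k] = Q[start:start + m.shape[0]]
        start += m.shape[0]
    return out


def reduce_for_tangling(tensor: RateTensor, conditions, n_dims: int = 8,
                        softnorm_c: float = DEFAULT_SOFTNORM_C) -> dict:
    """Soft-normalize, take middle cycles, PCA the pooled condition set to
    the top ``n_dims``, and return per-condition (time x dim) states."""
    mid = extract_middle_cycles(soft_normalize(tensor, c=softnorm_c))
    labels = [c.label if isinstance(c, Condition) else c for c in conditions]
    stacked = np.vstack([mid.matrix(lab) for lab in labels])
    k = min(n_dims, min(stacked.shape))
    space = fit_condition_subspace(stacked, rank=k)
    T = mid.matrix(labels[0]).shape[0]
    proj = (stacked - space.mean) @ space.basis
    return {lab: proj[i * T:(i + 1) * T] for i, lab in enumerate(labels)}


@dataclass
class TanglingComparison:
    distributions: dict  # 'driving' / 'non_driving' / 'muscle' -> Q samples
    summary: pd.DataFrame  # group, mean, sd, n

    def mean(self, group: str) -> float:
        return float(np.mean(self.distributions[group]))


def tangling_comparison(neural: RateTensor, emg: RateTensor,
                        params: TanglingParams | None = None) -> TanglingComparison:
    """Pooled tangling distributions for driving cortex, non-driving cortex,
    and muscles.

    For each hemisphere, tangling is computed separately over the four
    conditions of each arm (neural states soft-normalized, c=5); the
    distributions are pooled across hemispheres into a 'driving' set
    (contralateral arm performing) and a 'non-driving' set.  Muscle
    tangling (range-normalized, c=0) is computed per arm over that arm's
    performing conditions and pooled.
    """
    params = params or TanglingParams()
    pools = {"driving": [], "non_driving": [], "muscle": []}
    for hemi in ("left", "right"):
        mask = (neural.channels["hemisphere"] == hemi).to_numpy()
        sub = neural.select_channels(mask)
        for arm in ("left", "right"):
            conds = conditions_for_arm(arm)
            states = reduce_for_tangling(sub, conds, n_dims=params.n_dims)
            q = tangling(states, params)
            group = "driving" if driving_hemisphere(arm) == hemi else "non_driving"
            pools[group].extend(q.values())
    for arm in ("left", "right"):
        mask = (emg.channels["arm"] == arm).to_numpy()
        sub = emg.select_channels(mask)
        conds = conditions_for_arm(arm)
        states = reduce_for_tangling(sub, conds, n_dims=params.n_dims,
                                     softnorm_c=0.0)
        q = tangling(states, params)
        pools["muscle"].extend(q.values())
    dists = {g: np.concatenate(v) for g, v in pools.items()}
    summary = pd.DataFrame([
        {"group": g, "mean": float(np.mean(v)), "sd": float(np.std(v)),
         "n": int(v.size)} for g, v in dists.items()])
    return TanglingComparison(distributions=dists, summary=summary)
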