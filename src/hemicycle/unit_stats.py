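"""Single-unit and pairwise statistics.

Modulation and the arm preference index, driven/non-driven response
correlations with a shuffle null, the top-start/bottom-start control,
pairwise correlation structure and its meta-correlation, the
median-speed-split randomization control, the Fano-factor regression, and
the required-magnification solver.

Conventions: Pearson correlation throughout; population (ddof=0) standard
deviation for modulation; per-condition mean-centering before
concatenation where stated; missing values propagate as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditions import (ALL_CONDITIONS, Condition, conditions_for_arm,
                         conditions_for_start, driven_arm, other_arm)
from .preprocess import RateTensor, extract_middle_cycles, trial_mean_speed
from .session import SessionData


@dataclass
class ConcatenatedResponse:
    """A rate sequence concatenated across conditions (middle cycles)."""

    values: np.ndarray
    boundaries: np.ndarray  # start index of each condition segment
    centered: bool


@dataclass
class ArmPreferenceResult:
    modulation_driven: float
    modulation_non_driven: float
    index: float  # NaN when both modulations are zero


def concatenate_response(tensor: RateTensor, channel_index: int,
                         conditions, center: bool = True,
                         window_by_condition=None) -> ConcatenatedResponse:
    """Concatenate one channel's trial-averaged rate across conditions.

    ``window_by_condition`` optionally maps a condition label to
    ``(first_cycle, last_cycle, phase_offset)``; the default is cycles 2-5.
    """
    segments = []
    boundaries = [0]
    for cond in conditions:
        label = cond.label if isinstance(cond, Condition) else cond
        window = (window_by_condition or {}).get(label, (2, 5, 0.0))
        sliced = extract_middle_cycles(tensor, *window)
        seg = sliced.values[:, channel_index, sliced.condition_index(label)]
        if center:
            seg = seg - seg.mean()
        segments.append(seg)
        boundaries.append(boundaries[-1] + seg.size)
    return ConcatenatedResponse(values=np.concatenate(segments),
                                boundaries=np.array(boundaries[:-1]),
                                centered=center)


def modulation(resp) -> float:
    """Population standard deviation of a concatenated response (spikes/s)."""
    values = resp.values if isinstance(resp, ConcatenatedResponse) else np.asarray(resp)
    if values.size == 0:
        raise ValueError("empty response")
    return float(np.std(values))


def arm_preference_index(mod_driven: float, mod_non_driven: float) -> ArmPreferenceResult:
    """(driven - non-driven) / (driven + non-driven); NaN if both are zero."""
    if mod_driven < 0 or mod_non_driven < 0:
        raise ValueError("modulations must be nonnegative")
    total = mod_driven + mod_non_driven
    index = float("nan") if total == 0 else (mod_driven - mod_non_driven) / total
    return ArmPreferenceResult(mod_driven, mod_non_driven, float(index))


def response_correlation(a, b) -> float:
    """Pearson r between two concatenated responses; NaN on zero variance."""
    x = a.values if isinstance(a, ConcatenatedResponse) else np.asarray(a, float)
    y = b.values if isinstance(b, ConcatenatedResponse) else np.asarray(b, float)
    if x.size != y.size:
        raise ValueError("responses must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ---------------------------------------------------------------------------
# Per-unit driven / non-driven machinery


def _paired_arm_conditions(hemisphere: str):
    """Driven-arm and non-driven-arm condition lists, matched by
    (direction, start) so concatenation order pairs corresponding conditions."""
    drv = driven_arm(hemisphere)
    driven_conds = sorted(conditions_for_arm(drv),
                          key=lambda c: (c.direction, c.start))
    nondriven_conds = [c.with_other_arm() for c in driven_conds]
    return driven_conds, nondriven_conds


def arm_concat_pair(tensor: RateTensor, channel_index: int, hemisphere: str,
                    center: bool = True):
    """(r_driven, r_non_driven) concatenated responses for one unit."""
    driven_conds, nondriven_conds = _paired_arm_conditions(hemisphere)
    r_d = concatenate_response(tensor, channel_index, driven_conds, center)
    r_n = concatenate_response(tensor, channel_index, nondriven_conds, center)
    return r_d, r_n


def start_concat_pair(tensor: RateTensor, channel_index: int,
                      center: bool = True):
    """(r_top, r_bottom): same response compared across starting positions.

    Top-start conditions use cycles 2-5; bottom-start conditions use cycles
    1.5-4.5 so that pedal phase matches despite the half-cycle offset.
    """
    top = sorted(conditions_for_start("top"), key=lambda c: (c.arm, c.direction))
    bottom = [Condition(c.arm, c.direction, "bottom") for c in top]
    r_top = concatenate_response(tensor, channel_index, top, center)
    bottom_windows = {c.label: (2, 5, -0.5) for c in bottom}
    r_bottom = concatenate_response(tensor, channel_index, bottom, center,
                                    window_by_condition=bottom_windows)
    return r_top, r_bottom


def unit_table(neural: RateTensor) -> pd.DataFrame:
    """Per-unit summary: modulation per arm, arm preference, correlations."""
    rows = []
    for i, (uid, hemi) in enumerate(
            zip(neural.channels["channel_id"], neural.channels["hemisphere"])):
        r_d_c, r_n_c = arm_concat_pair(neural, i, hemi, center=True)
        r_d, r_n = arm_concat_pair(neural, i, hemi, center=False)
        ap = arm_preference_index(modulation(r_d), modulation(r_n))
        r_top, r_bottom = start_concat_pair(neural, i, center=True)
        rows.append({
            "unit_id": uid, "hemisphere": hemi,
            "modulation_driven": ap.modulation_driven,
            "modulation_non_driven": ap.modulation_non_driven,
            "arm_preference": ap.index,
            "r_arm": response_correlation(r_d_c, r_n_c),
            "r_startpos": response_correlation(r_top, r_bottom),
        })
    return pd.DataFrame(rows)


def muscle_table(emg: RateTensor) -> pd.DataFrame:
    """Per-muscle modulation for its own arm performing vs not, and API."""
    rows = []
    for i, (cid, arm) in enumerate(
            zip(emg.channels["channel_id"], emg.channels["arm"])):
        own = sorted(conditions_for_arm(arm), key=lambda c: (c.direction, c.start))
        other = [c.with_other_arm() for c in own]
        m_d = modulation(concatenate_response(emg, i, own, center=False))
        m_n = modulation(concatenate_response(emg, i, other, center=False))
        ap = arm_preference_index(m_d, m_n)
        rows.append({"channel_id": cid, "arm": arm,
                     "modulation_driven": m_d, "modulation_non_driven": m_n,
                     "arm_preference": ap.index})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shuffle null for the mean driven/non-driven correlation


def shuffle_null_mean_correlation(neural: RateTensor, n_resamples: int = 1000,
                                  seed: int = 0):
    """Is the mean driven/non-driven correlation larger than chance?

    Each resample replaces every unit's r_driven with that of one randomly
    selected unit and its r_non_driven with that of another (draws with
    replacement), then takes the population-mean correlation.  Returns
    ``(observed_mean, null_distribution, p)`` with p the fraction of
    resampled means >= observed.
    """
    n = neural.values.shape[1]
    if n < 2:
        raise ValueError("need at least two units")
    pairs = [arm_concat_pair(neural, i, h, center=True)
             for i, h in enumerate(neural.channels["hemisphere"])]
    D = np.stack([p[0].values for p in pairs])
    N = np.stack([p[1].values for p in pairs])

    def _standardize(M):
        M = M - M.mean(axis=1, keepdims=True)
        sd = M.std(axis=1, keepdims=True)
        sd[sd == 0] = np.nan
        return M / sd

    Dz, Nz = _standardize(D), _standardize(N)
    corr = (Dz @ Nz.T) / D.shape[1]  # corr[i, j] = r(driven_i, nondriven_j)
    observed = float(np.nanmean(np.diag(corr)))
    rng = np.random.default_rng(seed)
    ii = rng.integers(0, n, size=(n_resamples, n))
    jj = rng.integers(0, n, size=(n_resamples, n))
    null = np.nanmean(corr[ii, jj], axis=1)
    p = float(np.mean(null >= observed))
    return observed, null, p


# ---------------------------------------------------------------------------
# Pairwise correlation structure and meta-correlation


@dataclass
class PairwiseCorrelationResult:
    matrices: dict  # condition label -> (n x n) correlation matrix
    kept_units: list  # channel ids retained (nonzero variance everywhere)
    scatter: pd.DataFrame  # pair x condition-type points
    meta_correlation: float


def pairwise_correlation_analysis(neural: RateTensor,
                                  hemisphere: str) -> PairwiseCorrelationResult:
    """Pairwise rate correlations for one hemisphere's units, per condition,
    and the meta-correlation between driven-arm and non-driven-arm pairwise
    correlations across all pairs and condition types."""
    mask = (neural.channels["hemisphere"] == hemisphere).to_numpy()
    sub = neural.select_channels(mask)
    mid = extract_middle_cycles(sub)
    n = sub.values.shape[1]
    stds = {lab: mid.matrix(lab).std(axis=0) for lab in mid.conditions}
    keep = np.ones(n, dtype=bool)
    for lab in mid.conditions:
        keep &= stds[lab] > 0
    kept_units = [u for u, k in zip(sub.channels["channel_id"], keep) if k]
    matrices = {lab: np.corrcoef(mid.matrix(lab)[:, keep].T)
                for lab in mid.conditions}

    drv = driven_arm(hemisphere)
    rows = []
    iu, ju = np.triu_indices(int(keep.sum()), k=1)
    for cond in conditions_for_arm(drv):
        m_d = matrices[cond.label]
        m_n = matrices[cond.with_other_arm().label]
        rows.append(pd.DataFrame({
            "i": iu, "j": ju,
            "condition_type": f"{cond.direction}-{cond.start}",
            "r_driven": m_d[iu, ju], "r_non_driven": m_n[iu, ju]}))
    scatter = (pd.concat(rows, ignore_index=True) if rows
               else pd.DataFrame(columns=["i", "j", "condition_type",
                                          "r_driven", "r_non_driven"]))
    if len(scatter) >= 2:
        meta = float(np.corrcoef(scatter["r_driven"], scatter["r_non_driven"])[0, 1])
    else:
        meta = float("nan")
    return PairwiseCorrelationResult(matrices=matrices, kept_units=kept_units,
                                     scatter=scatter, meta_correlation=meta)


def session_meta_correlation(neural: RateTensor) -> float:
    """Meta-correlation pooled over both hemispheres' unit pairs."""
    points = []
    for hemi in ("left", "right"):
        res = pairwise_correlation_analysis(neural, hemi)
        points.append(res.scatter[["r_driven", "r_non_driven"]])
    allp = pd.concat(points, ignore_index=True)
    if len(allp) < 2:
        return float("nan")
    return float(np.corrcoef(allp["r_driven"], allp["r_non_driven"])[0, 1])


# ---------------------------------------------------------------------------
# Median-speed-split randomization control


def nonperforming_speeds(session: SessionData, condition: Condition) -> dict:
    """trial_id -> mean unsigned angular speed of the non-performing pedal."""
    out = {}
    for tid in session.trials_of(condition):
        tr = session.traces[tid]
        angle = tr[f"pedal_{other_arm(condition.arm)}"].to_numpy()
        out[tid] = trial_mean_speed(angle, session.fs)
    return out


def speed_split_test(trial_rates: np.ndarray, speeds: np.ndarray,
                     n_perm: int = 1000, alpha: float = 0.05,
                     min_trials: int = 8, seed: int = 0):
    """Pointwise randomization test of rate vs non-performing-arm speed.

    ``trial_rates`` is (trials x T) aligned rates for one unit/condition;
    ``speeds`` the per-trial mean non-performing-arm speed.  Trials are
    split at the median speed (ties go below); the observed |mean
    difference| at each timepoint is compared with ``n_perm`` random
    splits of the same sizes.  A timepoint is flagged when the observed
    difference exceeds the (1 - alpha) fraction of random splits.

    Returns ``(significant, flagged_fraction)`` or ``(None, nan)`` when
    fewer than ``min_trials`` trials are available.
    """
    R = np.asarray(trial_rates, dtype=float)
    s = np.asarray(speeds, dtype=float)
    n = R.shape[0]
    if n < min_trials:
        return None, float("nan")
    above = s > np.median(s)
    n_above = int(above.sum())
    if n_above == 0 or n_above == n:
        return None, float("nan")
    w_above, w_below = 1.0 / n_above, 1.0 / (n - n_above)
    obs = np.abs(R[above].mean(axis=0) - R[~above].mean(axis=0))
    rng = np.random.default_rng(seed)
    ranks = rng.random((n_perm, n)).argsort(axis=1).argsort(axis=1)
    group_a = ranks < n_above
    W = np.where(group_a, w_above, -w_below)
    null = np.abs(W @ R)  # n_perm x T
    exceed = (null < obs[None, :]).mean(axis=0)
    significant = exceed >= 1.0 - alpha
    return significant, float(significant.mean())


def speed_split_summary(session: SessionData, aligned_by_condition: dict,
                        first_cycle: int = 2, last_cycle: int = 5,
                        n_perm: int = 1000, alpha: float = 0.05,
                        min_trials: int = 8, seed: int = 0) -> pd.DataFrame:
    """Run the speed-split test for every unit x condition.

    ``aligned_by_condition`` is the output of
    :func:`hemicycle.preprocess.align_session`.  Returns a tidy frame with
    one row per (unit, condition) and the fraction of flagged timepoints;
    the overall flagged fraction is the mean over rows weighted equally by
    timepoint (rows all share the same T).
    """
    from .preprocess import CYCLE_MS
    n_units = len(session.unit_ids)
    rows = []
    root = np.random.SeedSequence(seed)
    streams = iter(root.spawn(len(ALL_CONDITIONS) * n_units))
    for cond in ALL_CONDITIONS:
        aligned = aligned_by_condition.get(cond.label, [])
        if not aligned:
            continue
        speeds_by_trial = nonperforming_speeds(session, cond)
        speeds = np.array([speeds_by_trial[a.trial_id] for a in aligned])
        t = aligned[0].time_ms
        window = (t >= (first_cycle - 1) * CYCLE_MS) & (t < last_cycle * CYCLE_MS)
        stack = np.stack([a.rates[window] for a in aligned])  # trials x T x ch
        for u in range(n_units):
            child = next(streams)
            sig, frac = speed_split_test(
                stack[:, :, u], speeds, n_perm=n_perm, alpha=alpha,
                min_trials=min_trials,
                seed=child.generate_state(1)[0] & 0x7FFFFFFF)
            rows.append({"unit_id": session.unit_ids[u],
                         "condition": cond.label,
                         "flagged_fraction": frac,
                         "n_trials": stack.shape[0]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fano factor


def fano_factor(session: SessionData, window_ms: float = 250.0,
                min_trials: int = 10, through_origin: bool = False,
                return_table: bool = False):
    """Slope of spike-count variance vs mean across units/conditions/windows.

    Counts are taken on unwarped trials in two windows of ``window_ms``
    flanking the moment the performing pedal crosses 3.5 cycles of
    unsigned travel.  Conditions with fewer than ``min_trials`` trials are
    skipped.  The slope comes from an OLS regression of variance on mean
    (free intercept by default); ~1 for Poisson-like counts.
    """
    win_s = window_ms * 1e-3
    half_travel = 3.5
    points = []
    for cond in ALL_CONDITIONS:
        trial_ids = session.trials_of(cond)
        if len(trial_ids) < min_trials:
            continue
        mids = {}
        for tid in trial_ids:
            tr = session.traces[tid]
            t = tr["time_s"].to_numpy()
            angle = tr[f"pedal_{cond.arm}"].to_numpy()
            phi = np.concatenate([[0.0], np.cumsum(np.abs(np.diff(angle)))])
            if phi[-1] < half_travel:
                continue
            mids[tid] = float(np.interp(half_travel, phi, t))
        if len(mids) < min_trials:
            continue
        for unit_id in session.unit_ids:
            pre, post = [], []
            for tid, mid in mids.items():
                st = session.spike_times(unit_id, tid)
                pre.append(np.count_nonzero((st >= mid - win_s) & (st < mid)))
                post.append(np.count_nonzero((st >= mid) & (st < mid + win_s)))
            for name, counts in (("pre", pre), ("post", post)):
                c = np.asarray(counts, dtype=float)
                points.append({"unit_id": unit_id, "condition": cond.label,
                               "window": name, "mean": c.mean(),
                               "var": c.var(ddof=1)})
    if not points:
        raise ValueError("no unit/condition with enough trials")
    table = pd.DataFrame(points)
    x, y = table["mean"].to_numpy(), table["var"].to_numpy()
    if through_origin:
        slope = float((x @ y) / (x @ x))
    else:
        slope = float(np.polyfit(x, y, 1)[0])
    return (slope, table) if return_table else slope


# ---------------------------------------------------------------------------
# Required-magnification solver


def required_magnification(muscle_mods, target_median_api: float,
                           tol: float = 1e-9) -> float:
    """Smallest k >= 1 scaling non-driven modulation so that the median
    muscle arm-preference index drops to ``target_median_api``.

    ``muscle_mods`` is a sequence of (mod_driven, mod_non_driven) pairs.
    The median of (d - k*n)/(d + k*n) is monotonically nonincreasing in k,
    so the solution is found by bisection after doubling an upper bound.
    """
    pairs = np.asarray(list(muscle_mods), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("muscle_mods must be (n, 2) pairs")
    d, n = pairs[:, 0], pairs[:, 1]

    def median_api(k):
        tot = d + k * n
        with np.errstate(invalid="ignore"):
            idx = np.where(tot > 0, (d - k * n) / tot, np.nan)
        return float(np.nanmedian(idx))

    if np.all(n == 0):
        raise ValueError("target unreachable: all non-driven modulations are 0")
    if median_api(1.0) <= target_median_api:
        return 1.0
    lo, hi = 1.0, 2.0
    while median_api(hi) > target_median_api:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("target unreachable within k <= 1e12")
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if median_api(mid) <= target_median_api:
            hi = mid
        else:
            lo = mid
    return float(hi)
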