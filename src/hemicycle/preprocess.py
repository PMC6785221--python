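"""Spike/EMG conditioning, trial alignment, and trial averaging.

Single-trial spike trains are converted to continuous firing rates by
convolution with a 25 ms (SD) Gaussian.  Trials are then aligned onto a
canonical 2 cycles/s time base in two steps: (1) anchor on completion of
the first half-cycle; (2) re-express each rate as a function of unsigned
cumulative pedal angle over the middle six cycles and map angle linearly
onto 0-3000 ms (500 ms per cycle).  Alignment never alters the rate
values, only their time base.  Aligned trials of one condition are
averaged pointwise to give trial-averaged rates with standard errors.

Raw EMG voltage is converted to intensity by 40 Hz high-pass filtering,
rectification, and 25 ms Gaussian smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .conditions import ALL_CONDITIONS, Condition
from .session import SessionData

CYCLE_MS = 500.0  # canonical cycle duration (2 cycles/s)
CANONICAL_MS = 3000.0  # middle six cycles on the canonical time base
FIRST_MIDDLE_ANGLE = 0.5  # cycles of unsigned travel at the alignment anchor
DEFAULT_KERNEL_SD_MS = 25.0
DEFAULT_DT_MS = 10.0  # analysis resolution
SMOOTH_DT_MS = 1.0  # internal smoothing/alignment grid


def gaussian_kernel(sd_ms: float, dt_ms: float) -> np.ndarray:
    """Unit-mass Gaussian kernel truncated at +/- 4 SD, in units of 1/s."""
    if sd_ms <= 0:
        raise ValueError("kernel sd must be > 0")
    half = int(np.ceil(4.0 * sd_ms / dt_ms))
    x = np.arange(-half, half + 1) * dt_ms
    k = np.exp(-0.5 * (x / sd_ms) ** 2)
    return k / (k.sum() * dt_ms * 1e-3)


def smooth_spike_train(spike_times_s, grid_ms, kernel_sd_ms: float = DEFAULT_KERNEL_SD_MS):
    """Convolve a spike train with a Gaussian to get a rate trace (spikes/s).

    ``grid_ms`` must be uniform.  Spikes just outside the grid still
    contribute their tail mass (the grid is padded by 4 SD before
    convolution).  Unsorted spike times are fine.
    """
    grid_ms = np.asarray(grid_ms, dtype=float)
    if grid_ms.size < 2:
        raise ValueError("grid must have at least two points")
    dt = grid_ms[1] - grid_ms[0]
    if not np.allclose(np.diff(grid_ms), dt):
        raise ValueError("grid must be uniform")
    spikes_ms = np.asarray(spike_times_s, dtype=float) * 1e3
    pad = int(np.ceil(4.0 * kernel_sd_ms / dt))
    edges = np.concatenate([grid_ms - dt / 2, [grid_ms[-1] + dt / 2]])
    padded_edges = np.concatenate([
        grid_ms[0] - dt / 2 - dt * np.arange(pad, 0, -1),
        edges,
        grid_ms[-1] + dt / 2 + dt * np.arange(1, pad + 1),
    ])
    counts, _ = np.histogram(spikes_ms, bins=padded_edges)
    kernel = gaussian_kernel(kernel_sd_ms, dt)
    rate = np.convolve(counts.astype(float), kernel, mode="same")
    return rate[pad:rate.size - pad]


def preprocess_emg(raw, fs: float, highpass_hz: float = 40.0,
                   kernel_sd_ms: float = DEFAULT_KERNEL_SD_MS):
    """Raw EMG voltage -> nonnegative intensity trace.

    Zero-phase 4th-order Butterworth high-pass at ``highpass_hz``, then
    rectification, then Gaussian smoothing (SD ``kernel_sd_ms``).
    """
    raw = np.asarray(raw, dtype=float)
    if fs <= 2.0 * highpass_hz:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the {highpass_hz} Hz "
            "high-pass corner")
    sos = signal.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, raw)
    rectified = np.abs(filtered)
    sigma = kernel_sd_ms * 1e-3 * fs
    from scipy.ndimage import gaussian_filter1d
    return gaussian_filter1d(rectified, sigma=sigma, mode="nearest")


def trial_mean_speed(angle_cycles, fs: float) -> float:
    """Mean unsigned angular speed |d(theta)/dt| over a trial, cycles/s."""
    angle = np.asarray(angle_cycles, dtype=float)
    if angle.size < 2:
        return 0.0
    return float(np.mean(np.abs(np.diff(angle)) * fs))


@dataclass
class AlignedTrial:
    """One trial on the canonical 2 cycles/s middle-six-cycle time base."""

    time_ms: np.ndarray  # canonical grid, 0 .. <3000 ms
    rates: np.ndarray  # T x channels
    pedal_angle: np.ndarray  # warped performing-arm angle (cycles)
    trial_id: str
    condition: Condition


def unsigned_cumulative_angle(angle_cycles) -> np.ndarray:
    """Cumulative |delta theta| in cycles; monotone even for backward cycling."""
    angle = np.asarray(angle_cycles, dtype=float)
    return np.concatenate([[0.0], np.cumsum(np.abs(np.diff(angle)))])


def align_trial(rate_traces, pedal_angle, time_ms, condition: Condition,
                trial_id: str = "", dt_ms: float = DEFAULT_DT_MS) -> AlignedTrial:
    """Warp a trial's rate traces onto the canonical middle-six-cycle grid.

    ``rate_traces`` is (T x channels) on the uniform ``time_ms`` grid shared
    with ``pedal_angle`` (performing arm, cycles).  The warp anchors at the
    first crossing of 0.5 cycles of unsigned cumulative travel and maps each
    subsequent cycle of travel onto 500 ms.  Values are interpolated, never
    rescaled.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    rate_traces = np.atleast_2d(np.asarray(rate_traces, dtype=float))
    if rate_traces.shape[0] != time_ms.size:
        rate_traces = rate_traces.T
    phi = unsigned_cumulative_angle(pedal_angle)
    n_middle = CANONICAL_MS / CYCLE_MS
    if phi[-1] < FIRST_MIDDLE_ANGLE + n_middle:
        raise ValueError(
            f"trial {trial_id or '<unnamed>'}: pedal covers only {phi[-1]:.2f} "
            f"cycles; needs {FIRST_MIDDLE_ANGLE + n_middle:.1f} for alignment")
    t_canon = np.arange(0.0, CANONICAL_MS, dt_ms)
    phi_target = FIRST_MIDDLE_ANGLE + t_canon / CYCLE_MS
    # Invert the monotone angle-vs-time curve, then sample every trace there.
    u = np.interp(phi_target, phi, time_ms)
    aligned = np.empty((t_canon.size, rate_traces.shape[1]))
    for j in range(rate_traces.shape[1]):
        aligned[:, j] = np.interp(u, time_ms, rate_traces[:, j])
    pedal_aligned = np.interp(u, time_ms, np.asarray(pedal_angle, dtype=float))
    return AlignedTrial(time_ms=t_canon, rates=aligned,
                        pedal_angle=pedal_aligned, trial_id=trial_id,
                        condition=condition)


def trial_average(aligned_trials):
    """Pointwise mean and standard error across aligned trials of one condition."""
    if len(aligned_trials) == 0:
        raise ValueError("need at least one aligned trial")
    stack = np.stack([at.rates for at in aligned_trials])  # trials x T x ch
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    if n > 1:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    return mean, sem


@dataclass
class RateTensor:
    """Trial-averaged rates (or EMG intensities) on the canonical time base.

    ``values`` and ``sem`` are (time x channel x condition).  ``channels``
    carries per-channel metadata: ``channel_id``, ``kind`` ('unit' or
    'emg'), ``hemisphere`` (units) or ``arm`` (EMG channels).
    """

    values: np.ndarray
    sem: np.ndarray
    time_ms: np.ndarray
    channels: pd.DataFrame
    conditions: list  # condition label strings

    def __post_init__(self):
        if np.any(self.sem < 0):
            raise ValueError("standard errors must be nonnegative")
        dt = np.diff(self.time_ms)
        if self.time_ms.size > 1 and not (np.all(dt > 0)
                                          and np.allclose(dt, dt[0])):
            raise ValueError("time grid must be strictly increasing and uniform")

    @property
    def channel_ids(self):
        return list(self.channels["channel_id"])

    def condition_index(self, condition) -> int:
        label = condition.label if isinstance(condition, Condition) else condition
        return self.conditions.index(label)

    def matrix(self, condition) -> np.ndarray:
        """Time x channel matrix for one condition."""
        return self.values[:, :, self.condition_index(condition)]

    def select_channels(self, mask) -> "RateTensor":
        mask = np.asarray(mask)
        return RateTensor(values=self.values[:, mask, :],
                          sem=self.sem[:, mask, :], time_ms=self.time_ms,
                          channels=self.channels.loc[mask].reset_index(drop=True),
                          conditions=list(self.conditions))

    # -- I/O ------------------------------------------------------------
    def to_hdf5(self, path) -> None:
        # track_times=False keeps reruns byte-identical for manifest hashing
        with h5py.File(path, "w") as f:
            for name, data in (("values", self.values), ("sem", self.sem),
                               ("time_ms", self.time_ms)):
                f.create_dataset(name, data=data, track_times=False)
            f.create_dataset("conditions",
                             data=np.array(self.conditions, dtype="S"),
                             track_times=False)
            grp = f.create_group("channels", track_order=False)
            for col in self.channels.columns:
                grp.create_dataset(
                    col, data=self.channels[col].astype(str).to_numpy(dtype="S"),
                    track_times=False)

    @classmethod
    def from_hdf5(cls, path) -> "RateTensor":
        with h5py.File(path, "r") as f:
            channels = pd.DataFrame({
                col: [v.decode() for v in f["channels"][col][()]]
                for col in f["channels"]})
            return cls(values=f["values"][()], sem=f["sem"][()],
                       time_ms=f["time_ms"][()], channels=channels,
                       conditions=[c.decode() for c in f["conditions"][()]])

    def to_csv(self, path) -> None:
        T, N, C = self.values.shape
        df = pd.DataFrame({
            "time_ms": np.tile(np.repeat(self.time_ms, N), C),
            "channel_id": np.tile(self.channel_ids, T * C),
            "condition": np.repeat(self.conditions, T * N),
            "value": self.values.transpose(2, 0, 1).ravel(),
            "sem": self.sem.transpose(2, 0, 1).ravel(),
        })
        df.to_csv(path, index=False, float_format="%.8g")


def extract_middle_cycles(tensor: RateTensor, first_cycle: int = 2,
                          last_cycle: int = 5,
                          phase_offset: float = 0.0) -> RateTensor:
    """Slice the canonical tensor to a contiguous cycle window.

    Cycle ``c`` occupies ``[(c-1)*500, c*500)`` ms; ``phase_offset`` (cycles)
    shifts the window, e.g. ``-0.5`` gives cycles 1.5-4.5.  The requested
    window must lie inside the canonical six middle cycles.
    """
    if first_cycle > last_cycle:
        raise ValueError("first_cycle must be <= last_cycle")
    lo_ms = (first_cycle - 1 + phase_offset) * CYCLE_MS
    hi_ms = (last_cycle + phase_offset) * CYCLE_MS
    if lo_ms < 0 or hi_ms > CANONICAL_MS:
        raise ValueError(
            f"window [{lo_ms}, {hi_ms}) ms lies outside the canonical "
            f"[0, {CANONICAL_MS}) ms range")
    mask = (tensor.time_ms >= lo_ms - 1e-9) & (tensor.time_ms < hi_ms - 1e-9)
    return RateTensor(values=tensor.values[mask], sem=tensor.sem[mask],
                      time_ms=tensor.time_ms[mask], channels=tensor.channels,
                      conditions=list(tensor.conditions))


# ---------------------------------------------------------------------------
# Session-level driver


def _smooth_trial_rates(spikes_by_unit: dict, unit_ids, grid_ms: np.ndarray,
                        kernel_sd_ms: float) -> np.ndarray:
    """Smoothed rates (T x units) for one trial, batched over units.

    ``spikes_by_unit`` maps unit_id -> spike times (s) on this trial.
    """
    dt = grid_ms[1] - grid_ms[0]
    pad = int(np.ceil(4.0 * kernel_sd_ms / dt))
    edges = np.concatenate([
        grid_ms[0] - dt / 2 - dt * np.arange(pad, 0, -1),
        grid_ms - dt / 2, [grid_ms[-1] + dt / 2],
        grid_ms[-1] + dt / 2 + dt * np.arange(1, pad + 1)])
    counts = np.zeros((len(unit_ids), edges.size - 1))
    for i, unit_id in enumerate(unit_ids):
        st = spikes_by_unit.get(unit_id)
        if st is not None and len(st):
            counts[i], _ = np.histogram(np.asarray(st) * 1e3, bins=edges)
    kernel = gaussian_kernel(kernel_sd_ms, dt)
    rates = signal.fftconvolve(counts, kernel[None, :], mode="same", axes=1)
    rates = np.maximum(rates, 0.0)  # fft round-off can dip below zero
    return rates[:, pad:counts.shape[1] - pad].T


def align_session(session: SessionData,
                  kernel_sd_ms: float = DEFAULT_KERNEL_SD_MS,
                  dt_ms: float = DEFAULT_DT_MS):
    """Smooth and align every trial.

    Returns ``(by_condition, channels)`` where ``by_condition`` maps a
    condition label to the list of AlignedTrial (channel axis = all units
    then all EMG channels) and ``channels`` is the channel-metadata frame.
    """
    emg_cols = session.emg_channels
    unit_meta = pd.DataFrame({
        "channel_id": session.unit_ids,
        "kind": "unit",
        "group": session.units["hemisphere"].to_numpy(),
    })
    emg_meta = pd.DataFrame({
        "channel_id": emg_cols,
        "kind": "emg",
        "group": [c.split("_")[1] for c in emg_cols],
    })
    channels = pd.concat([unit_meta, emg_meta], ignore_index=True)

    spikes_by_trial = {
        trial_id: {uid: grp["spike_time_s"].to_numpy()
                   for uid, grp in sub.groupby("unit_id", sort=False)}
        for trial_id, sub in session.spikes.groupby("trial_id", sort=False)
    }
    unit_ids = session.unit_ids
    by_condition = {c.label: [] for c in ALL_CONDITIONS}
    for _, row in session.trials.iterrows():
        trial_id = row["trial_id"]
        cond = Condition.from_label(row["condition"])
        tr = session.traces[trial_id]
        t_trace_ms = tr["time_s"].to_numpy() * 1e3
        grid_ms = np.arange(0.0, t_trace_ms[-1] + SMOOTH_DT_MS / 2, SMOOTH_DT_MS)
        rates = _smooth_trial_rates(spikes_by_trial.get(trial_id, {}),
                                    unit_ids, grid_ms, kernel_sd_ms)
        pedal = np.interp(grid_ms, t_trace_ms,
                          tr[f"pedal_{cond.arm}"].to_numpy())
        emg = np.column_stack([
            np.interp(grid_ms, t_trace_ms, tr[c].to_numpy()) for c in emg_cols
        ]) if emg_cols else np.empty((grid_ms.size, 0))
        traces = np.column_stack([rates, emg])
        aligned = align_trial(traces, pedal, grid_ms, cond,
                              trial_id=trial_id, dt_ms=dt_ms)
        by_condition[cond.label].append(aligned)
    return by_condition, channels


def compute_rate_tensors(session: SessionData,
                         kernel_sd_ms: float = DEFAULT_KERNEL_SD_MS,
                         dt_ms: float = DEFAULT_DT_MS):
    """Session -> (neural RateTensor, EMG RateTensor) on the canonical grid."""
    by_condition, channels = align_session(session, kernel_sd_ms, dt_ms)
    labels = [c.label for c in ALL_CONDITIONS if by_condition[c.label]]
    first = by_condition[labels[0]][0]
    T = first.time_ms.size
    n_ch = channels.shape[0]
    values = np.zeros((T, n_ch, len(labels)))
    sems = np.zeros_like(values)
    for k, label in enumerate(labels):
        mean, sem = trial_average(by_condition[label])
        values[:, :, k] = mean
        sems[:, :, k] = sem
    tensor = RateTensor(values=values, sem=sems, time_ms=first.time_ms,
                        channels=channels, conditions=labels)
    is_unit = (channels["kind"] == "unit").to_numpy()
    neural = tensor.select_channels(is_unit)
    neural.channels = neural.channels.rename(columns={"group": "hemisphere"})
    emg = tensor.select_channels(~is_unit)
    emg.channels = emg.channels.rename(columns={"group": "arm"})
    return neural, emg
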