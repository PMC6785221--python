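"""Synthetic session generator with full ground truth.

Generates recording sessions with the statistical structure the downstream
analyses assume, so that every stage has a recovery test:

- 8 unimanual conditions (2 performing arms x 2 cycling directions x 2
  starting pedal positions), 7-cycle trials near 2 cycles/s with
  trial-to-trial speed jitter;
- rhythmic latent signals per condition (cycle fundamental plus one
  harmonic, random phases per condition and latent);
- a left-arm and a right-arm latent basis over the unified two-hemisphere
  population, with configurable principal angles between them
  (``subspace_overlap``);
- per-unit mixed lateralization: every unit responds for both arms, with a
  configurable contralateral bias (``lateralization``);
- Poisson spiking with intensity = baseline + gain x mixed latents
  (rectified at zero);
- EMG as a rectified linear readout of the performing arm's latents plus
  noise, optional weak end-of-movement activity in the non-performing arm;
- a nearly stationary non-performing pedal whose small wiggles can be
  coupled to firing (``speed_coupling``) to exercise the speed-split
  control.

A single root seed derives a child stream for every stochastic sub-step, so
identical configs give byte-identical sessions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .conditions import ALL_CONDITIONS, Condition, driven_arm
from .session import SessionData

SPIKE_DT_S = 0.001  # intensity grid for Poisson thinning


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    Defaults emulate the study conditions the analyses assume: ~2 Hz
    cycling with modest trial-to-trial speed jitter, 7-cycle trials,
    mixed lateralization with a mild contralateral bias, and nearly
    orthogonal left-arm/right-arm latent subspaces.
    """

    n_units_per_hemisphere: int = 60
    n_muscles_per_arm: int = 6
    n_trials_per_condition: int = 20
    cycle_rate_mean: float = 2.0  # cycles/s
    cycle_rate_sd: float = 0.12  # cycles/s
    n_cycles: int = 7
    lateralization: float = 0.2  # 0 = arm-independent mixing, 1 = driven only
    subspace_overlap: float = 0.1  # cos of every principal angle between bases
    latent_dim_per_arm: int = 4
    harmonic_weight: float = 0.3
    baseline_rate: float = 30.0  # spikes/s
    rate_gain: float = 10.0  # spikes/s per unit latent deviation
    nonperforming_jitter_amplitude: float = 0.01  # cycles
    emg_noise_sd: float = 0.02  # intensity units
    stopping_emg_amplitude: float = 0.1  # non-performing-arm EMG at stop
    speed_coupling: float = 0.0  # couples non-performing speed to firing
    seed: int = 0
    fs: float = 200.0  # trace sampling rate, Hz
    hold_s: float = 0.3  # stationary hold before/after movement

    def validate(self) -> None:
        counts = ("n_units_per_hemisphere", "n_muscles_per_arm",
                  "n_trials_per_condition", "n_cycles", "latent_dim_per_arm")
        for name in counts:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        nonneg = ("cycle_rate_sd", "harmonic_weight", "baseline_rate",
                  "rate_gain", "nonperforming_jitter_amplitude",
                  "emg_noise_sd", "stopping_emg_amplitude", "speed_coupling",
                  "hold_s")
        for name in nonneg:
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("lateralization", "subspace_overlap"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if not (math.isfinite(self.cycle_rate_mean) and self.cycle_rate_mean > 0):
            raise ValueError(
                f"cycle_rate_mean must be finite and > 0, got {self.cycle_rate_mean!r}")
        if not (math.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"fs must be finite and > 0, got {self.fs!r}")
        n_units = 2 * self.n_units_per_hemisphere
        if n_units < 2 * self.latent_dim_per_arm:
            raise ValueError(
                "n_units_per_hemisphere too small for latent_dim_per_arm: "
                f"need >= {self.latent_dim_per_arm} units per hemisphere")


@dataclass
class SyntheticGroundTruth:
    """Generator internals enabling recovery tests downstream.

    ``left_arm_basis`` / ``right_arm_basis`` are orthonormal
    (units x latent_dim) column sets over the unified population; the
    cosine of every principal angle between them equals
    ``config.subspace_overlap``.
    """

    left_arm_basis: np.ndarray
    right_arm_basis: np.ndarray
    unit_gains: pd.DataFrame  # unit_id, hemisphere, gain_left_arm, gain_right_arm
    muscle_weights: dict  # arm -> (n_muscles x latent_dim) readout weights
    muscle_offsets: dict  # arm -> (n_muscles,) readout offsets
    condition_phases: dict  # label -> latent mixing matrix (see _latents)
    trial_speeds: dict  # trial_id -> performing-arm speed (cycles/s)
    config: GeneratorConfig

    def basis_for_arm(self, arm: str) -> np.ndarray:
        return self.left_arm_basis if arm == "left" else self.right_arm_basis

    def save(self, directory) -> None:
        directory = Path(directory)
        doc = {
            "left_arm_basis": self.left_arm_basis.tolist(),
            "right_arm_basis": self.right_arm_basis.tolist(),
            "unit_gains": self.unit_gains.to_dict(orient="records"),
            "muscle_weights": {a: w.tolist() for a, w in self.muscle_weights.items()},
            "muscle_offsets": {a: o.tolist() for a, o in self.muscle_offsets.items()},
            "condition_phases": {k: v.tolist() for k, v in self.condition_phases.items()},
            "trial_speeds": self.trial_speeds,
            "config": asdict(self.config),
        }
        (directory / "ground_truth.json").write_text(
            json.dumps(doc, sort_keys=True))

    @classmethod
    def load(cls, directory) -> "SyntheticGroundTruth":
        doc = json.loads((Path(directory) / "ground_truth.json").read_text())
        return cls(
            left_arm_basis=np.asarray(doc["left_arm_basis"]),
            right_arm_basis=np.asarray(doc["right_arm_basis"]),
            unit_gains=pd.DataFrame(doc["unit_gains"]),
            muscle_weights={a: np.asarray(w) for a, w in doc["muscle_weights"].items()},
            muscle_offsets={a: np.asarray(o) for a, o in doc["muscle_offsets"].items()},
            condition_phases={k: np.asarray(v) for k, v in doc["condition_phases"].items()},
            trial_speeds=doc["trial_speeds"],
            config=GeneratorConfig(**doc["config"]),
        )


def principal_angles(basis_a: np.ndarray, basis_b: np.ndarray) -> np.ndarray:
    """Principal angles (degrees, ascending) between two orthonormal bases.

    Computed from the singular values of ``basis_a.T @ basis_b``.  Identical
    bases give all zeros; bases spanning orthogonal subspaces give all 90.
    """
    a = np.asarray(basis_a, dtype=float)
    b = np.asarray(basis_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("bases must be 2-D with the same ambient dimension")
    for name, m in (("basis_a", a), ("basis_b", b)):
        gram = m.T @ m
        if not np.allclose(gram, np.eye(m.shape[1]), atol=1e-8):
            raise ValueError(f"{name} is not orthonormal")
    sv = np.linalg.svd(a.T @ b, compute_uv=False)
    angles = np.degrees(np.arccos(np.clip(sv, -1.0, 1.0)))
    return np.sort(angles)


def _orthonormal_pair(n_units: int, dim: int, overlap: float,
                      rng: np.random.Generator):
    """Two orthonormal n x dim bases with all principal-angle cosines == overlap."""
    q, _ = np.linalg.qr(rng.standard_normal((n_units, 2 * dim)))
    left = q[:, :dim]
    right = overlap * q[:, :dim] + math.sqrt(1.0 - overlap**2) * q[:, dim:2 * dim]
    return left, right


def _latents(phase_cycles: np.ndarray, mixer: np.ndarray,
             harmonic_weight: float) -> np.ndarray:
    """Latent time courses (T x d).

    Each latent is a mixture of the quadrature pair at the cycle
    fundamental and (scaled by ``harmonic_weight``) the pair at its first
    harmonic: z(t) = Q [cos, sin, h cos2, h sin2]^T.  With an orthogonal
    mixer Q the temporal spectrum of the latent set is exactly
    (1, 1, h, h)/sqrt(2), i.e. two strong and two weak directions whose
    balance never degenerates for unlucky phase draws.
    """
    th = 2.0 * np.pi * phase_cycles
    quad = np.column_stack([
        np.cos(th), np.sin(th),
        harmonic_weight * np.cos(2.0 * th),
        harmonic_weight * np.sin(2.0 * th)])
    return quad @ mixer.T


def _random_mixer(d: int, rng: np.random.Generator) -> np.ndarray:
    """d x 4 mixing matrix with orthonormal rows (d < 4) or columns (d >= 4)."""
    k = max(d, 4)
    q, _ = np.linalg.qr(rng.standard_normal((k, k)))
    return q[:, :4] if d >= 4 else q[:4, :4][:d, :]


def _draw_truncnorm(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def generate_session(config: GeneratorConfig):
    """Generate one synthetic session plus its ground truth.

    Returns
    -------
    (SessionData, SyntheticGroundTruth)
    """
    config.validate()
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    ss_bases, ss_gains, ss_muscles, ss_phases, ss_trials = root.spawn(5)

    n_units = 2 * cfg.n_units_per_hemisphere
    d = cfg.latent_dim_per_arm

    left_basis, right_basis = _orthonormal_pair(
        n_units, d, cfg.subspace_overlap, np.random.default_rng(ss_bases))

    # Per-unit arm gains: independent random magnitudes for the driven and
    # non-driven arm, the latter attenuated by the lateralization parameter.
    rng_g = np.random.default_rng(ss_gains)
    unit_ids = [f"u{i:04d}" for i in range(n_units)]
    hemispheres = (["left"] * cfg.n_units_per_hemisphere
                   + ["right"] * cfg.n_units_per_hemisphere)
    g_driven = rng_g.uniform(0.2, 1.0, size=n_units)
    g_nondriven = (1.0 - cfg.lateralization) * rng_g.uniform(0.2, 1.0, size=n_units)
    gain_left_arm = np.where([driven_arm(h) == "left" for h in hemispheres],
                             g_driven, g_nondriven)
    gain_right_arm = np.where([driven_arm(h) == "right" for h in hemispheres],
                              g_driven, g_nondriven)
    unit_gains = pd.DataFrame({
        "unit_id": unit_ids, "hemisphere": hemispheres,
        "gain_left_arm": gain_left_arm, "gain_right_arm": gain_right_arm,
    })

    # Muscle readouts: random directions over the latents with a bounded
    # row norm, so every muscle is robustly modulated (recordings with weak
    # signals would not have been kept), and offsets low enough that
    # rectification clips a substantial lower tail (muscle activity is a
    # nonlinear, nonnegative readout).
    rng_m = np.random.default_rng(ss_muscles)
    muscle_weights = {}
    muscle_offsets = {}
    for arm in ("left", "right"):
        W = rng_m.standard_normal((cfg.n_muscles_per_arm, d))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        W *= rng_m.uniform(0.8, 1.4, size=(cfg.n_muscles_per_arm, 1))
        muscle_weights[arm] = W
        muscle_offsets[arm] = rng_m.uniform(0.4, 0.9,
                                            size=cfg.n_muscles_per_arm)

    # Latents are functions of absolute pedal phase with mixing drawn per
    # (arm, direction): the two start positions of an arm/direction pair then
    # share the same response pattern up to the half-cycle offset, as in the
    # task, while forward/backward and left/right patterns are unrelated.
    rng_p = np.random.default_rng(ss_phases)
    mixer_sets = {
        (arm, direction): _random_mixer(d, rng_p)
        for arm in ("left", "right")
        for direction in ("forward", "backward")
    }
    condition_phases = {
        c.label: mixer_sets[(c.arm, c.direction)] for c in ALL_CONDITIONS
    }

    # Trial bookkeeping; two child streams per trial (kinematics, noise) so
    # the two generation passes stay independent and reorder-proof.
    trial_rows = []
    trial_defs = []
    idx = 0
    for cond in ALL_CONDITIONS:
        for _ in range(cfg.n_trials_per_condition):
            trial_defs.append((f"t{idx:04d}", cond))
            idx += 1
    kin_streams = ss_trials.spawn(2 * len(trial_defs))

    lo = max(0.2, cfg.cycle_rate_mean - 3 * cfg.cycle_rate_sd)
    hi = cfg.cycle_rate_mean + 3 * cfg.cycle_rate_sd

    # ---- pass 1: kinematics ------------------------------------------
    kinematics = {}
    for k, (trial_id, cond) in enumerate(trial_defs):
        rng_k = np.random.default_rng(kin_streams[2 * k])
        speed = _draw_truncnorm(rng_k, cfg.cycle_rate_mean, cfg.cycle_rate_sd,
                                lo, hi)
        move_s = cfg.n_cycles / speed
        total_s = cfg.hold_s + move_s + cfg.hold_s
        n_samp = int(round(total_s * cfg.fs)) + 1
        t = np.arange(n_samp) / cfg.fs

        tau = np.clip(t - cfg.hold_s, 0.0, move_s)
        theta0 = 0.0 if cond.start == "top" else 0.5
        sign = 1.0 if cond.direction == "forward" else -1.0
        theta_perf = theta0 + sign * speed * tau

        # Non-performing pedal: smooth wiggle about the bottom of the cycle,
        # amplitude-limited, active only during movement.
        moving = ((t >= cfg.hold_s) & (t <= cfg.hold_s + move_s)).astype(float)
        env = gaussian_filter1d(moving, sigma=0.05 * cfg.fs, mode="nearest")
        noise = gaussian_filter1d(rng_k.standard_normal(n_samp),
                                  sigma=0.15 * cfg.fs, mode="nearest")
        peak = np.max(np.abs(noise))
        if peak > 0:
            noise = noise / peak
        scale = rng_k.uniform(0.25, 1.0)
        jitter = cfg.nonperforming_jitter_amplitude * scale * noise * env
        theta_np = 0.5 + jitter

        np_speed = float(np.mean(np.abs(np.diff(theta_np)) * cfg.fs))
        kinematics[trial_id] = dict(
            t=t, speed=speed, theta_perf=theta_perf, theta_np=theta_np,
            moving_env=env, np_speed=np_speed, move_s=move_s)
        trial_rows.append({"trial_id": trial_id, "condition": cond.label,
                           "speed_cps": speed, "np_speed_cps": np_speed})

    trials = pd.DataFrame(trial_rows)

    # Standardized non-performing speed within condition (for speed coupling).
    s_tilde = {}
    for cond in ALL_CONDITIONS:
        ids = [tid for tid, c in trial_defs if c == cond]
        s = np.array([kinematics[tid]["np_speed"] for tid in ids])
        sd = s.std()
        z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
        s_tilde.update(dict(zip(ids, z)))

    # ---- pass 2: spikes and EMG --------------------------------------
    sqrt_n = math.sqrt(n_units)
    spike_rows = {"unit_id": [], "trial_id": [], "spike_time_s": []}
    traces = {}
    for k, (trial_id, cond) in enumerate(trial_defs):
        rng_n = np.random.default_rng(kin_streams[2 * k + 1])
        kin = kinematics[trial_id]
        t = kin["t"]
        basis = left_basis if cond.arm == "left" else right_basis
        gains = gain_left_arm if cond.arm == "left" else gain_right_arm
        phases = condition_phases[cond.label]

        # Dense grid for spike intensities.
        t_dense = np.arange(0.0, t[-1] + SPIKE_DT_S / 2, SPIKE_DT_S)
        tau_d = np.clip(t_dense - cfg.hold_s, 0.0, kin["move_s"])
        theta0 = 0.0 if cond.start == "top" else 0.5
        sign = 1.0 if cond.direction == "forward" else -1.0
        phase_d = theta0 + sign * kin["speed"] * tau_d
        env_d = np.interp(t_dense, t, kin["moving_env"])

        z = _latents(phase_d, phases, cfg.harmonic_weight)  # T x d
        mixed = z @ basis.T  # T x n_units
        mod_gain = 1.0 + cfg.speed_coupling * s_tilde[trial_id]
        rates = (cfg.baseline_rate
                 + cfg.rate_gain * mod_gain * sqrt_n
                 * (env_d[:, None] * mixed) * gains[None, :])
        np.maximum(rates, 0.0, out=rates)

        counts = rng_n.poisson(rates * SPIKE_DT_S)  # T x n_units
        for u in range(n_units):
            nz = np.nonzero(counts[:, u])[0]
            if nz.size == 0:
                continue
            reps = counts[nz, u]
            starts = np.repeat(t_dense[nz], reps)
            times = starts + rng_n.uniform(0.0, SPIKE_DT_S, size=starts.size)
            times.sort()
            spike_rows["unit_id"].extend([unit_ids[u]] * times.size)
            spike_rows["trial_id"].extend([trial_id] * times.size)
            spike_rows["spike_time_s"].extend(times.tolist())

        # EMG intensities on the trace grid.
        z_tr = _latents(
            theta0 + sign * kin["speed"] * np.clip(t - cfg.hold_s, 0.0, kin["move_s"]),
            phases, cfg.harmonic_weight)
        env_tr = kin["moving_env"]
        tr = pd.DataFrame({"time_s": t})
        tr["pedal_left"] = kin["theta_perf"] if cond.arm == "left" else kin["theta_np"]
        tr["pedal_right"] = kin["theta_perf"] if cond.arm == "right" else kin["theta_np"]
        stop_center = cfg.hold_s + kin["move_s"]
        stop_bump = np.exp(-0.5 * ((t - stop_center) / 0.15) ** 2)
        for arm in ("left", "right"):
            W = muscle_weights[arm]
            off = muscle_offsets[arm]
            if arm == cond.arm:
                drive = np.maximum(off[None, :] + z_tr @ W.T, 0.0) * env_tr[:, None]
            else:
                drive = cfg.stopping_emg_amplitude * stop_bump[:, None] * \
                    np.abs(off)[None, :]
            drive = drive + cfg.emg_noise_sd * \
                rng_n.standard_normal(drive.shape)
            np.maximum(drive, 0.0, out=drive)
            for m in range(cfg.n_muscles_per_arm):
                tr[f"emg_{arm}_{m}"] = drive[:, m]
        traces[trial_id] = tr

    spikes = pd.DataFrame(spike_rows)
    units = pd.DataFrame({"unit_id": unit_ids, "hemisphere": hemispheres})
    session = SessionData(
        units=units, trials=trials, spikes=spikes, traces=traces, fs=cfg.fs,
        meta={"generator": asdict(cfg)})
    truth = SyntheticGroundTruth(
        left_arm_basis=left_basis, right_arm_basis=right_basis,
        unit_gains=unit_gains, muscle_weights=muscle_weights,
        muscle_offsets=muscle_offsets, condition_phases=condition_phases,
        trial_speeds={tid: kinematics[tid]["speed"] for tid, _ in trial_defs},
        config=cfg)
    return session, truth


def save_session(session: SessionData, truth: SyntheticGroundTruth,
                 directory) -> None:
    """Write a session directory including ground truth."""
    directory = Path(directory)
    session.save(directory)
    truth.save(directory)
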