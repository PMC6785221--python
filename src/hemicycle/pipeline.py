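"""End-to-end orchestration: simulate -> preprocess -> unit stats ->
population geometry -> decoding, from a single config, with a manifest and
a machine-readable summary.

Every analysis default that matters (25 ms kernel, soft-norm c=5, 8
tangling dimensions, eps = 10% of variance, 1000 permutations, 100
hemisphere shuffles, middle cycles 2-5) appears explicitly in the config so
that deviations are visible in config diffs.  Reruns with an identical
config are byte-identical, manifest hashes included.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decoding, geometry, unit_stats
from .preprocess import RateTensor, align_session, compute_rate_tensors
from .session import SessionData
from .synthetic import GeneratorConfig, generate_session, save_session

log = logging.getLogger("hemicycle")

STAGES = ("simulate", "preprocess", "unit_stats", "population", "decoding")


@dataclass
class AnalysisParams:
    """Analysis parameters shared across stages (units noted per field)."""

    kernel_sd_ms: float = 25.0  # spike/EMG smoothing SD
    dt_ms: float = 10.0  # analysis resolution
    first_cycle: int = 2
    last_cycle: int = 5
    softnorm_c: float = 5.0  # spikes/s
    n_pcs: int = 5  # PCs for capture summaries / weight histograms
    tangling_dims: int = 8
    tangling_eps_fraction: float = 0.10
    speed_split_permutations: int = 1000
    speed_split_alpha: float = 0.05
    speed_split_min_trials: int = 8
    correlation_shuffles: int = 1000
    hemisphere_shuffles: int = 100
    pcr_rank: int = 10
    fano_window_ms: float = 250.0
    fano_min_trials: int = 10
    magnification_target: float | None = None  # default: median unit API


@dataclass
class RunConfig:
    """Full run description; round-trips losslessly through YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    session_dir: str | None = None  # load instead of simulating when set
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    out_dir: str = "hemicycle_out"
    seed: int = 0

    def __post_init__(self):
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        merged = {s: True for s in STAGES}
        merged.update(self.stages)
        self.stages = merged

    def to_yaml(self, path) -> None:
        doc = {"generator": asdict(self.generator),
               "analysis": asdict(self.analysis),
               "session_dir": self.session_dir,
               "stages": dict(self.stages),
               "out_dir": str(self.out_dir), "seed": self.seed}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(generator=GeneratorConfig(**doc.get("generator", {})),
                   analysis=AnalysisParams(**doc.get("analysis", {})),
                   session_dir=doc.get("session_dir"),
                   stages=doc.get("stages", {}),
                   out_dir=doc.get("out_dir", "hemicycle_out"),
                   seed=int(doc.get("seed", 0)))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed below 2**31."""
        idx = STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(STAGES))[idx]
        return int(child.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# helpers


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


def _write_csv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.8g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _session_dir(config: RunConfig) -> Path:
    if config.session_dir:
        return Path(config.session_dir)
    return Path(config.out_dir) / "session"


def _load_tensors(config: RunConfig):
    base = Path(config.out_dir) / "tensors"
    return (RateTensor.from_hdf5(base / "neural.h5"),
            RateTensor.from_hdf5(base / "emg.h5"))


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig):
    gen = dataclasses.replace(config.generator, seed=config.stage_seed("simulate"))
    session, truth = generate_session(gen)
    out = Path(config.out_dir) / "session"
    save_session(session, truth, out)
    log.info("simulate: %d units, %d trials, %d spikes -> %s",
             len(session.unit_ids), len(session.trials),
             len(session.spikes), out)
    return [out / "session.json", out / "spikes.csv", out / "traces.csv",
            out / "ground_truth.json"]


def stage_preprocess(config: RunConfig):
    session = SessionData.load(_session_dir(config))
    p = config.analysis
    neural, emg = compute_rate_tensors(session, kernel_sd_ms=p.kernel_sd_ms,
                                       dt_ms=p.dt_ms)
    out = Path(config.out_dir) / "tensors"
    out.mkdir(parents=True, exist_ok=True)
    neural.to_hdf5(out / "neural.h5")
    emg.to_hdf5(out / "emg.h5")
    neural.to_csv(out / "neural.csv")
    emg.to_csv(out / "emg.csv")
    log.info("preprocess: %d conditions x %d samples, %d neural + %d EMG channels",
             len(neural.conditions), neural.time_ms.size,
             neural.values.shape[1], emg.values.shape[1])
    return [out / "neural.h5", out / "emg.h5", out / "neural.csv",
            out / "emg.csv"]


def stage_unit_stats(config: RunConfig):
    p = config.analysis
    seed = config.stage_seed("unit_stats")
    session = SessionData.load(_session_dir(config))
    neural, emg = _load_tensors(config)
    out = Path(config.out_dir) / "unit_stats"
    out.mkdir(parents=True, exist_ok=True)

    units = unit_stats.unit_table(neural)
    muscles = unit_stats.muscle_table(emg)
    _write_csv(out / "unit_table.csv", units)
    _write_csv(out / "muscle_table.csv", muscles)

    observed, null, pval = unit_stats.shuffle_null_mean_correlation(
        neural, n_resamples=p.correlation_shuffles, seed=seed)
    meta = unit_stats.session_meta_correlation(neural)

    aligned, _ = align_session(session, kernel_sd_ms=p.kernel_sd_ms,
                               dt_ms=p.dt_ms)
    speed = unit_stats.speed_split_summary(
        session, aligned, first_cycle=p.first_cycle, last_cycle=p.last_cycle,
        n_perm=p.speed_split_permutations, alpha=p.speed_split_alpha,
        min_trials=p.speed_split_min_trials, seed=seed + 1)
    _write_csv(out / "speed_split.csv", speed)

    try:
        fano = unit_stats.fano_factor(session, window_ms=p.fano_window_ms,
                                      min_trials=p.fano_min_trials)
    except ValueError:
        fano = None

    target = p.magnification_target
    if target is None:
        target = float(units["arm_preference"].median())
    pairs = muscles[["modulation_driven", "modulation_non_driven"]].to_numpy()
    try:
        magnification = unit_stats.required_magnification(pairs, target)
    except ValueError:
        magnification = None

    _write_json(out / "summary_stats.json", {
        "mean_arm_correlation": observed,
        "arm_correlation_null_mean": float(np.mean(null)),
        "arm_correlation_p": pval,
        "meta_correlation": meta,
        "speed_split_flagged_fraction":
            float(speed["flagged_fraction"].mean()) if len(speed) else None,
        "fano_slope": fano,
        "required_magnification": magnification,
        "magnification_target": target,
    })
    log.info("unit_stats: %d units, %d muscles, flagged %.4f",
             len(units), len(muscles),
             speed["flagged_fraction"].mean() if len(speed) else float("nan"))
    return [out / "unit_table.csv", out / "muscle_table.csv",
            out / "speed_split.csv", out / "summary_stats.json"]


def stage_population(config: RunConfig):
    p = config.analysis
    neural, emg = _load_tensors(config)
    out = Path(config.out_dir) / "population"
    out.mkdir(parents=True, exist_ok=True)

    sweep = geometry.triplet_sweep(neural, n_pcs=p.n_pcs,
                                   softnorm_c=p.softnorm_c)
    _write_csv(out / "capture_curves.csv", sweep.curves)
    _write_csv(out / "capture_summary.csv", sweep.summary)

    weight_rows = []
    for arm in ("left", "right"):
        dists, medians = geometry.contribution_weight_distributions(
            neural, arm, n_pcs=p.n_pcs, softnorm_c=p.softnorm_c)
        for hemi, vals in dists.items():
            weight_rows.append({"arm_subspace": arm, "hemisphere": hemi,
                                "median_abs_weight": medians[hemi],
                                "n_weights": int(vals.size)})
    _write_csv(out / "contribution_weights.csv", pd.DataFrame(weight_rows))

    params = geometry.TanglingParams(n_dims=p.tangling_dims,
                                     epsilon_fraction=p.tangling_eps_fraction,
                                     dt_s=p.dt_ms * 1e-3)
    comparison = geometry.tangling_comparison(neural, emg, params)
    rows = []
    for group, values in comparison.distributions.items():
        for q in values:
            rows.append({"group": group, "Q": q})
    _write_csv(out / "tangling.csv", pd.DataFrame(rows))
    _write_csv(out / "tangling_summary.csv", comparison.summary)
    log.info("population: same-arm %.3f / opposite-arm %.3f at %d PCs",
             sweep.capture_at("same_arm").mean(),
             sweep.capture_at("opposite_arm").mean(), p.n_pcs)
    return [out / "capture_curves.csv", out / "capture_summary.csv",
            out / "contribution_weights.csv", out / "tangling.csv",
            out / "tangling_summary.csv"]


def stage_decoding(config: RunConfig):
    p = config.analysis
    seed = config.stage_seed("decoding")
    neural, emg = _load_tensors(config)
    out = Path(config.out_dir) / "decoding"
    out.mkdir(parents=True, exist_ok=True)

    cross = decoding.cross_hemisphere_muscle_decode(neural, emg)
    _write_csv(out / "cross_hemisphere_r2.csv", cross)

    shuffle = decoding.hemisphere_shuffle_test(
        neural, rank=p.pcr_rank, n_resamples=p.hemisphere_shuffles, seed=seed)
    _write_json(out / "hemisphere_shuffle.json", {
        "observed_gap": shuffle["observed_gap"],
        "null_mean": float(np.mean(shuffle["null"])),
        "null_q95": float(np.quantile(shuffle["null"], 0.95)),
        "p": shuffle["p"], "significant": shuffle["significant"],
        "rank": p.pcr_rank, "n_resamples": p.hemisphere_shuffles})

    files = [out / "cross_hemisphere_r2.csv", out / "hemisphere_shuffle.json"]
    for strategy in ("train_performing", "train_both"):
        res = decoding.wrong_arm_generalization(neural, emg, strategy)
        _write_csv(out / f"wrong_arm_{strategy}_modulation.csv", res.modulation)
        _write_csv(out / f"wrong_arm_{strategy}_api.csv", res.arm_preference)
        files += [out / f"wrong_arm_{strategy}_modulation.csv",
                  out / f"wrong_arm_{strategy}_api.csv"]
    log.info("decoding: median driving R2 %.3f",
             cross[cross.source == "driving"]["r2"].median())
    return files


_STAGE_FUNCS = {"simulate": stage_simulate, "preprocess": stage_preprocess,
                "unit_stats": stage_unit_stats, "population": stage_population,
                "decoding": stage_decoding}


def run_all(config: RunConfig) -> dict:
    """Run the enabled stages in order and write a hashed manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    produced = {}
    for stage in STAGES:
        if stage == "simulate" and config.session_dir:
            continue
        if not config.stages.get(stage, True):
            continue
        try:
            files = _STAGE_FUNCS[stage](config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        produced[stage] = [str(f.relative_to(out)) if f.is_relative_to(out)
                           else str(f) for f in files]
    manifest = {
        "stages": produced,
        "files": {f: _sha256(out / f) if (out / f).exists() else None
                  for files in produced.values() for f in files},
        "seed": config.seed,
    }
    _write_json(out / "manifest.json", manifest)
    return manifest


# ---------------------------------------------------------------------------
# summary


def _maybe(path: Path, reader):
    try:
        return reader(path) if path.exists() else None
    except Exception:
        return None


def summarize(out_dir) -> dict:
    """Collapse a report bundle into one JSON-able summary document.

    Missing stage outputs are reported as nulls, not failures.
    """
    out = Path(out_dir)
    summary = {
        "median_unit_arm_preference": None,
        "median_muscle_arm_preference": None,
        "median_decoded_arm_preference": None,
        "median_arm_correlation": None,
        "median_startpos_correlation": None,
        "meta_correlation": None,
        "speed_split_flagged_fraction": None,
        "fano_slope": None,
        "required_magnification": None,
        "capture_same_arm_mean": None, "capture_same_arm_sd": None,
        "capture_opposite_arm_mean": None, "capture_opposite_arm_sd": None,
        "tangling_mean_driving": None, "tangling_sd_driving": None,
        "tangling_mean_non_driving": None, "tangling_sd_non_driving": None,
        "tangling_mean_muscle": None, "tangling_sd_muscle": None,
        "decoder_r2_median_driving": None,
        "decoder_r2_median_non_driving": None,
    }
    units = _maybe(out / "unit_stats" / "unit_table.csv", pd.read_csv)
    if units is not None and len(units):
        summary["median_unit_arm_preference"] = float(units["arm_preference"].median())
        summary["median_arm_correlation"] = float(units["r_arm"].median())
        summary["median_startpos_correlation"] = float(units["r_startpos"].median())
    muscles = _maybe(out / "unit_stats" / "muscle_table.csv", pd.read_csv)
    if muscles is not None and len(muscles):
        summary["median_muscle_arm_preference"] = float(
            muscles["arm_preference"].median())
    stats = _maybe(out / "unit_stats" / "summary_stats.json",
                   lambda p: json.loads(p.read_text()))
    if stats:
        summary["meta_correlation"] = stats.get("meta_correlation")
        summary["speed_split_flagged_fraction"] = stats.get(
            "speed_split_flagged_fraction")
        summary["fano_slope"] = stats.get("fano_slope")
        summary["required_magnification"] = stats.get("required_magnification")
    capture = _maybe(out / "population" / "capture_summary.csv", pd.read_csv)
    if capture is not None and len(capture):
        for _, row in capture.iterrows():
            key = "same_arm" if row["relation"] == "same_arm" else "opposite_arm"
            summary[f"capture_{key}_mean"] = float(row["mean"])
            summary[f"capture_{key}_sd"] = float(row["sd"])
    tangling = _maybe(out / "population" / "tangling_summary.csv", pd.read_csv)
    if tangling is not None and len(tangling):
        for _, row in tangling.iterrows():
            summary[f"tangling_mean_{row['group']}"] = float(row["mean"])
            summary[f"tangling_sd_{row['group']}"] = float(row["sd"])
    cross = _maybe(out / "decoding" / "cross_hemisphere_r2.csv", pd.read_csv)
    if cross is not None and len(cross):
        med = cross.groupby("source")["r2"].median()
        summary["decoder_r2_median_driving"] = float(med.get("driving", np.nan))
        summary["decoder_r2_median_non_driving"] = float(
            med.get("non_driving", np.nan))
    api = _maybe(out / "decoding" / "wrong_arm_train_performing_api.csv",
                 pd.read_csv)
    if api is not None and len(api):
        summary["median_decoded_arm_preference"] = float(
            api["decoded_api"].median())
    return summary
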