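"""In-memory session container and its on-disk (plain text) layout.

A session holds everything recorded in one day: per-trial spike times for
units tagged by hemisphere, per-trial pedal-angle traces for both arms,
per-trial EMG intensity traces for muscles of both arms, and the condition
label of every trial.

On disk a session is a directory of small text files:

- ``session.json``  — unit table (id, hemisphere), trial table (id, condition
  label, performing-arm mean speed), trace sampling rate.
- ``spikes.csv``    — columns ``unit_id, trial_id, spike_time_s``.
- ``traces.csv``    — long format ``trial_id, time_s, channel_id, value``
  with channel ids ``pedal_left``, ``pedal_right``, ``emg_<arm>_<k>``.
- ``ground_truth.json`` (optional) — generator ground truth for recovery
  tests; absent for real recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import Condition

PEDAL_CHANNELS = ("pedal_left", "pedal_right")


@dataclass
class SessionData:
    """All trials of one recording session.

    Attributes
    ----------
    units : pandas.DataFrame
        Columns ``unit_id`` (str) and ``hemisphere`` ('left'/'right').
    trials : pandas.DataFrame
        Columns ``trial_id`` (str), ``condition`` (label string) and
        ``speed_cps`` (performing-arm mean angular speed, cycles/s).
    spikes : pandas.DataFrame
        Columns ``unit_id``, ``trial_id``, ``spike_time_s``.
    traces : dict
        ``trial_id -> DataFrame`` with a ``time_s`` column plus one column
        per channel (pedal angles in cycles, EMG intensities in arbitrary
        nonnegative units).
    fs : float
        Trace sampling rate in Hz.
    meta : dict
        Free-form provenance (generator config, etc.).
    """

    units: pd.DataFrame
    trials: pd.DataFrame
    spikes: pd.DataFrame
    traces: dict
    fs: float
    meta: dict = field(default_factory=dict)

    # -- convenience ----------------------------------------------------
    @property
    def unit_ids(self):
        return list(self.units["unit_id"])

    @property
    def emg_channels(self):
        first = next(iter(self.traces.values()))
        return [c for c in first.columns if c.startswith("emg_")]

    def condition_of(self, trial_id: str) -> Condition:
        row = self.trials.loc[self.trials["trial_id"] == trial_id].iloc[0]
        return Condition.from_label(row["condition"])

    def trials_of(self, condition: Condition):
        mask = self.trials["condition"] == condition.label
        return list(self.trials.loc[mask, "trial_id"])

    def spike_times(self, unit_id: str, trial_id: str) -> np.ndarray:
        # lazy (unit, trial) index; sessions are treated as immutable
        index = self.__dict__.get("_spike_index")
        if index is None:
            index = {
                key: np.sort(grp["spike_time_s"].to_numpy())
                for key, grp in self.spikes.groupby(["unit_id", "trial_id"],
                                                    sort=False)
            }
            self.__dict__["_spike_index"] = index
        return index.get((unit_id, trial_id), np.empty(0))

    # -- I/O ------------------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        doc = {
            "fs": self.fs,
            "units": self.units.to_dict(orient="records"),
            "trials": self.trials.to_dict(orient="records"),
            "meta": self.meta,
        }
        (directory / "session.json").write_text(
            json.dumps(doc, indent=1, sort_keys=True)
        )
        self.spikes.to_csv(directory / "spikes.csv", index=False,
                           float_format="%.6f")
        rows = []
        for trial_id in self.trials["trial_id"]:
            tr = self.traces[trial_id]
            long = tr.melt(id_vars="time_s", var_name="channel_id",
                           value_name="value")
            long.insert(0, "trial_id", trial_id)
            rows.append(long)
        pd.concat(rows, ignore_index=True).to_csv(
            directory / "traces.csv", index=False, float_format="%.6g"
        )

    @classmethod
    def load(cls, directory) -> "SessionData":
        directory = Path(directory)
        doc = json.loads((directory / "session.json").read_text())
        units = pd.DataFrame(doc["units"])
        trials = pd.DataFrame(doc["trials"])
        spikes = pd.read_csv(
            directory / "spikes.csv",
            dtype={"unit_id": str, "trial_id": str},
        )
        long = pd.read_csv(directory / "traces.csv",
                           dtype={"trial_id": str, "channel_id": str})
        traces = {}
        for trial_id, grp in long.groupby("trial_id", sort=False):
            wide = grp.pivot(index="time_s", columns="channel_id",
                             values="value").reset_index()
            wide.columns.name = None
            traces[trial_id] = wide
        return cls(units=units, trials=trials, spikes=spikes, traces=traces,
                   fs=float(doc["fs"]), meta=doc.get("meta", {}))
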