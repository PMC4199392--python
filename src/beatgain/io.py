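"""Table formats, estimate serialization and run configuration.

All data travel as delimited text (CSV) with fixed schemas:

* tones:   trial_id, experiment, condition, jitter_condition, role,
           index_in_role, nominal_onset_ms, jitter_ms, onset_ms, f_log2
* beats:   trial_id, beat_index, beat_time_ms
* taps:    trial_id, tap_index, tap_time_ms, interpolated
* choices: trial_id, choice, correct
* phases:  trial_id, role, index_in_role, onset_ms, ssi_rad, source,
           extrapolated

Estimates and reports are JSON; run configuration is YAML and round-trips
losslessly.  Times are ms, 0-based at the first reference onset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import IntegrityError, SchemaError
from .observer import (CHOICE_TABLE_COLUMNS, TAP_TABLE_COLUMNS, MotorTrace,
                       ObserverParams)
from .phase import PHASE_TABLE_COLUMNS
from .sequences import TONE_TABLE_COLUMNS

BEAT_TABLE_COLUMNS = ["trial_id", "beat_index", "beat_time_ms"]

_SCHEMAS = {
    "tones": TONE_TABLE_COLUMNS,
    "beats": BEAT_TABLE_COLUMNS,
    "taps": TAP_TABLE_COLUMNS,
    "choices": CHOICE_TABLE_COLUMNS,
    "phases": PHASE_TABLE_COLUMNS,
}


def validate_table(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Check a table against its schema; returns the frame unchanged.

    Raises SchemaError naming any missing/duplicated column, and
    IntegrityError naming the first trial with non-increasing tap times.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    required = _SCHEMAS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table is missing column(s) {missing}")
    dup = df.columns[df.columns.duplicated()].tolist()
    if dup:
        raise SchemaError(f"{kind} table has duplicated column(s) {dup}")
    if kind == "taps" and len(df):
        for tid, g in df.sort_values("tap_index").groupby("trial_id"):
            t = g["tap_time_ms"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise IntegrityError(
                    f"taps of trial {tid} are not strictly increasing")
    return df


def write_tables(tables: dict[str, pd.DataFrame], directory) -> None:
    """Write named tables (tones/beats/taps/choices/phases) as CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, df in tables.items():
        validate_table(df, kind)
        df.to_csv(directory / f"{kind}.csv", index=False)


def read_tables(directory, kinds=None) -> dict[str, pd.DataFrame]:
    """Read and validate the CSV tables present in ``directory``."""
    directory = Path(directory)
    out = {}
    for kind in (kinds or _SCHEMAS):
        path = directory / f"{kind}.csv"
        if path.exists():
            out[kind] = validate_table(pd.read_csv(path), kind)
        elif kinds is not None:
            raise FileNotFoundError(f"required table {path} not found")
    return out


def dataset_tables(dataset) -> dict[str, pd.DataFrame]:
    """The standard table dict of a SimulatedDataset."""
    return {
        "tones": dataset.tones_table(),
        "beats": dataset.beats_table(),
        "taps": dataset.taps_table(),
        "choices": dataset.choices_table(),
    }


def traces_from_taps(taps: pd.DataFrame) -> dict[int, MotorTrace]:
    """Rebuild MotorTrace objects from a taps table."""
    validate_table(taps, "taps")
    out = {}
    for tid, g in taps.sort_values("tap_index").groupby("trial_id"):
        out[int(tid)] = MotorTrace(
            trial_id=int(tid),
            tap_times_ms=g["tap_time_ms"].to_numpy(dtype=float),
            interpolated=g["interpolated"].to_numpy(dtype=bool))
    return out


def beats_map(beats: pd.DataFrame) -> dict[int, np.ndarray]:
    validate_table(beats, "beats")
    return {int(tid): g.sort_values("beat_index")["beat_time_ms"].to_numpy(float)
            for tid, g in beats.groupby("trial_id")}


# ---------------------------------------------------------------------------
# estimates
# ---------------------------------------------------------------------------

def write_estimate(results, path, extra: dict | None = None) -> None:
    """Serialize a fitted Results object (anything with .to_dict) to JSON."""
    payload = results.to_dict()
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)


def read_estimate(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {obj!r}")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce a simulated session and its analysis."""

    experiment: str = "exp1"
    n_trials_per_condition: int = 210
    delta: float = 0.1
    sigma_f: float = 0.2
    seed: int = 0
    observer: dict = field(default_factory=lambda: dataclasses.asdict(ObserverParams()))
    staircase: dict = field(default_factory=lambda: {
        "n_trials": 400, "delta0": 0.4, "step_down": 0.005,
        "step_up": 0.015, "coarse_factor": 4.0, "switch_reversals": 6})
    analysis: dict = field(default_factory=lambda: {
        "link": "probit", "include_sine": True, "n_windows": 64,
        "octile_scheme": "sliding_quantile"})

    def observer_params(self) -> ObserverParams:
        return ObserverParams(**self.observer)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    @property
    def config_hash(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]
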