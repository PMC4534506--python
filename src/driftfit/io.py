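"""Trial-table CSV schema, run configuration, and report serialisation.

Trial files are long-format CSV with one row per trial and integer
millisecond RTs (lossless, human-readable); seconds are used everywhere
in memory.  Validation is strict: closed vocabularies, positive RTs,
and unknown config keys are rejected.
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

from .simulate import StudyDataset, TRIAL_COLUMNS

CSV_COLUMNS = ["participant_id", "group", "condition", "stimulus_class",
               "response", "rt_ms", "censored"]
RESPONSES = {"old", "new"}
STIMULUS_CLASSES = {"old", "new"}


class TrialTableError(ValueError):
    """A trial file violated the schema."""


def write_trials(dataset: StudyDataset, path: str | Path) -> None:
    """Write a StudyDataset to the trial CSV schema (deterministic order)."""
    t = dataset.trials
    out = pd.DataFrame({
        "participant_id": t["participant"],
        "group": t["group"],
        "condition": t["condition"],
        "stimulus_class": t["stimulus_class"],
        "response": t["response"],
        "rt_ms": np.rint(t["rt"] * 1000).astype(int),
        "censored": t["censored"].astype(int),
    })
    out.to_csv(path, index=False, lineterminator="\n")


def read_trials(path: str | Path, design_id: str = "custom",
                deadline: float = 4.0) -> StudyDataset:
    """Read and validate a trial CSV; RTs are converted ms -> s.

    Raises :class:`TrialTableError` naming the first offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.response not in RESPONSES:
            raise TrialTableError(
                f"{path}:{i}: unknown response label {row.response!r}")
        if row.stimulus_class not in STIMULUS_CLASSES:
            raise TrialTableError(
                f"{path}:{i}: unknown stimulus class {row.stimulus_class!r}")
        if not (isinstance(row.rt_ms, (int, np.integer)) and row.rt_ms > 0):
            raise TrialTableError(f"{path}:{i}: rt_ms must be a positive "
                                  f"integer, got {row.rt_ms!r}")
        if row.censored not in (0, 1):
            raise TrialTableError(f"{path}:{i}: censored must be 0 or 1")
    trials = pd.DataFrame({
        "participant": df["participant_id"],
        "group": df["group"],
        "condition": df["condition"],
        "stimulus_class": df["stimulus_class"],
        "response": df["response"],
        "rt": df["rt_ms"] / 1000.0,
        "censored": df["censored"].astype(bool),
    })
    try:
        return StudyDataset(trials=trials, design_id=design_id,
                            deadline=deadline)
    except ValueError as err:
        raise TrialTableError(f"{path}: {err}") from err


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (YAML-loadable; unknown keys rejected)."""

    design: str = "exp1"
    method: str = "ks"
    seed: int = 1
    s: float = 0.1
    n_per_group: int | None = None
    trim_lo: float = 0.3
    trim_hi: float = 4.0
    deadline: float = 4.0
    restarts: int = 2
    estimate_variability: bool = False

    def __post_init__(self) -> None:
        if self.design not in ("exp1", "exp2", "exp3", "custom"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.method not in ("ez", "ks", "chisq"):
            raise ValueError(f"unknown method {self.method!r}")
        if not (0 <= self.trim_lo < self.trim_hi):
            raise ValueError("require 0 <= trim_lo < trim_hi")
        if self.s <= 0 or self.deadline <= 0:
            raise ValueError("s and deadline must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def sha1(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def dump_json(obj, path: str | Path) -> None:
    """Serialise report objects (dataclasses, DataFrames, numpy) to JSON."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"cannot serialise {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
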