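"""Trial-log and configuration I/O.

Interchange format is tidy CSV, one trial per row, with columns
``trial, participant_id, block, offer, choice, rating`` (``rating`` may
be empty; a ``norm_at_trial`` column is present for simulated data).
Trial indices are 1-based.  Choices may be spelled ``accept``/``reject``
(any case) or as the task's keyboard codes ``1``/``2``.

Output files written by the pipeline start with ``#``-prefixed comment
lines carrying the config fingerprint; readers here skip them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import OptimizerConfig
from .models import MODEL_IDS
from .simulate import CohortSpec, ParamDist, TRIAL_COLUMNS, default_param_sampler
from .task import TaskConfig

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_trial_log",
    "write_trial_log",
    "config_fingerprint",
]

REQUIRED_COLUMNS = ("trial", "participant_id", "block", "offer", "choice")

_CHOICE_CODES = {"accept": "accept", "1": "accept", "reject": "reject", "2": "reject"}


class ValidationError(ValueError):
    """A trial log or config failed validation; the message names the row."""


def _parse_choice(value, row_no: int) -> str:
    s = str(value).strip().lower()
    if s.endswith(".0"):  # numeric CSV round-trip of keyboard codes
        s = s[:-2]
    try:
        return _CHOICE_CODES[s]
    except KeyError:
        raise ValidationError(f"row {row_no}: unknown choice code {value!r}")


def read_trial_log(path: str | Path, endowment: int = 20) -> pd.DataFrame:
    """Read and validate a tidy trial-level CSV into TrialRecord rows.

    Enforces 1-based contiguous trial indices per participant, offers in
    ``[0, endowment]``, known choice codes and no duplicate
    (participant, trial) pairs; violations raise
    :class:`ValidationError` naming the offending row.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    if "rating" not in df.columns:
        df["rating"] = pd.NA

    choices = [
        _parse_choice(v, i + 2)  # +2: header line + 1-based
        for i, v in enumerate(df["choice"].tolist())
    ]
    df["choice"] = choices
    df["trial"] = df["trial"].astype(int)
    df["offer"] = df["offer"].astype(int)
    df["rating"] = pd.array(
        [pd.NA if pd.isna(v) else int(v) for v in df["rating"]], dtype="Int64"
    )

    bad = df.index[(df["offer"] < 0) | (df["offer"] > endowment)]
    if len(bad):
        row = int(bad[0]) + 2
        raise ValidationError(
            f"row {row}: offer {df.loc[bad[0], 'offer']} outside [0, {endowment}]"
        )
    rated = df["rating"].dropna()
    if len(rated) and ((rated < 1) | (rated > 9)).any():
        raise ValidationError("ratings must lie in [1, 9]")
    dup = df.duplicated(subset=["participant_id", "trial"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValidationError(f"row {row}: duplicate (participant, trial) pair")
    for pid, grp in df.groupby("participant_id"):
        t = np.sort(grp["trial"].to_numpy())
        if t[0] != 1 or not np.array_equal(t, np.arange(1, len(t) + 1)):
            raise ValidationError(
                f"participant {pid!r}: trial indices must be 1..n without gaps"
            )
    cols = [c for c in TRIAL_COLUMNS if c in df.columns]
    return df[cols + [c for c in df.columns if c not in cols]]


def write_trial_log(df: pd.DataFrame, path: str | Path,
                    fingerprint: str | None = None) -> None:
    """Write a tidy trial log, optionally prefixed with a config fingerprint."""
    path = Path(path)
    with path.open("w") as fh:
        if fingerprint:
            fh.write(f"# config_fingerprint={fingerprint}\n")
        df.to_csv(fh, index=False)


def config_fingerprint(config_dict: dict) -> str:
    """Short stable hash of a canonicalized config dict (provenance stamp)."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class RunConfig:
    """Top-level pipeline configuration (task, cohort, models, optimizer)."""

    task: TaskConfig = field(default_factory=TaskConfig)
    n_participants: int = 30
    cohort_model_id: str = "RW_fixed"
    param_sampler: dict | None = None  # name -> {mean, sd, low, high}
    models: tuple[str, ...] = MODEL_IDS
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    bh_q: float = 0.05
    sliding_window: int = 5

    def __post_init__(self) -> None:
        for m in self.models:
            if m not in MODEL_IDS:
                raise ValidationError(f"unknown model_id {m!r} in config")
        if self.cohort_model_id not in MODEL_IDS:
            raise ValidationError(f"unknown cohort model_id {self.cohort_model_id!r}")
        if not 0 < self.bh_q < 1:
            raise ValidationError(f"bh_q must be in (0, 1), got {self.bh_q}")

    def cohort_spec(self, seed: int) -> CohortSpec:
        sampler = None
        if self.param_sampler is not None:
            sampler = {
                name: ParamDist(d["mean"], d["sd"], d["low"], d["high"])
                for name, d in self.param_sampler.items()
            }
        return CohortSpec(
            n_participants=self.n_participants,
            model_id=self.cohort_model_id,
            param_sampler=sampler,
            task=self.task,
            seed=seed,
        )

    def to_dict(self) -> dict:
        return {
            "task": self.task.to_dict(),
            "cohort": {
                "n_participants": self.n_participants,
                "model_id": self.cohort_model_id,
                "param_sampler": self.param_sampler,
            },
            "models": list(self.models),
            "optimizer": self.optimizer.to_dict(),
            "analysis": {"bh_q": self.bh_q, "sliding_window": self.sliding_window},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cohort = d.get("cohort", {})
        analysis = d.get("analysis", {})
        return cls(
            task=TaskConfig.from_dict(d.get("task", {})),
            n_participants=int(cohort.get("n_participants", 30)),
            cohort_model_id=cohort.get("model_id", "RW_fixed"),
            param_sampler=cohort.get("param_sampler"),
            models=tuple(d.get("models", MODEL_IDS)),
            optimizer=OptimizerConfig.from_dict(d.get("optimizer", {})),
            bh_q=float(analysis.get("bh_q", 0.05)),
            sliding_window=int(analysis.get("sliding_window", 5)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def fingerprint(self) -> str:
        return config_fingerprint(self.to_dict())
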