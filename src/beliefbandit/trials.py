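"""Trial-table data model and delimited-text IO.

The canonical in-memory container is a :class:`pandas.DataFrame` with one
row per bandit trial.  Choices and the hidden (rewarded-side) state are
coded ``{-1, +1}`` with -1 = left; rewards are ``{0, 1}``.  Trials the
animal failed to initiate are kept as rows whose choice, reward and latent
columns are missing (NaN), and are excluded by downstream analyses.  Event
times are seconds as floats; within a trial they are non-decreasing in the
order CI <= CO <= SI <= O <= SO0 <= SO1 <= SOf (center in/out, side in,
outcome, and the zeroth/first/final side-out pokes).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "EVENT_COLUMNS",
    "DURATION_COLUMNS",
    "LATENT_COLUMNS",
    "TrialValidationError",
    "validate_trials",
    "read_session_table",
    "write_session_table",
    "RunConfig",
]

KEY_COLUMNS = ["subject_id", "session_id", "trial"]
CORE_COLUMNS = ["choice", "reward", "state", "block", "rewards_in_block"]
EVENT_COLUMNS = ["CI", "CO", "SI", "O", "SO0", "SO1", "SOf"]
DURATION_COLUMNS = ["MVMT", "ITI", "center_dur", "port_dur", "SO_lat"]
LATENT_COLUMNS = ["belief_right", "Q_left", "Q_right", "D", "rpe"]

#: Deterministic column order for written tables.
COLUMNS = (KEY_COLUMNS + CORE_COLUMNS + EVENT_COLUMNS + DURATION_COLUMNS
           + ["da_pt"] + LATENT_COLUMNS)

_FLOAT_FMT = "%.6f"


class TrialValidationError(ValueError):
    """A trial table violates the data-model invariants."""


def _check_domain(df: pd.DataFrame, col: str, allowed: set) -> None:
    vals = df[col].dropna().unique()
    bad = [v for v in vals if v not in allowed]
    if bad:
        raise TrialValidationError(
            f"column {col!r} contains values {bad!r} outside {sorted(allowed)}")


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate invariants and return the table sorted by (subject, session, trial)."""
    for col in KEY_COLUMNS + ["choice", "reward"]:
        if col not in df.columns:
            raise TrialValidationError(f"missing required column {col!r}")
    # monotonicity is checked on the incoming row order, before sorting,
    # so shuffled or duplicated trial indices within a session are caught
    for (_, _), grp in df.groupby(["subject_id", "session_id"], sort=False):
        t = grp["trial"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise TrialValidationError(
                f"non-monotone trial index in session "
                f"{grp['subject_id'].iloc[0]}/{grp['session_id'].iloc[0]}")
    df = df.sort_values(KEY_COLUMNS, kind="stable").reset_index(drop=True)
    _check_domain(df, "choice", {-1.0, 1.0})
    _check_domain(df, "reward", {0.0, 1.0})
    if "state" in df.columns:
        _check_domain(df, "state", {-1.0, 1.0})

    present = [c for c in EVENT_COLUMNS if c in df.columns]
    for a, b in zip(present[:-1], present[1:]):
        both = df[[a, b]].dropna()
        bad = both[both[a] > both[b] + 1e-12]
        if len(bad):
            raise TrialValidationError(
                f"event-order invariant violated: {a} > {b} on row(s) "
                f"{bad.index[:5].tolist()} (events must satisfy "
                "CI <= CO <= SI <= O <= SO0 <= SO1 <= SOf)")

    if "rewards_in_block" in df.columns and "block" in df.columns:
        for (_, _), grp in df.groupby(["subject_id", "session_id"], sort=False):
            blk = grp["block"].to_numpy()
            cnt = grp["rewards_in_block"].to_numpy()
            inc = np.where(np.diff(blk) > 0)[0] + 1
            if np.any(cnt[inc] != 0):
                raise TrialValidationError(
                    "rewards_in_block must reset to 0 when block increments")

    missing_choice = df["choice"].isna()
    if missing_choice.any():
        cols = [c for c in ["reward"] + LATENT_COLUMNS if c in df.columns]
        leak = df.loc[missing_choice, cols].notna().any(axis=1)
        if leak.any():
            raise TrialValidationError(
                "rows with missing choice must have missing reward and latents")
    return df


_CHOICE_ALIASES = {"L": -1.0, "R": 1.0, "l": -1.0, "r": 1.0}


def _normalize_choice(col: pd.Series) -> pd.Series:
    """Normalise {0,1} or {L,R} choice coding to the canonical {-1,+1}."""
    if col.dtype == object:
        col = col.map(lambda v: _CHOICE_ALIASES.get(v, v))
    col = pd.to_numeric(col, errors="raise")
    vals = set(col.dropna().unique())
    if vals and vals <= {0.0, 1.0}:
        col = col.replace({0.0: -1.0})
    return col


def read_session_table(path: Union[str, Path], dialect: str = "csv") -> pd.DataFrame:
    """Read a delimited trial table, normalise choice coding, and validate."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep=sep)
    except (pd.errors.ParserError, ValueError) as exc:
        raise TrialValidationError(f"malformed trial table {path}: {exc}") from exc
    if "choice" in df.columns:
        df["choice"] = _normalize_choice(df["choice"])
    return validate_trials(df)


def write_session_table(df: pd.DataFrame, path: Union[str, Path],
                        dialect: str = "csv") -> Path:
    """Write a validated trial table with deterministic column order.

    Floats are written at fixed precision so a write/read round trip is
    bit-stable at that precision.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = validate_trials(df)
    cols = [c for c in COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    path = Path(path)
    df.to_csv(path, sep=sep, index=False, columns=cols, float_format=_FLOAT_FMT)
    return path


@dataclasses.dataclass
class RunConfig:
    """Reproducibility envelope for an analysis run.

    The seed is recorded in every serialized artifact; two runs with the
    same config produce identical outputs.
    """

    seed: int = 0
    model: str = "BIfp"
    model_params: Optional[dict] = None
    n_trials: int = 500
    n_sessions: int = 5
    n_starts: int = 10
    cv_fraction: float = 0.7
    out_dir: str = "."

    def to_json(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
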