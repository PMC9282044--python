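"""Tempo-mismatch scores, per-condition summaries, and the tidy export.

The tempo-mismatch score quantifies how well a child matched a pacing
stimulus: signed mismatch = drumming IOI − target IOI (positive means
drumming slower than the target), absolute mismatch = |signed|.
Unpaced SMT trials have no target and therefore no mismatch.

The tidy per-trial table is the input for downstream mixed-effects
modelling, which is deliberately left to standard statistics tooling;
excluded trials are exported separately with a single primary reason
code each (off-camera, interference, no-drumming, no-tempo).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pose_io import TRIAL_TYPES
from .tempo import TempoEstimate

#: Exclusion reason codes in priority order; the first applicable wins.
EXCLUSION_REASONS = ("off-camera", "interference", "no-drumming", "no-tempo")


@dataclass(frozen=True)
class Coding:
    """One row of the manual-coding table for a trial."""

    hands_visible: bool = True
    hand_used: str = "both"  # L | R | both | none
    interference: bool = False
    n_strikes: int | None = None

    def __post_init__(self) -> None:
        if self.hand_used not in ("L", "R", "both", "none"):
            raise ValueError(f"hand_used must be L/R/both/none, got {self.hand_used!r}")


def read_coding(path: str | Path) -> dict[tuple[str, int], Coding]:
    """Read a manual-coding CSV keyed by (child_id, trial_index)."""
    out: dict[tuple[str, int], Coding] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ns = row.get("n_strikes", "")
            out[(str(row["child_id"]), int(row["trial_index"]))] = Coding(
                hands_visible=str(row["hands_visible"]).strip().lower() in ("1", "true", "y", "yes"),
                hand_used=str(row["hand_used"]).strip(),
                interference=str(row["interference"]).strip().lower() in ("1", "true", "y", "yes"),
                n_strikes=int(ns) if ns not in ("", None) else None,
            )
    return out


@dataclass
class TrialRecord:
    """Everything known about one processed trial; unit of the tidy export."""

    child_id: str
    trial_index: int
    trial_type: str
    order_condition: int
    target_ioi: float | None
    tempo: TempoEstimate | None
    retained: bool
    coding: Coding = field(default_factory=Coding)
    mismatch: float | None = None
    abs_mismatch: float | None = None
    n_strikes: int | None = None
    gap_fraction: float = 0.0
    missing_frac: float = 0.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        has_tempo = self.tempo is not None and self.tempo.valid
        if self.retained and has_tempo and self.target_ioi is not None:
            signed, absolute = tempo_mismatch(self.tempo.ioi, self.target_ioi)
            self.mismatch = signed
            self.abs_mismatch = absolute
        else:
            self.mismatch = None
            self.abs_mismatch = None

    @property
    def drum_ioi(self) -> float | None:
        if self.tempo is not None and self.tempo.valid:
            return self.tempo.ioi
        return None

    @property
    def included(self) -> bool:
        return self.exclusion_reason is None

    @property
    def exclusion_reason(self) -> str | None:
        """First applicable reason code, or None if the trial is analysable."""
        if not self.coding.hands_visible:
            return "off-camera"
        if self.coding.interference:
            return "interference"
        if self.coding.hand_used == "none" or not self.retained:
            return "no-drumming"
        if self.tempo is None or not self.tempo.valid:
            return "no-tempo"
        return None


def tempo_mismatch(drum_ioi: float, target_ioi: float) -> tuple[float, float]:
    """Signed and absolute tempo mismatch in ms.

    signed = drumming IOI − target IOI; positive values mean the child
    drummed slower than the pacing stimulus.
    """
    if drum_ioi <= 0 or target_ioi <= 0:
        raise ValueError("IOIs must be positive")
    signed = drum_ioi - target_ioi
    return signed, abs(signed)


def _field_values(records: Iterable[TrialRecord], field_name: str) -> dict[str, list[float]]:
    by_type: dict[str, list[float]] = {t: [] for t in TRIAL_TYPES}
    for r in records:
        if not (r.retained and r.tempo is not None and r.tempo.valid):
            continue
        if field_name == "ioi":
            val = r.drum_ioi
        elif field_name == "abs_mismatch":
            val = r.abs_mismatch
        elif field_name == "n_strikes":
            val = r.n_strikes
        else:
            raise ValueError(f"unknown summary field {field_name!r}")
        if val is not None:
            by_type[r.trial_type].append(float(val))
    return by_type


def summarise_condition(
    records: Iterable[TrialRecord],
    field_name: str = "ioi",
) -> pd.DataFrame:
    """Descriptive statistics per trial type: N, mean, sd, median, se.

    Only retained trials with a valid tempo contribute.  sd is the
    sample standard deviation (n−1); se = sd/√N.  Empty conditions get
    an N=0 row with absent moments; N=1 leaves sd/se undefined.
    """
    by_type = _field_values(records, field_name)
    rows = []
    for t in TRIAL_TYPES:
        vals = np.asarray(by_type[t])
        n = len(vals)
        rows.append(
            {
                "trial_type": t,
                "N": n,
                "mean": vals.mean() if n else np.nan,
                "sd": vals.std(ddof=1) if n > 1 else np.nan,
                "median": np.median(vals) if n else np.nan,
                "se": vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


_TIDY_COLUMNS = [
    "child_id",
    "trial_index",
    "trial_type",
    "target_ioi",
    "drum_ioi",
    "mismatch",
    "abs_mismatch",
    "hand",
    "peak_power",
    "n_strikes",
    "gap_fraction",
    "missing_frac",
    "order_condition",
]


def export_tidy(records: Sequence[TrialRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into the analysable tidy table and the exclusions table.

    The two tables partition the input exactly.  SMT trials keep empty
    target/mismatch columns: they carry no target to match and are
    excluded from mismatch analyses downstream.
    """
    tidy_rows = []
    excl_rows = []
    for r in records:
        reason = r.exclusion_reason
        if reason is None:
            tidy_rows.append(
                {
                    "child_id": r.child_id,
                    "trial_index": r.trial_index,
                    "trial_type": r.trial_type,
                    "target_ioi": np.nan if r.target_ioi is None else r.target_ioi,
                    "drum_ioi": r.drum_ioi,
                    "mismatch": np.nan if r.mismatch is None else r.mismatch,
                    "abs_mismatch": np.nan if r.abs_mismatch is None else r.abs_mismatch,
                    "hand": r.tempo.hand if r.tempo is not None else None,
                    "peak_power": r.tempo.peak_power if r.tempo is not None else np.nan,
                    "n_strikes": np.nan if r.n_strikes is None else r.n_strikes,
                    "gap_fraction": r.gap_fraction,
                    "missing_frac": r.missing_frac,
                    "order_condition": r.order_condition,
                }
            )
        else:
            excl_rows.append(
                {
                    "child_id": r.child_id,
                    "trial_index": r.trial_index,
                    "trial_type": r.trial_type,
                    "reason": reason,
                    "flags": ";".join(r.flags),
                }
            )
    tidy = pd.DataFrame(tidy_rows, columns=_TIDY_COLUMNS)
    excl = pd.DataFrame(
        excl_rows, columns=["child_id", "trial_index", "trial_type", "reason", "flags"]
    )
    return tidy, excl
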