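"""End-to-end orchestration: raw frame JSON to tidy per-trial table.

For each trial the pipeline runs: collate -> relabel -> ghost flagging
-> manual-ledger corrections -> child selection -> per-hand vertical
signal -> gap interpolation -> mean-centering -> power spectrum ->
peak tempo -> best hand -> strike detection -> retention -> mismatch.
Outputs are a tidy CSV of analysable trials, an exclusions CSV with
reason codes, per-trial spectra, condition summaries, and a run report
recording the configuration and per-trial flags.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kinematics import (
    EmptyTrackError,
    UnusableTrialError,
    build_vertical_signal,
    interpolate_gaps,
    mean_center,
    missing_member_fraction,
)
from .pose_io import PoseTimeSeries, TrialInfo, collate_trial_dir, read_trial_metadata
from .stats import Coding, TrialRecord, export_tidy, read_coding, summarise_condition
from .synth import CohortSpec, generate_cohort
from .tempo import (
    DEFAULT_MIN_FREQ_HZ,
    DEFAULT_MIN_PROMINENCE_FRAC,
    StrikeTrain,
    TempoEstimate,
    best_hand,
    detect_strikes,
    peak_tempo,
    power_spectrum,
    retention,
)
from .track_cleaning import (
    DEFAULT_MIN_MEAN_CONF,
    DEFAULT_MIN_PRESENCE_FRAC,
    CorrectionLedger,
    Directive,
    NoTracksError,
    apply_ledger,
    flag_ghosts,
    relabel_series,
    select_child,
)

logger = logging.getLogger(__name__)


class DataError(RuntimeError):
    """Unrecoverable problem with the input dataset."""


@dataclass
class RunConfig:
    """Configuration of one extraction run; every default is logged."""

    input_dir: str
    metadata_path: str
    coding_path: str | None = None
    ledger_path: str | None = None
    matcher: str = "location"
    min_freq_hz: float = DEFAULT_MIN_FREQ_HZ
    fps_override: float | None = None
    ghost_min_presence: float = DEFAULT_MIN_PRESENCE_FRAC
    ghost_min_conf: float = DEFAULT_MIN_MEAN_CONF
    max_gap_s: float = 1.0
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC
    output_dir: str | None = None
    write_spectra: bool = True
    seed: int = 0


@dataclass
class TrialResult:
    record: TrialRecord
    spectra: dict = field(default_factory=dict)  # hand -> PowerSpectrum
    signals: dict = field(default_factory=dict)  # hand -> centered HandSignal
    child_label: int | None = None


def process_series(
    series: PoseTimeSeries,
    coding: Coding | None = None,
    ledger: CorrectionLedger | None = None,
    matcher: str = "location",
    min_freq_hz: float = DEFAULT_MIN_FREQ_HZ,
    ghost_min_presence: float = DEFAULT_MIN_PRESENCE_FRAC,
    ghost_min_conf: float = DEFAULT_MIN_MEAN_CONF,
    max_gap_s: float = 1.0,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
) -> TrialResult:
    """Run the cleaning + extraction pipeline on one collated trial."""
    info = series.trial_info
    flags: list[str] = []
    if coding is None:
        coding = Coding()
        flags.append("uncoded")

    cleaned = relabel_series(series, method=matcher)
    flagged = flag_ghosts(cleaned, ghost_min_presence, ghost_min_conf)
    if ledger is not None:
        cleaned = apply_ledger(cleaned, ledger)

    estimates: dict[str, TempoEstimate] = {}
    signals = {}
    spectra = {}
    child = None
    try:
        child = select_child(cleaned, ledger, flagged)
        if ledger is None or ledger.child_label is None:
            flags.append("fallback-child-selection")
        for hand in ("left", "right"):
            try:
                sig = build_vertical_signal(cleaned, child, hand)
                sig = interpolate_gaps(sig, max_gap_s=max_gap_s)
                sig = mean_center(sig)
            except (EmptyTrackError, UnusableTrialError):
                estimates[hand] = TempoEstimate.invalid(hand)
                continue
            if sig.long_gap:
                flags.append(f"long-gap-{hand}")
            signals[hand] = sig
            spec = power_spectrum(sig)
            spectra[hand] = spec
            estimates[hand] = peak_tempo(spec, min_freq=min_freq_hz, hand=hand)
    except NoTracksError:
        flags.append("no-tracks")
        estimates = {"left": TempoEstimate.invalid("left"), "right": TempoEstimate.invalid("right")}

    tempo = best_hand(estimates.get("left"), estimates.get("right"))
    if not tempo.valid:
        flags.append("no-tempo")

    # Strike detection on the best hand's signal (assistive; the manual
    # coding table, when present, supplies the authoritative count).
    strike_hand = tempo.hand if tempo.hand in signals else next(iter(signals), None)
    strikes = (
        detect_strikes(signals[strike_hand], min_prominence_frac)
        if strike_hand is not None
        else StrikeTrain(times=np.empty(0))
    )
    n_strikes = coding.n_strikes if coding.n_strikes is not None else len(strikes)
    retained = coding.hand_used != "none" and retention(strikes)

    gap_fraction = signals[strike_hand].gap_fraction if strike_hand else 1.0
    missing_frac = (
        missing_member_fraction(cleaned, child, strike_hand)
        if child is not None and strike_hand is not None
        else 1.0
    )

    record = TrialRecord(
        child_id=info.child_id,
        trial_index=info.trial_index,
        trial_type=info.trial_type,
        order_condition=info.order_condition,
        target_ioi=info.target_ioi,
        tempo=tempo,
        retained=retained,
        coding=coding,
        n_strikes=n_strikes,
        gap_fraction=gap_fraction,
        missing_frac=missing_frac,
        flags=flags,
    )
    return TrialResult(record=record, spectra=spectra, signals=signals, child_label=child)


def _read_dataset_ledgers(path: str | Path) -> dict[tuple[str, int] | None, CorrectionLedger]:
    """Ledger CSV; optional child_id/trial_index columns scope directives.

    Rows without those columns apply to every trial.
    """
    df = pd.read_csv(path)
    out: dict[tuple[str, int] | None, CorrectionLedger] = {}
    scoped = "child_id" in df.columns and "trial_index" in df.columns
    for _, row in df.iterrows():
        key = (str(row["child_id"]), int(row["trial_index"])) if scoped else None
        pb = row.get("person_b")
        d = Directive(
            kind=str(row["kind"]),
            start=int(row["start_frame"]),
            end=int(row["end_frame"]),
            person_a=int(row["person_a"]),
            person_b=None if pd.isna(pb) else int(pb),
        )
        out.setdefault(key, CorrectionLedger()).directives.append(d)
    return out


def _trial_dir(input_dir: Path, info: TrialInfo) -> Path:
    cand = input_dir / info.child_id / f"trial{info.trial_index}"
    if cand.is_dir():
        return cand
    cand = input_dir / info.trial_id
    if cand.is_dir():
        return cand
    raise DataError(f"no frame directory for trial {info.trial_id} under {input_dir}")


def run_extract(config: RunConfig):
    """Process a whole dataset directory; returns (tidy, exclusions, report)."""
    input_dir = Path(config.input_dir)
    if not Path(config.metadata_path).is_file():
        raise DataError(f"metadata table not found: {config.metadata_path}")
    infos = read_trial_metadata(config.metadata_path)
    if config.fps_override is not None:
        infos = [
            TrialInfo(
                child_id=i.child_id,
                trial_index=i.trial_index,
                trial_type=i.trial_type,
                fps=config.fps_override,
                order_condition=i.order_condition,
                target_ioi=i.target_ioi,
            )
            for i in infos
        ]

    coding_map: dict[tuple[str, int], Coding] = {}
    if config.coding_path is not None:
        coding_map = read_coding(config.coding_path)
    else:
        logger.warning("no coding table supplied; trials will be flagged 'uncoded'")
    ledger_map = (
        _read_dataset_ledgers(config.ledger_path) if config.ledger_path is not None else {}
    )

    results: list[TrialResult] = []
    for info in infos:
        series = collate_trial_dir(_trial_dir(input_dir, info), info)
        ledger = ledger_map.get((info.child_id, info.trial_index), ledger_map.get(None))
        res = process_series(
            series,
            coding=coding_map.get((info.child_id, info.trial_index)),
            ledger=ledger,
            matcher=config.matcher,
            min_freq_hz=config.min_freq_hz,
            ghost_min_presence=config.ghost_min_presence,
            ghost_min_conf=config.ghost_min_conf,
            max_gap_s=config.max_gap_s,
            min_prominence_frac=config.min_prominence_frac,
        )
        results.append(res)

    records = [r.record for r in results]
    tidy, exclusions = export_tidy(records)
    report = {
        "version": __version__,
        "config": asdict(config),
        "n_trials": len(records),
        "n_included": int(len(tidy)),
        "n_excluded": int(len(exclusions)),
        "trial_flags": {
            f"{r.record.child_id}_t{r.record.trial_index}": r.record.flags
            for r in results
            if r.record.flags
        },
    }

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        tidy.to_csv(out / "tidy.csv", index=False)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        for field_name in ("ioi", "abs_mismatch", "n_strikes"):
            summarise_condition(records, field_name).to_csv(
                out / f"summary_{field_name}.csv", index=False
            )
        if config.write_spectra:
            spec_dir = out / "spectra"
            spec_dir.mkdir(exist_ok=True)
            for r in results:
                rows = []
                for hand, spec in r.spectra.items():
                    rows.append(
                        pd.DataFrame(
                            {
                                "child_id": r.record.child_id,
                                "trial_type": r.record.trial_type,
                                "hand": hand,
                                "freq_hz": spec.freq,
                                "power": spec.power,
                            }
                        )
                    )
                if rows:
                    pd.concat(rows).to_csv(
                        spec_dir / f"{r.record.child_id}_t{r.record.trial_index}.csv",
                        index=False,
                    )
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return tidy, exclusions, report


def run_simulate(spec: CohortSpec | str | Path, out_dir: str | Path):
    """Materialise a synthetic cohort to disk (see :mod:`drumpose.synth`)."""
    if not isinstance(spec, CohortSpec):
        spec = CohortSpec.from_json(spec)
    return generate_cohort(spec, out_dir=out_dir)
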