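"""Per-hand vertical displacement signals from cleaned pose series.

The hand's position in each frame is a confidence-weighted mean over
the wrist body keypoint and the 21 hand keypoints of that side.  Its
image y-coordinate is negated so that upward motion is positive — a
drum strike is then a local minimum of the signal.  Gaps (frames where
no contributing keypoint was detected) are linearly interpolated, and
the signal is mean-centered before spectral analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pose_io import LEFT_HAND, LEFT_WRIST, RIGHT_HAND, RIGHT_WRIST, FramePose, PoseTimeSeries

DEFAULT_MAX_GAP_S = 1.0


class EmptyTrackError(ValueError):
    """The requested person is absent (no contributing keypoint) in every frame."""


class UnusableTrialError(ValueError):
    """Fewer than two observed samples: nothing to interpolate between."""


def hand_member_indices(hand: str) -> np.ndarray:
    """Keypoint indices contributing to one hand: side wrist + 21 hand points."""
    if hand == "left":
        return np.r_[LEFT_WRIST, np.arange(LEFT_HAND.start, LEFT_HAND.stop)]
    if hand == "right":
        return np.r_[RIGHT_WRIST, np.arange(RIGHT_HAND.start, RIGHT_HAND.stop)]
    raise ValueError(f"hand must be 'left' or 'right', got {hand!r}")


@dataclass
class HandSignal:
    """Uniformly sampled vertical hand displacement for one trial.

    ``v`` is in pixels, up-positive.  ``observed`` marks samples backed
    by at least one detected keypoint; the rest are gaps (filled by
    :func:`interpolate_gaps`).  ``gap_fraction`` is the fraction of
    samples that were interpolated; ``long_gap`` flags a trial whose
    longest gap exceeded the interpolation limit (processed but marked
    for manual review).
    """

    child_id: str
    trial_type: str
    hand: str
    t: np.ndarray
    v: np.ndarray
    observed: np.ndarray
    fps: float
    gap_fraction: float = 0.0
    long_gap: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if not (len(self.t) == len(self.v) == len(self.observed)):
            raise ValueError("t, v and observed must share a length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if dt.min() <= 0 or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("t must be strictly increasing with a constant step")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fps

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per sample."""
        return pd.DataFrame(
            {
                "child_id": self.child_id,
                "trial_type": self.trial_type,
                "hand": self.hand,
                "frame": np.arange(self.n_samples),
                "t": self.t,
                "v": self.v,
                "observed": self.observed,
            }
        )


def hand_position(frame: FramePose, person: int, hand: str):
    """Confidence-weighted hand position in one frame.

    Returns ``(x, y, confidence)`` where the position is the mean of
    the detected members (wrist + hand keypoints) weighted by their
    detection confidences, and the returned confidence is the plain
    mean of the contributing confidences.  Returns None when no member
    is detected.
    """
    idx = hand_member_indices(hand)
    members = frame.keypoints[person, idx]
    conf = members[:, 2]
    detected = np.any(members != 0.0, axis=-1) & (conf > 0)
    if not detected.any():
        return None
    w = conf[detected]
    xy = (members[detected, :2] * w[:, None]).sum(axis=0) / w.sum()
    return float(xy[0]), float(xy[1]), float(w.mean())


def hand_position_series(series: PoseTimeSeries, person: int, hand: str):
    """Vectorised :func:`hand_position` over all frames of one track.

    Returns ``(pos, conf, mask)``: ``pos`` is ``(n_frames, 2)`` (NaN
    where missing), ``conf`` the mean contributing confidence, ``mask``
    True where the hand was observed.
    """
    idx = hand_member_indices(hand)
    members = series.data[:, person, idx, :]  # (n_frames, 22, 3)
    conf = members[..., 2]
    detected = np.any(members != 0.0, axis=-1) & (conf > 0)
    w = np.where(detected, conf, 0.0)
    wsum = w.sum(axis=1)
    mask = wsum > 0
    denom = np.where(mask, wsum, 1.0)
    pos = (members[..., :2] * w[..., None]).sum(axis=1) / denom[:, None]
    pos[~mask] = np.nan
    n_det = detected.sum(axis=1)
    mean_conf = np.where(mask, wsum / np.maximum(n_det, 1), np.nan)
    return pos, mean_conf, mask


def missing_member_fraction(series: PoseTimeSeries, person: int, hand: str) -> float:
    """Fraction of contributing marker samples (wrist+hand triples) undetected.

    This is the marker-level missing-data rate that gap interpolation /
    reweighting has to absorb, reported per trial.
    """
    idx = hand_member_indices(hand)
    members = series.data[:, person, idx, :]
    detected = np.any(members != 0.0, axis=-1)
    return float(1.0 - detected.mean())


def build_vertical_signal(series: PoseTimeSeries, person: int, hand: str) -> HandSignal:
    """Raw up-positive vertical hand signal; gaps left unfilled (NaN)."""
    pos, _conf, mask = hand_position_series(series, person, hand)
    if not mask.any():
        raise EmptyTrackError(
            f"{series.trial_info.trial_id}: person {person} {hand} hand never observed"
        )
    v = -pos[:, 1]  # image y grows downward; negate so up is positive
    return HandSignal(
        child_id=series.trial_info.child_id,
        trial_type=series.trial_info.trial_type,
        hand=hand,
        t=series.times,
        v=v,
        observed=mask,
        fps=series.trial_info.fps,
        gap_fraction=float((~mask).mean()),
    )


def _longest_gap(mask: np.ndarray) -> int:
    """Length of the longest run of unobserved samples."""
    longest = run = 0
    for obs in mask:
        run = 0 if obs else run + 1
        longest = max(longest, run)
    return longest


def interpolate_gaps(signal: HandSignal, max_gap_s: float = DEFAULT_MAX_GAP_S) -> HandSignal:
    """Fill gaps: linear between flanking samples, nearest-value at edges.

    Observed samples are conserved exactly.  Gaps longer than
    ``max_gap_s`` do not abort processing but set ``long_gap`` so the
    trial is flagged for manual review (a gap longer than a drumming
    period distorts the spectrum).
    """
    mask = signal.observed
    if mask.sum() < 2:
        raise UnusableTrialError(
            f"{signal.child_id} {signal.trial_type} {signal.hand}: "
            f"{int(mask.sum())} observed sample(s); need at least 2"
        )
    obs_idx = np.where(mask)[0]
    v = np.array(signal.v, dtype=float)
    # np.interp holds the nearest observed value beyond the edges.
    v[~mask] = np.interp(np.where(~mask)[0], obs_idx, v[obs_idx])
    long_gap = _longest_gap(mask) / signal.fps > max_gap_s
    return replace(
        signal,
        v=v,
        gap_fraction=float((~mask).mean()),
        long_gap=long_gap or signal.long_gap,
    )


def mean_center(signal: HandSignal) -> HandSignal:
    """Subtract the trial-mean vertical displacement (idempotent)."""
    v = signal.v - signal.v.mean()
    return replace(signal, v=v)
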