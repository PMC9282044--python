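"""Consistent person labelling across frames, ghost removal, corrections.

A markerless pose model labels people per frame, so "person 0" in one
frame may be "person 1" in the next.  This module relabels persons into
persistent tracks by matching each frame against the previous one,
either by location (centroid of detected body keypoints) or by figure
size (height of the body bounding box), using an exact minimum-cost
assignment.  Spurious background detections ("ghosts") are flagged by
low presence or low confidence, and a manual correction ledger can
swap, delete, or designate the child track for any frame range.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .pose_io import BODY, N_KEYPOINTS, FramePose, PoseTimeSeries

logger = logging.getLogger(__name__)

#: Above this fraction of the frame diagonal a match is rejected and the
#: person starts a fresh track (prevents teleporting matches).
DEFAULT_MAX_MATCH_FRAC = 0.25
DEFAULT_MIN_PRESENCE_FRAC = 0.2
DEFAULT_MIN_MEAN_CONF = 0.3

_BRUTE_FORCE_LIMIT = 4


class DirectiveError(ValueError):
    """A ledger directive references an unknown label or frame range."""


class NoTracksError(ValueError):
    """Child selection was asked for on a series with no tracks."""


@dataclass(frozen=True)
class Directive:
    """One manual correction: kind in {swap, delete, set_child}.

    Frame ranges are half-open ``[start, end)``, 0-based.  ``person_b``
    is used only by swap.
    """

    kind: str
    start: int
    end: int
    person_a: int
    person_b: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("swap", "delete", "set_child"):
            raise DirectiveError(f"unknown directive kind {self.kind!r}")
        if self.kind == "swap" and self.person_b is None:
            raise DirectiveError("swap requires person_b")


@dataclass
class CorrectionLedger:
    directives: list[Directive] = field(default_factory=list)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrectionLedger":
        directives = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                pb = row.get("person_b", "")
                directives.append(
                    Directive(
                        kind=row["kind"],
                        start=int(row["start_frame"]),
                        end=int(row["end_frame"]),
                        person_a=int(row["person_a"]),
                        person_b=int(pb) if pb not in ("", None) else None,
                    )
                )
        return cls(directives)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["kind", "start_frame", "end_frame", "person_a", "person_b"])
            for d in self.directives:
                w.writerow([d.kind, d.start, d.end, d.person_a,
                            "" if d.person_b is None else d.person_b])

    @property
    def child_label(self) -> int | None:
        label = None
        for d in self.directives:
            if d.kind == "set_child":
                label = d.person_a
        return label


@dataclass
class Assignment:
    """Mapping from current-frame person index to persistent track label."""

    mapping: dict[int, int]
    unmatched_new: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = list(self.mapping.values())
        if len(set(labels)) != len(labels):
            raise ValueError("assignment mapping must be injective")


def person_centroids(data: np.ndarray) -> np.ndarray:
    """Centroid of detected body keypoints, vectorised.

    ``data`` is ``(..., 67, 3)``; returns ``(..., 2)`` with NaN where a
    person has no detected body keypoint.  Hands are excluded: they
    vanish too often to give a stable centroid.
    """
    body = data[..., BODY, :]
    detected = np.any(body != 0.0, axis=-1)
    n = detected.sum(axis=-1)
    with np.errstate(invalid="ignore"):
        cent = np.where(detected[..., None], body[..., :2], 0.0).sum(axis=-2) / np.where(
            n[..., None] > 0, n[..., None], 1
        )
    cent = np.where(n[..., None] > 0, cent, np.nan)
    return cent


def person_sizes(data: np.ndarray) -> np.ndarray:
    """Height of the detected-body-keypoint bounding box; NaN if none."""
    body = data[..., BODY, :]
    detected = np.any(body != 0.0, axis=-1)
    y = body[..., 1]
    ymax = np.where(detected, y, -np.inf).max(axis=-1)
    ymin = np.where(detected, y, np.inf).min(axis=-1)
    size = ymax - ymin
    return np.where(np.isfinite(size), size, np.nan)


def _solve_assignment(cost: np.ndarray, max_cost: float) -> dict[int, int]:
    """Min-cost matching of columns (current) to rows (previous tracks).

    Exact brute force over injections for small problems (deterministic
    identity-order tie-break); Hungarian otherwise.  Pairs with cost
    above ``max_cost`` are dropped.  Costs are capped at ``max_cost``
    *during* optimisation: an edge that will be rejected anyway (e.g. a
    departing track vs an arriving one) must not be traded against good
    matches just to shrink the total.
    """
    n_prev, n_curr = cost.shape
    if n_prev == 0 or n_curr == 0:
        return {}
    raw = cost
    if np.isfinite(max_cost):
        cost = np.minimum(cost, max_cost)
    if max(n_prev, n_curr) <= _BRUTE_FORCE_LIMIT:
        best = None
        best_cost = np.inf
        if n_prev >= n_curr:
            for rows in permutations(range(n_prev), n_curr):
                c = sum(cost[r, j] for j, r in enumerate(rows))
                if c < best_cost:
                    best_cost = c
                    best = {j: r for j, r in enumerate(rows)}
        else:
            for cols in permutations(range(n_curr), n_prev):
                c = sum(cost[i, j] for i, j in enumerate(cols))
                if c < best_cost:
                    best_cost = c
                    best = {j: i for i, j in enumerate(cols)}
        pairs = best or {}
    else:
        rows, cols = linear_sum_assignment(cost)
        pairs = {int(j): int(i) for i, j in zip(rows, cols)}
    return {j: i for j, i in pairs.items() if raw[i, j] <= max_cost}


def _match_features(
    prev_feat: np.ndarray,
    curr_feat: np.ndarray,
    max_cost: float,
) -> Assignment:
    """Match on per-person feature vectors; NaN features are skipped."""
    prev_ok = np.where(~np.isnan(prev_feat).any(axis=-1))[0]
    curr_ok = np.where(~np.isnan(curr_feat).any(axis=-1))[0]
    cost = np.linalg.norm(
        prev_feat[prev_ok][:, None, :] - curr_feat[curr_ok][None, :, :], axis=-1
    )
    pairs = _solve_assignment(cost, max_cost)
    mapping: dict[int, int] = {}
    fresh = []
    next_label = len(prev_feat)
    for j_local, j in enumerate(curr_ok):
        if j_local in pairs:
            mapping[int(j)] = int(prev_ok[pairs[j_local]])
        else:
            mapping[int(j)] = next_label
            fresh.append(next_label)
            next_label += 1
    return Assignment(mapping=mapping, unmatched_new=fresh)


def match_by_location(
    prev: FramePose,
    curr: FramePose,
    max_dist: float = np.inf,
) -> Assignment:
    """Match current persons to previous ones by body-centroid distance.

    The assignment minimises the total centroid distance over matched
    pairs; unmatched current persons receive fresh labels.  Persons with
    no detected body keypoint are skipped.
    """
    return _match_features(
        person_centroids(prev.keypoints), person_centroids(curr.keypoints), max_dist
    )


def match_by_size(
    prev: FramePose,
    curr: FramePose,
    max_diff: float = np.inf,
) -> Assignment:
    """Match by figure size: minimise summed |body bounding-box height difference|."""
    return _match_features(
        person_sizes(prev.keypoints)[:, None], person_sizes(curr.keypoints)[:, None], max_diff
    )


def _frame_diagonal(data: np.ndarray) -> float:
    xy = data[..., :2]
    detected = np.any(data != 0.0, axis=-1)
    if not detected.any():
        return np.inf
    xmax = xy[..., 0][detected].max()
    ymax = xy[..., 1][detected].max()
    return float(np.hypot(xmax, ymax))


def relabel_series(
    series: PoseTimeSeries,
    method: str = "location",
    max_match_dist: float | None = None,
) -> PoseTimeSeries:
    """Relabel persons into persistent tracks across a whole trial.

    Frame 0 labels are taken as listed; each later frame is matched
    against the previous *relabelled* frame with the chosen matcher.
    Unmatched persons mint fresh labels, so the output person dimension
    may grow (e.g. a ghost confined to its own track).  Coordinates are
    never altered, only person indexing.
    """
    if method not in ("location", "size"):
        raise ValueError(f"unknown matching method {method!r}")
    data = series.data
    n_frames, n_persons = data.shape[:2]
    if method == "location":
        feats = person_centroids(data)  # (n_frames, n_persons, 2)
        if max_match_dist is None:
            max_match_dist = DEFAULT_MAX_MATCH_FRAC * _frame_diagonal(data)
    else:
        feats = person_sizes(data)[..., None]  # (n_frames, n_persons, 1)
        if max_match_dist is None:
            max_match_dist = np.inf

    # label_of[f, p] = persistent label of input person p at frame f (-1: absent)
    label_of = np.full((n_frames, n_persons), -1, dtype=int)
    present = ~np.isnan(feats).any(axis=-1)  # detected body this frame

    prev_labels: list[int] = []
    prev_feats_list: list[np.ndarray] = []
    n_labels = 0
    for p in range(n_persons):
        if present[0, p]:
            label_of[0, p] = p
            prev_labels.append(p)
            prev_feats_list.append(feats[0, p])
            n_labels = max(n_labels, p + 1)
        elif np.any(data[0, p] != 0.0):  # partial person without body kps
            label_of[0, p] = p
            n_labels = max(n_labels, p + 1)
    if n_labels == 0:
        n_labels = n_persons

    for f in range(1, n_frames):
        curr_idx = np.where(present[f])[0]
        if prev_labels and curr_idx.size:
            prev_feat = np.asarray(prev_feats_list)
            curr_feat = feats[f, curr_idx]
            cost = np.linalg.norm(
                prev_feat[:, None, :] - curr_feat[None, :, :], axis=-1
            )
            pairs = _solve_assignment(cost, max_match_dist)
        else:
            pairs = {}
        new_labels = []
        new_feats = []
        for j_local, p in enumerate(curr_idx):
            if j_local in pairs:
                lab = prev_labels[pairs[j_local]]
            else:
                lab = n_labels
                n_labels += 1
            label_of[f, p] = lab
            new_labels.append(lab)
            new_feats.append(feats[f, p])
        prev_labels = new_labels
        prev_feats_list = new_feats

    out = np.zeros((n_frames, n_labels, N_KEYPOINTS, 3))
    f_idx, p_idx = np.where(label_of >= 0)
    out[f_idx, label_of[f_idx, p_idx]] = data[f_idx, p_idx]
    return PoseTimeSeries(
        trial_info=series.trial_info,
        data=out,
        provenance=list(series.provenance),
        child_label=series.child_label,
    )


def flag_ghosts(
    series: PoseTimeSeries,
    min_presence_frac: float = DEFAULT_MIN_PRESENCE_FRAC,
    min_mean_conf: float = DEFAULT_MIN_MEAN_CONF,
) -> set[int]:
    """Flag tracks present in too few frames or with too-low confidence.

    A track is flagged when it appears in fewer than
    ``min_presence_frac`` of frames OR its mean detection confidence
    (over detected keypoints) is below ``min_mean_conf``.
    """
    detected = np.any(series.data != 0.0, axis=-1)  # (f, p, k)
    present = detected.any(axis=-1)  # (f, p)
    presence_frac = present.mean(axis=0)
    conf = series.data[..., 2]
    n_det = detected.sum(axis=(0, 2))
    mean_conf = np.where(
        n_det > 0, np.where(detected, conf, 0.0).sum(axis=(0, 2)) / np.maximum(n_det, 1), 0.0
    )
    flagged = {
        p
        for p in range(series.n_persons)
        if presence_frac[p] < min_presence_frac or mean_conf[p] < min_mean_conf
    }
    active = {p for p in range(series.n_persons) if present[:, p].any()}
    if active and active <= flagged:
        logger.warning(
            "%s: every track flagged as ghost; no candidate child remains",
            series.trial_info.trial_id,
        )
    return flagged


def apply_ledger(series: PoseTimeSeries, ledger: CorrectionLedger) -> PoseTimeSeries:
    """Apply manual corrections in listed order.

    swap exchanges two labels over a frame range; delete blanks a label
    over a range; set_child records the child label in trial metadata.
    """
    data = series.data.copy()
    child = series.child_label
    n_frames, n_persons = data.shape[:2]
    for d in ledger.directives:
        if not (0 <= d.start <= d.end <= n_frames):
            raise DirectiveError(f"{d}: frame range outside [0, {n_frames}]")
        if not (0 <= d.person_a < n_persons):
            raise DirectiveError(f"{d}: unknown label {d.person_a}")
        if d.kind == "swap":
            if not (0 <= d.person_b < n_persons):
                raise DirectiveError(f"{d}: unknown label {d.person_b}")
            sl = slice(d.start, d.end)
            a, b = d.person_a, d.person_b
            data[sl, [a, b]] = data[sl, [b, a]]
        elif d.kind == "delete":
            data[d.start : d.end, d.person_a] = 0.0
        else:  # set_child
            child = d.person_a
    return PoseTimeSeries(
        trial_info=series.trial_info,
        data=data,
        provenance=list(series.provenance),
        child_label=child,
    )


def select_child(
    series: PoseTimeSeries,
    ledger: CorrectionLedger | None = None,
    flagged: set[int] | None = None,
) -> int:
    """Pick the child's track label.

    A ledger ``set_child`` directive (or a child label already recorded
    on the series) takes precedence.  Otherwise a heuristic fallback is
    used and logged: the unflagged track whose hands show the greatest
    vertical-displacement variance — the drumming child moves its hands
    far more than a seated caregiver.
    """
    if ledger is not None and ledger.child_label is not None:
        return ledger.child_label
    if series.child_label is not None:
        return series.child_label

    detected = np.any(series.data != 0.0, axis=-1)
    candidates = [
        p
        for p in range(series.n_persons)
        if detected[:, p].any() and (flagged is None or p not in flagged)
    ]
    if not candidates:
        raise NoTracksError(f"{series.trial_info.trial_id}: no candidate tracks")
    if len(candidates) == 1:
        return candidates[0]

    from .kinematics import hand_position_series  # local import avoids cycle at import time

    scores = []
    for p in candidates:
        var = 0.0
        for hand in ("left", "right"):
            pos, _conf, mask = hand_position_series(series, p, hand)
            if mask.sum() >= 2:
                var += float(np.var(pos[mask, 1]))
        scores.append(var)
    winner = candidates[int(np.argmax(scores))]
    logger.info(
        "%s: child selected by variance fallback -> track %d (scores %s)",
        series.trial_info.trial_id,
        winner,
        dict(zip(candidates, np.round(scores, 2))),
    )
    return winner
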