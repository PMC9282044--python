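"""Synthetic pose-JSON cohorts with complete ground truth.

Emulates the experimental structure the pipeline is built for: each
child contributes six 20-s trials — an unpaced spontaneous-motor-tempo
(SMT) trial first and last, and four paced trials at target IOIs of
400-700 ms presented in one of two counterbalanced orders.  The child
drums in bursts: the drumming hand's vertical trajectory is a
lift-and-hit cycle train whose period is a convex mix of the target
IOI and the child's own SMT (``adaptation`` = 0 drums at the SMT
regardless of pacing, 1 matches the target exactly), with per-cycle
Gaussian timing jitter.  An optional static caregiver sits higher in
frame and is rendered larger than the child, giving size-based
matching a real signal.

Pose-model pathologies are injected with known rates and fully logged:
per-frame person-listing permutations (identity switches), episodic
low-confidence static "ghost" figures, and independent zeroing of
keypoint triples (missing data).  Replaying the log on the clean data
reproduces the corrupted data exactly, so every cleaning stage can be
validated against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pose_io import (
    LEFT_HAND,
    LEFT_WRIST,
    N_KEYPOINTS,
    ORDER_SEQUENCES,
    RIGHT_HAND,
    RIGHT_WRIST,
    FramePose,
    PoseTimeSeries,
    TrialInfo,
    trial_metadata_frame,
    write_openpose_frame,
)

# ---------------------------------------------------------------------------
# Figure templates (BODY_25 layout, unit body height, image y grows down).

_B = np.zeros((25, 2))
_B[0] = (0.00, -0.18)   # nose
_B[1] = (0.00, 0.00)    # neck
_B[2] = (-0.15, 0.02)   # R shoulder
_B[3] = (-0.22, 0.22)   # R elbow
_B[4] = (-0.24, 0.42)   # R wrist
_B[5] = (0.15, 0.02)    # L shoulder
_B[6] = (0.22, 0.22)    # L elbow
_B[7] = (0.24, 0.42)    # L wrist
_B[8] = (0.00, 0.48)    # mid hip
_B[9] = (-0.09, 0.48)   # R hip
_B[10] = (-0.10, 0.72)  # R knee
_B[11] = (-0.11, 0.96)  # R ankle
_B[12] = (0.09, 0.48)   # L hip
_B[13] = (0.10, 0.72)   # L knee
_B[14] = (0.11, 0.96)   # L ankle
_B[15] = (-0.03, -0.20)  # R eye
_B[16] = (0.03, -0.20)   # L eye
_B[17] = (-0.07, -0.17)  # R ear
_B[18] = (0.07, -0.17)   # L ear
_B[19] = (0.13, 1.00)    # L big toe
_B[20] = (0.15, 1.00)    # L small toe
_B[21] = (0.10, 0.98)    # L heel
_B[22] = (-0.13, 1.00)   # R big toe
_B[23] = (-0.15, 1.00)   # R small toe
_B[24] = (-0.10, 0.98)   # R heel
BODY_TEMPLATE = _B

# 21 hand keypoints fanned out below the wrist.
_h = [(0.0, 0.0)]
for finger in range(5):
    fx = (finger - 2) * 0.018
    for joint in range(1, 5):
        _h.append((fx, 0.02 + 0.016 * joint))
HAND_TEMPLATE = np.asarray(_h)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the experiment the pipeline targets: 20-s trials at
    30 fps, three ~5-s drumming bursts per trial, child SMT drawn from
    Normal(550, 80) ms, moderate pacing adaptation and per-cycle motor
    jitter of 30 ms.  All corruption rates default to zero (clean
    data); ``seed`` fixes every random draw.
    """

    n_children: int = 10
    fps: float = 30.0
    trial_s: float = 20.0
    smt_mean_ms: float = 550.0
    smt_sd_ms: float = 80.0
    adaptation: float = 0.5
    motor_noise_sd_ms: float = 30.0
    n_bursts: int = 3
    burst_s: float = 5.0
    rest_s: float = 2.0
    caregiver_present: bool = True
    swap_rate: float = 0.0
    ghost_rate: float = 0.0
    missing_rate: float = 0.0
    waveform: str = "raised_cosine"  # or "sine"
    amplitude_px: float = 40.0
    pos_noise_px: float = 0.5
    frame_w: int = 640
    frame_h: int = 480
    drumming_hand: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("swap_rate", "ghost_rate", "missing_rate", "adaptation"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if abs(self.trial_s * self.fps - round(self.trial_s * self.fps)) > 1e-9:
            raise ValueError("trial_s x fps must be an integral frame count")
        if self.waveform not in ("raised_cosine", "sine"):
            raise ValueError(f"waveform must be raised_cosine or sine, got {self.waveform!r}")
        if self.drumming_hand not in ("left", "right"):
            raise ValueError("drumming_hand must be left or right")

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_s * self.fps))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown cohort-spec fields: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class GhostEpisode:
    """A static spurious figure present over frames [start, end)."""

    start: int
    end: int
    keypoints: np.ndarray  # (67, 3), constant over the episode

    def to_dict(self) -> dict:
        return {"start": self.start, "end": self.end, "keypoints": self.keypoints.tolist()}


@dataclass
class TrialTruth:
    """Complete ground truth for one generated trial."""

    child_id: str
    trial_index: int
    trial_type: str
    order_condition: int
    target_ioi: float | None
    smt_ms: float
    true_ioi: float
    strike_times: np.ndarray
    drumming_hand: str
    child_person_index: int
    n_persons_clean: int
    swap_events: list[tuple[int, list[int]]] = field(default_factory=list)
    ghost_episodes: list[GhostEpisode] = field(default_factory=list)
    missing_triples: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=int))

    def to_dict(self) -> dict:
        return {
            "child_id": self.child_id,
            "trial_index": self.trial_index,
            "trial_type": self.trial_type,
            "order_condition": self.order_condition,
            "target_ioi": self.target_ioi,
            "smt_ms": self.smt_ms,
            "true_ioi": self.true_ioi,
            "strike_times": np.asarray(self.strike_times).tolist(),
            "drumming_hand": self.drumming_hand,
            "child_person_index": self.child_person_index,
            "n_persons_clean": self.n_persons_clean,
            "swap_events": [[f, list(p)] for f, p in self.swap_events],
            "ghost_episodes": [g.to_dict() for g in self.ghost_episodes],
            "missing_triples": np.asarray(self.missing_triples).tolist(),
        }


@dataclass
class TrialData:
    """Generated frames (per-frame person arrays), truth, and metadata."""

    frames: list[np.ndarray]
    truth: TrialTruth
    info: TrialInfo

    def to_series(self) -> PoseTimeSeries:
        """Pad to a common person count, as collation of the JSON would."""
        n_frames = len(self.frames)
        max_p = max((f.shape[0] for f in self.frames), default=0)
        data = np.zeros((n_frames, max_p, N_KEYPOINTS, 3))
        names = self.frame_names()
        for k, fr in enumerate(self.frames):
            if fr.shape[0]:
                data[k, : fr.shape[0]] = fr
        return PoseTimeSeries(trial_info=self.info, data=data, provenance=names)

    def frame_names(self) -> list[str]:
        tid = self.info.trial_id
        return [f"{tid}_{k:012d}_keypoints.json" for k in range(len(self.frames))]

    def to_json_docs(self) -> list[tuple[str, str]]:
        return [
            (name, write_openpose_frame(FramePose(fr.reshape(-1, N_KEYPOINTS, 3))))
            for name, fr in zip(self.frame_names(), self.frames)
        ]

    def write(self, trial_dir: str | Path) -> None:
        trial_dir = Path(trial_dir)
        trial_dir.mkdir(parents=True, exist_ok=True)
        for name, doc in self.to_json_docs():
            (trial_dir / name).write_text(doc)


# ---------------------------------------------------------------------------
# Motion model


def burst_windows(spec: CohortSpec) -> list[tuple[float, float]]:
    """Drumming-burst intervals in seconds (bursts separated by rests)."""
    windows = []
    t = 0.5
    for _ in range(spec.n_bursts):
        end = min(t + spec.burst_s, spec.trial_s - 0.1)
        if end > t:
            windows.append((t, end))
        t = end + spec.rest_s
    return windows


def strike_times_for_trial(
    spec: CohortSpec, ioi_ms: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Strike times per burst: successive gaps = IOI + N(0, motor noise).

    Strikes lie on one continuous lattice spanning the whole trial (the
    child's motor clock keeps ticking through rests) and only those
    falling inside a burst window are expressed, so bursts stay
    phase-coherent with each other.
    """
    windows = burst_windows(spec)
    if not windows:
        return []
    lattice = [windows[0][0]]
    while lattice[-1] <= spec.trial_s:
        gap = ioi_ms + rng.normal(0.0, spec.motor_noise_sd_ms)
        gap = max(gap, 0.2 * ioi_ms)  # keep periods positive and sane
        lattice.append(lattice[-1] + gap / 1000.0)
    lattice = np.asarray(lattice)
    per_burst = []
    for start, end in windows:
        inside = lattice[(lattice >= start - 1e-12) & (lattice <= end)]
        if len(inside):
            per_burst.append(inside)
    return per_burst


def lift_trajectory(
    t: np.ndarray,
    strikes_per_burst: Sequence[np.ndarray],
    amplitude: float,
    waveform: str,
) -> np.ndarray:
    """Vertical lift (pixels, up-positive) of the drumming hand over time.

    Each inter-strike interval is one lift-and-hit cycle: the hand is
    at the surface (lift 0) at every strike.  ``raised_cosine`` squares
    the raised-cosine arch, concentrating time near the surface and
    adding harmonic content; ``sine`` is the plain arch (a pure tone).
    """
    lift = np.zeros_like(t)
    for strikes in strikes_per_burst:
        if len(strikes) < 2:
            continue
        inside = (t >= strikes[0]) & (t <= strikes[-1])
        if not inside.any():
            continue
        seg = np.searchsorted(strikes, t[inside], side="right") - 1
        seg = np.clip(seg, 0, len(strikes) - 2)
        s0 = strikes[seg]
        s1 = strikes[seg + 1]
        phase = (t[inside] - s0) / (s1 - s0)
        arch = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        if waveform == "raised_cosine":
            arch = arch**2
        lift[inside] = amplitude * arch
    return lift


def _figure_keypoints(
    root: np.ndarray, scale: float, lift: np.ndarray | None, drumming_hand: str | None
) -> np.ndarray:
    """Assemble (n_frames, 67, 2) coordinates for one figure.

    ``lift`` (up-positive, per frame) moves the drumming hand's wrist
    and 21 hand keypoints; everything else is static.
    """
    n_frames = 1 if lift is None else len(lift)
    base = np.zeros((N_KEYPOINTS, 2))
    base[:25] = root + scale * BODY_TEMPLATE
    base[LEFT_HAND] = base[LEFT_WRIST] + scale * HAND_TEMPLATE
    base[RIGHT_HAND] = base[RIGHT_WRIST] + scale * HAND_TEMPLATE
    coords = np.broadcast_to(base, (n_frames, N_KEYPOINTS, 2)).copy()
    if lift is not None and drumming_hand is not None:
        if drumming_hand == "right":
            idx = np.r_[RIGHT_WRIST, np.arange(RIGHT_HAND.start, RIGHT_HAND.stop)]
        else:
            idx = np.r_[LEFT_WRIST, np.arange(LEFT_HAND.start, LEFT_HAND.stop)]
        coords[:, idx, 1] -= lift[:, None]  # image y decreases as the hand lifts
    return coords


def generate_trial(
    spec: CohortSpec,
    child_id: str,
    trial_index: int,
    trial_type: str,
    order_condition: int,
    smt_ms: float,
    seed,
) -> TrialData:
    """Generate one trial: clean figures, drumming motion, then corruption.

    The drummed IOI is ``adaptation*target + (1-adaptation)*smt`` on
    paced trials and the child's SMT on unpaced trials.  Identical
    spec + seed give byte-identical output.
    """
    rng = np.random.default_rng(seed)
    info = TrialInfo(
        child_id=child_id,
        trial_index=trial_index,
        trial_type=trial_type,
        fps=spec.fps,
        order_condition=order_condition,
    )
    if info.is_smt:
        true_ioi = smt_ms
    else:
        true_ioi = spec.adaptation * info.target_ioi + (1.0 - spec.adaptation) * smt_ms

    n_frames = spec.n_frames
    t = np.arange(n_frames) / spec.fps
    strikes_per_burst = strike_times_for_trial(spec, true_ioi, rng)
    lift = lift_trajectory(t, strikes_per_burst, spec.amplitude_px, spec.waveform)

    base_scale = 200.0
    figures = []
    if spec.caregiver_present:
        caregiver_root = np.array([0.62 * spec.frame_w, 0.30 * spec.frame_h])
        figures.append(_figure_keypoints(caregiver_root, base_scale, None, None))
    child_root = np.array([0.35 * spec.frame_w, 0.45 * spec.frame_h])
    figures.append(
        _figure_keypoints(child_root, 0.6 * base_scale, lift, spec.drumming_hand)
    )
    child_person_index = len(figures) - 1

    n_persons = len(figures)
    coords = np.zeros((n_frames, n_persons, N_KEYPOINTS, 2))
    for p, fig in enumerate(figures):
        coords[:, p] = fig if fig.shape[0] == n_frames else fig[0]
    if spec.pos_noise_px > 0:
        coords += rng.normal(0.0, spec.pos_noise_px, size=coords.shape)
    conf = rng.uniform(0.4, 0.95, size=(n_frames, n_persons, N_KEYPOINTS))
    clean = np.round(np.concatenate([coords, conf[..., None]], axis=-1), 3)

    frames = [clean[k].copy() for k in range(n_frames)]
    frames, swap_events, ghost_episodes, missing = corrupt(frames, spec, rng)

    truth = TrialTruth(
        child_id=child_id,
        trial_index=trial_index,
        trial_type=trial_type,
        order_condition=order_condition,
        target_ioi=info.target_ioi,
        smt_ms=smt_ms,
        true_ioi=true_ioi,
        strike_times=np.concatenate(strikes_per_burst) if strikes_per_burst else np.empty(0),
        drumming_hand=spec.drumming_hand,
        child_person_index=child_person_index,
        n_persons_clean=n_persons,
        swap_events=swap_events,
        ghost_episodes=ghost_episodes,
        missing_triples=missing,
    )
    return TrialData(frames=frames, truth=truth, info=info)


def _make_ghost(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """A static partial figure of low-confidence body keypoints."""
    kp = np.zeros((N_KEYPOINTS, 3))
    pos = np.array([rng.uniform(0, spec.frame_w), rng.uniform(0, spec.frame_h)])
    visible = rng.choice(25, size=10, replace=False)
    kp[visible, :2] = np.round(pos + rng.normal(0, 15.0, size=(10, 2)), 3)
    kp[visible, 2] = np.round(rng.uniform(0.05, 0.3, size=10), 3)
    return kp


_GHOST_MEAN_SPAN = 6


def corrupt(
    frames: list[np.ndarray],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list, list, np.ndarray]:
    """Inject ghosts, identity swaps, and missing triples; log everything.

    Per frame: a ghost episode (static low-confidence figure spanning a
    few frames) starts with probability ``ghost_rate / mean_span`` so
    roughly ``ghost_rate`` of frames contain a ghost; the person
    listing is permuted with probability ``swap_rate``; each keypoint
    triple is independently zeroed with probability ``missing_rate``.
    Replaying the returned log on clean frames reproduces the output
    exactly (see :func:`replay_corruption`).
    """
    frames = [f.copy() for f in frames]
    n_frames = len(frames)

    ghost_episodes: list[GhostEpisode] = []
    if spec.ghost_rate > 0:
        f = 0
        while f < n_frames:
            if rng.random() < spec.ghost_rate / _GHOST_MEAN_SPAN:
                span = int(rng.integers(3, 2 * _GHOST_MEAN_SPAN - 2))
                end = min(f + span, n_frames)
                ghost_episodes.append(GhostEpisode(start=f, end=end, keypoints=_make_ghost(spec, rng)))
                f = end
            else:
                f += 1
        for ep in ghost_episodes:
            for k in range(ep.start, ep.end):
                frames[k] = np.vstack([frames[k], ep.keypoints[None]])

    swap_events: list[tuple[int, list[int]]] = []
    if spec.swap_rate > 0:
        for k in range(n_frames):
            n_p = frames[k].shape[0]
            if n_p >= 2 and rng.random() < spec.swap_rate:
                perm = rng.permutation(n_p)
                while (perm == np.arange(n_p)).all():
                    perm = rng.permutation(n_p)
                frames[k] = frames[k][perm]
                swap_events.append((k, perm.tolist()))

    missing_list = []
    if spec.missing_rate > 0:
        for k in range(n_frames):
            mask = rng.random(frames[k].shape[:2]) < spec.missing_rate
            if mask.any():
                frames[k][mask] = 0.0
                p_idx, kp_idx = np.where(mask)
                missing_list.append(
                    np.column_stack([np.full(len(p_idx), k), p_idx, kp_idx])
                )
    missing = (
        np.concatenate(missing_list).astype(int)
        if missing_list
        else np.empty((0, 3), dtype=int)
    )
    return frames, swap_events, ghost_episodes, missing


def replay_corruption(clean_frames: Sequence[np.ndarray], truth: TrialTruth) -> list[np.ndarray]:
    """Re-apply a logged corruption record to clean frames.

    Ground-truth completeness check: the result must equal the
    corrupted frames bit for bit.
    """
    frames = [f.copy() for f in clean_frames]
    for ep in truth.ghost_episodes:
        for k in range(ep.start, ep.end):
            frames[k] = np.vstack([frames[k], ep.keypoints[None]])
    for k, perm in truth.swap_events:
        frames[k] = frames[k][np.asarray(perm)]
    for k, p, kp in np.asarray(truth.missing_triples, dtype=int).reshape(-1, 3):
        frames[k][p, kp] = 0.0
    return frames


# ---------------------------------------------------------------------------
# Cohort assembly


def child_trial_plan(order_condition: int) -> list[tuple[int, str]]:
    """The six (trial_index, trial_type) slots for one child."""
    plan = [(1, "SMT1")]
    for i, target in enumerate(ORDER_SEQUENCES[order_condition]):
        plan.append((2 + i, f"P{target}"))
    plan.append((6, "SMT2"))
    return plan


def draw_child_smt(spec: CohortSpec, child_index: int) -> float:
    """The child's spontaneous motor tempo in ms (fixed per child)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(child_index, 0)))
    return float(np.clip(rng.normal(spec.smt_mean_ms, spec.smt_sd_ms), 300.0, 1200.0))


def generate_cohort(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
) -> tuple[list[TrialData], dict]:
    """Generate n_children x 6 trials; children alternate order 1/2.

    When ``out_dir`` is given the cohort is materialised as per-frame
    JSON files under ``<out_dir>/<child_id>/trial<k>/`` plus a trial
    metadata CSV (``trials.csv``) and a ground-truth manifest
    (``ground_truth.json``).
    """
    trials: list[TrialData] = []
    for c in range(spec.n_children):
        child_id = f"child{c:03d}"
        order = 1 if c % 2 == 0 else 2
        smt = draw_child_smt(spec, c)
        for trial_index, trial_type in child_trial_plan(order):
            seed = np.random.SeedSequence(spec.seed, spawn_key=(c, trial_index))
            trials.append(
                generate_trial(spec, child_id, trial_index, trial_type, order, smt, seed)
            )
    manifest = {
        "spec": asdict(spec),
        "trials": [t.truth.to_dict() for t in trials],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for t in trials:
            t.write(out_dir / t.info.child_id / f"trial{t.info.trial_index}")
        trial_metadata_frame([t.info for t in trials]).to_csv(
            out_dir / "trials.csv", index=False
        )
        (out_dir / "ground_truth.json").write_text(json.dumps(manifest))
    return trials, manifest
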