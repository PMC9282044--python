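"""Reading, collating and storing markerless-pose keypoint time series.

The on-disk input is the OpenPose per-frame JSON dialect: one file per
video frame, each containing a ``people`` list.  Every person carries
flat ``[x, y, c]`` triple arrays for 25 BODY_25 body keypoints and,
optionally, 21 keypoints per hand.  Coordinates are image pixels with
the origin at the top-left (y grows downward); ``c`` is a detection
confidence in [0, 1].  The all-zero triple ``(0, 0, 0)`` marks an
undetected keypoint.

A trial's worth of frames is collated into a :class:`PoseTimeSeries`,
a dense ``(n_frames, n_persons, 67, 3)`` array (25 body + 21 left-hand
+ 21 right-hand keypoints) padded to a common person count.  Datasets
of many trials round-trip through a single compressed ``.npz`` store
with a sidecar CSV of trial metadata.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_BODY = 25
N_HAND = 21
N_KEYPOINTS = N_BODY + 2 * N_HAND  # 67

BODY = slice(0, N_BODY)
LEFT_HAND = slice(N_BODY, N_BODY + N_HAND)
RIGHT_HAND = slice(N_BODY + N_HAND, N_KEYPOINTS)

# BODY_25 wrist indices (model-defined landmark numbering).
RIGHT_WRIST = 4
LEFT_WRIST = 7

TRIAL_TYPES = ("SMT1", "P400", "P500", "P600", "P700", "SMT2")
PACED_TARGETS = {"P400": 400.0, "P500": 500.0, "P600": 600.0, "P700": 700.0}
#: Counterbalanced target-IOI sequences for trials 2-5.
ORDER_SEQUENCES = {1: (400, 600, 500, 700), 2: (700, 500, 600, 400)}

SCHEMA_VERSION = 1

_FRAME_INDEX_RE = re.compile(r"(\d+)_keypoints\.json$")


class PoseParseError(ValueError):
    """Raised when a frame document is not valid JSON."""


class PoseFormatError(ValueError):
    """Raised when a frame document violates the keypoint-array layout."""


class EmptyTrialError(ValueError):
    """Raised when a trial contains zero frame documents."""


class StoreVersionError(ValueError):
    """Raised when a store was written by a newer schema than this reader."""


@dataclass(frozen=True)
class TrialInfo:
    """Metadata for one 20-s trial of one child.

    ``trial_type`` is one of SMT1/SMT2 (unpaced spontaneous-motor-tempo
    trials) or P400/P500/P600/P700 (paced trials whose stimulus
    inter-onset interval in ms is the numeric suffix).  ``target_ioi``
    is present exactly for paced trials.
    """

    child_id: str
    trial_index: int
    trial_type: str
    fps: float
    order_condition: int
    target_ioi: float | None = None

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if not 1 <= self.trial_index <= 6:
            raise ValueError(f"trial_index must be 1..6, got {self.trial_index}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.order_condition not in (1, 2):
            raise ValueError("order_condition must be 1 or 2")
        if self.is_smt:
            if self.target_ioi is not None:
                raise ValueError("SMT trials carry no target_ioi")
        else:
            expected = PACED_TARGETS[self.trial_type]
            if self.target_ioi is None:
                object.__setattr__(self, "target_ioi", expected)
            elif self.target_ioi != expected:
                raise ValueError(
                    f"target_ioi {self.target_ioi} inconsistent with {self.trial_type}"
                )

    @property
    def is_smt(self) -> bool:
        return self.trial_type in ("SMT1", "SMT2")

    @property
    def trial_id(self) -> str:
        return f"{self.child_id}_t{self.trial_index}"


@dataclass
class FramePose:
    """All detected persons in one frame: array ``(n_persons, 67, 3)``."""

    keypoints: np.ndarray

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.ndim != 3 or kp.shape[1:] != (N_KEYPOINTS, 3):
            raise ValueError(f"expected (n, {N_KEYPOINTS}, 3), got {kp.shape}")
        self.keypoints = kp

    @property
    def n_persons(self) -> int:
        return self.keypoints.shape[0]

    def body(self, person: int) -> np.ndarray:
        return self.keypoints[person, BODY]

    def left_hand(self, person: int) -> np.ndarray:
        return self.keypoints[person, LEFT_HAND]

    def right_hand(self, person: int) -> np.ndarray:
        return self.keypoints[person, RIGHT_HAND]

    def missing(self, person: int) -> np.ndarray:
        """Boolean (67,) mask of undetected keypoints for one person."""
        return ~np.any(self.keypoints[person] != 0.0, axis=-1)


@dataclass
class PoseTimeSeries:
    """One trial of consistently shaped pose data.

    ``data`` has shape ``(n_frames, n_persons, 67, 3)``; padding persons
    (added so every frame shares a person count) are entirely the
    missing triple.  ``provenance`` records the source file name of each
    frame ("" for frames synthesised to fill an index gap).
    ``child_label`` is filled in by track cleaning once the child's
    track is known.
    """

    trial_info: TrialInfo
    data: np.ndarray
    provenance: list[str] = field(default_factory=list)
    child_label: int | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 4 or d.shape[2:] != (N_KEYPOINTS, 3):
            raise ValueError(f"expected (n_frames, n_persons, {N_KEYPOINTS}, 3), got {d.shape}")
        if d.shape[0] < 1:
            raise EmptyTrialError("a trial needs at least one frame")
        self.data = d
        if not self.provenance:
            self.provenance = [""] * d.shape[0]
        if len(self.provenance) != d.shape[0]:
            raise ValueError("provenance length must match n_frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_persons(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds: frame k at k/fps."""
        return np.arange(self.n_frames) / self.trial_info.fps

    def missing(self) -> np.ndarray:
        """Boolean (n_frames, n_persons, 67) mask of undetected keypoints."""
        return ~np.any(self.data != 0.0, axis=-1)

    def frame(self, k: int) -> FramePose:
        return FramePose(self.data[k].copy())


def _reshape_triples(raw: Sequence[float], n_slots: int, what: str, source: str) -> np.ndarray:
    arr = np.asarray(raw, dtype=float)
    if arr.size % 3 != 0:
        raise PoseFormatError(
            f"{source}: {what} array length {arr.size} is not a multiple of 3"
        )
    arr = arr.reshape(-1, 3)
    if arr.shape[0] > n_slots:
        raise PoseFormatError(
            f"{source}: {what} has {arr.shape[0]} keypoints, at most {n_slots} allowed"
        )
    if arr.shape[0] < n_slots:
        pad = np.zeros((n_slots - arr.shape[0], 3))
        arr = np.vstack([arr, pad])
    return arr


def read_openpose_frame(json_doc: str, source: str = "<doc>") -> FramePose:
    """Parse one OpenPose-dialect frame document.

    Absent hand arrays become 21 missing triples; person order is
    preserved.  Face and 3-D keypoint fields are ignored.
    """
    try:
        doc = json.loads(json_doc)
    except json.JSONDecodeError as exc:
        raise PoseParseError(f"{source}: malformed JSON ({exc})") from exc
    people = doc.get("people")
    if people is None:
        raise PoseFormatError(f"{source}: document has no 'people' list")
    persons = np.zeros((len(people), N_KEYPOINTS, 3))
    for i, person in enumerate(people):
        persons[i, BODY] = _reshape_triples(
            person.get("pose_keypoints_2d", []), N_BODY, "body", source
        )
        persons[i, LEFT_HAND] = _reshape_triples(
            person.get("hand_left_keypoints_2d", []), N_HAND, "left hand", source
        )
        persons[i, RIGHT_HAND] = _reshape_triples(
            person.get("hand_right_keypoints_2d", []), N_HAND, "right hand", source
        )
    return FramePose(persons)


def write_openpose_frame(frame: FramePose) -> str:
    """Serialise a frame back to the OpenPose JSON dialect (lossless)."""
    people = []
    for p in range(frame.n_persons):
        kp = frame.keypoints[p]
        people.append(
            {
                "person_id": [-1],
                "pose_keypoints_2d": kp[BODY].ravel().tolist(),
                "face_keypoints_2d": [],
                "hand_left_keypoints_2d": kp[LEFT_HAND].ravel().tolist(),
                "hand_right_keypoints_2d": kp[RIGHT_HAND].ravel().tolist(),
            }
        )
    return json.dumps({"version": 1.3, "people": people})


def frame_index_from_name(name: str) -> int | None:
    """Frame counter from the OpenPose file-name convention.

    OpenPose writes ``<prefix>_<zero-padded counter>_keypoints.json``;
    falls back to the last digit run in the name.  Returns None when no
    digits are present.
    """
    m = _FRAME_INDEX_RE.search(name)
    if m:
        return int(m.group(1))
    runs = re.findall(r"\d+", name)
    return int(runs[-1]) if runs else None


def collate_trial(
    frame_docs: Iterable[str | tuple[str, str]],
    trial_info: TrialInfo,
) -> PoseTimeSeries:
    """Combine per-frame documents into one multi-dimensional series.

    ``frame_docs`` is a sequence of JSON texts or ``(file_name, text)``
    pairs.  When names are supplied the frames are ordered by the index
    parsed from each name, so input order is immaterial; index gaps are
    filled with fully missing frames (with a warning).  The person
    dimension is padded to the per-trial maximum.
    """
    docs = list(frame_docs)
    if not docs:
        raise EmptyTrialError(f"{trial_info.trial_id}: no frame documents")

    named = [d if isinstance(d, tuple) else (f"frame{i:012d}", d) for i, d in enumerate(docs)]
    indices = [frame_index_from_name(name) for name, _ in named]
    if any(i is None for i in indices):
        indices = list(range(len(named)))
    order = np.argsort(np.asarray(indices, dtype=int), kind="stable")
    named = [named[i] for i in order]
    indices = [indices[i] for i in order]

    first, last = indices[0], indices[-1]
    n_frames = last - first + 1
    if n_frames != len(named):
        warnings.warn(
            f"{trial_info.trial_id}: non-contiguous frame indices "
            f"({len(named)} docs spanning {n_frames} frames); gaps treated as missing",
            stacklevel=2,
        )

    frames: list[np.ndarray | None] = [None] * n_frames
    provenance = [""] * n_frames
    max_persons = 0
    for (name, text), idx in zip(named, indices):
        fp = read_openpose_frame(text, source=name)
        frames[idx - first] = fp.keypoints
        provenance[idx - first] = name
        max_persons = max(max_persons, fp.n_persons)

    data = np.zeros((n_frames, max_persons, N_KEYPOINTS, 3))
    for k, kp in enumerate(frames):
        if kp is not None and kp.shape[0]:
            data[k, : kp.shape[0]] = kp
    return PoseTimeSeries(trial_info=trial_info, data=data, provenance=provenance)


def collate_trial_dir(trial_dir: str | Path, trial_info: TrialInfo) -> PoseTimeSeries:
    """Collate every ``*_keypoints.json`` file under ``trial_dir``."""
    trial_dir = Path(trial_dir)
    paths = sorted(trial_dir.glob("*_keypoints.json"))
    if not paths:
        paths = sorted(trial_dir.glob("*.json"))
    docs = [(p.name, p.read_text()) for p in paths]
    return collate_trial(docs, trial_info)


# ---------------------------------------------------------------------------
# Dataset store: one compressed .npz per dataset + CSV metadata sidecar.

_META_COLUMNS = [
    "child_id",
    "trial_index",
    "trial_type",
    "target_ioi",
    "fps",
    "order_condition",
]


def trial_metadata_frame(infos: Iterable[TrialInfo]) -> pd.DataFrame:
    rows = [
        {
            "child_id": ti.child_id,
            "trial_index": ti.trial_index,
            "trial_type": ti.trial_type,
            "target_ioi": ti.target_ioi if ti.target_ioi is not None else np.nan,
            "fps": ti.fps,
            "order_condition": ti.order_condition,
        }
        for ti in infos
    ]
    return pd.DataFrame(rows, columns=_META_COLUMNS)


def read_trial_metadata(path: str | Path) -> list[TrialInfo]:
    df = pd.read_csv(path)
    infos = []
    for _, row in df.iterrows():
        target = row.get("target_ioi", np.nan)
        infos.append(
            TrialInfo(
                child_id=str(row["child_id"]),
                trial_index=int(row["trial_index"]),
                trial_type=str(row["trial_type"]),
                fps=float(row["fps"]),
                order_condition=int(row["order_condition"]),
                target_ioi=None if pd.isna(target) else float(target),
            )
        )
    return infos


def save_dataset(
    series_list: Sequence[PoseTimeSeries],
    store_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write a dataset to one compressed binary store + CSV sidecar."""
    store_path = Path(store_path)
    arrays: dict[str, np.ndarray] = {
        "__schema_version__": np.asarray([SCHEMA_VERSION]),
    }
    for s in series_list:
        tid = s.trial_info.trial_id
        arrays[f"{tid}/data"] = s.data
        arrays[f"{tid}/provenance"] = np.asarray(s.provenance, dtype=object)
        arrays[f"{tid}/child_label"] = np.asarray(
            [-1 if s.child_label is None else s.child_label]
        )
    try:
        np.savez_compressed(store_path, **arrays, allow_pickle=True)
    except TypeError:  # older numpy: savez takes no allow_pickle
        np.savez_compressed(store_path, **arrays)
    if metadata_path is None:
        metadata_path = store_path.with_suffix(".trials.csv")
    trial_metadata_frame([s.trial_info for s in series_list]).to_csv(
        metadata_path, index=False
    )


def load_dataset(
    store_path: str | Path,
    metadata_path: str | Path | None = None,
) -> list[PoseTimeSeries]:
    """Read back a dataset written by :func:`save_dataset`."""
    store_path = Path(store_path)
    if metadata_path is None:
        metadata_path = store_path.with_suffix(".trials.csv")
    infos = read_trial_metadata(metadata_path)
    out = []
    with np.load(store_path, allow_pickle=True) as store:
        version = int(store["__schema_version__"][0])
        if version > SCHEMA_VERSION:
            raise StoreVersionError(
                f"store schema v{version} is newer than supported v{SCHEMA_VERSION}"
            )
        for ti in infos:
            tid = ti.trial_id
            child = int(store[f"{tid}/child_label"][0])
            out.append(
                PoseTimeSeries(
                    trial_info=ti,
                    data=store[f"{tid}/data"],
                    provenance=[str(x) for x in store[f"{tid}/provenance"]],
                    child_label=None if child < 0 else child,
                )
            )
    return out


def round_trip_store(series: PoseTimeSeries, directory: str | Path) -> PoseTimeSeries:
    """Write a single series to ``directory`` and read it back.

    Coordinates are bit-exact across the round trip; metadata and the
    missing mask are preserved.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    store = directory / f"{series.trial_info.trial_id}.npz"
    save_dataset([series], store)
    return load_dataset(store)[0]
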