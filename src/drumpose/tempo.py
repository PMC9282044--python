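"""Tempo extraction: FFT power spectrum, peak picking, strikes, retention.

The centered vertical hand signal is transformed with the discrete
Fourier transform into a one-sided power spectrum on the grid
``k/duration`` Hz.  Larger non-rhythmic movements are filtered out by
cutting the spectrum below 1 Hz; the frequency of maximum remaining
power is the trial's drumming tempo, reported as an inter-onset
interval IOI = 1000/f ms.  Of the two hands, the "best" hand — the one
with the higher spectral peak — represents the trial.

Strike detection (local minima of the up-positive signal, i.e. surface
contacts) and the retention rule (at least four consecutive strikes
less than 2000 ms apart) assist the manual trial coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, get_window

from .kinematics import HandSignal

DEFAULT_MIN_FREQ_HZ = 1.0
DEFAULT_MIN_PROMINENCE_FRAC = 0.25
#: Relative floor under which a restricted spectrum counts as "no tempo".
PEAK_POWER_FLOOR_REL = 1e-12
DEFAULT_MIN_STRIKES = 4
DEFAULT_MAX_GAP_MS = 2000.0


@dataclass
class PowerSpectrum:
    """One-sided power spectrum: squared DFT magnitude on grid k/duration Hz."""

    freq: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if len(self.freq) != len(self.power):
            raise ValueError("freq and power must share a length")
        if len(self.freq) and self.freq[0] != 0.0:
            raise ValueError("spectrum must start at 0 Hz")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def df(self) -> float:
        """Spectral bin width (Hz)."""
        return float(self.freq[1] - self.freq[0]) if len(self.freq) > 1 else np.nan

    @property
    def nyquist(self) -> float:
        return float(self.freq[-1])


@dataclass
class TempoEstimate:
    frequency: float
    ioi: float
    peak_power: float
    hand: str | None
    valid: bool

    @classmethod
    def invalid(cls, hand: str | None = None) -> "TempoEstimate":
        return cls(frequency=np.nan, ioi=np.nan, peak_power=0.0, hand=hand, valid=False)


@dataclass
class StrikeTrain:
    """Strictly increasing strike (surface-contact) times in seconds."""

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("strike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def intervals_ms(self) -> np.ndarray:
        return np.diff(self.times) * 1000.0


def power_spectrum(
    signal: HandSignal,
    window: str | None = None,
    pad_factor: int = 1,
) -> PowerSpectrum:
    """Power spectrum of a centered, gap-filled, uniformly sampled signal.

    No taper is applied by default (rectangular window) and no
    zero-padding (``pad_factor=1`` keeps the native 1/duration grid; a
    larger factor interpolates the spectrum onto a finer grid).
    """
    if len(signal.t) > 1:
        dt = np.diff(signal.t)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("power_spectrum requires a uniform time grid")
    v = signal.v
    if window is not None:
        v = v * get_window(window, len(v))
    n = len(v) * int(pad_factor)
    spec = np.fft.rfft(v, n=n)
    power = np.abs(spec) ** 2
    freq = np.fft.rfftfreq(n, d=1.0 / signal.fps)
    return PowerSpectrum(freq=freq, power=power)


def peak_tempo(
    spectrum: PowerSpectrum,
    min_freq: float = DEFAULT_MIN_FREQ_HZ,
    hand: str | None = None,
    peak_power_floor: float | None = None,
) -> TempoEstimate:
    """Tempo = frequency of maximum power at or above ``min_freq``.

    Exact ties resolve to the lowest-frequency bin (prefer the
    fundamental over aliases).  If every bin above the cutoff is at or
    below the power floor the result is flagged invalid ("no tempo")
    rather than raising — a non-drummer has no spurious peak extracted.
    """
    if min_freq >= spectrum.nyquist:
        raise ValueError(
            f"min_freq {min_freq} Hz is not below Nyquist {spectrum.nyquist} Hz"
        )
    if peak_power_floor is None:
        peak_power_floor = PEAK_POWER_FLOOR_REL * float(spectrum.power.sum())
    keep = spectrum.freq >= min_freq
    power = spectrum.power[keep]
    freq = spectrum.freq[keep]
    if len(power) == 0 or power.max() <= peak_power_floor:
        return TempoEstimate.invalid(hand)
    k = int(np.argmax(power))  # argmax returns the first (= lowest-frequency) maximum
    f = float(freq[k])
    return TempoEstimate(
        frequency=f,
        ioi=ioi_from_frequency(f),
        peak_power=float(power[k]),
        hand=hand,
        valid=True,
    )


def ioi_from_frequency(f: float) -> float:
    """Inter-onset interval in ms for a tempo in Hz: IOI = 1000/f."""
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    return 1000.0 / f


def best_hand(left: TempoEstimate | None, right: TempoEstimate | None) -> TempoEstimate:
    """The hand whose spectrum has the higher peak power represents the trial.

    A single valid estimate wins by default; an exact power tie goes to
    the right hand.  Both invalid -> an invalid (no-tempo) estimate is
    returned, flagged rather than raised.
    """
    left = left if left is not None else TempoEstimate.invalid("left")
    right = right if right is not None else TempoEstimate.invalid("right")
    if not left.valid and not right.valid:
        return TempoEstimate.invalid(None)
    if left.valid and not right.valid:
        return left
    if right.valid and not left.valid:
        return right
    return left if left.peak_power > right.peak_power else right


def detect_strikes(
    signal: HandSignal,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
) -> StrikeTrain:
    """Strikes = prominent local minima of the up-positive signal.

    Prominence threshold is relative to the signal's peak-to-peak
    range, so small ripples riding on the drumming motion are ignored.
    Purely assistive; never overrides the manual coding table.
    """
    v = signal.v
    ptp = float(v.max() - v.min()) if len(v) else 0.0
    if ptp == 0.0:
        return StrikeTrain(times=np.empty(0))
    idx, _props = find_peaks(-v, prominence=min_prominence_frac * ptp)
    return StrikeTrain(times=idx / signal.fps)


def retention(
    strikes: StrikeTrain,
    min_strikes: int = DEFAULT_MIN_STRIKES,
    max_gap_ms: float = DEFAULT_MAX_GAP_MS,
) -> bool:
    """A trial counts as drumming if it has a qualifying strike run.

    True iff some run of at least ``min_strikes`` consecutive strikes
    has every inter-strike gap strictly below ``max_gap_ms``.
    """
    times = strikes.times
    if len(times) < min_strikes:
        return False
    gaps_ok = np.diff(times) * 1000.0 < max_gap_ms
    run = 1
    for ok in gaps_ok:
        run = run + 1 if ok else 1
        if run >= min_strikes:
            return True
    return min_strikes <= 1
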