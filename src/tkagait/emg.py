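"""Surface-EMG conditioning into 200-point normalized activation envelopes.

Chain: 4th-order Butterworth high-pass at 50 Hz, full-wave rectification,
4th-order Butterworth low-pass at 20 Hz (zero-phase by default), amplitude
normalization to the per-channel maximum over all cycles of one
subject-activity, and time normalization to 200 points with 100 points
assigned to stance and 100 to swing so that envelopes are comparable
independently of absolute phase durations.

Channel order is fixed throughout the package: RF (rectus femoris),
VM (vastus medialis), VL (vastus lateralis), TA (tibialis anterior),
HM (medial hamstrings), HL (lateral hamstrings), GM/GL (gastrocnemius
medialis/lateralis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "MUSCLES",
    "RawEMG",
    "NormalizedEMG",
    "filter_chain",
    "normalize_amplitude",
    "time_normalize_200",
    "process_trials",
]

MUSCLES = ("RF", "VM", "VL", "TA", "HM", "HL", "GM", "GL")

#: stance occupies columns 0..99, swing columns 100..199 of a normalized cycle
N_STANCE = 100
N_SWING = 100
N_POINTS = N_STANCE + N_SWING

_MIN_RATE = 1000.0


@dataclass
class RawEMG:
    """Multi-channel raw EMG for one trial: (8, n) array at ``rate`` Hz.

    ``events`` are sample indices (heel_strike_1, toe_off, heel_strike_2)
    on the EMG time axis.
    """

    signals: np.ndarray
    rate: float
    events: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] != len(MUSCLES):
            raise ValueError(
                f"expected {len(MUSCLES)} channels ({', '.join(MUSCLES)}), "
                f"got {self.signals.shape[0]}"
            )
        hs1, to, hs2 = self.events
        if not 0 <= hs1 < to < hs2 < self.signals.shape[1]:
            raise ValueError("events must satisfy 0 <= hs1 < toe_off < hs2 < n_samples")


@dataclass
class NormalizedEMG:
    """Amplitude- and time-normalized envelopes for one cycle: (8, 200) in [0, 1]."""

    envelopes: np.ndarray

    def __post_init__(self) -> None:
        self.envelopes = np.asarray(self.envelopes, dtype=float)
        if self.envelopes.shape != (len(MUSCLES), N_POINTS):
            raise ValueError(f"envelopes must be (8, {N_POINTS})")
        if self.envelopes.min() < -1e-12 or self.envelopes.max() > 1.0 + 1e-9:
            raise ValueError("normalized envelopes must lie in [0, 1]")


def filter_chain(
    raw: np.ndarray,
    rate: float,
    highpass_hz: float = 50.0,
    lowpass_hz: float = 20.0,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """High-pass -> full-wave rectify -> low-pass; returns non-negative envelopes.

    Filters are Butterworth of the printed order applied along the last axis.
    With ``zero_phase=True`` (default) each filter runs forward-backward,
    which doubles the effective order but introduces no group delay that
    would bias activation-timing statistics; set False for causal
    single-pass filtering.
    """
    if rate < _MIN_RATE:
        raise ValueError(
            f"sampling rate {rate:g} Hz violates the Nyquist margin for the "
            f"{highpass_hz:g} Hz high-pass / {lowpass_hz:g} Hz low-pass chain; "
            f"need at least {_MIN_RATE:g} Hz"
        )
    x = np.asarray(raw, dtype=float)
    sos_hp = signal.butter(order, highpass_hz, btype="highpass", fs=rate, output="sos")
    sos_lp = signal.butter(order, lowpass_hz, btype="lowpass", fs=rate, output="sos")
    filt = signal.sosfiltfilt if zero_phase else signal.sosfilt
    y = filt(sos_hp, x, axis=-1)
    y = np.abs(y)
    y = filt(sos_lp, y, axis=-1)
    return np.clip(y, 0.0, None)


def normalize_amplitude(cycles: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """Divide each channel by its maximum over all cycles of one subject-activity.

    Returns the normalized cycles and the per-channel maxima used. An
    all-zero channel is left at zero with a warning rather than producing
    NaNs.
    """
    if len(cycles) == 0:
        raise ValueError("need at least one cycle to normalize")
    stack = [np.atleast_2d(np.asarray(c, dtype=float)) for c in cycles]
    n_ch = stack[0].shape[0]
    maxima = np.zeros(n_ch)
    for c in stack:
        maxima = np.maximum(maxima, c.max(axis=-1))
    zero = maxima <= 0.0
    if zero.any():
        names = [MUSCLES[i] if n_ch == len(MUSCLES) else str(i) for i in np.nonzero(zero)[0]]
        warnings.warn(
            f"channel(s) {', '.join(names)} are all-zero across cycles; left at zero",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(zero, 1.0, maxima)
    return [c / safe[:, None] for c in stack], maxima


def _resample_segment(seg: np.ndarray, n_out: int) -> np.ndarray:
    src = np.linspace(0.0, 1.0, seg.shape[-1])
    dst = np.linspace(0.0, 1.0, n_out)
    if seg.ndim == 1:
        return np.interp(dst, src, seg)
    return np.vstack([np.interp(dst, src, row) for row in seg])


def time_normalize_200(envelope: np.ndarray, events: tuple[int, int, int]) -> np.ndarray:
    """Resample stance to 100 points and swing to 100 points, concatenated.

    ``events`` are (heel_strike_1, toe_off, heel_strike_2) sample indices on
    the envelope's own axis. Stance covers [heel_strike_1, toe_off) and
    swing [toe_off, heel_strike_2], so a 200-sample cycle with equal 100-
    sample phases passes through unchanged; linear interpolation.
    """
    env = np.asarray(envelope, dtype=float)
    hs1, to, hs2 = events
    if not (to - hs1 >= 2 and hs2 - to >= 1):
        raise ValueError("stance and swing must each span at least two samples")
    if hs2 >= env.shape[-1] or hs1 < 0:
        raise ValueError("events fall outside the envelope")
    stance = _resample_segment(env[..., hs1:to], N_STANCE)
    swing = _resample_segment(env[..., to : hs2 + 1], N_SWING)
    return np.concatenate([stance, swing], axis=-1)


def process_trials(
    trials: list[RawEMG],
    highpass_hz: float = 50.0,
    lowpass_hz: float = 20.0,
    order: int = 4,
    zero_phase: bool = True,
) -> list[NormalizedEMG]:
    """Full chain for all cycles of one subject-activity.

    Filter each trial, time-normalize to 200 points, then amplitude-normalize
    jointly so each channel's maximum over the subject-activity equals 1.
    """
    per_cycle = []
    for tr in trials:
        env = filter_chain(
            tr.signals, tr.rate, highpass_hz, lowpass_hz, order, zero_phase
        )
        per_cycle.append(time_normalize_200(env, tr.events))
    normed, _ = normalize_amplitude(per_cycle)
    return [NormalizedEMG(c) for c in normed]
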