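"""Retrospective physiological noise regressors (RETROICOR-style).

Cardiac phase is linear between successive pulse peaks; respiratory phase is
assigned by an amplitude-histogram transfer signed by the direction of the
respiratory trace.  Nuisance columns are sin/cos expansions of each phase up
to a configurable Fourier order (default 2, giving 8 columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

DEFAULT_ORDER = 2


@dataclass
class PhysioTrace:
    """Cardiac and respiratory traces sampled at ``fs_hz``."""

    fs_hz: float
    cardiac: np.ndarray
    respiratory: np.ndarray
    cardiac_peaks_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.cardiac) != len(self.respiratory):
            raise ValueError("cardiac and respiratory traces differ in length")
        if self.cardiac_peaks_s is not None:
            peaks = np.asarray(self.cardiac_peaks_s, dtype=float)
            if np.any(np.diff(peaks) <= 0):
                raise ValueError("cardiac peak times must be strictly increasing")
            self.cardiac_peaks_s = peaks

    @property
    def duration_s(self) -> float:
        return len(self.cardiac) / self.fs_hz

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(len(self.cardiac)) / self.fs_hz
        return pd.DataFrame(
            {"time_s": t, "cardiac": self.cardiac,
             "respiratory": self.respiratory}
        )


@dataclass
class PhaseSeries:
    """Cardiac and respiratory phase evaluated at volume times."""

    cardiac_phase: np.ndarray  # in [0, 2*pi)
    respiratory_phase: np.ndarray  # in [-pi, pi]
    order: int = DEFAULT_ORDER


def detect_cardiac_peaks(trace: np.ndarray, fs_hz: float) -> np.ndarray:
    """Local-maximum pulse-peak detection above an adaptive threshold."""
    trace = np.asarray(trace, dtype=float)
    height = trace.mean() + 0.5 * trace.std()
    min_dist = max(1, int(0.4 * fs_hz))  # refractory: max ~150 bpm
    idx, _ = signal.find_peaks(trace, height=height, distance=min_dist)
    return idx / fs_hz


def cardiac_phase(
    peaks_s: np.ndarray, volume_times_s: np.ndarray
) -> np.ndarray:
    """Phase 2*pi*(t - t_k)/(t_{k+1} - t_k) within each beat.

    Volumes before the first or after the last peak are extrapolated with
    the nearest inter-beat interval (logged).
    """
    peaks = np.asarray(peaks_s, dtype=float)
    t = np.asarray(volume_times_s, dtype=float)
    if len(peaks) < 2:
        raise ValueError("need at least 2 cardiac peaks")
    outside = (t < peaks[0]) | (t >= peaks[-1])
    if outside.any():
        logger.warning(
            "%d volume(s) outside cardiac peak span; extrapolating with "
            "nearest inter-beat interval", int(outside.sum()),
        )
    k = np.clip(np.searchsorted(peaks, t, side="right") - 1, 0, len(peaks) - 2)
    ibi = peaks[k + 1] - peaks[k]
    phase = 2 * np.pi * (t - peaks[k]) / ibi
    return np.mod(phase, 2 * np.pi)


def respiratory_phase(
    trace: np.ndarray, fs_hz: float, volume_times_s: np.ndarray
) -> np.ndarray:
    """Histogram-equalized respiratory phase in [-pi, pi].

    phase = sign(da/dt) * pi * H(a) / H_max where H is the cumulative
    amplitude histogram of the full trace; inspiration (rising amplitude)
    maps to positive phase.
    """
    trace = np.asarray(trace, dtype=float)
    if np.ptp(trace) == 0:
        raise ValueError("respiratory trace is constant")
    order_stat = np.sort(trace)
    idx = np.clip(
        np.round(np.asarray(volume_times_s) * fs_hz).astype(int),
        0,
        len(trace) - 1,
    )
    amp = trace[idx]
    # empirical CDF via rank (midpoint convention for ties)
    left = np.searchsorted(order_stat, amp, side="left")
    right = np.searchsorted(order_stat, amp, side="right")
    cdf = (left + right) / (2.0 * len(order_stat))
    deriv = np.gradient(trace)
    sign = np.where(deriv[idx] >= 0, 1.0, -1.0)
    return sign * np.pi * cdf


def phases_for_volumes(
    physio: PhysioTrace,
    volume_times_s: np.ndarray,
    order: int = DEFAULT_ORDER,
) -> PhaseSeries:
    peaks = physio.cardiac_peaks_s
    if peaks is None:
        peaks = detect_cardiac_peaks(physio.cardiac, physio.fs_hz)
    return PhaseSeries(
        cardiac_phase=cardiac_phase(peaks, volume_times_s),
        respiratory_phase=respiratory_phase(
            physio.respiratory, physio.fs_hz, volume_times_s
        ),
        order=order,
    )


def retroicor_regressors(phases: PhaseSeries) -> tuple[np.ndarray, list[str]]:
    """sin/cos columns of cardiac and respiratory phase up to ``order``.

    Returns (columns, names); 2 x 2 x order columns (8 at the default
    order 2).
    """
    cols = []
    names = []
    for label, phi in (
        ("cardiac", phases.cardiac_phase),
        ("resp", phases.respiratory_phase),
    ):
        for m in range(1, phases.order + 1):
            cols.append(np.sin(m * phi))
            names.append(f"{label}_sin{m}")
            cols.append(np.cos(m * phi))
            names.append(f"{label}_cos{m}")
    return np.column_stack(cols), names
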