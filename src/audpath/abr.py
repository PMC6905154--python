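"""Click-evoked auditory brainstem response (ABR) processing.

Pipeline: derive the Cz-minus-ipsilateral-mastoid channel, epoch around each
click after correcting for the 0.91-ms acoustic tube delay, reject epochs on
an RMS criterion, average, band-pass filter (zero-phase Butterworth,
50-1500 Hz), baseline-correct on the 2 ms preceding eardrum arrival, and
pick wave I and wave V features inside fixed latency windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

ACOUSTIC_DELAY_MS = 0.91
EPOCH_WINDOW_MS = (-10.0, 13.0)
BASELINE_WINDOW_MS = (-2.0, 0.0)
BAND_HZ = (50.0, 1500.0)
FILTER_ORDER = 4
RMS_REJECT_SDS = 2.0

WAVE1_WINDOW_MS = (1.5, 2.5)
WAVE1_TROUGH_OFFSET_MS = (0.3, 0.8)
WAVE1_TROUGH_OFFSET_SHORT_MS = (0.2, 0.6)
WAVE5_WINDOW_MS = (5.3, 6.6)
WAVE5_WINDOW_LATE_MAX_MS = 7.1

EARS = ("left", "right")


class AbrError(RuntimeError):
    pass


@dataclass(frozen=True)
class ClickEvents:
    """Click onset times and per-click ear labels.

    Presentations alternate strictly between ears (22 Hz total, 11 Hz per
    ear at the acquisition defaults).
    """

    onsets_s: np.ndarray
    ears: np.ndarray  # array of "left"/"right"

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_s, dtype=float)
        ears = np.asarray(self.ears)
        if onsets.shape != ears.shape:
            raise ValueError("onsets and ear labels must have equal length")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("click onsets must be strictly increasing")
        bad = set(np.unique(ears)) - set(EARS)
        if bad:
            raise ValueError(f"unknown ear labels: {sorted(bad)}")
        if len(ears) > 1 and np.any(ears[1:] == ears[:-1]):
            raise ValueError("ears must strictly alternate between clicks")
        object.__setattr__(self, "onsets_s", onsets)
        object.__setattr__(self, "ears", ears)

    def for_ear(self, ear: str) -> np.ndarray:
        return self.onsets_s[self.ears == ear]


@dataclass
class RawRecording:
    """Three-channel scalp recording: vertex (Cz) and both mastoids."""

    fs_hz: float
    cz: np.ndarray
    left_mastoid: np.ndarray
    right_mastoid: np.ndarray

    def __post_init__(self) -> None:
        if self.fs_hz < 4000:
            raise ValueError(
                f"sampling rate {self.fs_hz} Hz too low to resolve the "
                "1.5-kHz filter edge (need >= 4 kHz)"
            )
        n = len(self.cz)
        if len(self.left_mastoid) != n or len(self.right_mastoid) != n:
            raise ValueError("channels must have equal length")


@dataclass
class EpochSet:
    """Per-ear epoch matrix with rejection flags.

    ``epochs`` is [epoch x sample] over the window [-10, +13] ms relative to
    eardrum arrival; ``times_ms`` gives the per-sample latency.
    """

    ear: str
    fs_hz: float
    epochs: np.ndarray
    times_ms: np.ndarray
    kept: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_dropped_edge: int = 0

    def __post_init__(self) -> None:
        if self.kept is None:
            self.kept = np.ones(len(self.epochs), dtype=bool)

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


@dataclass
class AbrWaveform:
    """Averaged, filtered, baseline-corrected waveform for one ear."""

    ear: str
    fs_hz: float
    times_ms: np.ndarray
    amplitude: np.ndarray
    n_kept: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.times_ms, "amplitude_uv": self.amplitude}
        )


@dataclass
class AbrFeatures:
    """Picked wave I/V features for one ear (or the across-ear average)."""

    ear: str
    wave1_latency_ms: float
    wave1_peak_amplitude: float
    wave1_trough_latency_ms: float
    wave1_trough_amplitude: float
    wave5_latency_ms: float
    wave5_peak_amplitude: float
    wave1_amplitude: float  # peak minus following trough
    wave5_amplitude: float  # peak re baseline (zero)
    ratio_1_5: float
    window_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "window_overrides"}
        d["window_overrides"] = ";".join(
            f"{k}={v}" for k, v in self.window_overrides.items()
        )
        return d


# ---------------------------------------------------------------------------
# pipeline stages


def derive_channel(raw: RawRecording, ear: str) -> np.ndarray:
    """Cz minus ipsilateral mastoid for the stimulated ear."""
    if ear not in EARS:
        raise ValueError(f"ear must be one of {EARS}, got {ear!r}")
    mastoid = raw.left_mastoid if ear == "left" else raw.right_mastoid
    return np.asarray(raw.cz, dtype=float) - np.asarray(mastoid, dtype=float)


def extract_epochs(
    trace: np.ndarray,
    events: ClickEvents,
    ear: str,
    fs_hz: float,
    acoustic_delay_ms: float = ACOUSTIC_DELAY_MS,
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
) -> EpochSet:
    """Cut one epoch per click for ``ear``, timed to eardrum arrival.

    The epoch time axis is relative to click onset + the acoustic tube
    delay.  Events whose window falls outside the recording are dropped and
    counted.
    """
    trace = np.asarray(trace, dtype=float)
    lo = int(round(window_ms[0] * 1e-3 * fs_hz))
    hi = int(round(window_ms[1] * 1e-3 * fs_hz))
    times_ms = np.arange(lo, hi) / fs_hz * 1e3
    arrivals = events.for_ear(ear) + acoustic_delay_ms * 1e-3
    centers = np.round(arrivals * fs_hz).astype(int)
    ok = (centers + lo >= 0) & (centers + hi <= len(trace))
    dropped = int((~ok).sum())
    if dropped:
        logger.warning(
            "dropped %d/%d %s-ear epochs at recording edges",
            dropped, len(centers), ear,
        )
    offsets = np.arange(lo, hi)
    epochs = trace[centers[ok][:, None] + offsets[None, :]]
    return EpochSet(
        ear=ear, fs_hz=fs_hz, epochs=epochs, times_ms=times_ms,
        n_dropped_edge=dropped,
    )


def reject_epochs(epochs: EpochSet) -> EpochSet:
    """Flag epochs whose RMS exceeds mean + 2 SD of the per-epoch RMS.

    Single pass: the mean and SD are computed once over all epochs.  The
    comparison is strict, so identical epochs (SD = 0) are all kept.
    """
    if len(epochs.epochs) < 2:
        raise AbrError("need at least 2 epochs to compute rejection stats")
    rms = np.sqrt(np.mean(epochs.epochs**2, axis=1))
    threshold = rms.mean() + RMS_REJECT_SDS * rms.std()
    kept = rms <= threshold
    if not kept.any():
        raise AbrError("all epochs rejected; degenerate recording")
    return EpochSet(
        ear=epochs.ear,
        fs_hz=epochs.fs_hz,
        epochs=epochs.epochs,
        times_ms=epochs.times_ms,
        kept=kept,
        n_dropped_edge=epochs.n_dropped_edge,
    )


def average_filter_baseline(
    epochs: EpochSet,
    band_hz: tuple[float, float] = BAND_HZ,
    order: int = FILTER_ORDER,
) -> AbrWaveform:
    """Average kept epochs, band-pass filter, and baseline-correct.

    Filtering is zero-phase (forward-backward) so wave latencies are not
    shifted; this doubles the effective attenuation of the stated
    fourth-order Butterworth design.  The mean over [-2, 0] ms is then
    subtracted, so the baseline-window mean of the output is exactly zero.
    """
    if epochs.n_kept < 1:
        raise AbrError("no kept epochs to average")
    if band_hz[1] >= epochs.fs_hz / 2:
        raise ValueError(
            f"band edge {band_hz[1]} Hz at or above Nyquist "
            f"({epochs.fs_hz / 2} Hz)"
        )
    avg = epochs.epochs[epochs.kept].mean(axis=0)
    sos = signal.butter(
        order, band_hz, btype="bandpass", fs=epochs.fs_hz, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, avg)
    in_baseline = (epochs.times_ms >= BASELINE_WINDOW_MS[0]) & (
        epochs.times_ms < BASELINE_WINDOW_MS[1]
    )
    filtered = filtered - filtered[in_baseline].mean()
    return AbrWaveform(
        ear=epochs.ear,
        fs_hz=epochs.fs_hz,
        times_ms=epochs.times_ms,
        amplitude=filtered,
        n_kept=epochs.n_kept,
    )


def _window_indices(times_ms, lo, hi):
    idx = np.nonzero((times_ms >= lo) & (times_ms <= hi))[0]
    if len(idx) == 0:
        raise ValueError(f"window [{lo}, {hi}] ms outside waveform span")
    return idx


def _pick_local_max(y: np.ndarray, idx: np.ndarray) -> int:
    """Largest strictly-greater-than-neighbours local maximum in ``idx``.

    Candidates are interior points of the whole waveform; ties break toward
    earlier latency.  Returns -1 when no interior local maximum exists in
    the window.
    """
    cand = [
        i
        for i in idx
        if 0 < i < len(y) - 1 and y[i] > y[i - 1] and y[i] > y[i + 1]
    ]
    if not cand:
        return -1
    best = cand[0]
    for i in cand[1:]:
        if y[i] > y[best]:
            best = i
    return best


def pick_peaks(
    waveform: AbrWaveform,
    wave1_window_ms: tuple[float, float] = WAVE1_WINDOW_MS,
    trough_offset_ms: tuple[float, float] = WAVE1_TROUGH_OFFSET_MS,
    wave5_window_ms: tuple[float, float] = WAVE5_WINDOW_MS,
    wave5_max_ms: float | None = None,
) -> AbrFeatures:
    """Pick wave I and wave V features in fixed latency windows.

    Wave I: largest interior local maximum in [1.5, 2.5] ms after arrival,
    falling back to the highest point in the window when no local maximum
    exists.  Its trough is the lowest point 0.3-0.8 ms after the wave I peak
    (override [0.2, 0.6] ms for short wave I morphologies).  Wave V: same
    local-maximum rule in [5.3, 6.6] ms, optionally extended to 7.1 ms for
    late peaks.  Wave I amplitude is peak minus trough; wave V amplitude is
    peak relative to the (zero) baseline.
    """
    t, y = waveform.times_ms, waveform.amplitude
    overrides: dict = {}
    if trough_offset_ms != WAVE1_TROUGH_OFFSET_MS:
        overrides["wave1_trough_offset_ms"] = trough_offset_ms
    w5_hi = wave5_window_ms[1]
    if wave5_max_ms is not None:
        w5_hi = wave5_max_ms
        overrides["wave5_max_ms"] = wave5_max_ms

    # wave I
    idx1 = _window_indices(t, *wave1_window_ms)
    i1 = _pick_local_max(y, idx1)
    if i1 < 0:
        i1 = idx1[int(np.argmax(y[idx1]))]
    # wave I trough
    idxt = _window_indices(
        t, t[i1] + trough_offset_ms[0], t[i1] + trough_offset_ms[1]
    )
    it = idxt[int(np.argmin(y[idxt]))]
    # wave V
    idx5 = _window_indices(t, wave5_window_ms[0], w5_hi)
    i5 = _pick_local_max(y, idx5)
    if i5 < 0:
        i5 = idx5[int(np.argmax(y[idx5]))]

    amp1 = float(y[i1] - y[it])
    amp5 = float(y[i5])
    return AbrFeatures(
        ear=waveform.ear,
        wave1_latency_ms=float(t[i1]),
        wave1_peak_amplitude=float(y[i1]),
        wave1_trough_latency_ms=float(t[it]),
        wave1_trough_amplitude=float(y[it]),
        wave5_latency_ms=float(t[i5]),
        wave5_peak_amplitude=float(y[i5]),
        wave1_amplitude=amp1,
        wave5_amplitude=amp5,
        ratio_1_5=amp1 / amp5 if amp5 != 0 else float("nan"),
        window_overrides=overrides,
    )


def summarize(
    features: dict[str, AbrFeatures], allow_single_ear: bool = False
) -> AbrFeatures:
    """Average wave amplitudes across ears; ratio from averaged amplitudes."""
    present = [features[e] for e in EARS if e in features]
    if len(present) < 2 and not allow_single_ear:
        raise ValueError(
            "both ears required (pass allow_single_ear=True to override)"
        )
    mean = lambda attr: float(np.mean([getattr(f, attr) for f in present]))
    amp1 = mean("wave1_amplitude")
    amp5 = mean("wave5_amplitude")
    return AbrFeatures(
        ear="both" if len(present) == 2 else present[0].ear,
        wave1_latency_ms=mean("wave1_latency_ms"),
        wave1_peak_amplitude=mean("wave1_peak_amplitude"),
        wave1_trough_latency_ms=mean("wave1_trough_latency_ms"),
        wave1_trough_amplitude=mean("wave1_trough_amplitude"),
        wave5_latency_ms=mean("wave5_latency_ms"),
        wave5_peak_amplitude=mean("wave5_peak_amplitude"),
        wave1_amplitude=amp1,
        wave5_amplitude=amp5,
        ratio_1_5=amp1 / amp5 if amp5 != 0 else float("nan"),
    )


def process_recording(
    raw: RawRecording,
    events: ClickEvents,
    trough_offset_ms: tuple[float, float] = WAVE1_TROUGH_OFFSET_MS,
    wave5_max_ms: float | None = None,
) -> tuple[dict[str, AbrWaveform], dict[str, AbrFeatures], AbrFeatures]:
    """Full per-ear pipeline plus the across-ear summary."""
    waveforms: dict[str, AbrWaveform] = {}
    features: dict[str, AbrFeatures] = {}
    for ear in EARS:
        if len(events.for_ear(ear)) == 0:
            continue
        trace = derive_channel(raw, ear)
        epochs = extract_epochs(trace, events, ear, raw.fs_hz)
        epochs = reject_epochs(epochs)
        wf = average_filter_baseline(epochs)
        waveforms[ear] = wf
        features[ear] = pick_peaks(
            wf, trough_offset_ms=trough_offset_ms, wave5_max_ms=wave5_max_ms
        )
    summary = summarize(features, allow_single_ear=len(features) == 1)
    return waveforms, features, summary


def features_frame(
    features: dict[str, AbrFeatures], summary: AbrFeatures | None = None
) -> pd.DataFrame:
    rows = [f.to_dict() for f in features.values()]
    if summary is not None:
        rows.append(summary.to_dict())
    return pd.DataFrame(rows)
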