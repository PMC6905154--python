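"""Adaptive audiometry: transformed up-down staircase and eligibility rules.

The procedure is a two-interval, two-alternative forced-choice track with a
two-down one-up rule and a fixed 2-dB step, stopped after 12 reversals; the
threshold estimate is the mean of the levels at the last eight reversals.
A 2-down-1-up track converges on the level where P(correct) = sqrt(0.5),
i.e. ~70.7 % correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

STEP_DB = 2.0
N_REVERSALS_STOP = 12
N_REVERSALS_AVERAGED = 8
DEFAULT_START_LEVEL = 40.0
LEVEL_CEILING_DB_HL = 90.0

#: Audiogram test frequencies (kHz).
AUDIOGRAM_FREQS_KHZ = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0)
#: Frequencies entering the eligibility rule (kHz).
ELIGIBILITY_FREQS_KHZ = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
ELIGIBILITY_MAX_DB_HL = 20.0


class StaircaseError(RuntimeError):
    """Raised on invalid staircase state transitions."""


@dataclass
class StaircaseTrack:
    """State of one adaptive track.

    ``levels[i]`` is the level presented on trial ``i`` and ``responses[i]``
    whether that trial was answered correctly.  A reversal is a trial at
    which the prescribed level-change direction differs from the previous
    prescribed change; its entry in ``reversal_levels`` is the level of the
    trial that triggered it.
    """

    start_level: float = DEFAULT_START_LEVEL
    step_db: float = STEP_DB
    ceiling: float = LEVEL_CEILING_DB_HL
    levels: list[float] = field(default_factory=list)
    responses: list[bool] = field(default_factory=list)
    reversal_levels: list[float] = field(default_factory=list)
    terminated: bool = False
    _next_level: float = field(init=False)
    _run_correct: int = field(init=False, default=0)
    _last_direction: int = field(init=False, default=0)  # -1 down, +1 up

    def __post_init__(self) -> None:
        self._next_level = self.start_level

    @property
    def next_level(self) -> float:
        """Level to present on the next trial."""
        return self._next_level


def staircase_step(track: StaircaseTrack, correct: bool) -> StaircaseTrack:
    """Record one trial outcome and update the track in place.

    Two consecutive correct responses prescribe a 2-dB decrease, any
    incorrect response a 2-dB increase.  The track terminates after 12
    reversals.
    """
    if track.terminated:
        raise StaircaseError("cannot step a terminated track")
    level = track._next_level
    track.levels.append(level)
    track.responses.append(bool(correct))

    direction = 0
    if correct:
        track._run_correct += 1
        if track._run_correct == 2:
            direction = -1
            track._run_correct = 0
    else:
        direction = +1
        track._run_correct = 0

    if direction != 0:
        if track._last_direction != 0 and direction != track._last_direction:
            track.reversal_levels.append(level)
            if len(track.reversal_levels) >= N_REVERSALS_STOP:
                track.terminated = True
        track._last_direction = direction
        track._next_level = min(
            level + direction * track.step_db, track.ceiling
        )
    return track


def threshold_from_track(track: StaircaseTrack) -> float:
    """Threshold estimate: mean of the last eight reversal levels.

    The instrument's "geometric mean of the signal level" is taken as the
    arithmetic mean of the dB values (the geometric mean of the linear
    amplitudes); a geometric mean of dB numbers is ill-defined at or below
    0 dB HL.
    """
    if len(track.reversal_levels) < N_REVERSALS_STOP:
        raise StaircaseError(
            f"track has {len(track.reversal_levels)} reversals; "
            f"{N_REVERSALS_STOP} required"
        )
    return float(np.mean(track.reversal_levels[-N_REVERSALS_AVERAGED:]))


def simulate_listener(
    true_threshold: float,
    slope: float = 4.0,
    guess_rate: float = 0.5,
    seed: int | np.random.Generator | None = None,
) -> Callable[[float], bool]:
    """Stochastic 2I-2AFC listener with a logistic psychometric function.

    P(correct | level) = guess_rate + (1 - guess_rate) * logistic((level -
    true_threshold) / slope).  At ``level = true_threshold`` performance is
    midway between chance and perfect (75 % for guess_rate 0.5).

    Returns a callable ``respond(level) -> bool`` that is reproducible under
    the given seed.
    """
    if slope <= 0:
        raise ValueError(f"slope={slope!r} must be > 0")
    rng = np.random.default_rng(seed)

    def respond(level: float) -> bool:
        p = guess_rate + (1.0 - guess_rate) / (
            1.0 + np.exp(-(level - true_threshold) / slope)
        )
        return bool(rng.random() < p)

    return respond


def psychometric_point(
    true_threshold: float,
    p_target: float,
    slope: float = 4.0,
    guess_rate: float = 0.5,
) -> float:
    """Level at which the simulated listener scores ``p_target`` correct."""
    if not (guess_rate < p_target < 1.0):
        raise ValueError("p_target must lie strictly between guess_rate and 1")
    q = (p_target - guess_rate) / (1.0 - guess_rate)
    return true_threshold + slope * float(np.log(q / (1.0 - q)))


def run_staircase(
    respond: Callable[[float], bool],
    start_level: float = DEFAULT_START_LEVEL,
    max_trials: int = 1000,
) -> StaircaseTrack:
    """Run a full track against a listener until 12 reversals (or cap)."""
    track = StaircaseTrack(start_level=start_level)
    for _ in range(max_trials):
        if track.terminated:
            break
        staircase_step(track, respond(track.next_level))
    return track


# ---------------------------------------------------------------------------
# audiograms and eligibility


@dataclass
class Audiogram:
    """Per-ear thresholds in dB HL keyed ``(ear, freq_khz)``.

    16-kHz thresholds above 90 dB HL are recorded as 90 with the ceiling
    flag set (equipment output limit).
    """

    thresholds: dict[tuple[str, float], float] = field(default_factory=dict)
    ceiling_flags: dict[tuple[str, float], bool] = field(default_factory=dict)

    def set(self, ear: str, freq_khz: float, threshold: float) -> None:
        key = (ear, freq_khz)
        if freq_khz == 16.0 and threshold > LEVEL_CEILING_DB_HL:
            self.thresholds[key] = LEVEL_CEILING_DB_HL
            self.ceiling_flags[key] = True
        else:
            self.thresholds[key] = float(threshold)
            self.ceiling_flags[key] = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "ear": ear,
                "frequency_khz": f,
                "threshold_db_hl": thr,
                "ceiling_flag": self.ceiling_flags.get((ear, f), False),
            }
            for (ear, f), thr in sorted(self.thresholds.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Audiogram":
        ag = cls()
        for _, row in df.iterrows():
            key = (str(row["ear"]), float(row["frequency_khz"]))
            ag.thresholds[key] = float(row["threshold_db_hl"])
            ag.ceiling_flags[key] = bool(row.get("ceiling_flag", False))
        return ag


def check_eligibility(audiogram: Audiogram) -> tuple[bool, list[str]]:
    """Normal-hearing eligibility: every 0.5-8 kHz threshold <= 20 dB HL.

    Thresholds at 12 and 16 kHz are recorded but do not enter the rule.
    Returns ``(eligible, reasons)`` where reasons name each failing
    ear/frequency.
    """
    reasons: list[str] = []
    for ear in ("left", "right"):
        for f in ELIGIBILITY_FREQS_KHZ:
            key = (ear, f)
            if key not in audiogram.thresholds:
                raise ValueError(f"audiogram missing {ear} ear at {f} kHz")
            thr = audiogram.thresholds[key]
            if thr > ELIGIBILITY_MAX_DB_HL:
                reasons.append(
                    f"{ear} ear at {f} kHz: {thr:g} dB HL > "
                    f"{ELIGIBILITY_MAX_DB_HL:g} dB HL"
                )
    return (len(reasons) == 0, reasons)
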