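"""Lifetime noise-exposure scoring from structured-interview activity records.

One exposure unit corresponds to a working year (8 h/day, 5 days/week,
52 weeks/year = 2080 h) at 90 dB(A).  Units from individual activities are
energy-additive and summed to a lifetime total, which drives the low/high
group allocation at the pre-specified 15-unit cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Hours in one nominal working year (8 h x 5 d x 52 wk).
WORKING_YEAR_HOURS = 2080.0

#: Reference level: 2080 h at this level is one exposure unit.
REFERENCE_LEVEL_DBA = 90.0

#: Low/high allocation boundary (units); totals at or above it are "high".
GROUP_CUTOFF_UNITS = 15.0

#: Convenience lookup for estimating speech-communication levels from vocal
#: effort (six levels spanning 87-110 dB(A)); any level is accepted directly.
VOCAL_EFFORT_DBA = {
    "casual": 87.0,
    "normal": 90.0,
    "raised": 93.0,
    "loud": 96.0,
    "very_loud": 102.0,
    "shouting": 110.0,
}

#: Age stratification bands used for group balancing.
AGE_STRATA = (
    (25, 27, "25-27"),
    (28, 30, "28-30"),
    (31, 33, "31-33"),
    (34, 36, "34-36"),
    (37, 40, "37-40"),
)


class ValidationError(ValueError):
    """Raised when a field value is outside its allowed range."""


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValidationError(
            f"{name}={value!r} outside allowed range [{lo}, {hi}]"
        )


@dataclass(frozen=True)
class NoiseActivity:
    """One noise-exposure activity from the structured interview.

    Parameters
    ----------
    years, weeks_per_year, days_per_week, hours_per_day
        Exposure duration components (Y, W, D, H).  Fractional values are
        accepted.
    level_dBA
        Estimated exposure level L in dB(A).
    protection_attenuation_dB
        Attenuation A of hearing protection in dB (>= 0).
    protection_proportion
        Proportion P of exposure time protection was worn, in [0, 1].
    label
        Free-text description.
    """

    years: float
    weeks_per_year: float
    days_per_week: float
    hours_per_day: float
    level_dBA: float
    protection_attenuation_dB: float = 0.0
    protection_proportion: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        _check_range("years", self.years, 0.0, float("inf"))
        _check_range("weeks_per_year", self.weeks_per_year, 0.0, 52.0)
        _check_range("days_per_week", self.days_per_week, 0.0, 7.0)
        _check_range("hours_per_day", self.hours_per_day, 0.0, 24.0)
        if not (self.level_dBA == self.level_dBA):  # NaN guard
            raise ValidationError("level_dBA is NaN")
        _check_range(
            "protection_attenuation_dB",
            self.protection_attenuation_dB,
            0.0,
            float("inf"),
        )
        _check_range(
            "protection_proportion", self.protection_proportion, 0.0, 1.0
        )


def activity_units(activity: NoiseActivity) -> float:
    """Exposure units contributed by a single activity.

    units = (Y*W*D*H / 2080) * [P*10^((L-A-90)/10) + (1-P)*10^((L-90)/10)]

    The duration term expresses exposure hours as working years; the level
    term is the energy ratio relative to 90 dB(A), with the protected
    fraction of time attenuated by A dB.
    """
    a = activity
    hours = a.years * a.weeks_per_year * a.days_per_week * a.hours_per_day
    protected = a.protection_proportion * 10.0 ** (
        (a.level_dBA - a.protection_attenuation_dB - REFERENCE_LEVEL_DBA) / 10.0
    )
    unprotected = (1.0 - a.protection_proportion) * 10.0 ** (
        (a.level_dBA - REFERENCE_LEVEL_DBA) / 10.0
    )
    return hours / WORKING_YEAR_HOURS * (protected + unprotected)


def total_exposure(activities: list[NoiseActivity]) -> float:
    """Sum of exposure units over all activities (empty list -> 0)."""
    return float(sum(activity_units(a) for a in activities))


def allocate_group(total_units: float) -> str:
    """Allocate ``'low'`` or ``'high'`` exposure group at the 15-unit cut-off.

    Exactly 15 units allocates high (the high-group range starts at 15).
    Allocation uses the unrounded total.
    """
    if total_units < 0:
        raise ValidationError(f"total_units={total_units!r} must be >= 0")
    return "high" if total_units >= GROUP_CUTOFF_UNITS else "low"


def age_stratum(age_years: float) -> str:
    """Age stratification band for a participant aged 25-40."""
    if not (25 <= age_years <= 40):
        raise ValidationError(
            f"age_years={age_years!r} outside eligible range [25, 40]"
        )
    for _lo, hi, label in AGE_STRATA:
        if age_years <= hi:
            return label
    raise AssertionError("unreachable: strata cover [25, 40]")


@dataclass
class ExposureRecord:
    """A participant's activities and derived exposure summary."""

    participant_id: str
    activities: list[NoiseActivity] = field(default_factory=list)
    age_years: float | None = None

    @property
    def total_units(self) -> float:
        return total_exposure(self.activities)

    @property
    def group(self) -> str:
        return allocate_group(self.total_units)

    @property
    def age_stratum(self) -> str | None:
        return None if self.age_years is None else age_stratum(self.age_years)


# ---------------------------------------------------------------------------
# tabular I/O

_ACTIVITY_COLUMNS = [
    "participant_id",
    "years",
    "weeks_per_year",
    "days_per_week",
    "hours_per_day",
    "level_dBA",
    "protection_attenuation_dB",
    "protection_proportion",
    "label",
]


def read_activities(path) -> dict[str, list[NoiseActivity]]:
    """Read activity records (CSV or JSON), one row/object per activity."""
    path = str(path)
    if path.endswith(".json"):
        df = pd.read_json(path)
    else:
        df = pd.read_csv(path)
    missing = {"participant_id", "years", "weeks_per_year", "days_per_week",
               "hours_per_day", "level_dBA"} - set(df.columns)
    if missing:
        raise ValidationError(f"activity table missing columns: {sorted(missing)}")
    out: dict[str, list[NoiseActivity]] = {}

    def opt(row, key, default):
        value = row.get(key, default)
        return default if pd.isna(value) else value

    for _, row in df.iterrows():
        act = NoiseActivity(
            years=float(row["years"]),
            weeks_per_year=float(row["weeks_per_year"]),
            days_per_week=float(row["days_per_week"]),
            hours_per_day=float(row["hours_per_day"]),
            level_dBA=float(row["level_dBA"]),
            protection_attenuation_dB=float(
                opt(row, "protection_attenuation_dB", 0.0)
            ),
            protection_proportion=float(
                opt(row, "protection_proportion", 0.0)
            ),
            label=str(opt(row, "label", "")),
        )
        out.setdefault(str(row["participant_id"]), []).append(act)
    return out


def score_cohort(
    activities: dict[str, list[NoiseActivity]],
    ages: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Score activities into a cohort table (totals, group, age stratum).

    Reported totals are rounded to 1 decimal; allocation uses unrounded
    values.
    """
    rows = []
    for pid, acts in activities.items():
        total = total_exposure(acts)
        age = None if ages is None else ages.get(pid)
        rows.append(
            {
                "participant_id": pid,
                "total_units": round(total, 1),
                "group": allocate_group(total),
                "age_years": age,
                "age_stratum": None if age is None else age_stratum(age),
            }
        )
    return pd.DataFrame(rows)
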