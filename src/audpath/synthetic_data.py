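"""Seeded synthetic-data generators for every pipeline input.

Generates cohort tables with group-structured lifetime-exposure units,
continuous three-channel ABR recordings with embedded wave I/V templates,
quasi-periodic cardiac/respiratory traces, and small 4D BOLD datasets whose
labelled blobs respond with sustained (early pathway) versus phasic
(thalamo-cortical) profiles, contaminated by drift, physiological
oscillations and AR(1) noise.  All generators are deterministic under the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nesi
from .abr import ClickEvents, RawRecording
from .fmri_design import BlockParadigm, DesignMatrix, Hrf, build_regressors
from .fmri_glm import REGIONS, VolumeSeries
from .physio import PhysioTrace

SUSTAINED_REGIONS = ("CN", "SOC", "NLL", "IC")
PHASIC_REGIONS = ("MGB", "AC")

#: Default (onset, offset, sustained) response weights in signal units on a
#: baseline of 100, i.e. percent signal change.
DEFAULT_REGION_WEIGHTS = {
    "CN": (0.4, 0.2, 1.0),
    "SOC": (0.5, 0.25, 1.0),
    "NLL": (0.5, 0.25, 0.9),
    "IC": (0.6, 0.3, 1.2),
    "MGB": (1.0, 0.6, 0.4),
    "AC": (1.4, 0.9, 0.3),
}

#: Voxel-index blob centres on the default 24^3 grid, (region, hemi) -> xyz.
DEFAULT_SEEDS = {
    ("CN", "left"): (7, 4, 4),
    ("CN", "right"): (16, 4, 4),
    ("SOC", "left"): (7, 9, 5),
    ("SOC", "right"): (16, 9, 5),
    ("NLL", "left"): (7, 14, 8),
    ("NLL", "right"): (16, 14, 8),
    ("IC", "left"): (7, 19, 10),
    ("IC", "right"): (16, 19, 10),
    ("MGB", "left"): (7, 19, 15),
    ("MGB", "right"): (16, 19, 15),
    ("AC", "left"): (4, 10, 19),
    ("AC", "right"): (19, 10, 19),
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs for the synthetic generators (defaults are desk-scale)."""

    seed: int = 0
    # cohort
    n_low: int = 30
    n_high: int = 32
    low_units_median: float = 3.6
    low_units_mean: float = 4.0
    low_units_range: tuple[float, float] = (0.0, 14.9)
    high_units_median: float = 31.0
    high_units_mean: float = 45.0
    high_units_range: tuple[float, float] = (15.0, 189.0)
    female_prob: tuple[float, float] = (12 / 30, 9 / 32)  # (low, high)
    tinnitus_prob: tuple[float, float] = (6 / 30, 13 / 32)
    tolerance_prob: tuple[float, float] = (6 / 30, 10 / 32)
    # cohort response fields
    region_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS)
    )
    group_effect_onset: float = 0.3  # multiplicative boost for high group
    beta_noise_sd: float = 0.35
    subject_re_sd: float = 0.25
    wave1_mean_uv: float = 0.23
    wave1_sd_uv: float = 0.08
    wave5_mean_uv: float = 0.50
    wave5_sd_uv: float = 0.12
    # ABR recording
    abr_fs_hz: float = 16000.0
    click_rate_hz: float = 22.0
    n_clicks_per_ear: int = 7000
    acoustic_delay_ms: float = 0.91
    wave1_latency_ms: float = 1.8
    wave1_amp_uv: float = 0.18
    wave1_sigma_ms: float = 0.25
    wave1_trough_latency_ms: float = 2.35
    wave1_trough_amp_uv: float = 0.10
    wave1_trough_sigma_ms: float = 0.25
    wave5_latency_ms: float = 5.7
    wave5_amp_uv: float = 0.50
    wave5_sigma_ms: float = 0.50
    abr_noise_sd_uv: float = 1.5
    artifact_rate: float = 0.005  # fraction of clicks hit by an artifact
    artifact_amp_uv: float = 60.0
    # BOLD
    grid: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 1.5
    blob_radius_vox: float = 2.0
    seeds_xyz: dict = field(default_factory=lambda: dict(DEFAULT_SEEDS))
    bold_baseline: float = 100.0
    bold_noise_sd: float = 0.6
    bold_ar1_rho: float = 0.3
    drift_amp: float = 0.8
    cardiac_freq_hz: float = 1.05
    resp_freq_hz: float = 0.26
    cardiac_amp: float = 0.4
    resp_amp: float = 0.4
    physio_fs_hz: float = 50.0
    physio_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.n_low < 2 or self.n_high < 2:
            raise ValueError("group sizes must be >= 2")
        if self.low_units_range[1] >= nesi.GROUP_CUTOFF_UNITS:
            raise ValueError(
                "low-group range crosses the 15-unit group cut-off"
            )
        if self.high_units_range[0] < nesi.GROUP_CUTOFF_UNITS:
            raise ValueError(
                "high-group range crosses the 15-unit group cut-off"
            )
        for name in ("beta_noise_sd", "subject_re_sd", "abr_noise_sd_uv",
                     "bold_noise_sd", "artifact_rate", "physio_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self._check_blob_overlap()

    def _check_blob_overlap(self) -> None:
        keys = list(self.seeds_xyz)
        for i, k1 in enumerate(keys):
            for k2 in keys[i + 1 :]:
                d = np.linalg.norm(
                    np.subtract(self.seeds_xyz[k1], self.seeds_xyz[k2])
                )
                if d <= 2 * self.blob_radius_vox:
                    raise ValueError(f"blobs overlap: {k1} and {k2}")


# ---------------------------------------------------------------------------
# cohort


def _truncated_lognormal(
    rng: np.random.Generator,
    n: int,
    median: float,
    mean: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Lognormal draws matched to (median, mean), rejection-truncated."""
    mu = np.log(median)
    sigma = float(np.sqrt(max(2.0 * np.log(mean / median), 1e-6)))
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _activity_for_units(units: float) -> nesi.NoiseActivity:
    """One full-time working-year activity whose level yields ``units``."""
    level = nesi.REFERENCE_LEVEL_DBA + 10.0 * np.log10(max(units, 1e-9))
    return nesi.NoiseActivity(
        years=1.0,
        weeks_per_year=52.0,
        days_per_week=5.0,
        hours_per_day=8.0,
        level_dBA=level,
        label="synthetic occupational exposure",
    )


def gen_cohort(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, list[nesi.ExposureRecord]]:
    """Cohort table plus matching per-participant exposure records.

    Exposure totals are truncated lognormals per group; ages are drawn
    uniformly over the stratification bands, cycling through strata so the
    groups stay balanced; ROI betas follow the configured region weights
    with a multiplicative onset-response group effect, a subject random
    effect and i.i.d. noise.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    records = []
    strata = [(25, 27), (28, 30), (31, 33), (34, 36), (37, 40)]
    for group, n in (("low", config.n_low), ("high", config.n_high)):
        gi = 0 if group == "low" else 1
        units = _truncated_lognormal(
            rng,
            n,
            getattr(config, f"{group}_units_median"),
            getattr(config, f"{group}_units_mean"),
            *getattr(config, f"{group}_units_range"),
        )
        for i in range(n):
            lo, hi = strata[i % len(strata)]
            age = float(rng.uniform(lo, hi + 1))
            age = min(age, 40.0)
            pid = f"{group}{i + 1:03d}"
            total = float(units[i])
            assert nesi.allocate_group(total) == group
            subj_re = rng.normal(0, config.subject_re_sd)
            row = {
                "participant_id": pid,
                "group": group,
                "total_units": total,
                "age_years": age,
                "age_stratum": nesi.age_stratum(age),
                "sex": "F" if rng.random() < config.female_prob[gi] else "M",
                "tinnitus": int(rng.random() < config.tinnitus_prob[gi]),
                "tolerance_reduced": int(
                    rng.random() < config.tolerance_prob[gi]
                ),
            }
            boost = (
                1.0 + config.group_effect_onset if group == "high" else 1.0
            )
            for region in REGIONS:
                w_on, w_off, w_sus = config.region_weights[region]
                for hemi in ("left", "right"):
                    row[f"onset_{region}_{hemi}"] = (
                        w_on * boost
                        + subj_re
                        + rng.normal(0, config.beta_noise_sd)
                    )
                    row[f"sustained_{region}_{hemi}"] = (
                        w_sus + subj_re + rng.normal(0, config.beta_noise_sd)
                    )
            amp1 = max(rng.normal(config.wave1_mean_uv, config.wave1_sd_uv),
                       0.01)
            amp5 = max(rng.normal(config.wave5_mean_uv, config.wave5_sd_uv),
                       0.05)
            row["wave1_amplitude_uv"] = amp1
            row["wave5_amplitude_uv"] = amp5
            row["ratio_1_5"] = amp1 / amp5
            rows.append(row)
            records.append(
                nesi.ExposureRecord(
                    participant_id=pid,
                    activities=[_activity_for_units(total)],
                    age_years=age,
                )
            )
    return pd.DataFrame(rows), records


# ---------------------------------------------------------------------------
# ABR recordings


def abr_template(config: SimConfig, times_ms: np.ndarray) -> np.ndarray:
    """Evoked-response template (uV) on a latency axis re eardrum arrival."""

    def bump(lat, amp, sig):
        return amp * np.exp(-((times_ms - lat) ** 2) / (2 * sig**2))

    return (
        bump(config.wave1_latency_ms, config.wave1_amp_uv,
             config.wave1_sigma_ms)
        - bump(config.wave1_trough_latency_ms, config.wave1_trough_amp_uv,
               config.wave1_trough_sigma_ms)
        + bump(config.wave5_latency_ms, config.wave5_amp_uv,
               config.wave5_sigma_ms)
    )


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude noise with the requested standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n)
    return pink * (sd / pink.std())


def gen_abr_recording(
    config: SimConfig, seed: int | None = None
) -> tuple[RawRecording, ClickEvents]:
    """Continuous 3-channel recording with clicks alternating between ears.

    Each click deposits the wave I/V template into the vertex channel
    ``acoustic_delay_ms`` after its event time; background is 1/f noise,
    with occasional high-amplitude artifact bursts to exercise rejection.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.abr_fs_hz
    n_clicks = 2 * config.n_clicks_per_ear
    interval = 1.0 / config.click_rate_hz
    onsets = 1.0 + np.arange(n_clicks) * interval
    ears = np.array(["left", "right"] * config.n_clicks_per_ear)[:n_clicks]
    events = ClickEvents(onsets_s=onsets, ears=ears)

    duration = onsets[-1] + 0.2
    n_samples = int(round(duration * fs))
    template_times = np.arange(-2.0, 11.0, 1e3 / fs)
    template = abr_template(config, template_times)
    t0_offset = int(round(-2.0e-3 * fs))  # template starts 2 ms pre-arrival

    cz = _pink_noise(rng, n_samples, config.abr_noise_sd_uv)
    left = _pink_noise(rng, n_samples, config.abr_noise_sd_uv / 2)
    right = _pink_noise(rng, n_samples, config.abr_noise_sd_uv / 2)

    arrivals = onsets + config.acoustic_delay_ms * 1e-3
    starts = np.round(arrivals * fs).astype(int) + t0_offset
    for s in starts:
        cz[s : s + len(template)] += template

    n_artifacts = rng.binomial(n_clicks, config.artifact_rate)
    if n_artifacts > 0 and config.artifact_amp_uv > 0:
        width = int(0.02 * fs)
        at = rng.integers(0, n_samples - width, size=n_artifacts)
        for s in at:
            cz[s : s + width] += config.artifact_amp_uv * rng.standard_normal(
                width
            )
    return RawRecording(
        fs_hz=fs, cz=cz, left_mastoid=left, right_mastoid=right
    ), events


# ---------------------------------------------------------------------------
# physiological traces


def gen_physio(
    config: SimConfig, duration_s: float, seed: int | None = None
) -> PhysioTrace:
    """Quasi-periodic cardiac and respiratory traces with marked peaks."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.physio_fs_hz
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # cardiac: jittered inter-beat intervals, pulse-like waveform
    mean_ibi = 1.0 / config.cardiac_freq_hz
    n_beats = int(np.ceil(duration_s / mean_ibi)) + 3
    ibis = mean_ibi * (
        1.0 + config.physio_jitter * rng.standard_normal(n_beats)
    )
    ibis = np.clip(ibis, 0.3 * mean_ibi, 2.0 * mean_ibi)
    peaks = np.cumsum(ibis) - ibis[0] + 0.2
    peaks = peaks[peaks < duration_s]
    cardiac = np.zeros(n)
    for pk in peaks:
        cardiac += np.exp(-((t - pk) ** 2) / (2 * 0.05**2))

    # respiration: sinusoid with slow phase wander
    wander = np.cumsum(
        config.physio_jitter * rng.standard_normal(n)
    ) / np.sqrt(fs)
    resp = np.sin(2 * np.pi * config.resp_freq_hz * t + wander)
    return PhysioTrace(
        fs_hz=fs, cardiac=cardiac, respiratory=resp, cardiac_peaks_s=peaks
    )


# ---------------------------------------------------------------------------
# BOLD datasets


def _blob_mask(shape, center, radius) -> np.ndarray:
    grid = np.indices(shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grid, center))
    return d2 <= radius**2


@dataclass
class BoldGroundTruth:
    """Injected per-region weights and nuisance parameters."""

    weights: dict  # (region, hemi) -> (onset, offset, sustained)
    rho: float
    task_design: DesignMatrix


def gen_bold_dataset(
    config: SimConfig,
    group: str = "low",
    paradigm: BlockParadigm | None = None,
    seed: int | None = None,
    noise_sd: float | None = None,
) -> tuple[VolumeSeries, PhysioTrace, BoldGroundTruth]:
    """Small 4D BOLD dataset with region blobs and structured noise.

    Blob voxels carry weighted HRF-convolved task responses on the global
    baseline; every voxel receives slow drift, cardiac/respiratory
    sinusoids and AR(1) noise.  High-exposure participants get onset
    weights scaled by ``1 + group_effect_onset``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    paradigm = paradigm or BlockParadigm()
    noise_sd = config.bold_noise_sd if noise_sd is None else noise_sd
    design = build_regressors(paradigm, Hrf())
    n_vol = design.n_volumes
    task = design.matrix  # [n_vol, 3]

    shape = config.grid
    data = np.full(shape + (n_vol,), config.bold_baseline, dtype=float)

    # shared structured nuisance (same phase across voxels, random ampl.)
    tvol = np.arange(n_vol) * paradigm.tr_s
    drift = config.drift_amp * np.sin(
        2 * np.pi * tvol / (4 * 128.0) + rng.uniform(0, 2 * np.pi)
    )
    physio = gen_physio(
        config, duration_s=n_vol * paradigm.tr_s, seed=rng.integers(2**31)
    )
    from .physio import cardiac_phase, respiratory_phase

    cphase = cardiac_phase(physio.cardiac_peaks_s, tvol)
    rphase = respiratory_phase(physio.respiratory, physio.fs_hz, tvol)
    nuisance = config.cardiac_amp * np.cos(cphase) + config.resp_amp * np.cos(
        rphase
    )

    boost = 1.0 + config.group_effect_onset if group == "high" else 1.0
    weights = {}
    signal_vol = np.zeros(shape + (n_vol,))
    for (region, hemi), center in config.seeds_xyz.items():
        w_on, w_off, w_sus = config.region_weights[region]
        w = (w_on * boost, w_off, w_sus)
        weights[(region, hemi)] = w
        mask = _blob_mask(shape, center, config.blob_radius_vox)
        signal_vol[mask] += task @ np.asarray(w)

    # AR(1) noise per voxel
    if noise_sd > 0:
        eps = rng.standard_normal(shape + (n_vol,)) * noise_sd
        noise = np.empty_like(eps)
        rho = config.bold_ar1_rho
        noise[..., 0] = eps[..., 0] / np.sqrt(1 - rho**2)
        for v in range(1, n_vol):
            noise[..., v] = rho * noise[..., v - 1] + eps[..., v]
    else:
        noise = 0.0

    data += signal_vol + drift + nuisance + noise
    vol = VolumeSeries(
        data,
        voxel_size_mm=config.voxel_size_mm,
        run_lengths=design.run_lengths,
    )
    truth = BoldGroundTruth(
        weights=weights, rho=config.bold_ar1_rho, task_design=design
    )
    return vol, physio, truth


def ground_truth_mask(config: SimConfig):
    """RoiMask matching the generated blob layout exactly."""
    from .fmri_glm import RoiMask

    labels = np.zeros(config.grid, dtype=np.int32)
    names = {}
    for i, ((region, hemi), center) in enumerate(
        config.seeds_xyz.items(), start=1
    ):
        labels[_blob_mask(config.grid, center, config.blob_radius_vox)] = i
        names[i] = (region, hemi)
    return RoiMask(labels=labels, label_names=names)


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced-size configuration for fast tests."""
    defaults = dict(
        seed=seed,
        n_clicks_per_ear=400,
        grid=(16, 16, 12),
        seeds_xyz={
            ("IC", "left"): (4, 5, 4),
            ("IC", "right"): (11, 5, 4),
            ("AC", "left"): (4, 11, 8),
            ("AC", "right"): (11, 11, 8),
        },
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
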