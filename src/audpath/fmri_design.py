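"""Block-paradigm construction and first-level design-matrix assembly.

The acquisition is a sparse-free continuous block design: per run, 64 s of
initial rest followed by 8 cycles of 24 s broadband noise on / 42 s off,
four runs at TR = 2 s (296 volumes/run).  Task regressors are a delta train
at stimulus onsets, a delta train at stimulus offsets, and a boxcar over the
on epochs, each convolved with a canonical double-gamma haemodynamic
response at fine temporal resolution and sampled at volume times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma

TASK_COLUMNS = ("onset", "offset", "sustained")


@dataclass(frozen=True)
class BlockParadigm:
    """Timing of the block design (all durations in seconds)."""

    initial_rest_s: float = 64.0
    on_s: float = 24.0
    off_s: float = 42.0
    cycles_per_run: int = 8
    n_runs: int = 4
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        for name in ("initial_rest_s", "on_s", "off_s"):
            value = getattr(self, name)
            if value % self.tr_s != 0:
                raise ValueError(
                    f"{name}={value} is not an integer multiple of "
                    f"TR={self.tr_s}"
                )

    @property
    def run_duration_s(self) -> float:
        return self.initial_rest_s + self.cycles_per_run * (
            self.on_s + self.off_s
        )

    @property
    def volumes_per_run(self) -> int:
        return int(round(self.run_duration_s / self.tr_s))

    @property
    def n_volumes(self) -> int:
        return self.volumes_per_run * self.n_runs

    def onset_times_s(self) -> np.ndarray:
        """Stimulus-on start times within one run."""
        return self.initial_rest_s + np.arange(self.cycles_per_run) * (
            self.on_s + self.off_s
        )

    def events_frame(self) -> pd.DataFrame:
        """BIDS-style events (onset, duration, trial_type) with run index."""
        rows = []
        for run in range(self.n_runs):
            for t0 in self.onset_times_s():
                rows.append(
                    {
                        "onset": t0,
                        "duration": self.on_s,
                        "trial_type": "noise",
                        "run": run + 1,
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class Hrf:
    """Canonical double-gamma haemodynamic response function.

    h(t) = pdf_gamma(t; peak) - pdf_gamma(t; undershoot) / ratio with unit
    dispersions, truncated at ``length_s``.
    """

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    length_s: float = 32.0

    def kernel(self, dt: float) -> np.ndarray:
        t = np.arange(0.0, self.length_s + dt / 2, dt)
        h = _gamma.pdf(
            t, self.peak_s / self.peak_dispersion, scale=self.peak_dispersion
        ) - _gamma.pdf(
            t,
            self.undershoot_s / self.undershoot_dispersion,
            scale=self.undershoot_dispersion,
        ) / self.ratio
        if h.sum() <= 0:
            raise ValueError("HRF kernel must integrate to a positive value")
        return h


@dataclass
class DesignMatrix:
    """Column-named design matrix with run boundaries."""

    matrix: np.ndarray
    names: list[str]
    run_lengths: list[int]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column count does not match names")
        if sum(self.run_lengths) != self.matrix.shape[0]:
            raise ValueError("run lengths do not sum to row count")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def with_columns(self, cols: np.ndarray, names: list[str]) -> "DesignMatrix":
        return DesignMatrix(
            np.column_stack([self.matrix, cols]),
            self.names + list(names),
            self.run_lengths,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.insert(0, "run_length", 0)
        df["run_length"] = np.repeat(self.run_lengths, self.run_lengths)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DesignMatrix":
        df = pd.read_csv(path, sep="\t")
        # run_length stores each run's length repeated on that run's rows
        run_lengths = []
        col = df["run_length"].to_numpy()
        i = 0
        while i < len(col):
            run_lengths.append(int(col[i]))
            i += int(col[i])
        mat = df.drop(columns=["run_length"]).to_numpy(dtype=float)
        return cls(mat, list(df.columns.drop("run_length")), run_lengths)


def volume_labels(paradigm: BlockParadigm) -> np.ndarray:
    """Per-volume stimulus state ("on"/"off") for the concatenated runs.

    A volume is labelled by the stimulus state at the start of its
    acquisition; epoch boundaries align with the TR grid, so this equals the
    state throughout the volume.  The initial rest is labelled off.
    """
    per_run = np.full(paradigm.volumes_per_run, "off", dtype=object)
    starts = np.arange(paradigm.volumes_per_run) * paradigm.tr_s
    for t0 in paradigm.onset_times_s():
        per_run[(starts >= t0) & (starts < t0 + paradigm.on_s)] = "on"
    return np.tile(per_run, paradigm.n_runs).astype(str)


def build_regressors(
    paradigm: BlockParadigm,
    hrf: Hrf | None = None,
    dt: float = 0.1,
) -> DesignMatrix:
    """HRF-convolved onset/offset/sustained task columns, runs concatenated.

    Onset deltas sit at each on-epoch start and offset deltas at each
    on-epoch end; the sustained boxcar spans each on epoch.  Convolution is
    performed at ``dt`` resolution per run (restarted across runs) and
    sampled at volume acquisition times.
    """
    hrf = hrf or Hrf()
    kernel = hrf.kernel(dt)
    n_fine = int(round(paradigm.run_duration_s / dt))
    n_vol = paradigm.volumes_per_run

    onset = np.zeros(n_fine)
    offset = np.zeros(n_fine)
    sustained = np.zeros(n_fine)
    for t0 in paradigm.onset_times_s():
        i0 = int(round(t0 / dt))
        i1 = int(round((t0 + paradigm.on_s) / dt))
        onset[i0] = 1.0
        if i1 < n_fine:
            offset[i1] = 1.0
        sustained[i0:i1] = 1.0

    sample_idx = np.round(
        np.arange(n_vol) * paradigm.tr_s / dt
    ).astype(int)
    # deltas are unit impulses (continuous convolution with the HRF);
    # the boxcar convolution is a Riemann integral, hence the dt factor
    cols_run = np.column_stack(
        [
            np.convolve(onset, kernel)[:n_fine][sample_idx],
            np.convolve(offset, kernel)[:n_fine][sample_idx],
            np.convolve(sustained, kernel)[:n_fine][sample_idx] * dt,
        ]
    )
    matrix = np.tile(cols_run, (paradigm.n_runs, 1))
    return DesignMatrix(
        matrix,
        list(TASK_COLUMNS),
        [n_vol] * paradigm.n_runs,
    )


def highpass_basis(
    paradigm: BlockParadigm, cutoff_s: float = 128.0
) -> np.ndarray:
    """Per-run discrete-cosine drift basis (block-diagonal, orthonormal).

    Each run contributes floor(2 * run_duration / cutoff) DCT-II columns
    spanning drift periods at or above the cutoff.
    """
    if cutoff_s <= 2 * paradigm.tr_s:
        raise ValueError("cutoff must exceed 2 TR")
    n = paradigm.volumes_per_run
    order = int(np.floor(2 * n * paradigm.tr_s / cutoff_s))
    t = np.arange(n)
    basis = np.column_stack(
        [np.cos(np.pi * (t + 0.5) * j / n) for j in range(1, order + 1)]
    )
    basis /= np.linalg.norm(basis, axis=0)
    blocks = np.zeros((n * paradigm.n_runs, order * paradigm.n_runs))
    for r in range(paradigm.n_runs):
        blocks[r * n : (r + 1) * n, r * order : (r + 1) * order] = basis
    return blocks


def drift_column_names(paradigm: BlockParadigm, cutoff_s: float = 128.0):
    n = paradigm.volumes_per_run
    order = int(np.floor(2 * n * paradigm.tr_s / cutoff_s))
    return [
        f"drift_run{r + 1}_{j + 1}"
        for r in range(paradigm.n_runs)
        for j in range(order)
    ]


def orthogonality(design: DesignMatrix, columns=TASK_COLUMNS) -> pd.DataFrame:
    """Pairwise Pearson correlations between task columns.

    Computed over the concatenated, unfiltered columns (signed; the design
    is assessed before high-pass filtering).
    """
    data = np.column_stack([design.column(c) for c in columns])
    if np.any(data.std(axis=0) == 0):
        bad = [c for c, s in zip(columns, data.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance column(s): {bad}")
    corr = np.corrcoef(data, rowvar=False)
    return pd.DataFrame(corr, index=list(columns), columns=list(columns))


def full_design(
    paradigm: BlockParadigm,
    hrf: Hrf | None = None,
    nuisance: np.ndarray | None = None,
    nuisance_names: list[str] | None = None,
    highpass_cutoff_s: float | None = 128.0,
    run_intercepts: bool = True,
) -> DesignMatrix:
    """Task columns + optional nuisance columns + per-run drift basis.

    Per-run constant columns model the signal baseline (the drift basis is
    zero-mean and does not absorb it).
    """
    design = build_regressors(paradigm, hrf)
    if run_intercepts:
        n = paradigm.volumes_per_run
        blocks = np.zeros((design.n_volumes, paradigm.n_runs))
        for r in range(paradigm.n_runs):
            blocks[r * n : (r + 1) * n, r] = 1.0
        design = design.with_columns(
            blocks,
            [f"intercept_run{r + 1}" for r in range(paradigm.n_runs)],
        )
    if nuisance is not None:
        design = design.with_columns(nuisance, nuisance_names or [
            f"nuisance_{i}" for i in range(nuisance.shape[1])
        ])
    if highpass_cutoff_s is not None:
        drift = highpass_basis(paradigm, highpass_cutoff_s)
        design = design.with_columns(
            drift, drift_column_names(paradigm, highpass_cutoff_s)
        )
    return design
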