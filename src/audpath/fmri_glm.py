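"""Voxel-wise first-level GLM and ROI machinery for 4D BOLD series.

Fitting is OLS followed by AR(1) prewhitening with a single rho pooled over
voxels, estimated from the lag-1 autocorrelation of the OLS residuals (run
boundaries respected).  Downstream: contrast/t maps, Gaussian smoothing,
composite suprathreshold ROI masks (Bonferroni-thresholded maps OR-combined
and split at seed locations), ROI mean betas, cycle-averaged
percent-signal-change time-courses, and a max-statistic permutation
two-sample group map for familywise error control within a mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .fmri_design import BlockParadigm, DesignMatrix

logger = logging.getLogger(__name__)

REGIONS = ("CN", "SOC", "NLL", "IC", "MGB", "AC")
HEMISPHERES = ("left", "right")

_GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class GlmError(RuntimeError):
    pass


@dataclass
class VolumeSeries:
    """4D BOLD array [x, y, z, volume] with voxel geometry."""

    data: np.ndarray
    voxel_size_mm: float = 1.5
    affine: np.ndarray | None = None
    run_lengths: list[int] | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4D [x, y, z, volume]")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.affine is None:
            self.affine = np.diag(
                [self.voxel_size_mm] * 3 + [1.0]
            ).astype(float)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class RoiMask:
    """Labelled integer volume with a label -> (region, hemisphere) map."""

    labels: np.ndarray
    label_names: dict[int, tuple[str, str]]
    affine: np.ndarray | None = None

    def region_voxels(self, region: str, hemisphere: str) -> np.ndarray:
        for lab, (reg, hemi) in self.label_names.items():
            if reg == region and hemi == hemisphere:
                return np.argwhere(self.labels == lab)
        return np.empty((0, 3), dtype=int)

    def binary(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class GlmFit:
    """Per-voxel GLM estimates over the in-mask voxels."""

    betas: np.ndarray  # [n_columns, n_voxels]
    sigma2: np.ndarray  # [n_voxels]
    rho: float
    df: int
    xtx_inv: np.ndarray  # (X'X)^-1 of the whitened design
    design_names: list[str]
    mask: np.ndarray | None = None  # 3D bool; None for 2D input

    def beta_for(self, name: str) -> np.ndarray:
        return self.betas[self.design_names.index(name)]


@dataclass
class ContrastMap:
    """Per-voxel contrast estimate and t statistic."""

    value: np.ndarray
    t: np.ndarray
    df: int
    mask: np.ndarray | None = None

    def volume(self, fill: float = 0.0) -> np.ndarray:
        """Scatter in-mask values back into a 3D volume."""
        if self.mask is None:
            raise ValueError("contrast was fitted on 2D data; no mask")
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = self.value
        return out

    def t_volume(self, fill: float = 0.0) -> np.ndarray:
        if self.mask is None:
            raise ValueError("contrast was fitted on 2D data; no mask")
        out = np.full(self.mask.shape, fill, dtype=float)
        out[self.mask] = self.t
        return out


# ---------------------------------------------------------------------------
# smoothing


def smooth_gaussian(
    vol: VolumeSeries, fwhm_mm: float = 2.0
) -> VolumeSeries:
    """Separable spatial Gaussian smoothing of each volume."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return vol
    sigma_vox = fwhm_mm * _GAUSS_FWHM_TO_SIGMA / vol.voxel_size_mm
    out = ndimage.gaussian_filter(
        vol.data, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0)
    )
    return VolumeSeries(
        out, vol.voxel_size_mm, vol.affine, vol.run_lengths
    )


# ---------------------------------------------------------------------------
# GLM


def _as_timeseries(Y, mask):
    """Return ([n_volumes, n_voxels] array, 3D bool mask or None)."""
    if isinstance(Y, VolumeSeries):
        if mask is None:
            mask = np.ones(Y.shape3d, dtype=bool)
        data = Y.data[mask].T  # [vol, vox]
        return np.asarray(data, dtype=float), mask
    arr = np.asarray(Y, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, None


def _whiten(arr: np.ndarray, rho: float, run_lengths) -> np.ndarray:
    """AR(1) prewhitening per run: y*_t = y_t - rho*y_{t-1}."""
    out = arr.copy()
    start = 0
    for n in run_lengths:
        block = arr[start : start + n]
        out[start] = block[0] * np.sqrt(1 - rho**2)
        out[start + 1 : start + n] = block[1:] - rho * block[:-1]
        start += n
    return out


def fit_glm(
    Y,
    X: DesignMatrix,
    mask: np.ndarray | None = None,
    ar1: bool = True,
) -> GlmFit:
    """Fit the GLM with pooled AR(1) prewhitening.

    ``Y`` may be a :class:`VolumeSeries` (with optional 3D mask) or an
    [n_volumes, n_voxels] array.  The AR(1) coefficient is estimated from
    the OLS residuals pooled over voxels, then both data and design are
    whitened per run and refitted.
    """
    data, mask3d = _as_timeseries(Y, mask)
    Xm = X.matrix
    if data.shape[0] != Xm.shape[0]:
        raise ValueError(
            f"data has {data.shape[0]} volumes, design {Xm.shape[0]} rows"
        )
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # name columns involved in collinearity via QR pivoting
        _, r = np.linalg.qr(Xm)
        diag = np.abs(np.diag(r))
        bad = [X.names[i] for i in np.nonzero(diag < 1e-8 * diag.max())[0]]
        raise GlmError(f"design is rank deficient; collinear columns: {bad}")

    run_lengths = X.run_lengths
    beta_ols, *_ = np.linalg.lstsq(Xm, data, rcond=None)
    resid = data - Xm @ beta_ols

    rho = 0.0
    if ar1:
        num = 0.0
        den = 0.0
        start = 0
        for n in run_lengths:
            r = resid[start : start + n]
            num += float(np.sum(r[1:] * r[:-1]))
            den += float(np.sum(r**2))
            start += n
        rho = num / den if den > 0 else 0.0
        rho = float(np.clip(rho, -0.999, 0.999))

    Xw = _whiten(Xm, rho, run_lengths)
    Yw = _whiten(data, rho, run_lengths)
    betas, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    residw = Yw - Xw @ betas
    df = data.shape[0] - rank
    sigma2 = np.sum(residw**2, axis=0) / df
    xtx_inv = np.linalg.pinv(Xw.T @ Xw)
    return GlmFit(
        betas=betas,
        sigma2=sigma2,
        rho=rho,
        df=df,
        xtx_inv=xtx_inv,
        design_names=list(X.names),
        mask=mask3d,
    )


def contrast(fit: GlmFit, weights) -> ContrastMap:
    """Contrast estimate c'beta and its t statistic per voxel."""
    c = np.zeros(len(fit.design_names))
    if isinstance(weights, dict):
        for name, w in weights.items():
            c[fit.design_names.index(name)] = w
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(fit.design_names):
            raise ValueError(
                f"weight length {len(w)} != column count "
                f"{len(fit.design_names)}"
            )
        c = w
    est = c @ fit.betas
    var_c = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(fit.sigma2 * var_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / se, 0.0)
    return ContrastMap(value=est, t=t, df=fit.df, mask=fit.mask)


# ---------------------------------------------------------------------------
# composite ROI mask


def composite_mask(
    maps: list[ContrastMap],
    seeds: dict[tuple[str, str], tuple[int, int, int]],
    alpha: float = 0.01,
    affine: np.ndarray | None = None,
) -> RoiMask:
    """Threshold, binarize and OR-combine contrast maps; label at seeds.

    Each map is thresholded voxel-wise at one-sided p < ``alpha`` with
    Bonferroni correction over the in-mask voxels.  Connected components of
    the OR-combined binary image are assigned the region/hemisphere of the
    seed they contain; components containing no seed are discarded (count
    logged), and a seed falling in no suprathreshold component yields an
    empty region with a warning.
    """
    if not maps:
        raise ValueError("no contrast maps given")
    shape = maps[0].mask.shape
    combined = np.zeros(shape, dtype=bool)
    for m in maps:
        if m.mask.shape != shape:
            raise ValueError("contrast maps do not share a grid")
        n_vox = int(m.mask.sum())
        t_crit = stats.t.isf(alpha / n_vox, m.df)
        combined |= m.t_volume(fill=-np.inf) > t_crit

    comp, n_comp = ndimage.label(combined)
    labels = np.zeros(shape, dtype=np.int32)
    label_names: dict[int, tuple[str, str]] = {}
    used_components: set[int] = set()
    next_label = 1
    for (region, hemi), xyz in seeds.items():
        cid = int(comp[tuple(xyz)])
        if cid == 0:
            logger.warning(
                "seed for %s/%s is in no suprathreshold component; "
                "region left empty", region, hemi,
            )
            continue
        labels[comp == cid] = next_label
        label_names[next_label] = (region, hemi)
        used_components.add(cid)
        next_label += 1
    n_discarded = n_comp - len(used_components)
    if n_discarded > 0:
        logger.info(
            "discarded %d suprathreshold component(s) containing no seed",
            n_discarded,
        )
    return RoiMask(labels=labels, label_names=label_names, affine=affine)


def roi_mean_beta(
    cmap: ContrastMap, mask: RoiMask, region: str, hemisphere: str
) -> float:
    """Mean contrast value over the voxels labelled region/hemisphere."""
    vox = mask.region_voxels(region, hemisphere)
    if len(vox) == 0:
        raise GlmError(f"region {region}/{hemisphere} is empty")
    vol = cmap.volume(fill=np.nan)
    vals = vol[vox[:, 0], vox[:, 1], vox[:, 2]]
    if np.any(np.isnan(vals)):
        raise GlmError(
            f"region {region}/{hemisphere} extends outside the fitted mask"
        )
    return float(vals.mean())


# ---------------------------------------------------------------------------
# cycle-averaged time-courses


def cycle_average(
    Y: VolumeSeries,
    mask: RoiMask,
    paradigm: BlockParadigm,
    region: str,
    hemisphere: str,
    baseline_s: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """ROI percent-signal-change time-course averaged over cycles and runs.

    Returns ``(times_s, percent)`` where times are relative to stimulus
    onset and span one 66-s cycle.  The baseline for each cycle is the
    ROI-mean signal over the ``baseline_s`` seconds immediately preceding
    onset (the tail of the preceding off/rest period).
    """
    vox = mask.region_voxels(region, hemisphere)
    if len(vox) == 0:
        raise GlmError(f"region {region}/{hemisphere} is empty")
    series = Y.data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0)

    n_vol = paradigm.volumes_per_run
    cycle_vols = int(round((paradigm.on_s + paradigm.off_s) / paradigm.tr_s))
    base_vols = int(round(baseline_s / paradigm.tr_s))
    segments = []
    for run in range(paradigm.n_runs):
        run_series = series[run * n_vol : (run + 1) * n_vol]
        for t0 in paradigm.onset_times_s():
            i0 = int(round(t0 / paradigm.tr_s))
            seg = run_series[i0 : i0 + cycle_vols]
            base = run_series[i0 - base_vols : i0].mean()
            if base == 0:
                if np.all(seg == 0):
                    segments.append(np.zeros_like(seg, dtype=float))
                    continue
                raise GlmError("zero baseline with non-zero signal")
            segments.append(100.0 * (seg - base) / abs(base))
    avg = np.mean(segments, axis=0)
    times = np.arange(cycle_vols) * paradigm.tr_s
    return times, avg


# ---------------------------------------------------------------------------
# second-level permutation group map


@dataclass
class GroupMapResult:
    t: np.ndarray  # observed two-sample t per in-mask voxel
    p_fwe: np.ndarray  # max-statistic familywise p per voxel
    max_t_null: np.ndarray  # permutation distribution of max |t|
    voxels: np.ndarray  # [n_voxels, 3] indices


def _two_sample_t(data: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance two-sample t (group 1 minus group 0)."""
    g1 = data[labels == 1]
    g0 = data[labels == 0]
    n1, n0 = len(g1), len(g0)
    m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
    ss = ((g1 - m1) ** 2).sum(axis=0) + ((g0 - m0) ** 2).sum(axis=0)
    sp2 = ss / (n1 + n0 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(se > 0, (m1 - m0) / se, 0.0)


def group_map(
    contrast_values: np.ndarray,
    group_labels,
    voxels: np.ndarray | None = None,
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> GroupMapResult:
    """Two-sample group-difference map with max-|t| permutation FWE.

    ``contrast_values`` is [n_participants, n_voxels]; ``group_labels`` a
    binary vector (1 = high).  Familywise p per voxel is the fraction of
    label permutations whose maximum |t| over voxels meets or exceeds the
    observed |t| (with the +1 correction for exactness).
    """
    data = np.asarray(contrast_values, dtype=float)
    labels = np.asarray(
        [1 if g in (1, "high", True) else 0 for g in group_labels]
    )
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise ValueError("need at least 2 participants per group")
    rng = np.random.default_rng(seed)
    t_obs = _two_sample_t(data, labels)
    # vectorized max-|t| null: all relabelings at once
    L = rng.permuted(
        np.tile(labels, (n_permutations, 1)), axis=1
    ).astype(float)
    n1 = labels.sum()
    n0 = len(labels) - n1
    sq = data**2
    s_tot = sq.sum(axis=0)
    m1 = (L @ data) / n1
    m0 = ((1.0 - L) @ data) / n0
    s1 = L @ sq
    ss = (s1 - n1 * m1**2) + ((s_tot - s1) - n0 * m0**2)
    sp2 = ss / (n1 + n0 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(se > 0, (m1 - m0) / se, 0.0)
    max_null = np.max(np.abs(t_null), axis=1)
    p_fwe = (1.0 + np.sum(max_null[:, None] >= np.abs(t_obs)[None, :], axis=0)
             ) / (n_permutations + 1.0)
    if voxels is None:
        voxels = np.arange(data.shape[1])[:, None]
    return GroupMapResult(
        t=t_obs, p_fwe=p_fwe, max_t_null=max_null, voxels=voxels
    )
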