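"""Cohort-level inferential statistics.

The central routine is a mixed (split-plot) ANCOVA on per-participant ROI
responses: within-subject factors (region, hemisphere) are handled through
orthonormal within-subject contrasts, each within stratum is tested against
its own subject-by-factor error, and between-subject factors plus a
de-meaned age covariate are tested against the subject error stratum.  No
sphericity correction is applied (uncorrected degrees of freedom).
Supporting tests: skew/kurtosis normality screening, Mood's median test,
Pearson chi-square on 2x2 tables, Mann-Whitney U, Pearson correlation, and
a paired-t percent-difference comparison used for pipeline evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# mixed (split-plot) ANCOVA


def _orthonormal_contrasts(n_levels: int) -> np.ndarray:
    """(n_levels x n_levels-1) orthonormal contrasts orthogonal to the mean."""
    full = np.linalg.qr(
        np.column_stack(
            [np.ones(n_levels), np.eye(n_levels)[:, : n_levels - 1]]
        )
    )[0]
    return full[:, 1:]


def _sum_coding(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero coding columns for a categorical vector."""
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) < 2:
        raise StatsError(f"factor has a single level: {levels}")
    cols = []
    for lev in levels[:-1]:
        col = np.where(labels == lev, 1.0, 0.0)
        col[labels == levels[-1]] = -1.0
        cols.append(col)
    return np.column_stack(cols), levels


def _type3_ss(U: np.ndarray, X: np.ndarray, term_cols: dict[str, list[int]]):
    """Drop-term (Type III) sums of squares for each term, plus residual SS.

    ``U`` is [n_subjects, q]; SS are summed over the q contrast columns.
    """
    fit_full, *_ = np.linalg.lstsq(X, U, rcond=None)
    resid = U - X @ fit_full
    sse = float(np.sum(resid**2))
    ss = {}
    for term, cols in term_cols.items():
        keep = [j for j in range(X.shape[1]) if j not in cols]
        Xr = X[:, keep]
        fit_r, *_ = np.linalg.lstsq(Xr, U, rcond=None)
        sse_r = float(np.sum((U - Xr @ fit_r) ** 2))
        ss[term] = sse_r - sse
    return ss, sse


@dataclass
class AnovaResult:
    """Tidy effect table: F, numerator/denominator df, p per effect."""

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect named {name!r}")
        return rows.iloc[0]

    def p(self, name: str) -> float:
        return float(self.effect(name)["p"])

    def F(self, name: str) -> float:
        return float(self.effect(name)["F"])


def mixed_ancova(
    table: pd.DataFrame,
    response: str,
    within: dict[str, tuple[str, ...]] | None = None,
    between: tuple[str, ...] = ("group",),
    covariate: str | None = "age_years",
) -> AnovaResult:
    """Split-plot ANCOVA of ROI responses on a cohort table.

    Parameters
    ----------
    table
        One row per participant.  Response cells are wide columns named
        ``{response}_{level1}_{level2}_...`` following the within-factor
        order, e.g. ``onset_CN_left``.
    response
        Response column prefix (e.g. ``"onset"`` or ``"sustained"``).
    within
        Ordered mapping of within-subject factor name -> level labels;
        default ``{"region": ("CN", "IC", "MGB", "AC"), "hemisphere":
        ("left", "right")}``.
    between
        Between-subject factor column names (entered additively).
    covariate
        Numeric covariate column, de-meaned before entry; tested in the
        between-subject stratum only, with its interactions with each
        within factor absorbing variance in the within strata.

    Notes
    -----
    Each within stratum uses its own error term (subject x factor within
    groups); denominator df follow the uncorrected split-plot layout, e.g.
    region F_3,3(N-p) and group F_1,N-p for p between-stratum parameters.
    """
    if within is None:
        within = {
            "region": ("CN", "IC", "MGB", "AC"),
            "hemisphere": ("left", "right"),
        }
    factor_names = list(within)
    level_lists = [within[f] for f in factor_names]

    # response cell matrix, subjects x cells (factor order = column order)
    cell_cols = []
    from itertools import product as _product

    for combo in _product(*level_lists):
        col = "_".join([response, *combo])
        if col not in table.columns:
            raise StatsError(f"missing response cell column: {col}")
        cell_cols.append(col)
    Y = table[cell_cols].to_numpy(dtype=float)
    if np.isnan(Y).any():
        bad = [c for c in cell_cols if table[c].isna().any()]
        raise StatsError(f"missing cells in columns: {bad}")
    n_subj = len(Y)

    # between-subject design: intercept + sum-coded factors + covariate
    X_parts = [np.ones((n_subj, 1))]
    term_cols: dict[str, list[int]] = {"intercept": [0]}
    col_ix = 1
    for bf in between:
        cols, _levels = _sum_coding(table[bf].to_numpy())
        X_parts.append(cols)
        term_cols[bf] = list(range(col_ix, col_ix + cols.shape[1]))
        col_ix += cols.shape[1]
    if covariate is not None:
        cov = table[covariate].to_numpy(dtype=float)
        cov = cov - cov.mean()
        X_parts.append(cov[:, None])
        term_cols[covariate] = [col_ix]
        col_ix += 1
    X = np.column_stack(X_parts)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise StatsError("between-subject design is rank deficient")
    df_error_between = n_subj - p

    rows = []

    def add_rows(ss_terms, sse, q, df_err_scale, within_label=None):
        df_err = q * df_err_scale
        mse = sse / df_err
        for term, ss in ss_terms.items():
            if term == "intercept" and within_label is None:
                continue  # grand mean is not a reported effect
            df_num = q * len(term_cols[term])
            name = (
                within_label
                if term == "intercept"
                else (f"{within_label}:{term}" if within_label else term)
            )
            F = (ss / df_num) / mse if mse > 0 else np.inf
            rows.append(
                {
                    "effect": name,
                    "F": F,
                    "df1": df_num,
                    "df2": df_err,
                    "p": float(stats.f.sf(F, df_num, df_err)),
                }
            )

    # between-subject stratum: subject means over cells
    t_mean = [np.full((len(lv), 1), 1.0 / np.sqrt(len(lv))) for lv in level_lists]
    contrasts = {f: _orthonormal_contrasts(len(within[f])) for f in factor_names}

    def kron_chain(mats):
        out = mats[0]
        for m in mats[1:]:
            out = np.kron(out, m)
        return out

    T0 = kron_chain(t_mean)
    U0 = Y @ T0
    ss0, sse0 = _type3_ss(U0, X, term_cols)
    add_rows(ss0, sse0, 1, df_error_between)

    # within strata: one per non-empty subset of within factors
    for k in range(1, len(factor_names) + 1):
        for subset in combinations(factor_names, k):
            mats = [
                contrasts[f] if f in subset else t_mean[i]
                for i, f in enumerate(factor_names)
            ]
            T = kron_chain(mats)
            U = Y @ T
            q = U.shape[1]
            if q == 0:  # a single-level factor contributes no contrasts
                continue
            ss, sse = _type3_ss(U, X, term_cols)
            add_rows(ss, sse, q, df_error_between,
                     within_label=":".join(subset))

    return AnovaResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# distribution screening


def _skew_z(x: np.ndarray) -> tuple[float, float]:
    """D'Agostino skewness z test.

    Unlike :func:`scipy.stats.skewtest`, exactly zero sample skewness maps
    to z = 0 (scipy substitutes y = 1 at the singular point).
    """
    n = len(x)
    b1 = float(stats.skew(x))
    y = b1 * np.sqrt((n + 1.0) * (n + 3.0) / (6.0 * (n - 2.0)))
    beta2 = (
        3.0 * (n**2 + 27.0 * n - 70.0) * (n + 1.0) * (n + 3.0)
        / ((n - 2.0) * (n + 5.0) * (n + 7.0) * (n + 9.0))
    )
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    z = delta * np.arcsinh(y / alpha)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def skew_kurtosis_screen(values, alpha: float = 0.01) -> dict:
    """z tests of sample skewness and excess kurtosis.

    Classified non-normal iff either two-sided p falls below ``alpha``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 8:
        raise StatsError("need at least 8 observations")
    if np.ptp(x) == 0:
        raise StatsError("constant input")
    z_skew, p_skew = _skew_z(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z_kurt, p_kurt = stats.kurtosistest(x)
    non_normal = (p_skew < alpha) or (p_kurt < alpha)
    return {
        "classification": "non-normal" if non_normal else "normal",
        "z_skew": float(z_skew),
        "p_skew": float(p_skew),
        "z_kurtosis": float(z_kurt),
        "p_kurtosis": float(p_kurt),
    }


# ---------------------------------------------------------------------------
# nonparametric / categorical tests


def moods_median_test(group_a, group_b) -> dict:
    """Mood's median test: chi-square on counts above/at-or-below the grand
    median."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs at least 2 observations")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise StatsError("all values identical; median test undefined")
    stat, p, med, tbl = stats.median_test(
        a, b, ties="below", correction=False
    )
    return {
        "chi2": float(stat),
        "p": float(p),
        "grand_median": float(med),
        "table": tbl,
    }


def chi_square_2x2(table, correction: bool = False) -> dict:
    """Pearson chi-square on a 2x2 contingency table (df = 1)."""
    tbl = np.asarray(table, dtype=float)
    if tbl.shape != (2, 2) or np.any(tbl < 0) or np.any(tbl != np.round(tbl)):
        raise StatsError("table must be 2x2 non-negative integer counts")
    if np.any(tbl.sum(axis=0) == 0) or np.any(tbl.sum(axis=1) == 0):
        raise StatsError("zero marginal in contingency table")
    (a, b), (c, d) = tbl
    n = tbl.sum()
    num = abs(a * d - b * c)
    if correction:
        num = max(num - n / 2.0, 0.0)
    chi2 = n * num**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return {"chi2": float(chi2), "df": 1, "p": float(stats.chi2.sf(chi2, 1))}


def mann_whitney_u(group_a, group_b) -> dict:
    """Mann-Whitney U with tie-corrected normal approximation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise StatsError("empty group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic")
    return {"U": float(res.statistic), "p": float(res.pvalue)}


def pearson_r(x, y) -> dict:
    """Sample Pearson correlation with t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("zero-variance input")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": len(x)}


def paired_t_percent_diff(beta_a, beta_b) -> dict:
    """Per-subject percent difference of b vs a, with a paired t test.

    Pairs with ``a == 0`` are excluded (warning).  A zero-variance
    difference with non-zero mean is flagged degenerate (infinite t).
    """
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    if a.shape != b.shape:
        raise StatsError("paired arrays must have equal length")
    keep = a != 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} pair(s) with zero reference beta",
            stacklevel=2,
        )
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise StatsError("fewer than 2 usable pairs")
    percent = 100.0 * (b - a) / np.abs(a)
    diffs = b - a
    # a constant non-zero percent change has zero spread on the reported
    # scale: flag as degenerate (the effect is exact, not estimated)
    degenerate = bool(np.ptp(percent) == 0 and percent.mean() != 0)
    if degenerate or (np.ptp(diffs) == 0 and diffs.mean() != 0):
        t, p = np.inf * np.sign(diffs.mean()), 0.0
    elif np.ptp(diffs) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(b, a)
    return {
        "percent_mean": float(percent.mean()),
        "percent_se": float(percent.std(ddof=1) / np.sqrt(len(percent)))
        if len(percent) > 1
        else float("nan"),
        "t": float(t),
        "p": float(p),
        "n": len(a),
        "n_excluded": n_excluded,
        "degenerate": degenerate,
    }
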