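"""Statistical designs on a cohort of segment volumes.

The central model is a split-plot (repeated-measures) ANCOVA: segment
(1..10 along the posterior->anterior axis) is the within-subject factor;
biomarker status or memory bin plus gender are between-subject factors; age
and intracranial volume are covariates.  The group x segment interaction —
does the group difference vary along the axis? — is the question of
interest, tested on the k-1 orthonormal polynomial within-subject contrasts
with the sums of squares pooled over contrasts:

    F = (SS_term / (df_term (k-1))) / (SS_err / ((n - p)(k-1)))

which reproduces the classical univariate repeated-measures table (for 10
segments and n complete cases with p between-design columns, interaction
df = (9 df_term, 9 (n-p))).  Between-subject effects are tested on the
subject means.  Factors are effect-coded and covariates centered, so the
drop-term sums of squares are Type III, matching the defaults of the GLM
repeated-measures procedures in the major commercial packages.  The
unadjusted univariate F is primary; the Greenhouse-Geisser epsilon is
computed and reported alongside.

Also provided: per-segment z-scoring, anterior/posterior 50% aggregation,
partial correlation via covariate residualization, and pairwise post hocs
(Bonferroni or Fisher LSD) on covariate-adjusted means.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .biomarker_rules import (
    DEFAULT_ABETA_CUTOFF,
    DEFAULT_PTAU_CUTOFF,
    bin_memory_errors,
    classify_abeta,
    classify_ptau,
)

logger = logging.getLogger("subaxis")

DEFAULT_ALPHA = 0.050


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise unusable model designs."""


# ---------------------------------------------------------------------------
# z-scoring and anterior/posterior aggregation
# ---------------------------------------------------------------------------

def zscore_by_segment(
    cohort: pd.DataFrame,
    value_column: str = "volume_mm3",
    out_column: str = "volume_z",
) -> pd.DataFrame:
    """Standardize volumes within each (hemisphere, segment) cell.

    z = (v - mean) / SD over the non-missing values of the analysis sample.
    Requires >= 3 non-missing values and a positive SD per cell.
    """
    out = cohort.copy()
    grouped = out.groupby(["hemisphere", "segment"], sort=False)[value_column]
    n = grouped.transform("count")
    if (n < 3).any():
        raise ValueError("fewer than 3 non-missing values in some cell(s)")
    sd = grouped.transform("std")
    if (sd == 0).any():
        raise ValueError("zero SD in some (hemisphere, segment) cell(s)")
    out[out_column] = (out[value_column] - grouped.transform("mean")) / sd
    return out


def aggregate_halves(
    cohort: pd.DataFrame,
    value_column: str = "volume_mm3",
    n_segments: int = 10,
) -> pd.DataFrame:
    """Posterior-50% / anterior-50% sums per participant and hemisphere.

    Posterior 50% = sum of segments 1..n/2, anterior 50% = sum of segments
    n/2+1..n; the bilateral variants are the left+right *sums*.  A
    participant missing any segment in a hemisphere (post-QC) is dropped for
    that hemisphere (and hence from the bilateral sums); drops are logged.

    Returns a wide table with one row per participant, the per-participant
    covariate columns, and columns ``{left,right}_{posterior,anterior}50``
    and ``bilateral_{posterior,anterior}50``.
    """
    half = n_segments // 2
    wide = cohort.pivot_table(
        index=["participant_id", "hemisphere"],
        columns="segment",
        values=value_column,
        dropna=False,
    )
    complete = wide.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "aggregate_halves: dropped %d participant-hemispheres with "
            "missing segments", n_dropped,
        )
    wide = wide[complete]
    post = wide[[s for s in wide.columns if s <= half]].sum(axis=1)
    ant = wide[[s for s in wide.columns if s > half]].sum(axis=1)
    halves = pd.DataFrame({"posterior50": post, "anterior50": ant}).unstack(
        "hemisphere"
    )
    halves.columns = [f"{h}_{m}" for m, h in halves.columns]
    hemis = sorted(cohort["hemisphere"].unique())
    for m in ("posterior50", "anterior50"):
        if len(hemis) == 2:
            halves[f"bilateral_{m}"] = (
                halves[f"{hemis[0]}_{m}"] + halves[f"{hemis[1]}_{m}"]
            )
        else:
            halves[f"bilateral_{m}"] = halves[f"{hemis[0]}_{m}"]
    meta_cols = [
        c for c in cohort.columns
        if c not in ("hemisphere", "segment", value_column, "volume_mm3",
                     "volume_z", "excluded")
    ]
    meta = cohort[meta_cols].drop_duplicates("participant_id").set_index(
        "participant_id"
    )
    return meta.join(halves, how="inner").reset_index()


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _effect_code(values: pd.Series) -> tuple[np.ndarray, list, dict]:
    """Sum-to-zero (effect) coding: L levels -> L-1 columns.

    Level order is sorted; the last level is coded -1 on every column.
    Returns (matrix, levels, {level: coding row}).
    """
    levels = sorted(pd.unique(values))
    L = len(levels)
    if L < 2:
        raise DesignError(f"factor has a single level: {levels}")
    rows = {}
    for i, lev in enumerate(levels):
        row = np.zeros(L - 1)
        if i < L - 1:
            row[i] = 1.0
        else:
            row[:] = -1.0
        rows[lev] = row
    mat = np.vstack([rows[v] for v in values])
    return mat, levels, rows


def _build_design(
    data: pd.DataFrame, factors: list[str], covariates: list[str]
) -> tuple[np.ndarray, dict, dict]:
    """Intercept + effect-coded factors + centered covariates.

    Returns (X, term_slices, factor_info) where term_slices maps term name
    to a column slice and factor_info maps factor name to (levels, coding
    rows).
    """
    n = len(data)
    cols = [np.ones((n, 1))]
    term_slices: dict[str, slice] = {"intercept": slice(0, 1)}
    factor_info: dict[str, tuple[list, dict]] = {}
    start = 1
    for f in factors:
        mat, levels, rows = _effect_code(data[f])
        cols.append(mat)
        term_slices[f] = slice(start, start + mat.shape[1])
        factor_info[f] = (levels, rows)
        start += mat.shape[1]
    for c in covariates:
        v = np.asarray(data[c], dtype=float)
        cols.append((v - v.mean())[:, None])
        term_slices[c] = slice(start, start + 1)
        start += 1
    X = np.hstack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DesignError(
            f"rank-deficient design: rank {rank} < {X.shape[1]} columns "
            f"(terms: {list(term_slices)})"
        )
    return X, term_slices, factor_info


def orthonormal_poly_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal polynomial contrast matrix (columns ⊥ constant)."""
    t = np.arange(k, dtype=float)
    V = np.vander(t - t.mean(), k, increasing=True)
    Q, _ = np.linalg.qr(V)
    C = Q[:, 1:]
    # sign convention: leading (linear) coefficient positive
    for j in range(C.shape[1]):
        if C[-1, j] < 0:
            C[:, j] = -C[:, j]
    return C


def _resid_ss(X: np.ndarray, Y: np.ndarray) -> float:
    """Frobenius residual sum of squares of the least-squares fit Y ~ X."""
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return float(np.sum(resid * resid))


# ---------------------------------------------------------------------------
# split-plot repeated-measures ANCOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermResult:
    F: float
    df_num: int
    df_den: int
    p: float

    def to_dict(self) -> dict:
        return {"F": self.F, "df_num": self.df_num, "df_den": self.df_den,
                "p": self.p}


@dataclass
class RMGLMResult:
    """Split-plot ANCOVA fit: F tests plus adjusted means and design state."""

    between_terms: dict[str, TermResult]
    interaction_terms: dict[str, TermResult]
    epsilon_gg: float
    n_complete: int
    n_between_columns: int
    k_within: int
    within_levels: list
    adjusted_means: pd.DataFrame
    # design state retained for post hocs
    _X: np.ndarray = field(repr=False, default=None)
    _B: np.ndarray = field(repr=False, default=None)
    _xtx_inv: np.ndarray = field(repr=False, default=None)
    _mse_columns: np.ndarray = field(repr=False, default=None)
    _mse_mean: float = field(repr=False, default=0.0)
    _factor_info: dict = field(repr=False, default_factory=dict)
    _term_slices: dict = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_complete": self.n_complete,
            "k_within": self.k_within,
            "epsilon_gg": self.epsilon_gg,
            "between": {t: r.to_dict() for t, r in self.between_terms.items()},
            "interaction": {
                t: r.to_dict() for t, r in self.interaction_terms.items()
            },
        }


def rm_glm_arrays(
    Y: np.ndarray,
    X: np.ndarray,
    term_slices: dict[str, slice],
) -> tuple[dict[str, TermResult], dict[str, TermResult], float, np.ndarray,
           np.ndarray, np.ndarray, float]:
    """Core split-plot computation on a wide outcome matrix.

    Y is n x k (complete cases), X the n x p between design with intercept.
    Returns between tests, interaction tests, GG epsilon, and fit state
    (B, (X'X)^-1, per-column MSE, subject-mean MSE).
    """
    n, k = Y.shape
    p = X.shape[1]
    if n <= p:
        raise DesignError(f"need n > p columns: n={n}, p={p}")
    C = orthonormal_poly_contrasts(k)
    Z = Y @ C                      # within-subject contrast scores
    ybar = Y.mean(axis=1)          # subject means carry between effects

    xtx_inv = np.linalg.inv(X.T @ X)
    B = np.linalg.lstsq(X, Y, rcond=None)[0]
    resid_Y = Y - X @ B
    mse_columns = (resid_Y ** 2).sum(axis=0) / (n - p)

    ss_full_z = _resid_ss(X, Z)
    ss_full_m = _resid_ss(X, ybar[:, None])
    mse_mean = ss_full_m / (n - p)

    between: dict[str, TermResult] = {}
    interaction: dict[str, TermResult] = {}
    for term, sl in term_slices.items():
        if term == "intercept":
            continue
        keep = np.ones(p, dtype=bool)
        keep[sl] = False
        X_red = X[:, keep]
        df_t = sl.stop - sl.start
        # between-subjects test on the subject means
        ss_t_m = _resid_ss(X_red, ybar[:, None]) - ss_full_m
        F_m = (ss_t_m / df_t) / (ss_full_m / (n - p))
        between[term] = TermResult(
            F=float(F_m), df_num=df_t, df_den=n - p,
            p=float(stats.f.sf(F_m, df_t, n - p)),
        )
        # term x within interaction, pooled over the k-1 contrasts
        ss_t_z = _resid_ss(X_red, Z) - ss_full_z
        df_num = df_t * (k - 1)
        df_den = (n - p) * (k - 1)
        F_z = (ss_t_z / df_num) / (ss_full_z / df_den)
        interaction[term] = TermResult(
            F=float(F_z), df_num=df_num, df_den=df_den,
            p=float(stats.f.sf(F_z, df_num, df_den)),
        )
    # Greenhouse-Geisser epsilon from the residual covariance in contrast space
    E = Z - X @ np.linalg.lstsq(X, Z, rcond=None)[0]
    S = (E.T @ E) / (n - p)
    eps = float(np.trace(S) ** 2 / ((k - 1) * np.sum(S * S)))
    return between, interaction, eps, B, xtx_inv, mse_columns, mse_mean


def rm_glm(
    cohort: pd.DataFrame,
    between: list[str],
    covariates: list[str] = ("age", "icv"),
    within_column: str = "segment",
    value_column: str = "volume_mm3",
) -> RMGLMResult:
    """Split-plot repeated-measures ANCOVA on a long cohort table.

    ``between`` names factor columns (e.g. ``["abeta_status", "sex"]``),
    ``covariates`` numeric columns; the within factor (default ``segment``)
    is pivoted wide.  Only complete cases — participants with all within
    levels present and no missing between variables — enter the model
    (listwise deletion).

    Returns F, degrees of freedom and p for each between term's main effect
    (on subject means) and its term x within interaction, plus covariate-
    adjusted cell means per (factor level, within level) with standard
    errors.
    """
    covariates = list(covariates)
    wide = cohort.pivot_table(
        index="participant_id", columns=within_column, values=value_column,
        dropna=False,
    )
    within_levels = list(wide.columns)
    meta = (
        cohort[["participant_id", *between, *covariates]]
        .drop_duplicates("participant_id")
        .set_index("participant_id")
    )
    data = meta.join(wide, how="inner").dropna()
    if data.empty:
        raise DesignError("no complete cases")
    for f in between:
        if data[f].nunique() < 2:
            raise DesignError(f"between factor {f!r} has < 2 levels")
    Y = data[within_levels].to_numpy(dtype=float)
    X, term_slices, factor_info = _build_design(data, list(between), covariates)
    bet, inter, eps, B, xtx_inv, mse_cols, mse_mean = rm_glm_arrays(
        Y, X, term_slices
    )
    n, p = X.shape

    # covariate-adjusted cell means (estimated marginal means): other factors
    # balanced (effect coding -> 0), covariates at their mean (centered -> 0)
    rows = []
    for f, (levels, coding) in factor_info.items():
        for lev in levels:
            x_row = np.zeros(p)
            x_row[0] = 1.0
            x_row[term_slices[f]] = coding[lev]
            leverage = float(x_row @ xtx_inv @ x_row)
            means = x_row @ B
            for wl, m, mse in zip(within_levels, means, mse_cols):
                rows.append({
                    "factor": f, "level": lev, within_column: wl,
                    "adjusted_mean": float(m),
                    "se": float(np.sqrt(leverage * mse)),
                })
    adj = pd.DataFrame(rows)
    return RMGLMResult(
        between_terms=bet,
        interaction_terms=inter,
        epsilon_gg=eps,
        n_complete=n,
        n_between_columns=p,
        k_within=len(within_levels),
        within_levels=within_levels,
        adjusted_means=adj,
        _X=X, _B=B, _xtx_inv=xtx_inv, _mse_columns=mse_cols,
        _mse_mean=mse_mean, _factor_info=factor_info,
        _term_slices=term_slices,
    )


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    p: float
    df: int
    n: int

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "df": self.df, "n": self.n}


def partial_correlation(x, y, covariates=None) -> PartialCorrResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (plus intercept) by
    least squares; r is the Pearson correlation of the residuals and the
    p-value comes from t = r sqrt(df / (1 - r^2)) with df = n - 2 - q.
    With no covariates this reduces to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Q = np.empty((x.size, 0))
    else:
        Q = np.asarray(covariates, dtype=float)
        if Q.ndim == 1:
            Q = Q[:, None]
        if Q.shape[0] != x.size:
            raise ValueError("covariates must have one row per observation")
    mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Q), axis=1)
    x, y, Q = x[mask], y[mask], Q[mask]
    n = x.size
    q = Q.shape[1]
    if n <= q + 3:
        raise ValueError(f"need n > n_covariates + 3: n={n}, q={q}")
    Z = np.column_stack([np.ones(n), Q])
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    # residuals that are numerically zero relative to the variable's scale
    # (e.g. a variable that is an exact linear function of the covariates)
    # carry no information to correlate
    if sx <= 1e-10 * max(np.linalg.norm(x - x.mean()), 1e-300) or \
            sy <= 1e-10 * max(np.linalg.norm(y - y.mean()), 1e-300):
        raise ValueError("constant residuals: cannot correlate")
    r = float(np.dot(rx, ry) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - 2 - q
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrResult(r=r, p=p, df=df, n=n)


# ---------------------------------------------------------------------------
# post hoc pairwise comparisons
# ---------------------------------------------------------------------------

def posthoc_pairwise(
    rm_result: RMGLMResult,
    factor: str,
    method: str = "bonferroni",
    within_level=None,
) -> pd.DataFrame:
    """Pairwise comparisons of covariate-adjusted means for one factor.

    Contrasts use the pooled error from the fitted model: the subject-mean
    error by default, or the per-level error when ``within_level`` names one
    within-subject level.  ``bonferroni`` multiplies each raw p by the
    number of comparisons (capped at 1); ``fisher_lsd`` leaves p raw.
    Requires >= 3 factor levels (with 2, the main effect already is the
    pairwise test).
    """
    if method not in ("bonferroni", "fisher_lsd"):
        raise ValueError(f"unknown post hoc method: {method}")
    levels, coding = rm_result._factor_info[factor]
    if len(levels) < 3:
        raise ValueError(
            "post hoc tests need >= 3 factor levels; use the main effect"
        )
    sl = rm_result._term_slices[factor]
    n, p = rm_result._X.shape
    if within_level is None:
        col_B = rm_result._B.mean(axis=1)
        mse = rm_result._mse_mean
    else:
        j = rm_result.within_levels.index(within_level)
        col_B = rm_result._B[:, j]
        mse = float(rm_result._mse_columns[j])
    pairs = [
        (levels[i], levels[j])
        for i in range(len(levels)) for j in range(i + 1, len(levels))
    ]
    m = len(pairs)
    rows = []
    for a, b in pairs:
        c = np.zeros(p)
        c[sl] = coding[a] - coding[b]
        diff = float(c @ col_B)
        se = float(np.sqrt(c @ rm_result._xtx_inv @ c * mse))
        t = diff / se
        p_raw = float(2 * stats.t.sf(abs(t), n - p))
        p_adj = min(1.0, m * p_raw) if method == "bonferroni" else p_raw
        rows.append({
            "level_a": a, "level_b": b, "difference": diff, "se": se,
            "t": t, "df": n - p, "p_raw": p_raw, "p_adjusted": p_adj,
            "method": method,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _ensure_status_columns(
    cohort: pd.DataFrame,
    abeta_cutoff: float,
    ptau_cutoff: float,
) -> pd.DataFrame:
    out = cohort.copy()
    out["abeta_status"] = [
        classify_abeta(v, abeta_cutoff) for v in out["abeta42"]
    ]
    out["ptau_status"] = [classify_ptau(v, ptau_cutoff) for v in out["ptau"]]
    out["memory_bin"] = [bin_memory_errors(int(e)) for e in out["memory_errors"]]
    return out


def run_full_analysis(
    cohort: pd.DataFrame,
    out_dir: str | os.PathLike | None = None,
    abeta_cutoff: float = DEFAULT_ABETA_CUTOFF,
    ptau_cutoff: float = DEFAULT_PTAU_CUTOFF,
    alpha: float = DEFAULT_ALPHA,
    posthoc_method: str = "bonferroni",
    make_plots: bool = True,
) -> dict:
    """Run the full segment-wise analysis suite on a QC'd cohort table.

    Emits (a) segment-wise biomarker-status contrasts per hemisphere with
    z-scored adjusted means, (b) segment-wise partial correlations of volume
    with P-tau controlling age and ICV, (c) the memory-bin analysis on the
    bilateral anterior/posterior 50% sums, and (d) the 2-level
    location x biomarker-status interaction within the SCD group.  Results
    are returned as a JSON-serializable dict; when ``out_dir`` is given,
    JSON, CSV and (optionally) PNG figures are written there.

    Output is deterministic: the same input table yields byte-identical
    JSON.
    """
    cohort = _ensure_status_columns(cohort, abeta_cutoff, ptau_cutoff)
    z = zscore_by_segment(cohort.dropna(subset=["volume_mm3"]))
    report: dict = {
        "config": {
            "abeta_cutoff": abeta_cutoff, "ptau_cutoff": ptau_cutoff,
            "alpha": alpha, "posthoc_method": posthoc_method,
        },
    }

    # (a) segment-wise group contrasts per hemisphere, z-scored outcomes
    contrasts = {}
    adjusted_tables = []
    for status in ("abeta_status", "ptau_status"):
        contrasts[status] = {}
        for hemi in sorted(z["hemisphere"].unique()):
            sub = z[z["hemisphere"] == hemi]
            res = rm_glm(
                sub, between=[status, "sex"], covariates=["age", "icv"],
                within_column="segment", value_column="volume_z",
            )
            contrasts[status][hemi] = res.to_dict()
            tab = res.adjusted_means.query("factor == @status").copy()
            tab.insert(0, "hemisphere", hemi)
            tab.insert(0, "status", status)
            adjusted_tables.append(tab)
    report["segment_contrasts"] = contrasts
    adjusted_means = pd.concat(adjusted_tables, ignore_index=True)

    # (b) segment-wise partial correlations with P-tau (age, ICV controlled)
    pcorr_rows = []
    for hemi in sorted(z["hemisphere"].unique()):
        for seg in sorted(z["segment"].unique()):
            cell = z[(z["hemisphere"] == hemi) & (z["segment"] == seg)]
            cell = cell.dropna(subset=["volume_mm3", "ptau", "age", "icv"])
            res = partial_correlation(
                cell["ptau"], cell["volume_mm3"],
                covariates=cell[["age", "icv"]].to_numpy(),
            )
            pcorr_rows.append({
                "hemisphere": hemi, "segment": int(seg),
                "r": res.r, "p": res.p, "df": res.df,
            })
    report["ptau_segment_correlations"] = pcorr_rows

    # (c) memory-bin analysis on bilateral anterior/posterior 50% sums
    halves = aggregate_halves(cohort)
    halves = halves.dropna(
        subset=["bilateral_posterior50", "bilateral_anterior50"]
    )
    long_halves = halves.melt(
        id_vars=[c for c in halves.columns if not c.endswith("50")],
        value_vars=["bilateral_posterior50", "bilateral_anterior50"],
        var_name="location", value_name="half_volume_mm3",
    )
    long_halves["location"] = long_halves["location"].str.replace(
        "bilateral_", "", regex=False
    ).str.replace("50", "", regex=False)
    mem_res = rm_glm(
        long_halves, between=["memory_bin", "sex"], covariates=["age", "icv"],
        within_column="location", value_column="half_volume_mm3",
    )
    memory = {"model": mem_res.to_dict(), "posthoc": {}}
    for loc in mem_res.within_levels:
        ph = posthoc_pairwise(
            mem_res, "memory_bin", method=posthoc_method, within_level=loc
        )
        memory["posthoc"][loc] = ph.to_dict(orient="records")
    report["memory_bins"] = memory

    # (d) 2-level location x status interaction within SCD
    scd = long_halves[long_halves["group"] == "SCD"] if "group" in \
        long_halves.columns else long_halves.iloc[0:0]
    report["scd_interaction"] = {}
    for status in ("abeta_status", "ptau_status"):
        if len(scd) and scd[status].nunique() == 2:
            res = rm_glm(
                scd, between=[status, "sex"], covariates=["age", "icv"],
                within_column="location", value_column="half_volume_mm3",
            )
            report["scd_interaction"][status] = res.to_dict()

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        adjusted_means.to_csv(
            os.path.join(out_dir, "adjusted_means.csv"), index=False
        )
        pd.DataFrame(pcorr_rows).to_csv(
            os.path.join(out_dir, "ptau_segment_correlations.csv"), index=False
        )
        if make_plots:
            _write_plots(adjusted_means, pd.DataFrame(pcorr_rows), out_dir)
    return report


def _write_plots(
    adjusted_means: pd.DataFrame, pcorr: pd.DataFrame, out_dir
) -> None:
    """Figure analogs: adjusted z-score vs segment per group; r vs segment."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for status, tab in adjusted_means.groupby("status"):
        hemis = sorted(tab["hemisphere"].unique())
        fig, axes = plt.subplots(
            1, len(hemis), figsize=(5 * len(hemis), 4), squeeze=False
        )
        for ax, hemi in zip(axes[0], hemis):
            sub = tab[tab["hemisphere"] == hemi]
            for lev, grp in sub.groupby("level"):
                grp = grp.sort_values("segment")
                ax.errorbar(
                    grp["segment"], grp["adjusted_mean"],
                    yerr=1.96 * grp["se"], label=str(lev), capsize=2,
                )
            ax.set_xlabel("segment (posterior -> anterior)")
            ax.set_ylabel("adjusted volume (z)")
            ax.set_title(f"{status}, {hemi}")
            ax.legend()
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"segments_{status}.png"), dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for hemi, grp in pcorr.groupby("hemisphere"):
        grp = grp.sort_values("segment")
        ax.plot(grp["segment"], grp["r"], "o-", label=hemi)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("segment (posterior -> anterior)")
    ax.set_ylabel("partial r with P-tau")
    ax.legend()
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "ptau_correlations.png"), dpi=120)
    plt.close(fig)
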