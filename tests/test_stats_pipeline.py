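"""Split-plot ANCOVA, partial correlation, aggregation and post hocs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from subaxis import (
    aggregate_halves,
    partial_correlation,
    posthoc_pairwise,
    rm_glm,
    run_full_analysis,
    zscore_by_segment,
)
from subaxis.stats_pipeline import DesignError, rm_glm_arrays, _build_design


def _long_table(Y, group=None, sex=None, age=None, icv=None,
                hemisphere="left"):
    """Wide outcome matrix -> long cohort-style table."""
    n, k = Y.shape
    rows = []
    for i in range(n):
        for s in range(k):
            rows.append({
                "participant_id": f"p{i:03d}",
                "group": None if group is None else group[i],
                "sex": "F" if sex is None else sex[i],
                "age": 70.0 if age is None else age[i],
                "icv": 1.4e6 if icv is None else icv[i],
                "hemisphere": hemisphere,
                "segment": s + 1,
                "volume_mm3": Y[i, s],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

def test_zscore_matches_direct_formula():
    rng = np.random.default_rng(0)
    Y = rng.normal(100, 12, (40, 3))
    table = _long_table(Y)
    z = zscore_by_segment(table)
    for s in range(3):
        col = Y[:, s]
        expected = (col - col.mean()) / col.std(ddof=1)
        got = z[z.segment == s + 1].sort_values("participant_id")["volume_z"]
        np.testing.assert_allclose(got, expected, atol=1e-12)


def test_zscore_rejects_tiny_or_constant_cells():
    Y = np.array([[1.0, 2.0], [3.0, 4.0]])
    with pytest.raises(ValueError):
        zscore_by_segment(_long_table(Y))
    const = np.ones((5, 2))
    with pytest.raises(ValueError, match="zero SD"):
        zscore_by_segment(_long_table(const))


# ---------------------------------------------------------------------------
# anterior/posterior aggregation
# ---------------------------------------------------------------------------

def test_halves_sum_and_conservation():
    Y = np.full((4, 10), 10.0)
    left = _long_table(Y, hemisphere="left")
    right = _long_table(Y * 2, hemisphere="right")
    table = pd.concat([left, right], ignore_index=True)
    halves = aggregate_halves(table)
    assert (halves["left_posterior50"] == 50.0).all()
    assert (halves["left_anterior50"] == 50.0).all()
    assert (halves["bilateral_posterior50"] == 150.0).all()
    total = halves["left_posterior50"] + halves["left_anterior50"]
    np.testing.assert_allclose(total, Y.sum(axis=1))


def test_posterior_atrophy_shows_in_half_ratio():
    Y = np.full((6, 10), 10.0)
    Y[:, :5] *= 0.8  # 20% posterior shrinkage
    halves = aggregate_halves(_long_table(Y))
    ratio = halves["left_posterior50"] / halves["left_anterior50"]
    np.testing.assert_allclose(ratio, 0.8)


def test_participant_with_missing_segment_dropped():
    Y = np.full((5, 10), 10.0)
    table = _long_table(Y)
    table.loc[
        (table.participant_id == "p000") & (table.segment == 4), "volume_mm3"
    ] = np.nan
    halves = aggregate_halves(table)
    assert "p000" not in halves["participant_id"].values
    assert len(halves) == 4


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

def test_partial_corr_without_covariates_is_pearson():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=(2, 60))
    res = partial_correlation(x, y)
    r_ref, p_ref = stats.pearsonr(x, y)
    assert res.r == pytest.approx(r_ref, abs=1e-12)
    assert res.p == pytest.approx(p_ref, rel=1e-9)
    assert res.df == 58


def test_partial_corr_removes_exact_linear_dependence():
    rng = np.random.default_rng(2)
    Q = rng.normal(size=(80, 2))
    x = rng.normal(size=80)
    y = 3.0 + Q @ [1.5, -2.0]  # y is exactly linear in the covariates
    with pytest.raises(ValueError, match="constant residuals"):
        partial_correlation(x, y, covariates=Q)


def _precision_matrix_partial_r(x, y, Q):
    """Independent oracle: partial correlation from the inverse of the full
    correlation matrix."""
    M = np.column_stack([x, y, Q])
    omega = np.linalg.inv(np.corrcoef(M, rowvar=False))
    return -omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])


@pytest.mark.parametrize("seed", range(10))
def test_partial_corr_matches_precision_matrix_oracle(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(20, 200)
    Q = rng.normal(size=(n, 2))
    x = rng.normal(size=n) + Q @ [0.5, -0.2]
    y = rng.normal(size=n) + Q @ [-0.3, 0.4] + 0.3 * x
    res = partial_correlation(x, y, covariates=Q)
    assert res.r == pytest.approx(_precision_matrix_partial_r(x, y, Q),
                                  abs=1e-10)


def test_partial_corr_matches_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(9)
    df = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("xyab"))
    res = partial_correlation(df.x, df.y, covariates=df[["a", "b"]].to_numpy())
    ref = pg.partial_corr(df, x="x", y="y", covar=["a", "b"])
    assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
    assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)


# ---------------------------------------------------------------------------
# split-plot repeated-measures ANCOVA
# ---------------------------------------------------------------------------

def test_k2_interaction_reduces_to_squared_t_on_difference_scores():
    """Two groups, k=2, no covariates: the group x within interaction F must
    equal the squared two-sample t on the within-subject differences."""
    rng = np.random.default_rng(3)
    n = 40
    group = np.repeat(["a", "b"], n // 2)
    Y = rng.normal(size=(n, 2))
    Y[group == "b", 1] += 0.8
    data = pd.DataFrame({"g": group})
    X, slices, _ = _build_design(data, ["g"], [])
    _, inter, _, *_ = rm_glm_arrays(Y, X, slices)
    d = Y[:, 1] - Y[:, 0]
    t, _ = stats.ttest_ind(d[group == "a"], d[group == "b"])
    assert inter["g"].F == pytest.approx(t ** 2, rel=1e-10)
    assert inter["g"].df_num == 1
    assert inter["g"].df_den == n - 2


def test_interaction_matches_pingouin_mixed_anova():
    """One between factor, no covariates: interaction F and df match an
    independent mixed-ANOVA implementation."""
    import pingouin as pg

    rng = np.random.default_rng(4)
    n, k = 30, 5
    group = np.repeat(["ctl", "pat"], n // 2)
    Y = rng.normal(size=(n, k)) + np.linspace(0, 0.5, k)
    Y[group == "pat"] += np.linspace(0.6, 0, k)
    data = pd.DataFrame({"g": group})
    X, slices, _ = _build_design(data, ["g"], [])
    _, inter, _, *_ = rm_glm_arrays(Y, X, slices)
    long = _long_table(Y)
    long["g"] = np.repeat(group, k)
    ref = pg.mixed_anova(
        long, dv="volume_mm3", within="segment", subject="participant_id",
        between="g",
    )
    row = ref[ref.Source == "Interaction"].iloc[0]
    assert inter["g"].F == pytest.approx(float(row.F), rel=1e-6)
    assert inter["g"].df_num == int(row.DF1)
    assert inter["g"].df_den == int(row.DF2)


def test_df_structure_matches_reported_shape():
    """For 10 segments, the interaction df must be (9 df_term, 9 (n - p))."""
    rng = np.random.default_rng(5)
    n = 120
    Y = rng.normal(size=(n, 10))
    table = _long_table(Y)
    table["status"] = np.repeat(
        np.where(rng.random(n) < 0.4, "positive", "negative"), 10
    )
    table["sex"] = np.repeat(
        np.where(rng.random(n) < 0.5, "F", "M"), 10
    )
    table["age"] = np.repeat(rng.normal(72, 5, n), 10)
    table["icv"] = np.repeat(rng.normal(1.45e6, 1.5e5, n), 10)
    res = rm_glm(table, between=["status", "sex"], covariates=["age", "icv"])
    p = 1 + 1 + 1 + 2  # intercept + 2 effect-coded factors + 2 covariates
    term = res.interaction_terms["status"]
    assert term.df_num == 9
    assert term.df_den == 9 * (n - p)
    assert res.between_terms["status"].df_den == n - p
    assert 0 < res.epsilon_gg <= 1.0


def test_statistics_invariant_to_row_order():
    rng = np.random.default_rng(6)
    n = 60
    Y = rng.normal(size=(n, 10))
    table = _long_table(Y)
    table["status"] = np.repeat(
        np.where(rng.random(n) < 0.5, "pos", "neg"), 10
    )
    shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
    r1 = rm_glm(table, between=["status"], covariates=[])
    r2 = rm_glm(shuffled, between=["status"], covariates=[])
    assert r1.interaction_terms["status"].F == pytest.approx(
        r2.interaction_terms["status"].F, rel=1e-10
    )


def test_rank_deficient_design_is_named():
    rng = np.random.default_rng(7)
    n = 20
    table = _long_table(rng.normal(size=(n, 4)))
    table["status"] = "same"  # single level
    with pytest.raises(DesignError):
        rm_glm(table, between=["status"], covariates=[])
    # aliased covariate: age duplicated
    table["status"] = np.repeat(np.where(rng.random(n) < 0.5, "a", "b"), 4)
    table["age2"] = table["age"]
    with pytest.raises(DesignError, match="rank-deficient"):
        rm_glm(table, between=["status"], covariates=["age", "age2"])


# ---------------------------------------------------------------------------
# post hocs
# ---------------------------------------------------------------------------

def _memory_bin_fit(effect=0.0, n_per_bin=40, seed=0):
    rng = np.random.default_rng(seed)
    bins = np.repeat(["0-1", "2-3", "4-5", "6-10"], n_per_bin)
    n = bins.size
    Y = rng.normal(500, 40, size=(n, 2))
    shift = {"0-1": 0.0, "2-3": 1.0, "4-5": 2.0, "6-10": 3.0}
    Y[:, 0] -= effect * np.vectorize(shift.get)(bins)
    table = _long_table(Y)
    table["memory_bin"] = np.repeat(bins, 2)
    return rm_glm(table, between=["memory_bin"], covariates=[],
                  value_column="volume_mm3")


def test_bonferroni_adjusts_six_comparisons():
    res = _memory_bin_fit(effect=10.0)
    ph = posthoc_pairwise(res, "memory_bin", method="bonferroni",
                         within_level=1)
    assert len(ph) == 6
    np.testing.assert_allclose(
        ph["p_adjusted"], np.minimum(1.0, 6 * ph["p_raw"])
    )
    lsd = posthoc_pairwise(res, "memory_bin", method="fisher_lsd",
                          within_level=1)
    np.testing.assert_allclose(lsd["p_adjusted"], lsd["p_raw"])


def test_null_posthocs_mostly_nonsignificant():
    sig = 0
    total = 0
    for seed in range(20):
        res = _memory_bin_fit(effect=0.0, seed=seed)
        ph = posthoc_pairwise(res, "memory_bin", method="bonferroni")
        sig += int((ph["p_adjusted"] < 0.05).any())
        total += 1
    assert sig / total <= 0.25  # family-wise alpha ~5% under the null


def test_extreme_bins_separate_before_adjacent_bins():
    """Under a monotone effect the 0-1 vs 6-10 contrast should be the
    strongest, significant before 0-1 vs 2-3."""
    wins = 0
    for seed in range(20):
        res = _memory_bin_fit(effect=12.0, seed=seed)
        ph = posthoc_pairwise(res, "memory_bin", method="fisher_lsd",
                             within_level=1).set_index(["level_a", "level_b"])
        p_far = ph.loc[("0-1", "6-10"), "p_adjusted"]
        p_near = ph.loc[("0-1", "2-3"), "p_adjusted"]
        wins += int(p_far < p_near)
    assert wins >= 18


def test_posthoc_requires_three_levels():
    rng = np.random.default_rng(8)
    n = 30
    table = _long_table(rng.normal(size=(n, 4)))
    table["status"] = np.repeat(np.where(rng.random(n) < 0.5, "a", "b"), 4)
    res = rm_glm(table, between=["status"], covariates=[])
    with pytest.raises(ValueError, match="3 factor levels"):
        posthoc_pairwise(res, "status")


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def test_full_analysis_report_structure_and_determinism(study_cohort, tmp_path):
    rep1 = run_full_analysis(study_cohort, make_plots=False)
    rep2 = run_full_analysis(study_cohort, make_plots=False)
    import json

    assert json.dumps(rep1, sort_keys=True) == json.dumps(rep2, sort_keys=True)
    assert set(rep1) == {
        "config", "segment_contrasts", "ptau_segment_correlations",
        "memory_bins", "scd_interaction",
    }
    for status in ("abeta_status", "ptau_status"):
        for hemi in ("left", "right"):
            term = rep1["segment_contrasts"][status][hemi]["interaction"]
            assert term[status]["df_num"] == 9


def test_correlation_profile_attenuates_toward_anterior(study_cohort):
    """Posterior-weighted generator effects: |r| with P-tau should decline
    from posterior to anterior segments (Spearman trend test)."""
    rep = run_full_analysis(study_cohort, make_plots=False)
    rows = [r for r in rep["ptau_segment_correlations"]
            if r["hemisphere"] == "left"]
    segs = [r["segment"] for r in rows]
    abs_r = [abs(r["r"]) for r in rows]
    rho, p = stats.spearmanr(segs, abs_r)
    assert rho < 0
    assert p < 0.05
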