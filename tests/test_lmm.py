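"""Mixed-model core: fitting, AICc, dredge, LRT, Wald tests, contrasts."""

import subprocess
import textwrap
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from thermosocial import (LMMSpec, TemperatureLMM, aicc, calibrate_confounds,
                          dredge_select, lrt, pairwise_contrasts, term_chisq)
from conftest import make_lmm_frame


@pytest.fixture(scope="module")
def simple_fit():
    rng = np.random.default_rng(0)
    df = make_lmm_frame(rng, n=300, beta_x=0.3, subject_sd=0.15)
    spec = LMMSpec(fixed_terms=("x",), random_factors=("subject_id",),
                   control="ambient_centered")
    return TemperatureLMM(df, spec).fit("ML")


def test_degenerate_random_effect_matches_ols():
    """With no between-group variance the mixed fit collapses to OLS."""
    rng = np.random.default_rng(1)
    df = make_lmm_frame(rng, n=400, beta_x=0.5, subject_sd=0.0)
    spec = LMMSpec(fixed_terms=("x",), random_factors=("subject_id",),
                   control=None)
    fit = TemperatureLMM(df, spec).fit("ML")
    ols = smf.ols("log_temp ~ x", df).fit()
    assert fit.fe_params["x"] == pytest.approx(ols.params["x"], abs=1e-6)
    assert fit.fe_params["Intercept"] == pytest.approx(ols.params["Intercept"],
                                                       abs=1e-6)
    assert fit.vcomp["subject_id"] < 1e-3  # effectively no group variance


def test_balanced_one_factor_matches_anova_estimator():
    """REML variance components equal the closed-form ANOVA (method-of-
    moments) estimator on a balanced one-factor design."""
    rng = np.random.default_rng(2)
    g, m = 8, 25
    intercepts = rng.normal(0, 0.4, g)
    rows = []
    for i in range(g):
        for _ in range(m):
            rows.append(dict(log_temp=2.0 + intercepts[i] + rng.normal(0, 0.3),
                             subject_id=f"S{i}"))
    df = pd.DataFrame(rows)
    fit = TemperatureLMM(df, LMMSpec(fixed_terms=(), control=None,
                                     random_factors=("subject_id",))).fit("REML")
    means = df.groupby("subject_id")["log_temp"].mean()
    grand = df["log_temp"].mean()
    msb = m * ((means - grand) ** 2).sum() / (g - 1)
    msw = ((df["log_temp"] - df["subject_id"].map(means)) ** 2).sum() / (g * (m - 1))
    sigma2_b = (msb - msw) / m
    assert fit.scale == pytest.approx(msw, rel=1e-4)
    assert fit.vcomp["subject_id"] == pytest.approx(sigma2_b, rel=1e-3)


def test_aicc_formula_substitution():
    fake = SimpleNamespace(method="ML", llf=-7.0, k_params=3, nobs=10)
    assert aicc(fake) == pytest.approx(14 + 6 + 24 / 6)


def test_aicc_approaches_aic_for_large_n(simple_fit):
    k, n, ll = simple_fit.k_params, simple_fit.nobs, simple_fit.llf
    aic = -2 * ll + 2 * k
    assert simple_fit.aicc - aic == pytest.approx(2 * k * (k + 1) / (n - k - 1))
    fake = SimpleNamespace(method="ML", llf=ll, k_params=k, nobs=10 ** 9)
    assert aicc(fake) == pytest.approx(aic, abs=1e-3)


def test_aicc_infinite_when_undersized():
    fake = SimpleNamespace(method="ML", llf=-7.0, k_params=10, nobs=11)
    assert aicc(fake) == np.inf


def test_dredge_enumerates_all_subsets():
    rng = np.random.default_rng(3)
    df = make_lmm_frame(rng, n=150)
    df["a"] = rng.normal(size=len(df))
    df["b"] = rng.normal(size=len(df))
    df["c"] = rng.normal(size=len(df))
    base = LMMSpec(random_factors=("subject_id",))
    table, _ = dredge_select(df, base, ("a", "b", "c"))
    assert len(table) == 8  # 2^3 subsets, no interactions


def test_dredge_marginality_and_empty_search():
    rng = np.random.default_rng(4)
    df = make_lmm_frame(rng, n=150)
    df["a"] = rng.normal(size=len(df))
    df["b"] = rng.normal(size=len(df))
    base = LMMSpec(random_factors=("subject_id",))
    table, _ = dredge_select(df, base, ("a", "b", "a:b"))
    # a:b only with both mains: {}, {a}, {b}, {a,b}, {a,b,a:b}
    assert len(table) == 5
    table0, best0 = dredge_select(df, base, ())
    assert len(table0) == 1
    assert best0.fixed_terms == ()


def test_dredge_ranking_invariant_under_candidate_order():
    rng = np.random.default_rng(5)
    df = make_lmm_frame(rng, n=200, beta_x=0.4)
    df["noise1"] = rng.normal(size=len(df))
    df["noise2"] = rng.normal(size=len(df))
    base = LMMSpec(random_factors=("subject_id",))
    _, best1 = dredge_select(df, base, ("x", "noise1", "noise2"))
    _, best2 = dredge_select(df, base, ("noise2", "x", "noise1"))
    assert set(best1.fixed_terms) == set(best2.fixed_terms)
    assert "x" in best1.fixed_terms


def test_lrt_identical_models_gives_zero(simple_fit):
    stat, df, p = lrt(simple_fit, simple_fit)
    assert stat == 0.0
    assert df == 0
    assert p == 1.0


def test_lrt_rejects_non_nested_fits():
    rng = np.random.default_rng(6)
    frame = make_lmm_frame(rng, n=150)
    frame["a"] = rng.normal(size=len(frame))
    frame["b"] = rng.normal(size=len(frame))
    base = LMMSpec(random_factors=("subject_id",))
    fa = TemperatureLMM(frame, base.with_terms(("a",))).fit("ML")
    fb = TemperatureLMM(frame, base.with_terms(("b",))).fit("ML")
    with pytest.raises(ValueError, match="nested"):
        lrt(fa, fb)


def test_lrt_requires_ml():
    rng = np.random.default_rng(7)
    frame = make_lmm_frame(rng, n=120)
    base = LMMSpec(random_factors=("subject_id",))
    full = TemperatureLMM(frame, base.with_terms(("x",))).fit("REML")
    null = TemperatureLMM(frame, base).fit("REML")
    with pytest.raises(ValueError, match="ML"):
        lrt(full, null)


def test_wald_chisq_equals_squared_z_for_single_coefficient(simple_fit):
    tab = term_chisq(simple_fit).set_index("term")
    est = simple_fit.fe_params["x"]
    se = simple_fit.bse_fe["x"]
    assert tab.loc["x", "chisq"] == pytest.approx((est / se) ** 2, abs=1e-8)
    assert tab.loc["x", "df"] == 1


def test_wald_skips_control_term(simple_fit):
    tab = term_chisq(simple_fit)
    assert set(tab["term"]) == {"x"}


def test_two_level_contrast_equals_coefficient_difference():
    rng = np.random.default_rng(8)
    df = make_lmm_frame(rng, n=240)
    df["grp"] = rng.choice(["lo", "hi"], len(df))
    df["log_temp"] += np.where(df["grp"] == "hi", 0.25, 0.0)
    spec = LMMSpec(fixed_terms=("grp",), random_factors=("subject_id",))
    fit = TemperatureLMM(df, spec).fit("REML")
    tab = pairwise_contrasts(fit, "grp", adjust="tukey")
    assert len(tab) == 1
    coef = fit.fe_params["grp[T.lo]"]
    assert abs(tab["estimate"].iloc[0]) == pytest.approx(abs(coef), abs=1e-10)
    # with a single comparison the Tukey adjustment is a no-op
    assert tab["p_adjusted"].iloc[0] == pytest.approx(
        tab["p_unadjusted"].iloc[0], abs=1e-6)


def test_contrasts_antisymmetric_and_bounded():
    rng = np.random.default_rng(9)
    df = make_lmm_frame(rng, n=300)
    df["grp"] = rng.choice(["a", "b", "c"], len(df))
    df["log_temp"] += df["grp"].map({"a": 0.0, "b": 0.2, "c": -0.1})
    spec = LMMSpec(fixed_terms=("grp",), random_factors=("subject_id",))
    fit = TemperatureLMM(df, spec).fit("REML")
    tab = pairwise_contrasts(fit, "grp")
    assert len(tab) == 3
    assert ((tab["p_adjusted"] >= 0) & (tab["p_adjusted"] <= 1)).all()
    emm_diff = dict(zip(zip(tab["level_1"], tab["level_2"]), tab["estimate"]))
    # contrasts are differences of a single set of marginal means, so
    # they must be additive/antisymmetric
    assert emm_diff[("a", "c")] == pytest.approx(
        emm_diff[("a", "b")] + emm_diff[("b", "c")], abs=1e-9)


def test_single_level_factor_contrast_errors(simple_fit):
    with pytest.raises(ValueError):
        pairwise_contrasts(simple_fit, "x")  # numeric, not a factor


def test_calibrate_confounds_flags_and_centers():
    rng = np.random.default_rng(10)
    n = 392
    subj = rng.integers(0, 9, n)
    ambient = rng.uniform(20, 30, n)
    movement = rng.choice(["no_movement", "steps", "travel"], n)
    humidity = rng.uniform(40, 95, n)
    y = (3.5 + 0.01 * (ambient - 25)
         + np.where(movement == "travel", -0.02, 0.0)
         + rng.normal(0, 0.02, 9)[subj] + rng.normal(0, 0.03, n))
    base = pd.DataFrame(dict(log_temp=y, subject_id=subj.astype(str),
                             ambient_c=ambient, movement=movement,
                             humidity_pct=humidity, distance_m=10.0))
    rep = calibrate_confounds(base)
    flagged = set(rep.controlled)
    assert "ambient_c" in flagged
    assert "movement" in flagged
    # constant confound skipped entirely
    assert "distance_m" not in set(rep.tests["confound"])
    centered = rep.center_ambient(base)
    assert abs(centered["ambient_centered"].mean()) < 1e-12


def test_rank_deficient_design_raises():
    rng = np.random.default_rng(11)
    df = make_lmm_frame(rng, n=100)
    df["x2"] = 2.0 * df["x"]
    spec = LMMSpec(fixed_terms=("x", "x2"), random_factors=("subject_id",))
    with pytest.raises(ValueError, match="collinear"):
        TemperatureLMM(df, spec).fit("ML")


def test_crossed_random_intercepts_against_lme4(tmp_path):
    """Independent oracle: lme4 fits the same crossed-intercepts model."""
    rng = np.random.default_rng(12)
    n = 240
    subj = rng.integers(0, 6, n)
    mov = rng.integers(0, 3, n)
    x = rng.normal(size=n)
    y = (2.0 + 0.3 * x + rng.normal(0, 0.25, 6)[subj]
         + rng.normal(0, 0.15, 3)[mov] + rng.normal(0, 0.2, n))
    df = pd.DataFrame(dict(log_temp=y, x=x,
                           subject_id=[f"S{i}" for i in subj],
                           movement=[f"m{i}" for i in mov]))
    spec = LMMSpec(fixed_terms=("x",), random_factors=("subject_id", "movement"),
                   control=None)
    fit = TemperatureLMM(df, spec).fit("ML")

    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rscript = textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(log_temp ~ x + (1|subject_id) + (1|movement), data=d,
                  REML=FALSE)
        cat(fixef(m)["x"], logLik(m), sep="\\n")
    """)
    out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                         text=True, timeout=120)
    assert out.returncode == 0, out.stderr
    r_beta, r_llf = (float(v) for v in out.stdout.split())
    assert fit.fe_params["x"] == pytest.approx(r_beta, abs=1e-4)
    assert fit.llf == pytest.approx(r_llf, abs=1e-3)
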