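"""Gaussian linear mixed models and the model-comparison machinery.

The analysis models log nose temperature with crossed random intercepts
for subject identity and prior movement, a centered ambient-temperature
control covariate, and candidate audience fixed effects.  This module
wraps statsmodels' ``MixedLM`` in a small Model/Results pair and adds
what the selection workflow needs: small-sample AIC (AICc), all-subsets
(dredge-style) selection respecting marginality, likelihood-ratio tests
against null models, per-term Wald chi-square tests, and estimated
marginal means with Tukey-adjusted pairwise contrasts.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

_SINGULAR_TOL = 1e-8


@dataclass(frozen=True)
class LMMSpec:
    """Specification of one mixed model.

    ``control`` (the centered ambient temperature by default) is part of
    every model including nulls; ``fixed_terms`` are the terms model
    selection operates on.  Interactions are written ``"a:b"``.
    """

    response: str = "log_temp"
    fixed_terms: tuple[str, ...] = ()
    random_factors: tuple[str, ...] = ("subject_id", "movement")
    control: str | None = "ambient_centered"

    def formula(self) -> str:
        rhs = []
        if self.control:
            rhs.append(self.control)
        rhs.extend(self.fixed_terms)
        return f"{self.response} ~ {' + '.join(rhs) if rhs else '1'}"

    def with_terms(self, terms) -> "LMMSpec":
        return replace(self, fixed_terms=tuple(terms))

    @property
    def null(self) -> "LMMSpec":
        """Corresponding null model: random factors + control only."""
        return self.with_terms(())


class TemperatureLMM:
    """Gaussian linear mixed model for (log) nose temperature.

    Random intercepts for each factor in ``spec.random_factors``.  With
    a single factor the model is an ordinary grouped random-intercept
    LMM; with several, the factors are crossed via variance components
    over one all-encompassing group.
    """

    def __init__(self, data: pd.DataFrame, spec: LMMSpec):
        needed = {spec.response, *spec.random_factors}
        if spec.control:
            needed.add(spec.control)
        for term in spec.fixed_terms:
            needed.update(v for v in term.split(":"))
        missing = needed - set(data.columns)
        if missing:
            raise ValueError(f"data lacks columns: {sorted(missing)}")
        data = data.dropna(subset=sorted(needed)).reset_index(drop=True)
        for f in spec.random_factors:
            if data[f].nunique() < 2:
                raise ValueError(f"random factor {f!r} needs >= 2 levels")
        self.data = data
        self.spec = spec

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, fixed_terms=(),
                       response: str = "log_temp",
                       random_factors=("subject_id", "movement"),
                       control: str | None = "ambient_centered") -> "TemperatureLMM":
        return cls(data, LMMSpec(response=response,
                                 fixed_terms=tuple(fixed_terms),
                                 random_factors=tuple(random_factors),
                                 control=control))

    def _build(self):
        spec = self.spec
        if len(spec.random_factors) == 1:
            return smf.mixedlm(spec.formula(), self.data,
                               groups=self.data[spec.random_factors[0]])
        vc = {f: f"0 + C({f})" for f in spec.random_factors}
        return smf.mixedlm(spec.formula(), self.data,
                           groups=np.ones(len(self.data)),
                           re_formula="0", vc_formula=vc)

    def fit(self, method: str = "ML") -> "LMMResults":
        """Fit by maximum likelihood (``"ML"``) or REML."""
        if method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")
        model = self._build()
        exog = model.exog
        rank = np.linalg.matrix_rank(exog)
        if rank < exog.shape[1]:
            names = model.data.design_info.column_names
            raise ValueError("rank-deficient fixed-effect design; collinear "
                             f"columns among {names}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=(method == "REML"))
        return LMMResults(self, model, res, method)


class LMMResults:
    """Estimates, variance components and fit statistics of one LMM."""

    def __init__(self, temperature_lmm: TemperatureLMM, model, res, method: str):
        self.model = temperature_lmm
        self.spec = temperature_lmm.spec
        self._sm_model = model
        self._sm_res = res
        self.method = method
        self.design_info = model.data.design_info
        self.fe_params = pd.Series(np.asarray(res.fe_params),
                                   index=self.design_info.column_names)
        k_fe = len(self.fe_params)
        cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
        self.cov_fe = pd.DataFrame(cov, index=self.fe_params.index,
                                   columns=self.fe_params.index)
        with np.errstate(invalid="ignore"):
            self.bse_fe = pd.Series(np.sqrt(np.diag(cov)),
                                    index=self.fe_params.index)
        self.scale = float(res.scale)  # residual variance
        self.vcomp = self._variance_components(res)
        self.llf = float(res.llf)
        self.nobs = int(model.exog.shape[0])
        self.converged = bool(res.converged)
        self.singular = any(v <= _SINGULAR_TOL * self.scale
                            for v in self.vcomp.values())
        self.k_fixed = k_fe
        #: parameters counted for information criteria: fixed coefficients
        #: + variance components + residual variance
        self.k_params = k_fe + len(self.vcomp) + 1

    def _variance_components(self, res) -> dict[str, float]:
        factors = self.spec.random_factors
        if len(factors) == 1:
            return {factors[0]: float(np.asarray(res.cov_re)[0, 0])}
        names = self._sm_model.exog_vc.names
        return dict(zip(names, np.asarray(res.vcomp, float)))

    @property
    def aicc(self) -> float:
        return aicc(self)

    @property
    def resid_df(self) -> int:
        return self.nobs - self.k_fixed

    def fitted_values(self) -> np.ndarray:
        return np.asarray(self._sm_res.fittedvalues)

    def resid(self) -> np.ndarray:
        return np.asarray(self._sm_res.resid)

    def term_slices(self) -> dict[str, slice]:
        return {t: s for t, s in self.design_info.term_name_slices.items()}

    def summary(self) -> str:
        lines = [
            f"Linear mixed model ({self.method}): {self.spec.formula()}",
            f"random intercepts: {', '.join(self.spec.random_factors)}",
            f"n = {self.nobs}, logLik = {self.llf:.3f}, AICc = {self.aicc:.3f}"
            + ("" if self.converged else "  [NOT CONVERGED]")
            + ("  [singular fit]" if self.singular else ""),
            "",
            f"{'term':<32}{'estimate':>12}{'SE':>10}{'z':>8}",
        ]
        for name in self.fe_params.index:
            est, se = self.fe_params[name], self.bse_fe[name]
            z = est / se if se > 0 else np.nan
            lines.append(f"{name:<32}{est:>12.4f}{se:>10.4f}{z:>8.2f}")
        lines.append("")
        for fac, v in self.vcomp.items():
            lines.append(f"var({fac}) = {v:.5f}")
        lines.append(f"var(residual) = {self.scale:.5f}")
        return "\n".join(lines)


def aicc(fit: LMMResults) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n - k - 1).

    ``k`` counts fixed coefficients, variance components and the
    residual variance.  Requires an ML fit; returns +inf (with a
    warning) when ``n <= k + 1``, where the correction blows up.
    """
    if fit.method != "ML":
        raise ValueError("AICc is defined here for ML fits only")
    k, n = fit.k_params, fit.nobs
    if n <= k + 1:
        logger.warning("AICc undefined for n=%d <= k+1=%d; returning inf", n, k + 1)
        return float("inf")
    return -2.0 * fit.llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _marginality_ok(subset: tuple[str, ...]) -> bool:
    chosen = set(subset)
    for term in subset:
        if ":" in term and any(m not in chosen for m in term.split(":")):
            return False
    return True


def dredge_select(data: pd.DataFrame, base_spec: LMMSpec,
                  candidate_terms, max_subsets: int = 2**16
                  ) -> tuple[pd.DataFrame, LMMSpec]:
    """All-subsets AICc model selection over ``candidate_terms``.

    Every marginality-respecting subset of the candidates is fitted by
    ML on top of the base random/control structure and ranked by AICc.
    Returns the full ranking table and the spec of the minimum-AICc
    model; AICc ties (< 1e-8) resolve toward fewer terms.
    """
    candidates = list(candidate_terms)
    if 2 ** len(candidates) > max_subsets:
        raise ValueError(f"{2 ** len(candidates)} subsets exceed max_subsets="
                         f"{max_subsets}; prune the candidate list")
    rows = []
    specs = {}
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            if not _marginality_ok(subset):
                continue
            spec = base_spec.with_terms(subset)
            fit = TemperatureLMM(data, spec).fit("ML")
            key = " + ".join(subset) if subset else "(null)"
            specs[key] = spec
            rows.append(dict(terms=key, n_terms=len(subset), k=fit.k_params,
                             loglik=fit.llf, aicc=fit.aicc,
                             converged=fit.converged))
    table = pd.DataFrame(rows)
    # ties (< 1e-8) break toward fewer terms, then stable by enumeration order
    table["_aicc_r"] = np.round(table["aicc"] / 1e-8) * 1e-8
    table = (table.sort_values(["_aicc_r", "n_terms"], kind="mergesort")
             .drop(columns="_aicc_r").reset_index(drop=True))
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    best = specs[table["terms"].iloc[0]]
    return table, best


def lrt(full: LMMResults, null: LMMResults) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits on the same observations.

    Returns (chi-square, df, p) with df the difference in fixed-parameter
    counts.
    """
    if full.method != "ML" or null.method != "ML":
        raise ValueError("LRT requires ML fits")
    if full.nobs != null.nobs:
        raise ValueError("fits use different observation counts")
    if not set(null.spec.fixed_terms) <= set(full.spec.fixed_terms):
        raise ValueError("models are not nested: null terms must be a subset "
                         "of the full model's terms")
    stat = max(2.0 * (full.llf - null.llf), 0.0)
    df = full.k_fixed - null.k_fixed
    if df == 0:
        return stat, 0, 1.0
    return stat, df, float(stats.chi2.sf(stat, df))


def term_chisq(fit: LMMResults) -> pd.DataFrame:
    """Wald chi-square test per fixed term (other terms retained).

    For each non-intercept term, chi2 = b' V^-1 b over the term's
    coefficients with V their estimated covariance.  Equivalent to a
    type-II/III Anova table for the additive models used here.
    """
    if not fit.converged:
        logger.debug("Wald tests on a non-converged fit")
    rows = []
    for term, sl in fit.term_slices().items():
        if term == "Intercept" or (fit.spec.control and term == fit.spec.control
                                   and term not in fit.spec.fixed_terms):
            continue
        beta = fit.fe_params.iloc[sl].to_numpy()
        V = fit.cov_fe.iloc[sl, sl].to_numpy()
        try:
            stat = float(beta @ np.linalg.solve(V, beta))
        except np.linalg.LinAlgError:
            logger.warning("aliased coefficients in term %r; skipped", term)
            continue
        df = len(beta)
        rows.append(dict(term=term, chisq=stat, df=df,
                         p=float(stats.chi2.sf(stat, df))))
    return pd.DataFrame(rows, columns=["term", "chisq", "df", "p"])


def _model_variables(fit: LMMResults) -> tuple[dict[str, list], list[str]]:
    """Categorical levels and numeric covariates of the fixed design."""
    cat, num = {}, []
    for fi in fit.design_info.factor_infos.values():
        name = fi.factor.name()
        var = name[2:-1] if name.startswith("C(") else name
        if fi.type == "categorical":
            cat[var] = list(fi.categories)
        else:
            num.append(var)
    return cat, num


def emmeans(fit: LMMResults, factor: str, by: str | None = None) -> pd.DataFrame:
    """Estimated marginal means of ``factor`` (optionally by cells of
    ``factor`` x ``by``).

    Means are predicted at numeric covariates' observed means, averaging
    with equal weights over the levels of every other categorical
    variable in the fixed design.
    """
    cat, num = _model_variables(fit)
    if factor not in cat:
        raise ValueError(f"{factor!r} is not a categorical fixed term of this model")
    if by is not None and by not in cat:
        raise ValueError(f"{by!r} is not a categorical fixed term of this model")
    if len(cat[factor]) < 2:
        raise ValueError(f"{factor!r} has a single level")
    data = fit.model.data
    num_means = {v: float(data[v].mean()) for v in num}
    target_vars = [factor] + ([by] if by else [])
    others = [v for v in cat if v not in target_vars]

    cells = list(itertools.product(*(cat[v] for v in target_vars)))
    rows = []
    for cell in cells:
        grid = []
        for combo in itertools.product(*(cat[v] for v in others)) if others else [()]:
            row = dict(zip(target_vars, cell)) | dict(zip(others, combo)) | num_means
            grid.append(row)
        (dm,) = build_design_matrices([fit.design_info], pd.DataFrame(grid))
        L = np.asarray(dm).mean(axis=0)
        est = float(L @ fit.fe_params.to_numpy())
        se = float(np.sqrt(L @ fit.cov_fe.to_numpy() @ L))
        label = ":".join(str(c) for c in cell)
        rows.append(dict(level=label, emmean=est, se=se, _L=L))
    return pd.DataFrame(rows)


def pairwise_contrasts(fit: LMMResults, factor: str, adjust: str = "tukey",
                       by: str | None = None) -> pd.DataFrame:
    """All pairwise differences of estimated marginal means.

    t statistics use the residual degrees of freedom (n minus fixed-design
    rank); ``adjust="tukey"`` applies the studentized-range adjustment
    over the compared set of means, ``"none"`` leaves p unadjusted.
    """
    if adjust not in ("tukey", "none"):
        raise ValueError("adjust must be 'tukey' or 'none'")
    emm = emmeans(fit, factor, by=by)
    V = fit.cov_fe.to_numpy()
    df = fit.resid_df
    k = len(emm)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        L = emm["_L"].iloc[i] - emm["_L"].iloc[j]
        est = float(L @ fit.fe_params.to_numpy())
        se = float(np.sqrt(L @ V @ L))
        t = est / se if se > 0 else np.nan
        p_un = 2.0 * float(stats.t.sf(abs(t), df))
        if adjust == "tukey":
            p_adj = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        else:
            p_adj = p_un
        rows.append(dict(level_1=emm["level"].iloc[i], level_2=emm["level"].iloc[j],
                         estimate=est, se=se, t=t, df=df,
                         p_unadjusted=p_un, p_adjusted=min(max(p_adj, 0.0), 1.0)))
    return pd.DataFrame(rows)


#: confounds screened on resting (baseline) events
DEFAULT_CONFOUNDS = ("ambient_c", "humidity_pct", "distance_m", "movement")


@dataclass
class ConfoundReport:
    """Outcome of the baseline confound screen."""

    tests: pd.DataFrame  # confound, chisq, df, p, flagged
    controlled: list[str]
    ambient_mean: float
    alpha: float = 0.05

    def center_ambient(self, data: pd.DataFrame,
                       column: str = "ambient_c",
                       out: str = "ambient_centered") -> pd.DataFrame:
        data = data.copy()
        data[out] = data[column] - self.ambient_mean
        return data


def calibrate_confounds(baseline: pd.DataFrame,
                        confounds=DEFAULT_CONFOUNDS,
                        response: str = "log_temp",
                        subject: str = "subject_id",
                        alpha: float = 0.05) -> ConfoundReport:
    """Screen potential confounds on resting (baseline) events.

    One LMM per confound — the confound as the only fixed effect,
    subject identity as a random intercept — with a Wald chi-square on
    the confound term.  Confounds with p < ``alpha`` are flagged for
    control in all downstream models.  The ambient temperature mean is
    recorded so the covariate can be centered consistently.
    """
    rows = []
    flagged = []
    for conf in confounds:
        if conf not in baseline.columns:
            logger.warning("confound %r not in data; skipped", conf)
            continue
        if baseline[conf].nunique() < 2:
            logger.warning("confound %r is constant on baseline; skipped", conf)
            continue
        spec = LMMSpec(response=response, fixed_terms=(conf,),
                       random_factors=(subject,), control=None)
        fit = TemperatureLMM(baseline, spec).fit("ML")
        tab = term_chisq(fit)
        stat, df, p = (float(tab["chisq"].iloc[0]), int(tab["df"].iloc[0]),
                       float(tab["p"].iloc[0]))
        is_flagged = p < alpha
        if is_flagged:
            flagged.append(conf)
        rows.append(dict(confound=conf, chisq=stat, df=df, p=p, flagged=is_flagged))
    tests = pd.DataFrame(rows, columns=["confound", "chisq", "df", "p", "flagged"])
    return ConfoundReport(tests=tests, controlled=flagged,
                          ambient_mean=float(baseline["ambient_c"].mean())
                          if "ambient_c" in baseline.columns else float("nan"),
                          alpha=alpha)
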