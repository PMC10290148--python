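"""Statistical model chain relating band power, condition, subject, and
percent-correct score.

Responses are band power in dB (a scaled log of power, so all linear-model
F and t statistics are identical to those on the natural log). Percent-
correct score enters as an ordered factor over the six levels {0, 20, ...,
100}: orthogonal-polynomial contrasts for the omnibus tests and successive-
difference (backward difference) contrasts for the step-wise post-hoc
t-tests. Term tests are Type II (each term against the model without it,
respecting marginality).

The alpha-beta association uses a random-intercept linear mixed model fitted
by REML (profiled over the variance ratio) with Satterthwaite
finite-sample-corrected denominator degrees of freedom. The multinomial
model treats score as a 6-level categorical response and partitions
likelihood-ratio deviance (-2 log LR, referred to chi-squared) per term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize
from scipy import stats as sps

logger = logging.getLogger(__name__)

SCORE_LEVELS = (0, 20, 40, 60, 80, 100)
POLY_NAMES = ("linear", "quadratic", "cubic", "quartic", "quintic")


@dataclass(frozen=True)
class TermStat:
    name: str
    statistic_name: str  # "F", "t", or "chi2"
    statistic: float
    df_num: float
    df_den: float | None
    p_value: float
    estimate: float | None = None
    se: float | None = None


@dataclass
class ModelResult:
    """Fitted-model summary: per-term tests, coefficients, and fit info."""

    description: str
    terms: list[TermStat]
    coefficients: pd.DataFrame | None = None
    loglik: float | None = None
    notes: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def term(self, name: str) -> TermStat:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term {name!r}; have {[t.name for t in self.terms]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.name, "statistic": t.statistic_name, "value": t.statistic,
                    "df_num": t.df_num, "df_den": t.df_den, "p_value": t.p_value,
                    "estimate": t.estimate, "se": t.se,
                }
                for t in self.terms
            ]
        )


def _resolve_power_column(table: pd.DataFrame, band: str, period: str) -> str:
    suffix = {"combined": "_db", "pre": "_pre_db", "during": "_during_db"}[period]
    for col in (f"{band}{suffix}", f"truth_{band}{suffix}"):
        if col in table.columns:
            return col
    raise KeyError(f"no {band}/{period} power column in table")


def _score_levels(table: pd.DataFrame) -> list[int]:
    observed = sorted(int(s) for s in table["score"].unique())
    if any(s not in SCORE_LEVELS for s in observed):
        raise ValueError(f"scores must be in {SCORE_LEVELS}")
    if len(observed) < len(SCORE_LEVELS):
        logger.warning("score levels %s absent; contrasts rebuilt on observed levels",
                       sorted(set(SCORE_LEVELS) - set(observed)))
    return observed


def _anova_terms(fit, typ: int = 2) -> list[TermStat]:
    table = sm.stats.anova_lm(fit, typ=typ)
    df_resid = float(fit.df_resid)
    out = []
    for name, row in table.iterrows():
        if name == "Residual":
            continue
        out.append(
            TermStat(
                name=name, statistic_name="F", statistic=float(row["F"]),
                df_num=float(row["df"]), df_den=df_resid, p_value=float(row["PR(>F)"]),
            )
        )
    return out


def _coef_frame(fit) -> pd.DataFrame:
    return pd.DataFrame(
        {"estimate": fit.params, "se": fit.bse, "t": fit.tvalues, "p_value": fit.pvalues}
    )


def power_score_anova(
    table: pd.DataFrame,
    band: str = "alpha",
    period: str = "combined",
    include_interaction: bool = False,
) -> ModelResult:
    """Linear model of log band power on ordered percent-correct score and
    condition, with Type II F tests and per-polynomial-contrast t statistics.
    """
    col = _resolve_power_column(table, band, period)
    if table["condition"].nunique() < 2:
        raise ValueError("need at least 2 conditions")
    levels = _score_levels(table)
    data = table[[col, "score", "condition"]].rename(columns={col: "power_db"})
    score_term = f"C(score, Poly, levels={list(levels)})"
    formula = f"power_db ~ {score_term} + C(condition)"
    if include_interaction:
        formula += f" + {score_term}:C(condition)"
    fit = smf.ols(formula, data=data).fit()
    terms = _anova_terms(fit)
    rename = {score_term: "score", "C(condition)": "condition",
              f"{score_term}:C(condition)": "score:condition"}
    terms = [
        TermStat(name=rename.get(t.name, t.name), statistic_name=t.statistic_name,
                 statistic=t.statistic, df_num=t.df_num, df_den=t.df_den, p_value=t.p_value)
        for t in terms
    ]
    # per-contrast t statistics (linear ... quintic) for the ordered factor
    for order, label in enumerate(POLY_NAMES[: len(levels) - 1], start=1):
        pname = _poly_param_name(fit.params.index, score_term, order)
        terms.append(
            TermStat(
                name=f"score_{label}", statistic_name="t",
                statistic=float(fit.tvalues[pname]), df_num=1.0,
                df_den=float(fit.df_resid), p_value=float(fit.pvalues[pname]),
                estimate=float(fit.params[pname]), se=float(fit.bse[pname]),
            )
        )
    return ModelResult(
        description=f"OLS {col} ~ ordered(score) + condition"
        + (" + score:condition" if include_interaction else ""),
        terms=terms, coefficients=_coef_frame(fit), loglik=float(fit.llf),
        extras={"df_resid": float(fit.df_resid), "n": int(fit.nobs)},
    )


def _poly_param_name(index, score_term: str, order: int) -> str:
    suffixes = {1: ".Linear", 2: ".Quadratic", 3: ".Cubic"}
    want = suffixes.get(order, f"^{order}")
    for name in index:
        if name.startswith(score_term) and name.endswith(want):
            return name
    raise KeyError(f"no polynomial term of order {order} in {list(index)}")


def successive_difference_tests(
    table: pd.DataFrame, band: str = "alpha", period: str = "combined"
) -> ModelResult:
    """Pairwise step t-tests on log power (successive-difference contrast
    coding over score levels: 20-0, 40-20, ..., 100-80), adjusting for
    condition."""
    col = _resolve_power_column(table, band, period)
    levels = _score_levels(table)
    data = table[[col, "score", "condition"]].rename(columns={col: "power_db"})
    score_term = f"C(score, Diff, levels={list(levels)})"
    fit = smf.ols(f"power_db ~ {score_term} + C(condition)", data=data).fit()
    terms = []
    for i in range(len(levels) - 1):
        pname = next(
            name for name in fit.params.index
            if name.startswith(score_term) and name.endswith(f"[D.{levels[i]}]")
        )
        terms.append(
            TermStat(
                name=f"step_{levels[i]}_to_{levels[i + 1]}", statistic_name="t",
                statistic=float(fit.tvalues[pname]), df_num=1.0,
                df_den=float(fit.df_resid), p_value=float(fit.pvalues[pname]),
                estimate=float(fit.params[pname]), se=float(fit.bse[pname]),
            )
        )
    return ModelResult(
        description=f"OLS {col} ~ diff(score) + condition", terms=terms,
        coefficients=_coef_frame(fit), loglik=float(fit.llf),
        extras={"df_resid": float(fit.df_resid)},
    )


# ---------------------------------------------------------------------------
# random-intercept linear mixed model with Satterthwaite df
# ---------------------------------------------------------------------------


class RandomInterceptLMM:
    """REML fit of y = X b + u_group + e with a scalar random intercept.

    The likelihood is profiled over the variance ratio lambda = tau^2 /
    sigma^2 using the per-group Woodbury identity, so the fit is a 1-D
    optimization regardless of n. Satterthwaite degrees of freedom for a
    contrast come from the delta method on (sigma^2, tau^2) with the REML
    observed information (numerical Hessian).
    """

    def __init__(self, y, X, groups, param_names=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        codes, _ = pd.factorize(np.asarray(groups))
        self.codes = codes
        self.n, self.p = self.X.shape
        self.param_names = list(param_names) if param_names is not None else [
            f"x{i}" for i in range(self.p)
        ]
        self._group_idx = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
        self._fit()

    def _profile_pieces(self, lam: float):
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        yWy = 0.0
        logdet_w = 0.0
        for idx in self._group_idx:
            Xi, yi = self.X[idx], self.y[idx]
            ni = len(idx)
            shrink = lam / (1.0 + ni * lam)
            sx = Xi.sum(axis=0)
            sy = yi.sum()
            A += Xi.T @ Xi - shrink * np.outer(sx, sx)
            b += Xi.T @ yi - shrink * sx * sy
            yWy += yi @ yi - shrink * sy * sy
            logdet_w += np.log1p(ni * lam)
        return A, b, yWy, logdet_w

    def _neg2_reml_profiled(self, lam: float) -> float:
        A, b, yWy, logdet_w = self._profile_pieces(lam)
        beta = np.linalg.solve(A, b)
        rss_w = yWy - b @ beta
        sigma2 = rss_w / (self.n - self.p)
        return (self.n - self.p) * (np.log(sigma2) + 1.0) + logdet_w + np.linalg.slogdet(A)[1]

    def neg2_reml(self, sigma2: float, tau2: float) -> float:
        lam = tau2 / sigma2
        A, b, yWy, logdet_w = self._profile_pieces(lam)
        beta = np.linalg.solve(A, b)
        rss_w = yWy - b @ beta
        return (
            (self.n - self.p) * np.log(sigma2) + logdet_w
            + np.linalg.slogdet(A)[1] + rss_w / sigma2
        )

    def _fit(self) -> None:
        res = optimize.minimize_scalar(
            lambda u: self._neg2_reml_profiled(np.exp(u)),
            bounds=(-18.0, 18.0), method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(np.exp(res.x))
        A, b, yWy, _ = self._profile_pieces(lam)
        self.beta = np.linalg.solve(A, b)
        rss_w = yWy - b @ self.beta
        self.sigma2 = rss_w / (self.n - self.p)
        self.tau2 = lam * self.sigma2
        self.lam = lam
        self._A = A
        self.cov_beta = self.sigma2 * np.linalg.inv(A)
        self.boundary = res.x <= -17.5

    def _contrast_var(self, c, sigma2: float, tau2: float) -> float:
        A, _, _, _ = self._profile_pieces(tau2 / sigma2)
        return sigma2 * float(c @ np.linalg.solve(A, c))

    def satterthwaite_df(self, c) -> float:
        """Satterthwaite denominator df for contrast c'beta."""
        c = np.asarray(c, dtype=float)
        if self.boundary:
            return float(self.n - self.p)
        theta = np.array([self.sigma2, self.tau2])
        h = 1e-4 * np.maximum(np.abs(theta), 1e-8)
        # observed information of the REML criterion (-2 log-lik) / 2
        H = np.zeros((2, 2))
        f0 = self.neg2_reml(*theta)
        for i in range(2):
            tp = theta.copy(); tp[i] += h[i]
            tm = theta.copy(); tm[i] -= h[i]
            H[i, i] = (self.neg2_reml(*tp) - 2.0 * f0 + self.neg2_reml(*tm)) / h[i] ** 2
        tpp = theta + h
        tmm = theta - h
        tpm = theta.copy(); tpm[0] += h[0]; tpm[1] -= h[1]
        tmp = theta.copy(); tmp[0] -= h[0]; tmp[1] += h[1]
        H[0, 1] = H[1, 0] = (
            self.neg2_reml(*tpp) - self.neg2_reml(*tpm)
            - self.neg2_reml(*tmp) + self.neg2_reml(*tmm)
        ) / (4.0 * h[0] * h[1])
        try:
            cov_theta = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return float(self.n - self.p)
        g = np.zeros(2)
        C0 = self._contrast_var(c, *theta)
        for i in range(2):
            tp = theta.copy(); tp[i] += h[i]
            tm = theta.copy(); tm[i] -= h[i]
            g[i] = (self._contrast_var(c, *tp) - self._contrast_var(c, *tm)) / (2.0 * h[i])
        denom = float(g @ cov_theta @ g)
        if denom <= 0:
            return float(self.n - self.p)
        df = 2.0 * C0**2 / denom
        return float(np.clip(df, 1.0, self.n - self.p))

    def wald_t(self, index: int):
        """(estimate, se, t, satterthwaite df, p) for one coefficient."""
        c = np.zeros(self.p)
        c[index] = 1.0
        est = float(self.beta[index])
        se = float(np.sqrt(self.cov_beta[index, index]))
        df = self.satterthwaite_df(c)
        t = est / se
        p = 2.0 * sps.t.sf(abs(t), df)
        return est, se, t, df, p


def alpha_beta_association(
    table: pd.DataFrame,
    response_band: str = "beta",
    predictor_band: str = "alpha",
    subject_mode: str = "random",
) -> ModelResult:
    """Trial-wise alpha-beta power association, accounting for subject.

    Log beta power is regressed on log alpha power and condition with a
    random intercept per subject (Type II Wald F with Satterthwaite df, the
    finite-sample stand-in for Kenward-Roger). With a single subject, or
    ``subject_mode='fixed'``, falls back to a fixed-effects linear model.
    """
    y_col = _resolve_power_column(table, response_band, "combined")
    x_col = _resolve_power_column(table, predictor_band, "combined")
    n_subjects = table["subject"].nunique()
    notes = ["Satterthwaite df approximates Kenward-Roger"]
    if n_subjects < 2 or subject_mode == "fixed":
        if n_subjects < 2:
            notes.append("single subject: fell back to fixed-effects OLS")
            logger.warning("single subject: mixed model fell back to fixed-effects OLS")
        data = table[[y_col, x_col, "condition", "subject"]].rename(
            columns={y_col: "y", x_col: "x"}
        )
        formula = "y ~ x + C(condition)" + (" + C(subject)" if n_subjects > 1 else "")
        fit = smf.ols(formula, data=data).fit()
        t = float(fit.tvalues["x"])
        terms = [
            TermStat(
                name=predictor_band, statistic_name="F", statistic=t**2, df_num=1.0,
                df_den=float(fit.df_resid), p_value=float(fit.pvalues["x"]),
                estimate=float(fit.params["x"]), se=float(fit.bse["x"]),
            )
        ]
        return ModelResult(
            description=f"OLS {y_col} ~ {x_col} + condition (fixed)",
            terms=terms, coefficients=_coef_frame(fit), loglik=float(fit.llf), notes=notes,
        )

    cond_levels = sorted(table["condition"].unique())
    X = np.column_stack(
        [np.ones(len(table)), table[x_col].to_numpy()]
        + [(table["condition"] == lvl).to_numpy(float) for lvl in cond_levels[1:]]
    )
    names = ["Intercept", predictor_band] + [f"condition[{lvl}]" for lvl in cond_levels[1:]]
    model = RandomInterceptLMM(table[y_col].to_numpy(), X, table["subject"], names)
    terms = []
    for i, name in enumerate(names):
        if name == "Intercept":
            continue
        est, se, t, df, p = model.wald_t(i)
        terms.append(
            TermStat(name=name if name != predictor_band else predictor_band,
                     statistic_name="F", statistic=t**2, df_num=1.0, df_den=df,
                     p_value=p, estimate=est, se=se)
        )
    coefs = pd.DataFrame(
        {"estimate": model.beta, "se": np.sqrt(np.diag(model.cov_beta))}, index=names
    )
    return ModelResult(
        description=f"LMM {y_col} ~ {x_col} + condition + (1 | subject), REML",
        terms=terms, coefficients=coefs, notes=notes,
        extras={"sigma2": model.sigma2, "tau2": model.tau2, "n_subjects": n_subjects},
    )


def individual_differences_anova(table: pd.DataFrame, outcome: str = "alpha_db") -> ModelResult:
    """Type II F tests for subject and condition on log alpha power, log beta
    power, or the (log) alpha-to-beta ratio."""
    if table["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if outcome == "log_ratio":
        a = _resolve_power_column(table, "alpha", "combined")
        b = _resolve_power_column(table, "beta", "combined")
        data = table[["subject", "condition"]].copy()
        data["y"] = table[a] - table[b]  # dB difference = scaled log ratio
        desc = "OLS log(alpha/beta) ~ subject + condition"
    else:
        band = outcome.removesuffix("_db")
        col = _resolve_power_column(table, band, "combined")
        data = table[["subject", "condition"]].copy()
        data["y"] = table[col]
        desc = f"OLS {col} ~ subject + condition"
    fit = smf.ols("y ~ C(subject) + C(condition)", data=data).fit()
    rename = {"C(subject)": "subject", "C(condition)": "condition"}
    terms = [
        TermStat(name=rename.get(t.name, t.name), statistic_name="F",
                 statistic=t.statistic, df_num=t.df_num, df_den=t.df_den, p_value=t.p_value)
        for t in _anova_terms(fit)
    ]
    return ModelResult(description=desc, terms=terms, coefficients=_coef_frame(fit),
                       loglik=float(fit.llf), extras={"df_resid": float(fit.df_resid)})


# ---------------------------------------------------------------------------
# multinomial deviance partitioning
# ---------------------------------------------------------------------------


def _fit_mnlogit(y_codes: np.ndarray, X: np.ndarray):
    model = sm.MNLogit(y_codes, X)
    last_err = None
    for method, kwargs in (("newton", {"maxiter": 200, "tol": 1e-8}),
                           ("lbfgs", {"maxiter": 2000}),
                           ("bfgs", {"maxiter": 2000, "gtol": 1e-8})):
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                fit = model.fit(method=method, disp=0, **kwargs)
        except Exception as err:  # singular Hessian, line-search failure, ...
            last_err = err
            continue
        if fit.mle_retvals.get("converged", True):
            return fit
        last_err = RuntimeError(f"{method} did not converge")
    raise RuntimeError(f"multinomial fit failed to converge: {last_err}")


def multinomial_deviance(
    table: pd.DataFrame,
    predictors: tuple[str, ...] = ("alpha", "beta"),
    condition_always: bool = True,
) -> ModelResult:
    """Multinomial regression of percent-correct score (6-level categorical,
    reference level 0) on log band powers and condition, with Type II
    likelihood-ratio deviance tests per term.

    Predictor names name bands ("alpha", "beta", "pre_beta", "during_beta")
    or are taken verbatim as column names. Predictors are standardized
    internally; deviance and p-values are invariant to that scaling.
    ``extras['deviance_vs_base']`` holds the deviances of the drop-one and
    full models relative to a condition-only base model.
    """
    period_map = {"pre": "pre", "during": "during"}
    cols = {}
    for p in predictors:
        if p in table.columns:
            cols[p] = p
            continue
        parts = p.split("_")
        if len(parts) == 2 and parts[0] in period_map:
            cols[p] = _resolve_power_column(table, parts[1], period_map[parts[0]])
        else:
            cols[p] = _resolve_power_column(table, p, "combined")

    levels = _score_levels(table)
    y = pd.Categorical(table["score"], categories=levels, ordered=True).codes
    n_levels = len(levels)

    cond_levels = sorted(table["condition"].unique())
    blocks: dict[str, np.ndarray] = {}
    for name, col in cols.items():
        x = table[col].to_numpy(dtype=float)
        blocks[name] = ((x - x.mean()) / x.std())[:, None]
    cond_block = np.column_stack(
        [(table["condition"] == lvl).to_numpy(float) for lvl in cond_levels[1:]]
    )
    if condition_always or "condition" in predictors:
        blocks["condition"] = cond_block

    def design(names):
        mats = [np.ones((len(table), 1))] + [blocks[n] for n in names]
        return np.column_stack(mats)

    all_terms = list(blocks)
    full = _fit_mnlogit(y, design(all_terms))
    terms = []
    for name in all_terms:
        reduced_names = [n for n in all_terms if n != name]
        reduced = _fit_mnlogit(y, design(reduced_names))
        dev = 2.0 * (full.llf - reduced.llf)
        df = (n_levels - 1) * blocks[name].shape[1]
        terms.append(
            TermStat(name=name, statistic_name="chi2", statistic=float(dev),
                     df_num=float(df), df_den=None, p_value=float(sps.chi2.sf(dev, df)))
        )

    base = _fit_mnlogit(y, design(["condition"] if "condition" in blocks else []))
    dev_vs_base = {"full": 2.0 * (full.llf - base.llf)}
    for name in all_terms:
        if name == "condition":
            continue
        single = _fit_mnlogit(y, design(["condition", name] if "condition" in blocks else [name]))
        dev_vs_base[name] = 2.0 * (single.llf - base.llf)

    return ModelResult(
        description="multinomial score ~ " + " + ".join(all_terms)
        + f" (levels {levels}, reference {levels[0]})",
        terms=terms, loglik=float(full.llf),
        extras={"deviance_vs_base": dev_vs_base, "n_levels": n_levels,
                "base_llf": float(base.llf)},
    )


def pre_during_correlation(
    table: pd.DataFrame, band: str = "alpha", within_subject: bool = False
) -> ModelResult:
    """Simple regression of during-stimulus on pre-stimulus log power across
    trials: R^2, df = n - 2, and the slope test.

    The default pools trials over subjects, so between-subject power offsets
    contribute to R^2. With ``within_subject=True`` both powers are
    subject-demeaned first, isolating the trial-level shared variance (the
    generator's ``rho_period``); df becomes n - 1 - n_subjects.
    """
    pre_col = _resolve_power_column(table, band, "pre")
    dur_col = _resolve_power_column(table, band, "during")
    x = table[pre_col].to_numpy(dtype=float)
    y = table[dur_col].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 trials")
    df = n - 2
    if within_subject:
        grp = table.groupby("subject")
        x = x - grp[pre_col].transform("mean").to_numpy()
        y = y - grp[dur_col].transform("mean").to_numpy()
        df = n - 1 - table["subject"].nunique()
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    slope_t = float(fit.tvalues[1])
    p = float(sps.f.sf(slope_t**2, 1, df))
    return ModelResult(
        description=f"OLS {dur_col} ~ {pre_col}" + (" (subject-demeaned)" if within_subject else ""),
        terms=[
            TermStat(name="pre_power", statistic_name="F", statistic=slope_t**2,
                     df_num=1.0, df_den=float(df), p_value=p,
                     estimate=float(fit.params[1]), se=float(fit.bse[1]))
        ],
        coefficients=_coef_frame(fit),
        extras={"r_squared": float(fit.rsquared), "df": df, "n": n},
    )
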