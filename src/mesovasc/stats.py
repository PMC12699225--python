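"""Cohort-level inference for longitudinal imaging outcomes.

Session- and vessel-level metrics are modelled with linear mixed-effects
regression (fixed effects of age, sex, genotype and their interactions; a
random intercept per mouse to absorb repeated measures). The module adds the
reporting layer the imaging analyses need: per-term Wald tests with a
documented between-within denominator-df convention, the Johnson-Neyman
solution for where a conditional slope crosses significance, Holm step-down
adjustment, and the small/large median-split group contrasts.

The likelihood optimisation itself is delegated to statsmodels
(MixedLM / OLS); the model specification, df conventions, Johnson-Neyman
algebra and contrast machinery live here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

DF_CONVENTION = "between-within"


@dataclass
class ModelFit:
    """Fixed-effect estimates with covariance and per-term Wald tests.

    ``df`` holds the denominator degrees of freedom assigned to each term by
    the between-within convention: terms constant within every mouse test
    against between-mouse df (``n_groups - n_between_terms``), terms varying
    within mice against within-mouse df
    (``n_obs - n_groups - n_within_terms``). ``fvalues`` are the squared
    t statistics (1-df Wald F tests).
    """

    params: pd.Series
    cov: pd.DataFrame
    bse: pd.Series
    tvalues: pd.Series
    fvalues: pd.Series
    pvalues: pd.Series
    df: pd.Series
    n_obs: int
    n_groups: int
    resid_var: float
    group_var: float
    method: str
    formula: str
    df_convention: str = DF_CONVENTION
    converged: bool = True

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-term confidence intervals at the term's assigned df."""
        tcrit = scipy.stats.t.ppf(1 - alpha / 2, self.df)
        return pd.DataFrame(
            {"lower": self.params - tcrit * self.bse, "upper": self.params + tcrit * self.bse}
        )

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": self.bse,
                "ci_low": ci["lower"],
                "ci_high": ci["upper"],
                "t": self.tvalues,
                "F": self.fvalues,
                "df_denom": self.df,
                "p": self.pvalues,
            }
        )


def _between_within_df(exog: np.ndarray, names: list[str], groups: np.ndarray,
                       n_obs: int, n_groups: int) -> pd.Series:
    """Assign each design column a between- or within-mouse denominator df."""
    gidx = pd.factorize(groups)[0]
    is_between = []
    for j in range(exog.shape[1]):
        col = exog[:, j]
        resid = col - pd.Series(col).groupby(gidx).transform("mean").to_numpy()
        is_between.append(np.allclose(resid, 0, atol=1e-10))
    n_between = int(np.sum(is_between))
    n_within = len(is_between) - n_between
    df_between = max(n_groups - n_between, 1)
    df_within = max(n_obs - n_groups - n_within, 1)
    return pd.Series(
        [df_between if b else df_within for b in is_between], index=names, dtype=float
    )


def fit_lme(
    table: pd.DataFrame,
    formula: str,
    group: str = "mouse_id",
    reml: bool = True,
) -> ModelFit:
    """Fit ``formula`` with a random intercept per ``group`` (REML).

    With one observation per group the random intercept is inestimable; a
    warning is logged and the fit falls back to ordinary least squares (the
    two coincide in that limit). Rank-deficient designs raise ``ValueError``
    naming the collinear term.
    """
    data = table.dropna(subset=[group]).copy()
    groups = data[group].to_numpy()
    n_groups = len(pd.unique(groups))

    # Build the design once (via OLS machinery) to vet rank and name columns.
    ols_model = smf.ols(formula, data=data)
    exog = ols_model.exog
    names = list(ols_model.exog_names)
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # name a term involved in the collinearity: smallest singular vector
        _, _, vt = np.linalg.svd(exog, full_matrices=False)
        worst = names[int(np.argmax(np.abs(vt[-1])))]
        raise ValueError(f"design matrix is rank deficient (term '{worst}' is collinear)")
    n_obs = exog.shape[0]

    if n_groups >= n_obs:
        log.warning(
            "one observation per %s: random intercept inestimable; using OLS", group
        )
        with warnings.catch_warnings():
            # n_obs == n_params leaves zero residual df; reported as NaN
            warnings.simplefilter("ignore", RuntimeWarning)
            res = ols_model.fit()
            params = res.params
            cov = res.cov_params()
        resid_var = float(res.mse_resid) if n_obs > exog.shape[1] else float("nan")
        group_var = 0.0
        method = "ols"
        df = pd.Series(float(max(n_obs - exog.shape[1], 1)), index=names)
        converged = True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, data=data, groups=groups)
            res = None
            for opt in ("bfgs", "powell", "nm"):
                try:
                    res = md.fit(reml=reml, method=opt)
                    break
                except np.linalg.LinAlgError:
                    continue
            if res is None:
                raise np.linalg.LinAlgError(
                    "mixed-model optimisation failed with every optimiser"
                )
        fe = list(md.exog_names)
        params = res.fe_params
        cov = res.cov_params().loc[fe, fe]
        resid_var = float(res.scale)
        group_var = float(np.atleast_2d(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
        if group_var <= 1e-10 * max(resid_var, 1e-12):
            log.warning("random-intercept variance estimated at the boundary (~0); fit retained")
        method = "mixedlm-reml" if reml else "mixedlm-ml"
        df = _between_within_df(md.exog, fe, groups, n_obs, n_groups)
        converged = bool(res.converged)
        names = fe

    bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
    tvals = params / bse
    pvals = pd.Series(
        2 * scipy.stats.t.sf(np.abs(tvals), df.loc[names]), index=names
    )
    return ModelFit(
        params=pd.Series(params, index=names),
        cov=pd.DataFrame(np.asarray(cov), index=names, columns=names),
        bse=bse,
        tvalues=pd.Series(tvals, index=names),
        fvalues=pd.Series(tvals**2, index=names),
        pvalues=pvals,
        df=df.loc[names],
        n_obs=n_obs,
        n_groups=n_groups,
        resid_var=resid_var,
        group_var=group_var,
        method=method,
        formula=formula,
        converged=converged,
    )


def fit_lm(table: pd.DataFrame, formula: str) -> ModelFit:
    """Ordinary least-squares fit in the same reporting container."""
    res = smf.ols(formula, data=table).fit()
    names = list(res.params.index)
    df = pd.Series(float(res.df_resid), index=names)
    tvals = res.params / res.bse
    return ModelFit(
        params=res.params,
        cov=res.cov_params(),
        bse=res.bse,
        tvalues=tvals,
        fvalues=tvals**2,
        pvalues=pd.Series(2 * scipy.stats.t.sf(np.abs(tvals), df), index=names),
        df=df,
        n_obs=int(res.nobs),
        n_groups=int(res.nobs),
        resid_var=float(res.mse_resid),
        group_var=0.0,
        method="ols",
        formula=formula,
        df_convention="residual",
    )


@dataclass
class JNRegion:
    """Johnson-Neyman solution for a conditional slope theta(m) = b1 + b3*m.

    ``boundaries`` are the moderator values where the slope's Wald statistic
    crosses the critical value (0, 1 or 2 of them). ``significant_between``
    says whether the slope is significant between the two boundaries (two
    roots), above/below the single boundary is encoded by evaluating
    :meth:`is_significant`.
    """

    boundaries: list[float]
    always_significant: bool = False
    never_significant: bool = False
    alpha: float = 0.05
    t_crit: float = float("nan")
    _coef: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0), repr=False)

    def is_significant(self, m: float) -> bool:
        """Whether theta(m) is significant at the region's alpha."""
        a, b, c = self._coef
        return a * m * m + b * m + c > 0

    def loss_boundary(self, eps: float = 1e-2) -> float:
        """The moderator value where significance is lost as m increases.

        Returns NaN when no boundary has that orientation (slope always or
        never significant, or significance only ever switches on).
        """
        for b in sorted(self.boundaries):
            if self.is_significant(b - eps) and not self.is_significant(b + eps):
                return float(b)
        return float("nan")


def _interaction_name(names: list[str], x: str, m: str) -> str:
    for cand in (f"{x}:{m}", f"{m}:{x}"):
        if cand in names:
            return cand
    raise KeyError(f"no interaction term between '{x}' and '{m}' in {names}")


def johnson_neyman(
    fit: ModelFit, predictor: str, moderator: str, alpha: float = 0.05,
    df: float | None = None,
) -> JNRegion:
    """Moderator values where the conditional effect of ``predictor`` crosses
    significance.

    For ``y ~ b0 + b1*x + b2*m + b3*x*m`` the conditional slope is
    ``theta(m) = b1 + b3*m`` with
    ``var theta(m) = var(b1) + m^2 var(b3) + 2 m cov(b1, b3)``; boundaries are
    the real roots of ``theta(m)^2 = t_crit^2 var theta(m)`` (a quadratic in
    ``m``). ``df`` defaults to the df assigned to the interaction term.
    """
    inter = _interaction_name(list(fit.params.index), predictor, moderator)
    b1 = float(fit.params[predictor])
    b3 = float(fit.params[inter])
    v11 = float(fit.cov.loc[predictor, predictor])
    v33 = float(fit.cov.loc[inter, inter])
    v13 = float(fit.cov.loc[predictor, inter])
    if df is None:
        df = float(fit.df[inter])
    t_crit = float(scipy.stats.t.ppf(1 - alpha / 2, df))
    c2 = t_crit**2
    # theta(m)^2 - c2 * var theta(m) > 0  <=>  significant
    A = b3**2 - c2 * v33
    B = 2 * (b1 * b3 - c2 * v13)
    C = b1**2 - c2 * v11
    scale = max(abs(A), abs(B), abs(C), 1e-300)
    region = JNRegion([], alpha=alpha, t_crit=t_crit, _coef=(A, B, C))
    if abs(A) < 1e-12 * scale:
        if abs(B) < 1e-12 * scale:
            # constant: significance does not depend on the moderator
            region.always_significant = C > 0
            region.never_significant = not region.always_significant
            return region
        region.boundaries = [-C / B]
        return region
    disc = B * B - 4 * A * C
    if disc <= 0:
        region.always_significant = A > 0
        region.never_significant = A < 0
        return region
    r = np.sqrt(disc)
    roots = sorted([(-B - r) / (2 * A), (-B + r) / (2 * A)])
    region.boundaries = [float(x) for x in roots]
    return region


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values.

    Sort ascending; the i-th order statistic becomes
    ``max_{j<=i} min(1, (k - j + 1) * p_(j))``; then unsort. Adjusted values
    dominate the raw ones elementwise and never exceed 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (k - np.arange(k)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(k)
    out[order] = adj_sorted
    return out


def split_contrasts(
    records: pd.DataFrame,
    age_cut: float = 11.0,
    outcome: str = "percent_change",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Old-vs-young dilation contrasts within sex, per vessel size class.

    Records need ``size_class`` (from the arterial median split), ``sex``,
    ``age`` (months), ``mouse_id`` and the outcome column. Ages are binned at
    ``age_cut`` (old = age >= cut). Per size class and sex, a mixed model with
    mouse random intercept (OLS when every mouse contributes one record)
    estimates the old - young difference; Holm adjustment runs across the
    whole contrast family. Empty cells yield a row with missing estimates.
    """
    df = records.copy()
    df["age_bin"] = np.where(df["age"] >= age_cut, "old", "young")
    rows = []
    for size_class in ("small", "large"):
        for sex in ("F", "M"):
            sub = df[(df["size_class"] == size_class) & (df["sex"] == sex)]
            n_young = int((sub["age_bin"] == "young").sum())
            n_old = int((sub["age_bin"] == "old").sum())
            row = {
                "size_class": size_class,
                "sex": sex,
                "n_young": n_young,
                "n_old": n_old,
                "estimate": np.nan,
                "se": np.nan,
                "t": np.nan,
                "df": np.nan,
                "p": np.nan,
            }
            if n_young == 0 or n_old == 0:
                log.warning(
                    "empty %s/%s age cell: contrast skipped", size_class, sex
                )
                rows.append(row)
                continue
            sub = sub.copy()
            sub["age_bin"] = pd.Categorical(sub["age_bin"], categories=["young", "old"])
            fit = fit_lme(sub, f"{outcome} ~ age_bin", group="mouse_id")
            term = next(n for n in fit.params.index if "age_bin" in n and "old" in n)
            row.update(
                estimate=float(fit.params[term]),
                se=float(fit.bse[term]),
                t=float(fit.tvalues[term]),
                df=float(fit.df[term]),
                p=float(fit.pvalues[term]),
            )
            rows.append(row)
    out = pd.DataFrame(rows)
    done = out["p"].notna()
    out["p_holm"] = np.nan
    if done.any():
        out.loc[done, "p_holm"] = holm_adjust(out.loc[done, "p"].to_numpy())
    out["significant"] = out["p_holm"] < alpha
    return out
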