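"""Cohort-level statistical analyses of simulated (or supplied) trial tables.

The headline analyses of a spreading-of-alternatives study:

* ``soa ~ abs_dv + disparity`` — linear mixed model; difficulty (small
  |dV|) should raise SoA in every accumulator model, while disparity should
  raise it only in models that carry attribute-level information.
* ``log(rt) ~ abs_dv + soa`` — linear mixed model; spread behaves like an
  effective increase in drift, so more spread predicts faster responses.
* choice ~ dv — logistic mixed model (consistency check of choices against
  ratings).

All mixed models take random intercepts and slopes per participant,
falling back to random intercepts alone when the richer fit fails to
converge.  Median splits and quantile-bin tables summarise consistency, RT
and SoA by choice difficulty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    """Fixed effects of one mixed-effects analysis."""

    name: str
    terms: dict = field(default_factory=dict)  # term -> {coef, se, ci_low, ci_high, p}
    random_structure: str = ""
    n_obs: int = 0
    n_groups: int = 0
    converged: bool = True

    def coef(self, term):
        return self.terms[term]["coef"]

    def ci(self, term):
        t = self.terms[term]
        return t["ci_low"], t["ci_high"]

    def to_dict(self):
        return {
            "name": self.name,
            "terms": self.terms,
            "random_structure": self.random_structure,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "converged": self.converged,
        }


def _terms_from_params(params, bse, pvalues, names):
    out = {}
    for nm in names:
        c, s = float(params[nm]), float(bse[nm])
        out[nm] = {
            "coef": c,
            "se": s,
            "ci_low": c - 1.96 * s,
            "ci_high": c + 1.96 * s,
            "p": float(pvalues[nm]) if pvalues is not None else np.nan,
        }
    return out


def _check_variance(data, cols):
    for c in cols:
        if np.isclose(data[c].std(ddof=0), 0.0):
            raise ValueError(f"predictor or outcome {c!r} has zero variance")


def _mixed_linear(name, formula, data, predictors, groups="participant_id"):
    data = data.dropna(subset=predictors + [groups]).copy()
    _check_variance(data, predictors)
    re_formula = "~" + " + ".join(p for p in predictors[1:]) if len(predictors) > 1 else "~1"
    structure = "intercept+slopes"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = smf.mixedlm(formula, data, groups=data[groups], re_formula=re_formula)
            res = md.fit(reml=True, method=["lbfgs", "cg"])
            ok = bool(res.converged)
        except Exception:
            ok = False
        if not ok:
            log.warning("%s: random-slope fit failed; falling back to intercepts", name)
            structure = "intercept-only"
            try:
                md = smf.mixedlm(formula, data, groups=data[groups])
                res = md.fit(reml=True, method=["lbfgs", "cg"])
            except Exception:
                res = None
        if not ok and (res is None or not np.all(np.isfinite(res.bse_fe))):
            # last resort for tiny/degenerate tables: pooled OLS with
            # cluster-robust standard errors by participant
            log.warning("%s: mixed fits failed; cluster-robust OLS fallback", name)
            ols = smf.ols(formula, data).fit(
                cov_type="cluster", cov_kwds={"groups": data[groups]}
            )
            return RegressionResult(
                name=name,
                terms=_terms_from_params(ols.params, ols.bse, ols.pvalues,
                                         list(ols.params.index)),
                random_structure="none (cluster-robust OLS fallback)",
                n_obs=int(ols.nobs),
                n_groups=data[groups].nunique(),
                converged=False,
            )
    fe = [n for n in res.fe_params.index]
    return RegressionResult(
        name=name,
        terms=_terms_from_params(res.fe_params, res.bse_fe, res.pvalues, fe),
        random_structure=structure,
        n_obs=int(res.nobs),
        n_groups=data[groups].nunique(),
        converged=bool(res.converged),
    )


def run_soa_regression(table: pd.DataFrame) -> RegressionResult:
    """Linear mixed model ``soa ~ abs_dv + disparity``, random slopes per participant."""
    if table["participant_id"].nunique() < 10:
        raise ValueError("need >= 10 participants")
    return _mixed_linear(
        "soa_on_absdv_disparity", "soa ~ abs_dv + disparity",
        table, ["soa", "abs_dv", "disparity"],
    )


def run_rt_regression(table: pd.DataFrame) -> RegressionResult:
    """Linear mixed model ``log(rt) ~ abs_dv + soa``."""
    if (table["rt"] <= 0).any():
        raise ValueError("rt must be > 0")
    data = table.copy()
    data["log_rt"] = np.log(data["rt"])
    return _mixed_linear(
        "logrt_on_absdv_soa", "log_rt ~ abs_dv + soa",
        data, ["log_rt", "abs_dv", "soa"],
    )


def run_consistency_regression(table: pd.DataFrame) -> RegressionResult:
    """Binomial mixed model (logit link) of choice on dv.

    Uses the variational Bayes binomial GLMM with random intercepts and
    dv slopes per participant; posterior means and SDs are reported as
    coefficients and standard errors.  On failure (e.g. complete
    separation) falls back to a cluster-robust GLM, logged.
    """
    data = table.dropna(subset=["choice", "dv"]).copy()
    _check_variance(data, ["dv"])
    data["participant_id"] = data["participant_id"].astype(str)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            md = sm.BinomialBayesMixedGLM.from_formula(
                "choice ~ dv",
                {"a": "0 + C(participant_id)", "b": "0 + C(participant_id):dv"},
                data,
            )
            # the VB fit draws its initialisation from the global RNG; pin it
            # so identical inputs give byte-identical reports
            state = np.random.get_state()
            np.random.seed(0)
            try:
                res = md.fit_vb()
            finally:
                np.random.set_state(state)
            params = pd.Series(res.fe_mean, index=md.exog_names)
            bse = pd.Series(res.fe_sd, index=md.exog_names)
            terms = _terms_from_params(params, bse, None, list(md.exog_names))
            return RegressionResult(
                name="choice_on_dv_logistic", terms=terms,
                random_structure="intercept+slopes (VB)",
                n_obs=len(data), n_groups=data["participant_id"].nunique(),
                converged=True,
            )
        except Exception as exc:
            log.warning("binomial GLMM failed (%s); cluster-robust GLM fallback", exc)
    glm = smf.glm("choice ~ dv", data, family=sm.families.Binomial()).fit(
        cov_type="cluster", cov_kwds={"groups": data["participant_id"]}
    )
    return RegressionResult(
        name="choice_on_dv_logistic",
        terms=_terms_from_params(glm.params, glm.bse, glm.pvalues, list(glm.params.index)),
        random_structure="none (cluster-robust GLM fallback)",
        n_obs=int(glm.nobs), n_groups=data["participant_id"].nunique(),
        converged=False,
    )


def median_split_summary(
    table: pd.DataFrame, outcome: str, difficulty_col: str = "abs_dv",
    stat: str = "mean",
) -> pd.DataFrame:
    """Difficult-vs-easy summary of an outcome by a pooled median split.

    ``difficult`` is below the median of ``difficulty_col`` across all
    trials (ties go to easy).  ``stat`` is ``mean`` or ``median``; SE is the
    usual standard error of the mean (scaled by 1.2533 for the median under
    approximate normality).
    """
    data = table.dropna(subset=[outcome, difficulty_col])
    med = data[difficulty_col].median()
    if np.isclose(data[difficulty_col].std(ddof=0), 0.0):
        log.warning("degenerate split: %s is constant", difficulty_col)
    labels = np.where(data[difficulty_col] < med, "difficult", "easy")
    rows = []
    for lab in ("difficult", "easy"):
        vals = data.loc[labels == lab, outcome]
        if len(vals) == 0:
            rows.append((lab, np.nan, np.nan, 0))
            continue
        centre = vals.mean() if stat == "mean" else vals.median()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        if stat == "median":
            se *= 1.2533
        rows.append((lab, float(centre), float(se), int(len(vals))))
    out = pd.DataFrame(rows, columns=["split", stat, "se", "n"])
    out.insert(0, "outcome", outcome)
    out.insert(1, "threshold", med)
    return out


def quantile_bin_table(
    table: pd.DataFrame,
    bin_var: str,
    split_var: str,
    outcome: str,
    n_bins: int = 5,
    reference: pd.Series | None = None,
) -> pd.DataFrame:
    """Outcome means in quantile bins of one variable, median-split by another.

    Bin edges come from the empirical quantiles of ``reference`` (defaults
    to ``table[bin_var]`` itself); the median split of ``split_var`` is done
    within each bin.  Empty cells are reported with NaN, not raised.
    """
    data = table.dropna(subset=[bin_var, split_var, outcome]).copy()
    ref = reference if reference is not None else data[bin_var]
    edges = np.unique(np.quantile(ref, np.linspace(0, 1, n_bins + 1)))
    data["bin"] = pd.cut(data[bin_var], edges, labels=False, include_lowest=True)
    rows = []
    for b in range(len(edges) - 1):
        cell = data[data["bin"] == b]
        if cell.empty:
            for lab in ("low", "high"):
                rows.append((b, edges[b], edges[b + 1], lab, np.nan, np.nan, 0))
            continue
        med = cell[split_var].median()
        halves = {"low": cell[cell[split_var] <= med], "high": cell[cell[split_var] > med]}
        for lab, half in halves.items():
            if half.empty:
                rows.append((b, edges[b], edges[b + 1], lab, np.nan, np.nan, 0))
            else:
                rows.append((
                    b, edges[b], edges[b + 1], lab,
                    float(half[outcome].mean()),
                    float(half[outcome].std(ddof=1) / np.sqrt(len(half)))
                    if len(half) > 1 else np.nan,
                    int(len(half)),
                ))
    return pd.DataFrame(
        rows,
        columns=["bin", "edge_low", "edge_high", f"{split_var}_half",
                 f"{outcome}_mean", f"{outcome}_se", "n"],
    )
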