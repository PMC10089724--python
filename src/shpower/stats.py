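"""Mixed-effects estimates for the comparative strike summaries.

Three estimands, one per headline comparison:

* the gape -> flow-speed scaling slope per group (elastic-powered vs.
  generalist), from a linear mixed model with group-specific fixed slopes
  and random intercepts for species and individual-within-species;
* group means of mass-specific suction power with a likelihood-ratio test
  of the group effect (the original analysis used phylogenetically
  informed Bayesian models; here phylogeny is collapsed to species-level
  random intercepts and the Bayes factor is replaced by an LRT, since the
  point estimates are the quantities of interest);
* the slope of tendon power against net suction power across strikes.

All estimators are invariant to row order and transform exactly under
unit-consistent rescaling of the inputs.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import DataError

log = logging.getLogger(__name__)


@dataclass
class SlopeEstimate:
    slope: float
    se: float
    intercept: float
    intercept_se: float
    n: int
    fallback: bool = False   # True when the species-level term was dropped


@dataclass
class GroupPowerResult:
    """Group means of mass-specific power and two tests of the group effect.

    ``pvalue`` is the calibrated small-sample test (Wald t with
    between-species degrees of freedom, df = #species - 2); the asymptotic
    chi-square LRT is also reported but is anticonservative when the group
    effect is judged against only a handful of species.
    """

    means: dict               # group value -> (estimated mean, s.e.)
    pvalue: float             # Wald-t, between-species df
    lrt_stat: float
    lrt_pvalue_asymptotic: float
    n: int
    fallback: bool = False


def _fit_mixed(formula: str, df: pd.DataFrame, reml: bool = True):
    """Species + individual-within-species random intercepts, falling back
    to individual-only intercepts when the richer fit is singular."""
    df = df.reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            md = smf.mixedlm(
                formula, df, groups=df["species"],
                re_formula="1", vc_formula={"individual": "0 + C(individual)"},
            )
            res = md.fit(reml=reml, method="lbfgs")
            if res.converged and np.all(np.isfinite(res.bse_fe)):
                return res, False
        except Exception:  # singular / linalg failures fall through
            pass
        log.warning("species-level random effect singular; "
                    "falling back to individual-only random intercept")
        try:
            md = smf.mixedlm(formula, df, groups=df["individual"], re_formula="1")
            res = md.fit(reml=reml, method="lbfgs")
            if res.converged and np.all(np.isfinite(res.bse_fe)):
                return res, True
        except Exception:
            pass
        # zero random-effect variance: the mixed model degenerates to OLS
        log.warning("random-effect fits singular; using ordinary least squares")
        return smf.ols(formula, df).fit(), True


def scaling_slope(
    summaries: pd.DataFrame,
    x: str = "peak_gape_m",
    y: str = "peak_flow_speed",
    group_col: str = "lamsa",
    include_intercept: bool = True,
    log_transform: bool = False,
) -> dict:
    """Per-group gape -> flow-speed slope (+- s.e.) from one mixed model.

    Returns a dict mapping each group value to a :class:`SlopeEstimate`.
    ``log_transform`` fits on log10 of both axes (the allometric option).
    """
    df = summaries.copy()
    _require(df, [x, y, group_col, "species", "individual"])
    for g, sub in df.groupby(group_col):
        if sub["individual"].nunique() < 2:
            raise DataError(f"group {g!r} has fewer than 2 individuals")
    if log_transform:
        df[x] = np.log10(df[x])
        df[y] = np.log10(df[y])
    if include_intercept:
        formula = f"{y} ~ 0 + C({group_col}) + C({group_col}):{x}"
    else:
        formula = f"{y} ~ 0 + C({group_col}):{x}"
    res, fb = _fit_mixed(formula, df)
    out = {}
    for g in df[group_col].unique():
        sl = f"C({group_col})[{g}]:{x}"
        ic = f"C({group_col})[{g}]"
        out[g] = SlopeEstimate(
            slope=float(res.params[sl]),
            se=float(res.bse[sl]),
            intercept=float(res.params[ic]) if include_intercept else 0.0,
            intercept_se=float(res.bse[ic]) if include_intercept else 0.0,
            n=int((df[group_col] == g).sum()),
            fallback=fb,
        )
    return out


def power_group_model(
    summaries: pd.DataFrame,
    y: str = "mass_specific_power",
    group_col: str = "lamsa",
) -> GroupPowerResult:
    """Group means of mass-specific power and an LRT for the group effect."""
    df = summaries.copy()
    _require(df, [y, group_col, "species", "individual"])
    if df[group_col].nunique() < 2:
        raise DataError("need both groups to compare mass-specific power")
    res, fb = _fit_mixed(f"{y} ~ 0 + C({group_col})", df, reml=True)
    means = {}
    names = []
    for g in df[group_col].unique():
        name = f"C({group_col})[{g}]"
        names.append(name)
        means[g] = (float(res.params[name]), float(res.bse[name]))
    # group difference tested on between-species degrees of freedom
    cov = res.cov_params().loc[names, names].to_numpy()
    diff = res.params[names[1]] - res.params[names[0]]
    se_diff = float(np.sqrt(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]))
    dof = max(int(df["species"].nunique()) - 2, 1)
    pval_t = float(2 * sps.t.sf(abs(diff) / se_diff, df=dof))

    full_ml, _ = _fit_mixed(f"{y} ~ 0 + C({group_col})", df, reml=False)
    null_ml, _ = _fit_mixed(f"{y} ~ 1", df, reml=False)
    lrt = max(0.0, 2.0 * (full_ml.llf - null_ml.llf))
    return GroupPowerResult(
        means=means, pvalue=pval_t, lrt_stat=float(lrt),
        lrt_pvalue_asymptotic=float(sps.chi2.sf(lrt, df=1)),
        n=len(df), fallback=fb,
    )


def tendon_fluid_slope(
    summaries: pd.DataFrame,
    x: str = "peak_net_power_W",
    y: str = "peak_tendon_power_W",
    include_intercept: bool = True,
) -> SlopeEstimate:
    """Slope (+- s.e.) of tendon power on net suction power across strikes."""
    df = summaries.dropna(subset=[x, y]).copy()
    _require(df, [x, y, "species", "individual"])
    if len(df) < 10:
        warnings.warn(f"only {len(df)} strikes with both powers; "
                      "slope estimate will be unstable", stacklevel=2)
    formula = f"{y} ~ {x}" if include_intercept else f"{y} ~ 0 + {x}"
    res, fb = _fit_mixed(formula, df)
    return SlopeEstimate(
        slope=float(res.params[x]),
        se=float(res.bse[x]),
        intercept=float(res.params.get("Intercept", 0.0)),
        intercept_se=float(res.bse.get("Intercept", 0.0)),
        n=len(df),
        fallback=fb,
    )


def _require(df: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"summary table is missing columns: {missing}")
    if df[cols].isna().all(axis=None):
        raise DataError("summary table is empty")
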