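"""Confirmatory factor analysis reports: fit indices, CR and AVE.

Wraps the ML engine in :mod:`carescreen.sem` with the reporting layer a
survey analyst expects: chi-square against the model's df, incremental
indices against an independence baseline (free variances and means),
RMSEA with a 90% interval from inverting the noncentral chi-square, SRMR,
the standardized solution, and factor-level composite reliability (CR)
and average variance extracted (AVE).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import SurveyDesign
from .sem import ModelSpec, SemFit, baseline_chi2, fit_model, group_stats

__all__ = ["FitIndices", "CfaFit", "fit_indices", "rmsea_ci", "cr_ave",
           "fit_cfa", "model_spec_from_design"]


@dataclass(frozen=True)
class FitIndices:
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]


def rmsea_ci(
    chi2: float, df: int, n_eff: int, level: float = 0.90
) -> tuple[float, float]:
    """RMSEA interval by inverting the noncentral chi-square.

    ``n_eff`` is the denominator sample term (n - 1 for one group,
    N - #groups for multigroup fits).
    """
    lo_q = (1.0 + level) / 2.0  # 0.95
    hi_q = (1.0 - level) / 2.0  # 0.05

    def _solve(target: float) -> float:
        # find ncp with P(X2_df(ncp) <= chi2) = target
        if stats.ncx2.cdf(chi2, df, 1e-10) <= target:
            return 0.0
        hi = max(chi2, df) * 2 + 10
        while stats.ncx2.cdf(chi2, df, hi) > target:
            hi *= 2
        return optimize.brentq(
            lambda nc: stats.ncx2.cdf(chi2, df, nc) - target, 1e-10, hi
        )

    ncp_lo = _solve(lo_q)
    ncp_hi = _solve(hi_q)
    return (
        float(np.sqrt(ncp_lo / (df * n_eff))),
        float(np.sqrt(ncp_hi / (df * n_eff))),
    )


def fit_indices(
    chi2_m: float,
    df_m: int,
    chi2_b: float,
    df_b: int,
    n_eff: int,
) -> FitIndices:
    """CFI, TLI and RMSEA (with 90% CI) from test statistics.

    ``n_eff`` as in :func:`rmsea_ci`.
    """
    if df_m <= 0:
        raise ValueError("fit indices need df > 0")
    if df_b <= df_m:
        raise ValueError("baseline df must exceed model df")
    dev_m = max(chi2_m - df_m, 0.0)
    dev_b = max(chi2_b - df_b, dev_m)
    cfi = 1.0 if dev_b == 0 else 1.0 - dev_m / dev_b
    ratio_b = chi2_b / df_b
    ratio_m = chi2_m / df_m
    tli = 1.0 if ratio_b == 1.0 else (ratio_b - ratio_m) / (ratio_b - 1.0)
    cfi = float(np.clip(cfi, 0.0, 1.0))
    tli = float(np.clip(tli, 0.0, 1.0))
    rmsea = float(np.sqrt(dev_m / (df_m * n_eff)))
    return FitIndices(
        cfi=cfi, tli=tli, rmsea=rmsea,
        rmsea_ci=rmsea_ci(chi2_m, df_m, n_eff),
    )


def cr_ave(
    loadings: pd.Series,
    residuals: pd.Series,
    factor_items: Mapping[str, Sequence[str]],
) -> tuple[dict[str, float], dict[str, float]]:
    """Composite reliability and average variance extracted per factor,
    from the standardized solution."""
    cr: dict[str, float] = {}
    ave: dict[str, float] = {}
    for factor, items in factor_items.items():
        lam = loadings.loc[list(items)].to_numpy()
        psi = residuals.loc[list(items)].to_numpy()
        cr[factor] = float(lam.sum() ** 2 / (lam.sum() ** 2 + psi.sum()))
        ave[factor] = float((lam**2).sum() / len(items))
    return cr, ave


@dataclass
class CfaFit:
    """A fitted single-group confirmatory factor model, fully reported."""

    n: int
    chi2: float
    df: int
    baseline_chi2: float
    baseline_df: int
    cfi: float
    tli: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float
    loadings: pd.Series
    factor_corr: pd.DataFrame
    residuals: pd.Series
    cr: dict[str, float]
    ave: dict[str, float]
    converged: bool
    grad_norm: float
    n_iter: int
    heywood: bool

    @property
    def chi2_df_ratio(self) -> float:
        return self.chi2 / self.df


def model_spec_from_design(design: SurveyDesign, **kwargs) -> ModelSpec:
    """Three-correlated-factor (or however many the design defines)
    measurement model with simple structure."""
    factor_items = {f: design.factor_items(f) for f in design.factors}
    return ModelSpec(
        items=design.scored_items, factor_items=factor_items, **kwargs
    )


def fit_cfa(items: pd.DataFrame, design: SurveyDesign) -> CfaFit:
    """Fit the design's factor model to a reverse-recoded item matrix."""
    spec = model_spec_from_design(design)
    st = group_stats(items, spec.items)
    fit = fit_model(spec, [st])
    b_chi2, b_df = baseline_chi2(spec, [st])
    n_eff = st.n - 1
    fi = fit_indices(fit.chi2, fit.df, b_chi2, b_df, n_eff)
    loadings, phi_corr, residuals = fit.standardized()
    factors = list(spec.factors)
    cr, ave = cr_ave(loadings, residuals, spec.factor_items)
    return CfaFit(
        n=st.n,
        chi2=fit.chi2,
        df=fit.df,
        baseline_chi2=b_chi2,
        baseline_df=b_df,
        cfi=fi.cfi,
        tli=fi.tli,
        rmsea=fi.rmsea,
        rmsea_ci=fi.rmsea_ci,
        srmr=fit.srmr(),
        loadings=loadings,
        factor_corr=pd.DataFrame(phi_corr, index=factors, columns=factors),
        residuals=residuals,
        cr=cr,
        ave=ave,
        converged=fit.converged,
        grad_norm=fit.grad_norm,
        n_iter=fit.n_iter,
        heywood=fit.heywood,
    )
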