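"""Internal-consistency coefficients.

Cronbach's alpha with a Feldt-type F confidence interval, McDonald's
omega (total and hierarchical) via a higher-order factor model and the
Schmid-Leiman transform, and corrected item-total correlations.

Omega is computed on the standardized metric: a first-order confirmatory
model gives standardized loadings ``lambda_j`` and the factor correlation
matrix; a single second-order general factor is fitted to the factor
correlations, giving second-order loadings ``gamma_f``; Schmid-Leiman then
splits each item into a general loading ``g_j = lambda_j * gamma_f(j)``
and a group loading ``s_j = lambda_j * sqrt(1 - gamma_f(j)^2)``.  With
``V = (sum g)^2 + sum_f (sum_{j in f} s_j)^2 + sum psi_j``:

    omega_h = (sum g)^2 / V
    omega_t = [(sum g)^2 + sum_f (sum s)^2] / V

``omega_h`` above 0.50 is conventionally read as supporting use of a
total score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import ResponseMatrix, SurveyDesign
from .sem import ModelSpec, fit_model, group_stats

__all__ = [
    "ReliabilityReport",
    "cronbach_alpha",
    "alpha_ci",
    "item_total_correlations",
    "omega_coefficients",
    "scale_reliability",
]


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha, ``k/(k-1) * (1 - sum var_j / var(total))``."""
    arr = np.asarray(items, dtype=float)
    n, k = arr.shape
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    item_var = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("alpha undefined: zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def alpha_ci(
    alpha: float, n: int, k: int, level: float = 0.95
) -> tuple[float, float]:
    """Feldt F-distribution confidence interval for alpha."""
    if n <= 1 or k <= 1:
        raise ValueError("alpha CI needs n > 1 and k > 1")
    if alpha >= 1.0:
        return (1.0, 1.0)
    gamma = 1.0 - level
    df1, df2 = n - 1, (n - 1) * (k - 1)
    low = 1.0 - (1.0 - alpha) * stats.f.ppf(1.0 - gamma / 2.0, df1, df2)
    high = 1.0 - (1.0 - alpha) * stats.f.ppf(gamma / 2.0, df1, df2)
    return float(low), float(high)


def item_total_correlations(items: pd.DataFrame) -> pd.Series:
    """Corrected item-total correlation: each item vs the sum of the rest."""
    if items.shape[1] < 3:
        raise ValueError("corrected item-total needs at least 3 items")
    arr = items.to_numpy(float)
    total = arr.sum(axis=1)
    out = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        rest = total - arr[:, j]
        if arr[:, j].std(ddof=1) == 0 or rest.std(ddof=1) == 0:
            raise ValueError(
                f"zero variance in item {items.columns[j]!r} or its rest-score"
            )
        out[j] = np.corrcoef(arr[:, j], rest)[0, 1]
    return pd.Series(out, index=items.columns, name="r_it")


def _second_order_loadings(phi: np.ndarray) -> np.ndarray:
    """Loadings of one general factor on the first-order factors.

    Closed form for three factors; a shared loading for two; iterated
    least squares on the off-diagonals otherwise.  Clipped to [0, 0.999].
    """
    m = phi.shape[0]
    if m == 2:
        g = np.sqrt(max(phi[0, 1], 0.0))
        gamma = np.array([g, g])
    elif m == 3:
        r12, r13, r23 = phi[0, 1], phi[0, 2], phi[1, 2]
        if min(r12, r13, r23) <= 0:
            gamma = _iterated_gamma(phi)
        else:
            gamma = np.array(
                [
                    np.sqrt(r12 * r13 / r23),
                    np.sqrt(r12 * r23 / r13),
                    np.sqrt(r13 * r23 / r12),
                ]
            )
    else:
        gamma = _iterated_gamma(phi)
    return np.clip(gamma, 0.0, 0.999)


def _iterated_gamma(phi: np.ndarray, n_iter: int = 200) -> np.ndarray:
    m = phi.shape[0]
    gamma = np.full(m, np.sqrt(max(np.mean(phi[np.triu_indices(m, 1)]), 0.01)))
    for _ in range(n_iter):
        for i in range(m):
            others = [j for j in range(m) if j != i]
            denom = sum(gamma[j] ** 2 for j in others)
            if denom > 0:
                gamma[i] = sum(phi[i, j] * gamma[j] for j in others) / denom
        gamma = np.clip(gamma, 0.0, 0.999)
    return gamma


def omega_coefficients(
    items: pd.DataFrame, factor_items: Mapping[str, Sequence[str]]
) -> tuple[float, float]:
    """(omega_total, omega_hierarchical) via the higher-order route."""
    k = items.shape[1]
    if k < 6 or len(factor_items) < 2:
        raise ValueError(
            "omega needs at least 6 items and at least 2 group factors"
        )
    spec = ModelSpec(
        items=tuple(items.columns),
        factor_items={f: tuple(v) for f, v in factor_items.items()},
    )
    fit = fit_model(spec, [group_stats(items)])
    loadings, phi_corr, residuals = fit.standardized()
    gamma = _second_order_loadings(phi_corr)
    factors = list(factor_items)
    gamma_item = np.array(
        [
            gamma[factors.index(f)]
            for f in factors
            for _ in factor_items[f]
        ]
    )
    order = [i for f in factors for i in factor_items[f]]
    lam = loadings.loc[order].to_numpy()
    psi = residuals.loc[order].to_numpy()
    g = lam * gamma_item
    s = lam * np.sqrt(1.0 - gamma_item**2)
    sum_g2 = g.sum() ** 2
    group_terms = 0.0
    pos = 0
    for f in factors:
        kf = len(factor_items[f])
        group_terms += s[pos : pos + kf].sum() ** 2
        pos += kf
    v = sum_g2 + group_terms + psi.sum()
    omega_h = sum_g2 / v
    omega_t = (sum_g2 + group_terms) / v
    return float(omega_t), float(omega_h)


def _omega_total_single_factor(items: pd.DataFrame) -> float:
    """Congeneric (one-factor) omega total for a subscale."""
    cols = tuple(items.columns)
    spec = ModelSpec(items=cols, factor_items={"f": cols})
    fit = fit_model(spec, [group_stats(items)])
    loadings, _, residuals = fit.standardized()
    lam = loadings.to_numpy()
    psi = residuals.to_numpy()
    return float(lam.sum() ** 2 / (lam.sum() ** 2 + psi.sum()))


@dataclass(frozen=True)
class ReliabilityReport:
    """Per-scale internal-consistency summary."""

    scale: str
    k: int
    n: int
    alpha: float
    alpha_ci: tuple[float, float]
    omega_t: float | None = None
    omega_h: float | None = None

    @property
    def ratio_h_t(self) -> float | None:
        if self.omega_h is None or self.omega_t in (None, 0.0):
            return None
        return self.omega_h / self.omega_t


def scale_reliability(
    matrix: ResponseMatrix, design: SurveyDesign, level: float = 0.95
) -> dict[str, ReliabilityReport]:
    """Alpha (+CI) and omega for the total scale and each subscale.

    The matrix must already be reverse-recoded.  The total scale gets the
    hierarchical omega decomposition (general + group factors); subscales
    get a congeneric omega total only.
    """
    reports: dict[str, ReliabilityReport] = {}
    total_items = matrix.items(design.scored_items)
    n = len(total_items)
    a = cronbach_alpha(total_items)
    factor_items = {f: design.factor_items(f) for f in design.factors}
    omega_t = omega_h = None
    if len(design.factors) >= 2 and total_items.shape[1] >= 6:
        omega_t, omega_h = omega_coefficients(total_items, factor_items)
    reports["total"] = ReliabilityReport(
        scale="total",
        k=total_items.shape[1],
        n=n,
        alpha=a,
        alpha_ci=alpha_ci(a, n, total_items.shape[1], level),
        omega_t=omega_t,
        omega_h=omega_h,
    )
    for factor in design.factors:
        block = matrix.items(design.factor_items(factor))
        a_f = cronbach_alpha(block)
        reports[factor] = ReliabilityReport(
            scale=factor,
            k=block.shape[1],
            n=n,
            alpha=a_f,
            alpha_ci=alpha_ci(a_f, n, block.shape[1], level),
            omega_t=_omega_total_single_factor(block),
            omega_h=None,
        )
    return reports
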