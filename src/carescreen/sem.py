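"""Maximum-likelihood covariance-structure engine.

Implements the confirmatory factor model

    Sigma(theta) = Lambda Phi Lambda' + Psi,      mu(theta) = nu + Lambda alpha

estimated by minimizing the normal-theory discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) + (xbar - mu)' Sigma^-1 (xbar - mu)
           - ln|S| - p

(the mean term is present only when a mean structure is requested).  The
model is identified by fixing the first indicator loading of each factor
to 1.0; factor covariances are parameterized through a Cholesky factor so
the optimizer cannot leave the positive-definite cone, and residual
variances are bounded below at 0.001 (a Heywood diagnostic is recorded
when any residual sits on that bound).

Multiple groups are supported with optional cross-group equality
constraints on loadings and intercepts, which is everything the
configural / metric / scalar invariance ladder needs.  The test statistic
is ``chi2 = sum_g (n_g - 1) F_g`` at the optimum.

Analytic gradients drive a quasi-Newton (L-BFGS-B) search; start values
follow the conventions documented in :func:`start_values` and up to three
jittered restarts (fixed jitter seed) are attempted on non-convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["ModelSpec", "GroupStats", "SemFit", "group_stats", "fit_model",
           "baseline_chi2"]

PSI_FLOOR = 1e-3
# factor-scale floor, relative to the typical item sd: keeps a group's
# factor variance away from exact collapse, which would leave that
# group's loadings on a flat manifold and stall any gradient method.
# The implied minimum common variance (~0.25% of an item variance) is
# negligible for fit statistics.
CHOL_DIAG_REL_FLOOR = 0.05
GRAD_TOL = 1e-5
# a fit whose function value has plateaued but whose projected gradient
# sits between GRAD_TOL and GRAD_TOL_FLAT is treated as a boundary
# solution
GRAD_TOL_FLAT = 5e-3
JITTER_SEED = 20250


@dataclass(frozen=True)
class ModelSpec:
    """Structure of a (possibly multigroup) confirmatory factor model."""

    items: tuple[str, ...]
    factor_items: Mapping[str, tuple[str, ...]]
    n_groups: int = 1
    mean_structure: bool = False
    equal_loadings: bool = False
    equal_intercepts: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(
            self,
            "factor_items",
            {f: tuple(v) for f, v in self.factor_items.items()},
        )
        assigned = [i for v in self.factor_items.values() for i in v]
        if sorted(assigned) != sorted(self.items):
            raise ValueError("factor_items must partition items")
        for f, v in self.factor_items.items():
            if len(v) < 2:
                raise ValueError(
                    f"factor {f!r} has {len(v)} indicator(s); the model is "
                    "underidentified with fewer than 2"
                )
        if self.equal_intercepts and not self.mean_structure:
            raise ValueError("equal_intercepts requires a mean structure")

    @property
    def p(self) -> int:
        return len(self.items)

    @property
    def m(self) -> int:
        return len(self.factor_items)

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(self.factor_items)

    def free_loadings(self) -> list[tuple[int, int]]:
        """(item index, factor index) of every free loading."""
        out = []
        item_pos = {it: j for j, it in enumerate(self.items)}
        for fi, f in enumerate(self.factors):
            for it in self.factor_items[f][1:]:
                out.append((item_pos[it], fi))
        return out

    def marker_loadings(self) -> list[tuple[int, int]]:
        item_pos = {it: j for j, it in enumerate(self.items)}
        return [
            (item_pos[self.factor_items[f][0]], fi)
            for fi, f in enumerate(self.factors)
        ]

    def n_free_parameters(self) -> int:
        n_load_sets = 1 if self.equal_loadings else self.n_groups
        n = len(self.free_loadings()) * n_load_sets
        n += self.n_groups * (self.m * (self.m + 1) // 2)  # Phi
        n += self.n_groups * self.p  # Psi
        if self.mean_structure:
            n += self.p if self.equal_intercepts else self.n_groups * self.p
            if self.equal_intercepts:
                n += self.m * (self.n_groups - 1)  # free factor means
        return n

    def df(self) -> int:
        moments = self.p * (self.p + 1) // 2
        if self.mean_structure:
            moments += self.p
        return moments * self.n_groups - self.n_free_parameters()


@dataclass(frozen=True)
class GroupStats:
    """Sufficient statistics of one group."""

    n: int
    cov: np.ndarray     # unbiased (n - 1 denominator) sample covariance
    mean: np.ndarray
    logdet_cov: float


def group_stats(data: pd.DataFrame | np.ndarray, items: Sequence[str] | None = None) -> GroupStats:
    if isinstance(data, pd.DataFrame):
        arr = data[list(items)].to_numpy(float) if items else data.to_numpy(float)
    else:
        arr = np.asarray(data, float)
    n, p = arr.shape
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    cov = np.cov(arr, rowvar=False, ddof=1)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("sample covariance matrix is not positive-definite")
    return GroupStats(n=n, cov=cov, mean=arr.mean(axis=0), logdet_cov=logdet)


# ---------------------------------------------------------------------------
# Parameter vector layout
# ---------------------------------------------------------------------------


class _Layout:
    """Maps the flat parameter vector onto per-group model matrices."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        p, m, G = spec.p, spec.m, spec.n_groups
        self.free_load = spec.free_loadings()
        self.markers = spec.marker_loadings()
        nl = len(self.free_load)
        ntri = m * (m + 1) // 2
        self.tril_idx = np.tril_indices(m)

        cursor = 0
        self.load_slices: list[slice] = []
        n_load_sets = 1 if spec.equal_loadings else G
        for _ in range(n_load_sets):
            self.load_slices.append(slice(cursor, cursor + nl))
            cursor += nl
        self.chol_slices: list[slice] = []
        for _ in range(G):
            self.chol_slices.append(slice(cursor, cursor + ntri))
            cursor += ntri
        self.psi_slices: list[slice] = []
        for _ in range(G):
            self.psi_slices.append(slice(cursor, cursor + p))
            cursor += p
        self.nu_slices: list[slice] = []
        self.alpha_slices: list[slice | None] = []
        if spec.mean_structure:
            n_nu_sets = 1 if spec.equal_intercepts else G
            for _ in range(n_nu_sets):
                self.nu_slices.append(slice(cursor, cursor + p))
                cursor += p
            for g in range(G):
                if g > 0 and spec.equal_intercepts:
                    self.alpha_slices.append(slice(cursor, cursor + m))
                    cursor += m
                else:
                    self.alpha_slices.append(None)
        self.n_params = cursor

    def load_slice(self, g: int) -> slice:
        return self.load_slices[0 if self.spec.equal_loadings else g]

    def nu_slice(self, g: int) -> slice:
        return self.nu_slices[0 if self.spec.equal_intercepts else g]

    def bounds(
        self, item_sd: float = 1.0
    ) -> list[tuple[float | None, float | None]]:
        b: list[tuple[float | None, float | None]] = [(None, None)] * self.n_params
        m = self.spec.m
        diag_floor = CHOL_DIAG_REL_FLOOR * item_sd
        diag_pos = {self._tri_pos(i, i) for i in range(m)}
        for sl in self.chol_slices:
            for k in range(sl.stop - sl.start):
                if k in diag_pos:
                    b[sl.start + k] = (diag_floor, None)
        for sl in self.psi_slices:
            for k in range(sl.stop - sl.start):
                b[sl.start + k] = (PSI_FLOOR, None)
        return b

    def _tri_pos(self, i: int, j: int) -> int:
        rows, cols = self.tril_idx
        for k in range(len(rows)):
            if rows[k] == i and cols[k] == j:
                return k
        raise IndexError

    # -- matrix construction ----------------------------------------------

    def matrices(self, theta: np.ndarray, g: int):
        spec = self.spec
        p, m = spec.p, spec.m
        lam = np.zeros((p, m))
        for (i, f) in self.markers:
            lam[i, f] = 1.0
        free = theta[self.load_slice(g)]
        for (i, f), v in zip(self.free_load, free):
            lam[i, f] = v
        L = np.zeros((m, m))
        L[self.tril_idx] = theta[self.chol_slices[g]]
        phi = L @ L.T
        psi = theta[self.psi_slices[g]]
        nu = alpha = None
        if spec.mean_structure:
            nu = theta[self.nu_slice(g)]
            sl = self.alpha_slices[g]
            alpha = theta[sl] if sl is not None else np.zeros(m)
        return lam, L, phi, psi, nu, alpha


# ---------------------------------------------------------------------------
# Objective and gradient
# ---------------------------------------------------------------------------


def _discrepancy(layout: _Layout, theta: np.ndarray, stats: Sequence[GroupStats]):
    """Weighted discrepancy ``sum_g (n_g - 1) F_g`` and its gradient."""
    spec = layout.spec
    total = 0.0
    grad = np.zeros_like(theta)
    for g, st in enumerate(stats):
        lam, L, phi, psi, nu, alpha = layout.matrices(theta, g)
        sigma = lam @ phi @ lam.T + np.diag(psi)
        try:
            c = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return np.inf, grad
        sigma_inv = np.linalg.inv(sigma)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        f = logdet + float(np.sum(sigma_inv * st.cov)) - st.logdet_cov - spec.p
        d = None
        if spec.mean_structure:
            mu = nu + lam @ alpha
            d = st.mean - mu
            sid = sigma_inv @ d
            f += float(d @ sid)
        w = st.n - 1
        total += w * f

        # dF = tr(E dSigma) - 2 d' Sigma^-1 dmu
        E = sigma_inv - sigma_inv @ st.cov @ sigma_inv
        if d is not None:
            E -= np.outer(sid, sid)
        g_lam = 2.0 * E @ lam @ phi
        if d is not None:
            g_lam += np.outer(-2.0 * sid, alpha)
        g_phi = lam.T @ E @ lam
        g_L = 2.0 * g_phi @ L
        g_psi = np.diag(E).copy()

        free_idx = layout.load_slice(g)
        g_free = np.array([g_lam[i, f_] for (i, f_) in layout.free_load])
        grad[free_idx] += w * g_free
        grad[layout.chol_slices[g]] += w * g_L[layout.tril_idx]
        grad[layout.psi_slices[g]] += w * g_psi
        if d is not None:
            g_nu = -2.0 * sid
            grad[layout.nu_slice(g)] += w * g_nu
            sl = layout.alpha_slices[g]
            if sl is not None:
                grad[sl] += w * (lam.T @ g_nu)
    return total, grad


# ---------------------------------------------------------------------------
# Start values and fitting
# ---------------------------------------------------------------------------


def start_values(layout: _Layout, stats: Sequence[GroupStats]) -> np.ndarray:
    """Conventional start values.

    Marker loadings are fixed at 1; free loadings start at the ratio of
    the item's sd to the marker's sd; factor variances at 0.49 * var of
    the marker item; factor covariances at 0.3 of the variance geometric
    mean; residual variances at half the item variance; intercepts at the
    sample means; free factor means at 0.
    """
    spec = layout.spec
    theta = np.zeros(layout.n_params)
    pooled_var = np.mean([np.diag(st.cov) for st in stats], axis=0)
    pooled_mean = np.mean([st.mean for st in stats], axis=0)

    marker_var = np.empty(spec.m)
    for (i, f) in layout.markers:
        marker_var[f] = pooled_var[i]

    for sl in layout.load_slices:
        vals = [
            np.sqrt(pooled_var[i] / marker_var[f])
            for (i, f) in layout.free_load
        ]
        theta[sl] = vals
    phi0 = np.empty((spec.m, spec.m))
    for a in range(spec.m):
        for b in range(spec.m):
            if a == b:
                phi0[a, a] = 0.49 * marker_var[a]
            else:
                phi0[a, b] = 0.3 * np.sqrt(
                    0.49 * marker_var[a] * 0.49 * marker_var[b]
                )
    L0 = np.linalg.cholesky(phi0)
    for g, sl in enumerate(layout.chol_slices):
        theta[sl] = L0[layout.tril_idx]
    for g, sl in enumerate(layout.psi_slices):
        var_g = np.diag(stats[min(g, len(stats) - 1)].cov)
        theta[sl] = np.maximum(0.5 * var_g, 2 * PSI_FLOOR)
    if spec.mean_structure:
        for sl in layout.nu_slices:
            theta[sl] = pooled_mean
    return theta


@dataclass
class SemFit:
    """A fitted covariance-structure model."""

    spec: ModelSpec
    stats: tuple[GroupStats, ...]
    theta: np.ndarray
    chi2: float
    df: int
    converged: bool
    grad_norm: float
    n_iter: int
    n_restarts: int
    heywood: bool
    _layout: _Layout = field(repr=False)

    @property
    def n_total(self) -> int:
        return sum(st.n for st in self.stats)

    def matrices(self, g: int = 0):
        """(Lambda, Phi, psi, nu, alpha) for group ``g`` (raw metric)."""
        lam, _, phi, psi, nu, alpha = self._layout.matrices(self.theta, g)
        return lam, phi, psi, nu, alpha

    def implied_cov(self, g: int = 0) -> np.ndarray:
        lam, phi, psi, *_ = self.matrices(g)
        return lam @ phi @ lam.T + np.diag(psi)

    def standardized(self, g: int = 0):
        """Standardized loadings (per item), factor correlations and
        standardized residual variances for group ``g``."""
        lam, phi, psi, *_ = self.matrices(g)
        sigma = lam @ phi @ lam.T + np.diag(psi)
        sd_item = np.sqrt(np.diag(sigma))
        sd_fact = np.sqrt(np.diag(phi))
        lam_std_mat = lam * sd_fact[None, :] / sd_item[:, None]
        lam_std = lam_std_mat.sum(axis=1)  # one loading per item (simple model)
        phi_corr = phi / np.outer(sd_fact, sd_fact)
        psi_std = psi / np.diag(sigma)
        loadings = pd.Series(lam_std, index=list(self.spec.items), name="loading")
        return loadings, phi_corr, pd.Series(
            psi_std, index=list(self.spec.items), name="residual"
        )

    def srmr(self) -> float:
        """Root mean square standardized residual, lower triangle with
        diagonal, (n_g - 1)-weighted across groups."""
        num = 0.0
        den = 0.0
        tri = np.tril_indices(self.spec.p)
        for g, st in enumerate(self.stats):
            sd = np.sqrt(np.diag(st.cov))
            scale = np.outer(sd, sd)
            resid = (st.cov - self.implied_cov(g)) / scale
            w = st.n - 1
            num += w * float((resid[tri] ** 2).mean())
            den += w
        return float(np.sqrt(num / den))


def baseline_chi2(spec: ModelSpec, stats: Sequence[GroupStats]) -> tuple[float, int]:
    """Independence baseline (free variances, free means): closed form.

    The MLE under independence is ``Sigma = diag(S)``, ``mu = xbar``, so
    ``F_b = sum_j ln S_jj - ln|S|`` per group.
    """
    chi2 = 0.0
    for st in stats:
        f = float(np.log(np.diag(st.cov)).sum()) - st.logdet_cov
        chi2 += (st.n - 1) * f
    p = spec.p
    df = len(stats) * (p * (p - 1) // 2)
    return chi2, df


def fit_model(
    spec: ModelSpec,
    stats: Sequence[GroupStats],
    max_restarts: int = 3,
    maxiter: int = 4000,
) -> SemFit:
    """Fit the model by quasi-Newton minimization with analytic gradients."""
    if len(stats) != spec.n_groups:
        raise ValueError("number of group statistics must match n_groups")
    if spec.df() < 0:
        raise ValueError(
            f"model is underidentified (df = {spec.df()} < 0)"
        )
    layout = _Layout(spec)
    n_scale = sum(st.n - 1 for st in stats)

    def objective(theta: np.ndarray):
        t, g = _discrepancy(layout, theta, stats)
        return t / n_scale, g / n_scale

    theta0 = start_values(layout, stats)
    typical_sd = float(
        np.sqrt(np.median(np.mean([np.diag(st.cov) for st in stats], axis=0)))
    )
    bounds = layout.bounds(typical_sd)
    rng = np.random.default_rng(JITTER_SEED)

    def solve(start):
        """One L-BFGS-B run plus Hessian-resetting polish passes."""
        res = optimize.minimize(
            objective, start, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-9,
                     "maxcor": 40},
        )
        gnorm = float(
            np.max(np.abs(_project_gradient(objective(res.x)[1], res.x,
                                            bounds)))
        )
        last_improvement = np.inf
        for _ in range(6):
            if gnorm <= GRAD_TOL:
                break
            res2 = optimize.minimize(
                objective, res.x, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-10,
                         "maxcor": 40},
            )
            new_gnorm = float(
                np.max(np.abs(_project_gradient(objective(res2.x)[1],
                                                res2.x, bounds)))
            )
            last_improvement = res.fun - res2.fun
            if res2.fun <= res.fun:
                res, gnorm = res2, new_gnorm
            if last_improvement <= 1e-8 * (1.0 + abs(res.fun)):
                break
        plateaued = last_improvement <= 1e-8 * (1.0 + abs(res.fun))
        ok = gnorm <= GRAD_TOL or (plateaued and gnorm <= GRAD_TOL_FLAT)
        return res, gnorm, ok

    best = None
    n_attempt = 0
    for attempt in range(max_restarts + 1):
        n_attempt = attempt
        start = theta0
        if attempt > 0:
            start = theta0 + rng.normal(0, 0.05 * (np.abs(theta0) + 0.1))
            start = np.array(
                [
                    np.clip(v, lo if lo is not None else -np.inf,
                            hi if hi is not None else np.inf)
                    for v, (lo, hi) in zip(start, bounds)
                ]
            )
        res, gnorm, ok = solve(start)
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm, ok)
        if ok:
            best = (res, gnorm, ok)
            break
    res, gnorm, ok = best
    chi2 = float(res.fun * n_scale)
    psi_on_floor = any(
        np.any(res.x[sl] <= PSI_FLOOR * 1.001) for sl in layout.psi_slices
    )
    return SemFit(
        spec=spec,
        stats=tuple(stats),
        theta=res.x,
        chi2=max(chi2, 0.0),
        df=spec.df(),
        converged=ok,
        grad_norm=gnorm,
        n_iter=int(res.nit),
        n_restarts=n_attempt,
        heywood=psi_on_floor,
        _layout=layout,
    )


def _project_gradient(grad, theta, bounds):
    """Zero out gradient components pushing against an active bound."""
    out = grad.copy()
    for k, (lo, hi) in enumerate(bounds):
        if lo is not None and theta[k] <= lo + 1e-10 and grad[k] > 0:
            out[k] = 0.0
        if hi is not None and theta[k] >= hi - 1e-10 and grad[k] < 0:
            out[k] = 0.0
    return out
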