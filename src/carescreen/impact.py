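"""Unscreened-vs-screened impact analysis.

The screened sample is nested inside the unscreened sample, so comparing
their means with an independent-samples test is inappropriate.  Instead,
the nested permutation test randomly reassigns the careless label to the
same number of respondents and asks how often the resulting
full-vs-subsample mean difference is at least as extreme as the observed
one.  Alongside it live the classical tools for comparing samples:
Fisher's z for correlations with Cohen's q, Cohen's d with a normal-
approximation CI and the Welch t, and the minimum detectable effect for a
given design.

Item-level vulnerability is ranked with the Composite Sensitivity Index

    CSI = |dM| + |dr| + |dlambda|

summing, per item, the absolute change between two parallel samples in
the item mean (recoded metric), the corrected item-total correlation, and
the standardized factor loading.  CSI-z standardizes each component
across items before summation so that no component dominates by virtue of
its scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cfa import fit_cfa
from .design import SurveyDesign
from .reliability import item_total_correlations

__all__ = [
    "PermutationResult",
    "CorrelationComparison",
    "EffectSize",
    "permutation_nested_mean_test",
    "fisher_q_compare",
    "cohens_d",
    "min_detectable_d",
    "compute_item_stats",
    "csi_compute",
    "csi_z",
    "rank_agreement",
    "top_k_report",
    "q_label",
    "d_label",
]

DEFAULT_B = 10_000
DEFAULT_SEED = 2025
EXHAUSTIVE_CAP = 500_000


# ---------------------------------------------------------------------------
# Nested permutation test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermutationResult:
    observed_delta: float
    p_two_sided: float
    iterations: int
    seed: int | None
    exhaustive: bool


def permutation_nested_mean_test(
    scores: pd.Series | np.ndarray,
    flags: pd.Series | np.ndarray,
    B: int = DEFAULT_B,
    seed: int = DEFAULT_SEED,
    exhaustive_cap: int = EXHAUSTIVE_CAP,
) -> PermutationResult:
    """Permutation test for a full-sample vs nested-subsample mean shift.

    ``observed_delta = mean(all) - mean(unflagged)``.  Each iteration
    reassigns the flag to the same number of respondents drawn without
    replacement and recomputes the difference; the two-sided p-value is
    the plain proportion of permuted |differences| at least as large as
    the observed |difference| (no +1 smoothing).  When ``C(N, k)`` does
    not exceed ``exhaustive_cap`` all reassignments are enumerated and
    the p-value is exact.
    """
    x = np.asarray(scores, dtype=float)
    f = np.asarray(flags, dtype=bool)
    n = len(x)
    k = int(f.sum())
    if k == 0 or k == n:
        raise ValueError("permutation test needs 0 < #flagged < N")
    mean_all = x.mean()
    total = x.sum()
    observed = mean_all - (total - x[f].sum()) / (n - k)

    n_comb = math.comb(n, k)
    tol = 1e-12 * (1.0 + abs(observed))
    if n_comb <= exhaustive_cap:
        deltas = np.empty(n_comb)
        for i, idx in enumerate(combinations(range(n), k)):
            deltas[i] = mean_all - (total - x[list(idx)].sum()) / (n - k)
        p = float((np.abs(deltas) >= abs(observed) - tol).mean())
        return PermutationResult(float(observed), p, n_comb, None, True)

    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(B, 2_000_000 // max(n, 1)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        flagged_sums = x[idx].sum(axis=1)
        deltas = mean_all - (total - flagged_sums) / (n - k)
        count += int((np.abs(deltas) >= abs(observed) - tol).sum())
        done += b
    return PermutationResult(float(observed), count / B, B, seed, False)


# ---------------------------------------------------------------------------
# Correlation and mean-difference effect sizes
# ---------------------------------------------------------------------------


def q_label(q: float) -> str:
    """Cohen's q bins; boundary values fall in the lower bin."""
    if q <= 0.10:
        return "negligible"
    if q <= 0.30:
        return "small"
    if q <= 0.50:
        return "medium"
    return "large"


def d_label(d: float) -> str:
    """Cohen's d bins; boundary values fall in the lower bin."""
    a = abs(d)
    if a <= 0.20:
        return "negligible"
    if a <= 0.50:
        return "small"
    if a <= 0.80:
        return "medium"
    return "large"


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    r2: float
    n1: int
    n2: int
    fisher_z: float
    p: float
    cohens_q: float
    q_label: str


def fisher_q_compare(
    r1: float, n1: int, r2: float, n2: int
) -> CorrelationComparison:
    """Fisher z-test for two correlations plus Cohen's q.

    The independent-samples formula is applied exactly as reported
    practice applies it to unscreened-vs-screened comparisons, even
    though the screened sample is nested in the unscreened one; with
    overlapping samples the p-value is approximate.
    """
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("correlations must be strictly inside (-1, 1)")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher z needs n > 3 in both samples")
    diff = math.atanh(r1) - math.atanh(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = diff / se
    p = 2.0 * stats.norm.sf(abs(z))
    q = abs(diff)
    return CorrelationComparison(r1, r2, n1, n2, z, float(p), q, q_label(q))


@dataclass(frozen=True)
class EffectSize:
    cohens_d: float
    ci: tuple[float, float]
    welch_t: float
    welch_df: float
    welch_p: float
    label: str
    n1: int
    n2: int


def cohens_d(
    group1: pd.Series | np.ndarray, group2: pd.Series | np.ndarray,
    level: float = 0.95,
) -> EffectSize:
    """Cohen's d (pooled sd) with a normal-approximation CI, plus Welch t."""
    x1 = np.asarray(group1, float)
    x2 = np.asarray(group2, float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if pooled == 0:
        raise ValueError("zero pooled variance")
    d = (x1.mean() - x2.mean()) / math.sqrt(pooled)
    se = math.sqrt(1.0 / n1 + 1.0 / n2 + d**2 / (2.0 * (n1 + n2)))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    welch = stats.ttest_ind(x1, x2, equal_var=False)
    welch_df = (v1 / n1 + v2 / n2) ** 2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    return EffectSize(
        cohens_d=float(d),
        ci=(float(d - zq * se), float(d + zq * se)),
        welch_t=float(welch.statistic),
        welch_df=float(welch_df),
        welch_p=float(welch.pvalue),
        label=d_label(d),
        n1=n1,
        n2=n2,
    )


def min_detectable_d(
    n1: int, n2: int, alpha: float = 0.05, power: float = 0.80
) -> float:
    """Smallest standardized mean difference a two-sided two-sample t-test
    detects with the given power, from the noncentral-t power function."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    df = n1 + n2 - 2
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)

    def achieved(d: float) -> float:
        ncp = d * math.sqrt(n1 * n2 / (n1 + n2))
        upper = stats.nct.sf(t_crit, df, ncp)
        lower = stats.nct.cdf(-t_crit, df, ncp)
        if not np.isfinite(lower):  # vanishes for large ncp
            lower = 0.0
        return float(upper + lower)

    hi = 0.5
    while achieved(hi) < power:
        hi *= 2.0
    return float(optimize.brentq(lambda d: achieved(d) - power, 1e-9, hi))


# ---------------------------------------------------------------------------
# Composite Sensitivity Index
# ---------------------------------------------------------------------------


def compute_item_stats(
    items: pd.DataFrame, design: SurveyDesign, loadings: pd.Series | None = None
) -> pd.DataFrame:
    """Per-item mean (recoded metric), corrected item-total correlation
    and standardized loading for one analysis sample.

    ``loadings`` from an already-fitted model may be passed to avoid a
    refit; otherwise the design's factor model is fitted here.
    """
    block = items[list(design.scored_items)]
    if loadings is None:
        loadings = fit_cfa(block, design).loadings
    return pd.DataFrame(
        {
            "M": block.mean(axis=0),
            "r_it": item_total_correlations(block),
            "loading": loadings.reindex(block.columns),
        }
    )


def _item_meta(design: SurveyDesign, items: pd.Index) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "factor": [design.factor_map[i] for i in items],
            "item_type": [
                "reverse" if i in design.reverse_set else "standard"
                for i in items
            ],
            "position": [design.position(i) for i in items],
        },
        index=items,
    )


def csi_compute(
    stats_uns: pd.DataFrame,
    stats_scr: pd.DataFrame,
    design: SurveyDesign | None = None,
) -> pd.DataFrame:
    """Composite Sensitivity Index table from two parallel item-stat
    tables (columns M, r_it, loading; one row per item).

    Components are absolute differences, the CSI their unweighted sum;
    the result is symmetric in the two samples.  Ranks (1 = most
    sensitive) break ties by presentation position when a design is
    given, by table order otherwise.
    """
    if set(stats_uns.index) != set(stats_scr.index):
        raise ValueError("item sets differ between the two samples")
    scr = stats_scr.reindex(stats_uns.index)
    table = pd.DataFrame(index=stats_uns.index)
    table["dM"] = (stats_uns["M"] - scr["M"]).abs()
    table["dr"] = (stats_uns["r_it"] - scr["r_it"]).abs()
    table["dlam"] = (stats_uns["loading"] - scr["loading"]).abs()
    table["CSI"] = table["dM"] + table["dr"] + table["dlam"]
    if design is not None:
        if design.instructed_item in table.index:
            raise ValueError("instructed item must not enter the CSI table")
        table = table.join(_item_meta(design, table.index))
        tiebreak = table["position"]
    else:
        tiebreak = pd.Series(range(len(table)), index=table.index)
    # deterministic ranks: sort by CSI descending, earlier position first
    sorter = sorted(
        table.index, key=lambda i: (-table.at[i, "CSI"], tiebreak.at[i])
    )
    ranks = pd.Series(
        {item: r + 1 for r, item in enumerate(sorter)}, name="rank"
    )
    table["rank"] = ranks
    return table


def csi_z(table: pd.DataFrame) -> pd.DataFrame:
    """Add the standardized index CSI_z (per-component z-scores summed
    across items) and its rank."""
    if len(table) < 3:
        raise ValueError("CSI_z needs at least 3 items")
    out = table.copy()
    zsum = pd.Series(0.0, index=table.index)
    for comp in ("dM", "dr", "dlam"):
        sd = table[comp].std(ddof=1)
        if sd <= 1e-12 * max(1.0, float(table[comp].abs().max())):
            raise ValueError(
                f"CSI_z undefined: component {comp!r} has zero variance "
                "across items"
            )
        zsum += (table[comp] - table[comp].mean()) / sd
    out["CSI_z"] = zsum
    tiebreak = (
        out["position"]
        if "position" in out
        else pd.Series(range(len(out)), index=out.index)
    )
    sorter = sorted(
        out.index, key=lambda i: (-out.at[i, "CSI_z"], tiebreak.at[i])
    )
    out["rank_z"] = pd.Series(
        {item: r + 1 for r, item in enumerate(sorter)}
    )
    return out


def rank_agreement(
    r1: pd.Series | np.ndarray, r2: pd.Series | np.ndarray
) -> dict[str, float]:
    """Spearman's rho and Kendall's tau-b between two rankings/scores."""
    a = np.asarray(r1, float)
    b = np.asarray(r2, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("rank agreement needs equal-length vectors, n >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("rank agreement undefined for constant input")
    rho, rho_p = stats.spearmanr(a, b)
    tau, tau_p = stats.kendalltau(a, b, variant="b")
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "kendall_tau_b": float(tau),
        "kendall_p": float(tau_p),
    }


def top_k_report(table: pd.DataFrame, k: int = 10) -> dict:
    """Items with the highest CSI, plus the reverse-item share among them.

    Ties break by presentation position (earlier item first).  When the
    table carries positions, the item immediately after the largest gap in
    positions — i.e. the item following the instructed slot — is noted.
    """
    if k > len(table):
        raise ValueError("k exceeds the number of items")
    ordered = table.sort_values("rank").index[:k]
    out: dict = {"top_items": list(ordered)}
    if "item_type" in table:
        n_rev = int((table.loc[ordered, "item_type"] == "reverse").sum())
        out["n_reverse_in_top_k"] = n_rev
        out["n_reverse_total"] = int((table["item_type"] == "reverse").sum())
    if "position" in table:
        pos = table["position"].sort_values()
        gaps = pos.diff()
        if (gaps > 1).any():
            after_gap = gaps[gaps > 1].index[0]
            out["item_after_instructed"] = after_gap
            out["item_after_instructed_rank"] = int(
                table.at[after_gap, "rank"]
            )
    return out
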