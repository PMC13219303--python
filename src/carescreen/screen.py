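"""Careless-responding indicators and sample partitioning.

Three indicators are computed per respondent:

* **instructed-item check** — failed when the response to the embedded
  attention check differs from the required category (the primary careless
  definition);
* **longstring** — the maximum run of consecutive identical responses over
  the full battery in presentation order, on the raw (non-recoded) values;
* **even-odd consistency** — within each factor, the mean of odd-position
  and even-position items is formed; the respondent's Pearson correlation
  across the factor (odd, even) pairs is Spearman-Brown stepped up and the
  index reported is ``1 - r_sb``, so 0 means perfectly consistent and 2
  maximally inconsistent.

The *extended* careless definition is the union: instructed failure OR
longstring at/above ``mean + 2 sd`` OR even-odd at/above ``mean + 2 sd``,
with both cuts estimated on the unscreened sample.  A univariate outlier
pre-screen on standardized total scores (``|z| > 4`` by default) is also
provided; it runs before careless screening and is conceptually distinct
from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    AnalysisSample,
    ResponseMatrix,
    SurveyDesign,
    recode_reverse,
    scale_scores,
)

__all__ = [
    "ScreenResult",
    "flag_instructed",
    "longstring_index",
    "evenodd_index",
    "outlier_flag",
    "extended_flags",
    "split_samples",
    "screen_study",
]

logger = logging.getLogger(__name__)

MAX_INCONSISTENCY = 2.0


@dataclass
class ScreenResult:
    """Per-respondent indicator values, flags, and the thresholds used."""

    table: pd.DataFrame  # instructed_fail, longstring, evenodd, flags
    longstring_cut: float
    evenodd_cut: float
    z_cut: float

    @property
    def flag_primary(self) -> pd.Series:
        return self.table["flag_primary"]

    @property
    def flag_extended(self) -> pd.Series:
        return self.table["flag_extended"]

    def prevalence(self, definition: str = "primary") -> float:
        """Fraction flagged, as a percentage of the sample."""
        flags = self.table[f"flag_{definition}"]
        return 100.0 * float(flags.mean())

    def thresholds(self) -> dict[str, float]:
        return {
            "longstring_cut": self.longstring_cut,
            "evenodd_cut": self.evenodd_cut,
            "z_cut": self.z_cut,
        }


def flag_instructed(matrix: ResponseMatrix, design: SurveyDesign) -> pd.Series:
    """True where the instructed item was answered with anything other
    than the required category."""
    if design.instructed_item is None:
        raise ValueError("design has no instructed item")
    if design.instructed_item not in matrix.data.columns:
        raise ValueError(
            f"instructed item column {design.instructed_item!r} absent"
        )
    col = matrix.data[design.instructed_item]
    flags = col != design.required_category
    flags.name = "instructed_fail"
    return flags


def longstring_index(matrix: ResponseMatrix) -> pd.Series:
    """Maximum run length of identical adjacent responses per respondent,
    over all columns in presentation order, on raw values."""
    values = matrix.data.to_numpy()
    if values.shape[1] < 1:
        raise ValueError("longstring needs at least one item")
    n, p = values.shape
    runs = np.ones(n, dtype=np.int64)
    best = np.ones(n, dtype=np.int64)
    for j in range(1, p):
        same = values[:, j] == values[:, j - 1]
        runs = np.where(same, runs + 1, 1)
        np.maximum(best, runs, out=best)
    return pd.Series(best, index=matrix.data.index, name="longstring")


def _half_means(
    matrix: ResponseMatrix, design: SurveyDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Per-factor odd-position and even-position item means (n x F)."""
    odd_means = []
    even_means = []
    for factor in design.factors:
        items = design.factor_items(factor)
        odd = [items[i] for i in range(0, len(items), 2)]
        even = [items[i] for i in range(1, len(items), 2)]
        odd_means.append(matrix.items(odd).mean(axis=1).to_numpy())
        even_means.append(matrix.items(even).mean(axis=1).to_numpy())
    return np.column_stack(odd_means), np.column_stack(even_means)


def evenodd_index(matrix: ResponseMatrix, design: SurveyDesign) -> pd.Series:
    """Even-odd inconsistency score, higher = more inconsistent.

    Requires a reverse-recoded matrix and at least three factors (the
    correlation runs across factor half-pairs).  Respondents whose
    half-mean vectors have zero variance (e.g. pure straightliners) get
    the maximal score 2; an undefined correlation must not reward the very
    behavior the index exists to catch.
    """
    if len(design.factors) < 3:
        raise ValueError("even-odd index needs at least 3 factors")
    odd, even = _half_means(matrix, design)
    odd_c = odd - odd.mean(axis=1, keepdims=True)
    even_c = even - even.mean(axis=1, keepdims=True)
    s_odd = np.sqrt((odd_c**2).sum(axis=1))
    s_even = np.sqrt((even_c**2).sum(axis=1))
    degenerate = (s_odd == 0) | (s_even == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (odd_c * even_c).sum(axis=1) / (s_odd * s_even)
    # lower clip keeps the step-up finite at r = -1; r = +1 maps cleanly to 0
    r = np.clip(r, -0.999, 1.0)
    r_sb = np.clip(2.0 * r / (1.0 + r), -1.0, 1.0)
    index = 1.0 - r_sb
    index[degenerate] = MAX_INCONSISTENCY
    n_degen = int(degenerate.sum())
    if n_degen:
        logger.info(
            "even-odd: %d respondent(s) with zero-variance half-means "
            "assigned maximal inconsistency %.1f",
            n_degen,
            MAX_INCONSISTENCY,
        )
    return pd.Series(index, index=matrix.data.index, name="evenodd")


def outlier_flag(scores: pd.Series, z_cut: float = 4.0) -> pd.Series:
    """Univariate outlier pre-screen: |z| of the total score above cut."""
    if len(scores) < 2:
        raise ValueError("outlier screen needs at least 2 respondents")
    sd = float(scores.std(ddof=1))
    if sd == 0:
        raise ValueError("outlier screen: zero score variance")
    z = (scores - scores.mean()) / sd
    flags = z.abs() > z_cut
    flags.name = "outlier"
    return flags


def extended_flags(
    instructed_fail: pd.Series,
    longstring: pd.Series,
    evenodd: pd.Series,
) -> tuple[pd.Series, float, float]:
    """Union careless definition with 2-SD cuts from the unscreened sample.

    Returns (flags, longstring_cut, evenodd_cut).  The instructed-item
    failures are always included, so the extended set is a superset of the
    primary set.
    """
    ls_sd = float(longstring.std(ddof=1))
    eo_sd = float(evenodd.std(ddof=1))
    if ls_sd == 0 or eo_sd == 0:
        raise ValueError("extended flags: degenerate index distribution")
    longstring_cut = float(longstring.mean()) + 2.0 * ls_sd
    evenodd_cut = float(evenodd.mean()) + 2.0 * eo_sd
    flags = (
        instructed_fail
        | (longstring >= longstring_cut)
        | (evenodd >= evenodd_cut)
    )
    flags.name = "flag_extended"
    return flags, longstring_cut, evenodd_cut


def split_samples(
    matrix: ResponseMatrix, flags: pd.Series
) -> tuple[AnalysisSample, AnalysisSample, AnalysisSample]:
    """Partition into (unscreened, screened, careless) analysis samples."""
    flags = flags.reindex(matrix.data.index)
    screened_ids = tuple(matrix.data.index[~flags])
    careless_ids = tuple(matrix.data.index[flags])
    if not screened_ids:
        raise ValueError("all respondents flagged: screened sample is empty")
    unscreened = AnalysisSample("unscreened", tuple(matrix.data.index), matrix)
    screened = AnalysisSample("screened", screened_ids, matrix)
    careless = AnalysisSample("careless", careless_ids, matrix)
    logger.info(
        "split: unscreened n=%d, screened n=%d, careless n=%d",
        unscreened.n,
        screened.n,
        careless.n,
    )
    return unscreened, screened, careless


def screen_study(
    matrix: ResponseMatrix, design: SurveyDesign, z_cut: float = 4.0
) -> ScreenResult:
    """Compute all indicators and both careless definitions.

    The longstring runs over the raw full battery; the even-odd index over
    the reverse-recoded focal items; the outlier z over recoded totals.
    """
    instructed = flag_instructed(matrix, design)
    longstring = longstring_index(matrix)
    recoded = recode_reverse(matrix, design)
    evenodd = evenodd_index(recoded, design)
    totals = scale_scores(recoded, design, "total")
    sd = float(totals.std(ddof=1))
    z = (totals - totals.mean()) / sd if sd > 0 else totals * 0.0
    ext, ls_cut, eo_cut = extended_flags(instructed, longstring, evenodd)
    table = pd.DataFrame(
        {
            "instructed_fail": instructed,
            "longstring": longstring,
            "evenodd": evenodd,
            "outlier_z": z,
            "flag_primary": instructed.rename("flag_primary"),
            "flag_extended": ext,
        }
    )
    return ScreenResult(
        table=table, longstring_cut=ls_cut, evenodd_cut=eo_cut, z_cut=z_cut
    )
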