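"""Survey blueprint and response-data model.

A :class:`SurveyDesign` captures the measurement structure of a Likert
instrument: which items exist and in what presentation order, which factor
each scored item measures, which items are reverse-worded, where the
instructed-response (attention check) item sits and which category it
requires, and the response-scale bounds.  Optional criterion scales (other
instruments in the same booklet, possibly on different response scales) are
carried alongside so that respondent-level indices such as the longstring
can be computed over the full battery.

A :class:`ResponseMatrix` is a thin wrapper over a pandas DataFrame
(respondents x items, integer categories) plus optional ground-truth labels
available for simulated data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DesignError",
    "ResponseValidationError",
    "CriterionScale",
    "SurveyDesign",
    "ResponseMatrix",
    "AnalysisSample",
    "read_design",
    "read_responses",
    "write_responses",
    "recode_reverse",
    "scale_scores",
]


class DesignError(ValueError):
    """Raised when a survey design violates a structural invariant."""


class ResponseValidationError(ValueError):
    """Raised when response data cannot be validated against a design."""


@dataclass(frozen=True)
class CriterionScale:
    """A criterion instrument administered alongside the focal scale."""

    name: str
    items: tuple[str, ...]
    scale_min: int
    scale_max: int

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise DesignError(
                f"criterion scale {self.name!r}: scale_min must be < scale_max"
            )
        if len(set(self.items)) != len(self.items):
            raise DesignError(f"criterion scale {self.name!r}: duplicate item ids")


@dataclass(frozen=True)
class SurveyDesign:
    """The measurement blueprint of a Likert instrument.

    Parameters
    ----------
    item_ids
        Focal items in presentation order, *including* the instructed item.
    factor_map
        item id -> factor label for every scored item.  The instructed item
        must not appear here: it belongs to no factor and is excluded from
        every psychometric computation.
    reverse_set
        Scored items that are reverse-worded and need analytic reflection.
    instructed_item
        Id of the embedded attention check, or ``None``.
    required_category
        The category the instructed item directs respondents to select.
    scale_min, scale_max
        Integer response bounds of the focal scale (e.g. 1 and 5).
    criterion_scales
        Optional additional instruments, appended after the focal battery in
        presentation order.
    """

    item_ids: tuple[str, ...]
    factor_map: Mapping[str, str]
    reverse_set: frozenset[str] = frozenset()
    instructed_item: str | None = None
    required_category: int | None = None
    scale_min: int = 1
    scale_max: int = 5
    criterion_scales: tuple[CriterionScale, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", tuple(self.item_ids))
        object.__setattr__(self, "factor_map", dict(self.factor_map))
        object.__setattr__(self, "reverse_set", frozenset(self.reverse_set))
        object.__setattr__(self, "criterion_scales", tuple(self.criterion_scales))
        self._validate()

    def _validate(self) -> None:
        if len(set(self.item_ids)) != len(self.item_ids):
            raise DesignError("item_ids: duplicate item identifiers")
        if self.scale_min >= self.scale_max:
            raise DesignError("scale bounds: scale_min must be < scale_max")
        scored = [i for i in self.item_ids if i != self.instructed_item]
        for item in scored:
            if item not in self.factor_map:
                raise DesignError(f"factor_map: item {item!r} has no factor")
        for item in self.factor_map:
            if item not in self.item_ids:
                raise DesignError(f"factor_map: unknown item {item!r}")
        if self.instructed_item is not None:
            if self.instructed_item not in self.item_ids:
                raise DesignError(
                    f"instructed_item {self.instructed_item!r} not among item_ids"
                )
            if self.instructed_item in self.factor_map:
                raise DesignError(
                    f"instructed_item {self.instructed_item!r} must not be "
                    "assigned to a factor"
                )
            if self.instructed_item in self.reverse_set:
                raise DesignError("instructed_item cannot be reverse-coded")
            if self.required_category is None:
                raise DesignError("required_category missing for instructed item")
            if not self.scale_min <= self.required_category <= self.scale_max:
                raise DesignError(
                    "required_category outside the response-scale bounds"
                )
        for item in self.reverse_set:
            if item not in self.item_ids:
                raise DesignError(f"reverse_set: unknown item {item!r}")
        battery = list(self.item_ids)
        for cs in self.criterion_scales:
            for item in cs.items:
                if item in battery:
                    raise DesignError(
                        f"criterion item {item!r} duplicates a focal item"
                    )
                battery.append(item)

    # -- derived structure -------------------------------------------------

    @property
    def factors(self) -> tuple[str, ...]:
        """Factor labels in order of first appearance."""
        seen: dict[str, None] = {}
        for item in self.item_ids:
            if item in self.factor_map:
                seen.setdefault(self.factor_map[item], None)
        return tuple(seen)

    @property
    def scored_items(self) -> tuple[str, ...]:
        """Focal items excluding the instructed item, presentation order."""
        return tuple(i for i in self.item_ids if i != self.instructed_item)

    def factor_items(self, factor: str) -> tuple[str, ...]:
        items = tuple(
            i for i in self.scored_items if self.factor_map[i] == factor
        )
        if not items:
            raise DesignError(f"unknown factor label {factor!r}")
        return items

    @property
    def battery_items(self) -> tuple[str, ...]:
        """Full presentation order: focal items then criterion scales."""
        out = list(self.item_ids)
        for cs in self.criterion_scales:
            out.extend(cs.items)
        return tuple(out)

    def bounds_for(self, item: str) -> tuple[int, int]:
        if item in self.item_ids:
            return self.scale_min, self.scale_max
        for cs in self.criterion_scales:
            if item in cs.items:
                return cs.scale_min, cs.scale_max
        raise DesignError(f"unknown item {item!r}")

    def position(self, item: str) -> int:
        """1-based presentation position within the full battery."""
        return self.battery_items.index(item) + 1

    @property
    def midpoint(self) -> int:
        return (self.scale_min + self.scale_max) // 2


@dataclass
class ResponseMatrix:
    """Respondents x items integer responses.

    ``data`` is indexed by respondent id; columns follow the design's
    battery order.  ``truth_labels`` (simulated data only) holds
    ``"attentive"`` or a careless-archetype name per respondent.
    """

    data: pd.DataFrame
    truth_labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.truth_labels is not None:
            self.truth_labels = self.truth_labels.reindex(self.data.index)

    @property
    def respondent_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_respondents(self) -> int:
        return len(self.data)

    def subset(self, respondent_ids: Iterable) -> "ResponseMatrix":
        ids = pd.Index(respondent_ids)
        labels = (
            self.truth_labels.loc[ids] if self.truth_labels is not None else None
        )
        return ResponseMatrix(self.data.loc[ids].copy(), labels)

    def items(self, item_ids: Sequence[str]) -> pd.DataFrame:
        return self.data[list(item_ids)]


@dataclass(frozen=True)
class AnalysisSample:
    """A named subset of a parent ResponseMatrix.

    The screening stage produces the triple (unscreened, screened,
    careless): screened and careless partition the unscreened sample.
    """

    label: str
    respondent_ids: tuple
    parent: ResponseMatrix = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.respondent_ids)

    @property
    def matrix(self) -> ResponseMatrix:
        return self.parent.subset(self.respondent_ids)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def _design_from_mapping(doc: Mapping) -> SurveyDesign:
    try:
        items = list(doc["items"])
        factors = dict(doc["factors"])
        scale = doc["scale"]
    except KeyError as exc:  # pragma: no cover - message formatting
        raise DesignError(f"design key missing required field {exc}") from exc
    factor_map: dict[str, str] = {}
    for label, member_items in factors.items():
        for item in member_items:
            if item in factor_map:
                raise DesignError(
                    f"item {item!r} assigned to more than one factor"
                )
            factor_map[item] = label
    instructed = doc.get("instructed_item")
    instructed_id = instructed["id"] if instructed else None
    required = instructed.get("required_category") if instructed else None
    criterion = tuple(
        CriterionScale(
            name=cs["name"],
            items=tuple(cs["items"]),
            scale_min=int(cs["scale"]["min"]),
            scale_max=int(cs["scale"]["max"]),
        )
        for cs in doc.get("criterion_scales", [])
    )
    return SurveyDesign(
        item_ids=tuple(items),
        factor_map=factor_map,
        reverse_set=frozenset(doc.get("reverse_items", [])),
        instructed_item=instructed_id,
        required_category=required,
        scale_min=int(scale["min"]),
        scale_max=int(scale["max"]),
        criterion_scales=criterion,
    )


def read_design(path: str | Path) -> SurveyDesign:
    """Read a survey design key from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise DesignError(f"{path}: design key is not a mapping")
    return _design_from_mapping(doc)


def design_to_mapping(design: SurveyDesign) -> dict:
    factors: dict[str, list[str]] = {f: [] for f in design.factors}
    for item in design.scored_items:
        factors[design.factor_map[item]].append(item)
    doc: dict = {
        "items": list(design.item_ids),
        "factors": factors,
        "reverse_items": sorted(design.reverse_set, key=design.item_ids.index),
        "scale": {"min": design.scale_min, "max": design.scale_max},
    }
    if design.instructed_item is not None:
        doc["instructed_item"] = {
            "id": design.instructed_item,
            "required_category": design.required_category,
        }
    if design.criterion_scales:
        doc["criterion_scales"] = [
            {
                "name": cs.name,
                "items": list(cs.items),
                "scale": {"min": cs.scale_min, "max": cs.scale_max},
            }
            for cs in design.criterion_scales
        ]
    return doc


def write_design(design: SurveyDesign, path: str | Path) -> None:
    path = Path(path)
    doc = design_to_mapping(design)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_responses(
    path: str | Path, design: SurveyDesign
) -> tuple[ResponseMatrix, pd.DataFrame]:
    """Read a response CSV and validate it against ``design``.

    The file must have a ``respondent_id`` column plus one column per
    battery item.  Rows with missing, non-integer or out-of-range values are
    excluded (complete-case policy) and reported in the returned rejection
    table (columns: respondent_id, item, value, reason).

    Returns
    -------
    (matrix, rejected)
        The validated ResponseMatrix and a DataFrame describing rejected
        cells; empty when all rows validate.
    """
    raw = pd.read_csv(path)
    if "respondent_id" not in raw.columns:
        raise ResponseValidationError("missing required column 'respondent_id'")
    battery = list(design.battery_items)
    missing = [c for c in battery if c not in raw.columns]
    if missing:
        raise ResponseValidationError(
            f"missing item column(s): {', '.join(missing)}"
        )
    raw = raw.set_index("respondent_id")[battery]

    problems: list[dict] = []
    bad_rows: set = set()
    for item in battery:
        lo, hi = design.bounds_for(item)
        col = raw[item]
        numeric = pd.to_numeric(col, errors="coerce")
        for rid, val, num in zip(col.index, col, numeric):
            if pd.isna(num):
                reason = "missing" if pd.isna(val) else "non-numeric"
            elif float(num) != int(num):
                reason = "non-integer"
            elif not lo <= int(num) <= hi:
                reason = f"out of range [{lo}, {hi}]"
            else:
                continue
            problems.append(
                {"respondent_id": rid, "item": item, "value": val, "reason": reason}
            )
            bad_rows.add(rid)
    rejected = pd.DataFrame(
        problems, columns=["respondent_id", "item", "value", "reason"]
    )
    keep = raw.index[~raw.index.isin(bad_rows)]
    clean = raw.loc[keep].astype(np.int64)
    return ResponseMatrix(clean), rejected


def write_responses(matrix: ResponseMatrix, path: str | Path) -> None:
    """Write responses as CSV (first column ``respondent_id``)."""
    out = matrix.data.copy()
    out.index.name = "respondent_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Recoding and scoring
# ---------------------------------------------------------------------------


def recode_reverse(matrix: ResponseMatrix, design: SurveyDesign) -> ResponseMatrix:
    """Reflect reverse-worded items: x -> (scale_min + scale_max) - x.

    Applying the recoding twice restores the original matrix.  Criterion
    and instructed columns are untouched.
    """
    data = matrix.data.copy()
    pivot = design.scale_min + design.scale_max
    for item in design.reverse_set:
        data[item] = pivot - data[item]
    return ResponseMatrix(data, matrix.truth_labels)


def scale_scores(
    matrix: ResponseMatrix,
    design: SurveyDesign,
    level: str = "total",
    statistic: str = "sum",
) -> pd.Series:
    """Per-respondent scale scores from an already reverse-recoded matrix.

    ``level`` is ``"total"`` (all scored focal items) or a factor label.
    ``statistic`` is ``"sum"`` (default convention; keeps integer
    arithmetic exact) or ``"mean"``.  The instructed item never enters.
    """
    if level == "total":
        items = design.scored_items
    else:
        items = design.factor_items(level)
    block = matrix.items(items)
    if statistic == "sum":
        scores = block.sum(axis=1)
    elif statistic == "mean":
        scores = block.mean(axis=1)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    scores.name = f"{level}_{statistic}"
    return scores
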