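"""Synthetic Likert survey generator with planted careless respondents.

Attentive respondents follow a correlated-factor graded model: factor
scores are drawn from a zero-mean multivariate normal, each item's latent
response is ``y = lambda * theta + eps`` with unit total variance, and the
latent response is cut into ordered categories at fixed thresholds.
Reverse-worded items are generated with a sign-flipped loading on the
presentation scale, so that after analytic recoding they align with their
factor.  Attentive respondents always answer the instructed item with the
required category.

Careless respondents ignore item content.  Five archetypes are available:

``acquiescent``
    every item drawn from the top two categories of its scale (default
    probabilities 0.52 / 0.48, mirroring the agree-dominant mix observed
    among attention-check failers);
``random_uniform``
    uniform over the scale's categories;
``midpoint_straightliner``
    the scale midpoint everywhere;
``fixed_straightliner``
    one randomly chosen category repeated across a scale block;
``late_onset``
    attentive up to a configured onset position, acquiescent afterwards.

The archetype process governs the instructed item too (content-blind
responding), so acquiescent respondents always fail it while uniform
responders pass it with probability 1/#categories.

Randomness is counter-based: respondent ``i`` draws from the substream
``default_rng([seed, i])``, so changing the total row count never perturbs
other rows' draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import CriterionScale, ResponseMatrix, SurveyDesign

__all__ = [
    "ARCHETYPES",
    "SimConfig",
    "SimulatedStudy",
    "CriterionBlock",
    "simulate_attentive",
    "simulate_careless",
    "assemble_study",
    "default_sdas_design",
    "default_sdas_config",
]

ARCHETYPES = (
    "acquiescent",
    "random_uniform",
    "midpoint_straightliner",
    "fixed_straightliner",
    "late_onset",
)

# master-rng stream tags (kept clear of per-respondent indices)
_SHUFFLE_STREAM = 2**31 - 11


@dataclass(frozen=True)
class CriterionBlock:
    """Latent specification of criterion instruments.

    Each criterion latent correlates with the equally weighted composite
    of the focal factors at ``latent_corr`` and with the other criterion
    latents at ``inter_corr``; items load on their own criterion latent
    at ``item_loading`` and are discretized with equal-probability
    thresholds.
    """

    scales: tuple[CriterionScale, ...]
    latent_corr: float = 0.40
    inter_corr: float = 0.60
    item_loading: float = 0.65


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study."""

    design: SurveyDesign
    n_respondents: int = 1112
    prevalence: float = 0.1133
    archetype_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "acquiescent": 0.70,
            "random_uniform": 0.15,
            "fixed_straightliner": 0.10,
            "late_onset": 0.05,
        }
    )
    loadings: Mapping[str, float] = field(default_factory=dict)
    factor_corr: np.ndarray | None = None
    thresholds: np.ndarray | None = None
    acquiescent_probs: tuple[float, float] = (0.52, 0.48)
    onset_position: int = 19
    # mean shift of the latent response in the keyed direction (sd units):
    # attentive endorsement of attitude items sits above the scale midpoint,
    # which is what makes reverse-worded items the large-mean-shift items
    # under acquiescent contamination
    item_intercept: float = 0.5
    seed: int = 2025
    criterion_block: CriterionBlock | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence < 1:
            raise ValueError("prevalence must lie in [0, 1)")
        for name in self.archetype_mix:
            if name not in ARCHETYPES:
                raise ValueError(f"unknown archetype {name!r}")
        for p in self.archetype_mix.values():
            if not 0 <= p <= 1:
                raise ValueError("archetype probabilities must lie in [0, 1]")
        thr = self.resolved_thresholds()
        if np.any(np.diff(thr) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        corr = self.resolved_factor_corr()
        if not np.allclose(corr, corr.T) or np.any(np.diag(corr) != 1.0):
            raise ValueError("factor_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("factor_corr must be positive-definite")

    # -- resolved defaults -------------------------------------------------

    def n_categories(self) -> int:
        return self.design.scale_max - self.design.scale_min + 1

    def resolved_thresholds(self) -> np.ndarray:
        if self.thresholds is not None:
            return np.asarray(self.thresholds, dtype=float)
        # symmetric neutral default: cumulative (0.1, 0.3, 0.7, 0.9) for
        # 5 categories, generalized to mildly peaked middle categories
        k = self.n_categories()
        if k == 5:
            cum = np.array([0.1, 0.3, 0.7, 0.9])
        else:
            cum = np.arange(1, k) / k
        return stats.norm.ppf(cum)

    def resolved_factor_corr(self) -> np.ndarray:
        m = len(self.design.factors)
        if self.factor_corr is not None:
            return np.asarray(self.factor_corr, dtype=float)
        return np.full((m, m), 0.5) + 0.5 * np.eye(m)

    def resolved_loadings(self) -> dict[str, float]:
        if self.loadings:
            return dict(self.loadings)
        return _default_loadings(self.design)


@dataclass
class SimulatedStudy:
    """A generated study: responses plus the generating truth."""

    matrix: ResponseMatrix
    design: SurveyDesign
    config: SimConfig
    loadings: dict[str, float]
    factor_corr: np.ndarray
    thresholds: np.ndarray
    seed: int

    @property
    def truth_labels(self) -> pd.Series:
        assert self.matrix.truth_labels is not None
        return self.matrix.truth_labels

    @property
    def n_careless_true(self) -> int:
        return int((self.truth_labels != "attentive").sum())


# ---------------------------------------------------------------------------
# Default SDAS-like blueprint
# ---------------------------------------------------------------------------


def default_sdas_design(include_criteria: bool = True) -> SurveyDesign:
    """The 37-position, three-factor blueprint the package emulates.

    36 scored items (economy 13, society 9, environment 14) on a 1-5
    scale, the instructed item at presentation position 26 requiring the
    midpoint, and six reverse-worded items at positions 1, 8, 10, 24, 31
    and 35.  With ``include_criteria`` two criterion instruments follow:
    19 items on 0-10 and 9 items on 1-7, for a 65-item battery.
    """
    items = tuple(f"SDAS_{i:02d}" for i in range(1, 38))
    factor_map: dict[str, str] = {}
    for i in range(1, 14):
        factor_map[f"SDAS_{i:02d}"] = "economy"
    for i in range(14, 23):
        factor_map[f"SDAS_{i:02d}"] = "society"
    for i in range(23, 38):
        if i == 26:
            continue
        factor_map[f"SDAS_{i:02d}"] = "environment"
    reverse = frozenset(f"SDAS_{i:02d}" for i in (1, 8, 10, 24, 31, 35))
    criteria: tuple[CriterionScale, ...] = ()
    if include_criteria:
        criteria = (
            CriterionScale(
                name="PSRS",
                items=tuple(f"PSRS_{i:02d}" for i in range(1, 20)),
                scale_min=0,
                scale_max=10,
            ),
            CriterionScale(
                name="OVC",
                items=tuple(f"OVC_{i}" for i in range(1, 10)),
                scale_min=1,
                scale_max=7,
            ),
        )
    return SurveyDesign(
        item_ids=items,
        factor_map=factor_map,
        reverse_set=reverse,
        instructed_item="SDAS_26",
        required_category=3,
        scale_min=1,
        scale_max=5,
        criterion_scales=criteria,
    )


def _default_loadings(design: SurveyDesign) -> dict[str, float]:
    """Deterministic loading pattern averaging ~0.57.

    Standard items ramp over 0.55-0.70 within each factor; reverse items
    get weak loadings (0.25-0.35), matching the empirical signature of
    reverse-worded attitude items.
    """
    loadings: dict[str, float] = {}
    for factor in design.factors:
        f_items = design.factor_items(factor)
        standard = [i for i in f_items if i not in design.reverse_set]
        reverse = [i for i in f_items if i in design.reverse_set]
        for j, item in enumerate(standard):
            span = max(len(standard) - 1, 1)
            loadings[item] = 0.55 + 0.15 * j / span
        for j, item in enumerate(reverse):
            span = max(len(reverse) - 1, 1)
            loadings[item] = 0.25 + 0.10 * j / span
    return loadings


def default_sdas_config(
    seed: int = 2025,
    n_respondents: int = 1112,
    prevalence: float = 0.1133,
    include_criteria: bool = True,
    **overrides,
) -> SimConfig:
    """The default study conditions: SDAS-like battery, ~11.3% careless,
    agree-skewed careless mix."""
    design = default_sdas_design(include_criteria)
    criterion_block = None
    if include_criteria:
        criterion_block = CriterionBlock(scales=design.criterion_scales)
    cfg = SimConfig(
        design=design,
        n_respondents=n_respondents,
        prevalence=prevalence,
        seed=seed,
        criterion_block=criterion_block,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _row_rng(seed: int, row_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, row_index])


@dataclass
class _Compiled:
    """Per-config arrays precomputed once before row generation."""

    battery: tuple[str, ...]
    chol: np.ndarray               # latent correlation factorization
    n_latent: int
    focal_items: tuple[str, ...]   # scored focal items, presentation order
    lam: np.ndarray                # signed loadings per focal item
    mu: np.ndarray                 # signed latent intercept per focal item
    factor_idx: np.ndarray         # latent index per focal item
    thresholds: np.ndarray
    scale_min: int
    instructed: str | None
    required: int | None
    crit_items: list[tuple[str, np.ndarray, int, int]]  # item, cuts, idx, lo
    crit_loading: float
    crit_mu: float = 0.0


def _compile(cfg: SimConfig) -> _Compiled:
    design = cfg.design
    loadings = cfg.resolved_loadings()
    corr, latent_names = _latent_cov(cfg)
    factors = list(design.factors)
    focal = tuple(i for i in design.item_ids if i != design.instructed_item)
    signs = np.array(
        [-1.0 if i in design.reverse_set else 1.0 for i in focal]
    )
    lam = signs * np.array([loadings[i] for i in focal])
    mu = signs * cfg.item_intercept
    factor_idx = np.array([factors.index(design.factor_map[i]) for i in focal])
    crit_items: list[tuple[str, np.ndarray, int, int]] = []
    crit_loading = 0.0
    if cfg.criterion_block is not None:
        crit_loading = cfg.criterion_block.item_loading
        for scale in cfg.criterion_block.scales:
            cuts = _criterion_thresholds(scale)
            idx = latent_names.index(scale.name)
            for item in scale.items:
                crit_items.append((item, cuts, idx, scale.scale_min))
    return _Compiled(
        battery=design.battery_items,
        chol=np.linalg.cholesky(corr),
        n_latent=len(latent_names),
        focal_items=focal,
        lam=lam,
        mu=mu,
        factor_idx=factor_idx,
        thresholds=cfg.resolved_thresholds(),
        scale_min=design.scale_min,
        instructed=design.instructed_item,
        required=design.required_category,
        crit_items=crit_items,
        crit_loading=crit_loading,
        crit_mu=cfg.item_intercept,
    )


def _latent_cov(cfg: SimConfig) -> tuple[np.ndarray, list[str]]:
    """Joint correlation matrix over focal factors and criterion latents."""
    factors = list(cfg.design.factors)
    corr = cfg.resolved_factor_corr()
    if cfg.criterion_block is None:
        return corr, factors
    cb = cfg.criterion_block
    m, c = len(factors), len(cb.scales)
    full = np.eye(m + c)
    full[:m, :m] = corr
    # latent_corr is the correlation between the criterion latent and the
    # equally weighted focal-factor composite; the per-factor entry that
    # achieves it is latent_corr * sqrt(1' Phi 1) / m
    per_factor = cb.latent_corr * np.sqrt(corr.sum()) / m
    full[:m, m:] = per_factor
    full[m:, :m] = per_factor
    for i in range(c):
        for j in range(c):
            if i != j:
                full[m + i, m + j] = cb.inter_corr
    if np.linalg.eigvalsh(full).min() <= 0:
        raise ValueError("criterion block makes the latent correlation non-PD")
    return full, factors + [s.name for s in cb.scales]


def _criterion_thresholds(scale: CriterionScale) -> np.ndarray:
    k = scale.scale_max - scale.scale_min + 1
    return stats.norm.ppf(np.arange(1, k) / k)


def _attentive_row(comp: _Compiled, rng: np.random.Generator) -> dict[str, int]:
    theta = comp.chol @ rng.standard_normal(comp.n_latent)
    y = comp.mu + comp.lam * theta[comp.factor_idx]
    y += np.sqrt(1.0 - comp.lam**2) * rng.standard_normal(len(comp.lam))
    cats = np.searchsorted(comp.thresholds, y) + comp.scale_min
    row = dict(zip(comp.focal_items, (int(c) for c in cats)))
    if comp.instructed is not None:
        row[comp.instructed] = int(comp.required)  # type: ignore[arg-type]
    if comp.crit_items:
        lam_c = comp.crit_loading
        eps = rng.standard_normal(len(comp.crit_items))
        resid = np.sqrt(1.0 - lam_c**2)
        for (item, cuts, idx, lo), e in zip(comp.crit_items, eps):
            yc = comp.crit_mu + lam_c * theta[idx] + resid * e
            row[item] = int(np.searchsorted(cuts, yc)) + lo
    return row


def _scale_blocks(cfg: SimConfig) -> list[tuple[tuple[str, ...], int, int]]:
    """(items, scale_min, scale_max) per presentation block."""
    design = cfg.design
    blocks = [(design.item_ids, design.scale_min, design.scale_max)]
    for cs in design.criterion_scales:
        blocks.append((cs.items, cs.scale_min, cs.scale_max))
    return blocks


def _careless_row(
    cfg: SimConfig, comp: _Compiled, archetype: str, rng: np.random.Generator
) -> dict[str, int]:
    if archetype == "late_onset":
        row = _attentive_row(comp, rng)
        onset = cfg.onset_position
        late = _archetype_values(cfg, "acquiescent", rng)
        for item in comp.battery[onset - 1 :]:
            row[item] = late[item]
        return row
    return _archetype_values(cfg, archetype, rng)


def _archetype_values(
    cfg: SimConfig, archetype: str, rng: np.random.Generator
) -> dict[str, int]:
    p_hi = cfg.acquiescent_probs
    row: dict[str, int] = {}
    for items, lo, hi in _scale_blocks(cfg):
        if archetype == "acquiescent":
            vals = rng.choice([hi - 1, hi], size=len(items), p=list(p_hi))
        elif archetype == "random_uniform":
            vals = rng.integers(lo, hi + 1, size=len(items))
        elif archetype == "midpoint_straightliner":
            vals = np.full(len(items), (lo + hi) // 2)
        elif archetype == "fixed_straightliner":
            vals = np.full(len(items), int(rng.integers(lo, hi + 1)))
        else:
            raise ValueError(f"unknown archetype {archetype!r}")
        row.update(zip(items, (int(v) for v in vals)))
    return row


def simulate_attentive(
    cfg: SimConfig, n: int, start_index: int = 0
) -> pd.DataFrame:
    """Generate ``n`` attentive rows (columns in battery order)."""
    comp = _compile(cfg)
    rows = [
        _attentive_row(comp, _row_rng(cfg.seed, start_index + i))
        for i in range(n)
    ]
    return pd.DataFrame(rows, columns=list(cfg.design.battery_items))


def simulate_careless(
    cfg: SimConfig, archetype: str, n: int, start_index: int = 0
) -> pd.DataFrame:
    """Generate ``n`` rows of one careless archetype."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    comp = _compile(cfg)
    rows = [
        _careless_row(cfg, comp, archetype, _row_rng(cfg.seed, start_index + i))
        for i in range(n)
    ]
    return pd.DataFrame(rows, columns=list(cfg.design.battery_items))


def assemble_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate a full study: attentive + careless rows, shuffled.

    The careless count is ``round(prevalence * n)``; archetypes are drawn
    from ``archetype_mix`` using each careless row's own substream, so the
    composition is reproducible row by row.
    """
    mix_total = float(sum(cfg.archetype_mix.values()))
    n_careless = int(round(cfg.prevalence * cfg.n_respondents))
    if n_careless and abs(mix_total - 1.0) > 1e-9:
        raise ValueError("archetype_mix probabilities must sum to 1")
    n_attentive = cfg.n_respondents - n_careless

    comp = _compile(cfg)
    names = list(cfg.archetype_mix)
    probs = [cfg.archetype_mix[a] for a in names]
    rows: list[dict[str, int]] = []
    labels: list[str] = []
    for i in range(cfg.n_respondents):
        rng = _row_rng(cfg.seed, i)
        if i < n_attentive:
            rows.append(_attentive_row(comp, rng))
            labels.append("attentive")
        else:
            archetype = str(rng.choice(names, p=probs))
            rows.append(_careless_row(cfg, comp, archetype, rng))
            labels.append(archetype)

    data = pd.DataFrame(rows, columns=list(cfg.design.battery_items))
    shuffle_rng = np.random.default_rng([cfg.seed, _SHUFFLE_STREAM])
    order = shuffle_rng.permutation(cfg.n_respondents)
    data = data.iloc[order].reset_index(drop=True)
    label_series = pd.Series(
        [labels[i] for i in order], name="truth_label"
    )
    data.index = pd.RangeIndex(1, cfg.n_respondents + 1, name="respondent_id")
    label_series.index = data.index

    matrix = ResponseMatrix(data, label_series)
    return SimulatedStudy(
        matrix=matrix,
        design=cfg.design,
        config=cfg,
        loadings=cfg.resolved_loadings(),
        factor_corr=cfg.resolved_factor_corr(),
        thresholds=cfg.resolved_thresholds(),
        seed=cfg.seed,
    )
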