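"""End-to-end pipeline: simulate/load -> screen -> parallel analyses -> impact.

One :func:`run_pipeline` call reproduces the full comparative design: every
psychometric analysis runs in parallel on the unscreened and the screened
sample (nested framing), while measurement invariance compares attentive
vs careless respondents as independent groups.  The report is a plain
JSON-serializable dictionary; identical configuration and seed give a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cfa import fit_cfa
from .design import (
    ResponseMatrix,
    SurveyDesign,
    read_design,
    read_responses,
    recode_reverse,
    scale_scores,
)
from .impact import (
    cohens_d,
    compute_item_stats,
    csi_compute,
    csi_z,
    fisher_q_compare,
    min_detectable_d,
    permutation_nested_mean_test,
    rank_agreement,
    top_k_report,
)
from .invariance import invariance_sequence
from .reliability import cronbach_alpha, scale_reliability
from .screen import outlier_flag, screen_study, split_samples
from .simulate import assemble_study, default_sdas_config

__all__ = ["RunConfig", "RunReport", "run_pipeline", "write_report",
           "accession_alpha_check"]

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

# top-level keys every complete report must carry
REPORT_REQUIRED_KEYS = (
    "provenance",
    "flow",
    "screening",
    "reliability",
    "cfa",
    "invariance",
    "impact",
    "csi",
    "warnings",
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 2025
    simulate: bool = True
    n_respondents: int = 1112
    prevalence: float = 0.1133
    include_criteria: bool = True
    responses_path: str | None = None
    design_path: str | None = None
    definition: str = "primary"  # or "extended"
    permutations: int = 10_000
    outlier_z: float = 4.0
    min_group_n: int = 100
    score_statistic: str = "sum"
    top_k: int = 10

    def __post_init__(self) -> None:
        if self.definition not in ("primary", "extended"):
            raise ValueError("definition must be 'primary' or 'extended'")
        if not self.simulate and not (self.responses_path and self.design_path):
            raise ValueError(
                "non-simulated runs need responses_path and design_path"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    """The pipeline's machine-readable result."""

    payload: dict
    csi_table: pd.DataFrame | None = None
    flags: pd.DataFrame | None = None

    def to_json(self) -> str:
        return json.dumps(self.payload, sort_keys=True, indent=2)


def _round_nested(obj, nd=10):
    if isinstance(obj, dict):
        return {k: _round_nested(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_nested(v, nd) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return round(v, nd) if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _reliability_section(reports) -> dict:
    return {
        scale: {
            "k": r.k,
            "n": r.n,
            "alpha": r.alpha,
            "alpha_ci": list(r.alpha_ci),
            "omega_t": r.omega_t,
            "omega_h": r.omega_h,
            "ratio_h_t": r.ratio_h_t,
        }
        for scale, r in reports.items()
    }


def _cfa_section(fit) -> dict:
    return {
        "n": fit.n,
        "chi2": fit.chi2,
        "df": fit.df,
        "cfi": fit.cfi,
        "tli": fit.tli,
        "rmsea": fit.rmsea,
        "rmsea_ci": list(fit.rmsea_ci),
        "srmr": fit.srmr,
        "cr": fit.cr,
        "ave": fit.ave,
        "mean_loading": float(fit.loadings.mean()),
        "loadings": {k: float(v) for k, v in fit.loadings.items()},
        "converged": fit.converged,
        "heywood": fit.heywood,
    }


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute all stages; see the module docstring for the design."""
    warnings: list[str] = []

    # --- stage 1: data ---------------------------------------------------
    if cfg.simulate:
        sim_cfg = default_sdas_config(
            seed=cfg.seed,
            n_respondents=cfg.n_respondents,
            prevalence=cfg.prevalence,
            include_criteria=cfg.include_criteria,
        )
        study = assemble_study(sim_cfg)
        matrix, design = study.matrix, study.design
    else:
        design = read_design(cfg.design_path)
        matrix, rejected = read_responses(cfg.responses_path, design)
        if len(rejected):
            n_rows = rejected["respondent_id"].nunique()
            warnings.append(
                f"input validation: {n_rows} row(s) rejected (complete-case)"
            )
    n_raw = matrix.n_respondents
    logger.info("stage data: %d respondents in", n_raw)

    # --- stage 2: outlier pre-screen -------------------------------------
    recoded_all = recode_reverse(matrix, design)
    totals_all = scale_scores(recoded_all, design, "total", cfg.score_statistic)
    outliers = outlier_flag(totals_all, cfg.outlier_z)
    matrix = matrix.subset(matrix.data.index[~outliers])
    n_outliers = int(outliers.sum())
    logger.info("stage outliers: %d removed, %d retained",
                n_outliers, matrix.n_respondents)

    # --- stage 3: careless screening -------------------------------------
    screen = screen_study(matrix, design, cfg.outlier_z)
    flags = screen.table[f"flag_{cfg.definition}"]
    unscreened, screened, careless = split_samples(matrix, flags)
    recoded = recode_reverse(matrix, design)
    logger.info(
        "stage screen (%s): flagged %d of %d (%.2f%%)",
        cfg.definition, careless.n, unscreened.n,
        screen.prevalence(cfg.definition),
    )

    uns_items = recoded.data.loc[list(unscreened.respondent_ids)]
    scr_items = recoded.data.loc[list(screened.respondent_ids)]
    car_items = recoded.data.loc[list(careless.respondent_ids)]

    # --- stage 4: reliability + CFA in parallel --------------------------
    rel = {
        "unscreened": _reliability_section(
            scale_reliability(ResponseMatrix(uns_items), design)
        ),
        "screened": _reliability_section(
            scale_reliability(ResponseMatrix(scr_items), design)
        ),
    }
    cfa_uns = fit_cfa(uns_items, design)
    cfa_scr = fit_cfa(scr_items, design)
    cfa = {
        "unscreened": _cfa_section(cfa_uns),
        "screened": _cfa_section(cfa_scr),
    }

    # --- stage 5: invariance (attentive vs careless, independent) --------
    invariance: dict = {"run": False, "reason": None, "levels": []}
    if careless.n == 0:
        invariance["reason"] = "no careless respondents flagged"
        logger.info("stage invariance skipped: %s", invariance["reason"])
    elif careless.n < cfg.min_group_n:
        invariance["reason"] = (
            f"careless group n={careless.n} below minimum {cfg.min_group_n}"
        )
        warnings.append(f"invariance skipped: {invariance['reason']}")
    else:
        scored = list(design.scored_items)
        try:
            inv = invariance_sequence(
                scr_items[scored], car_items[scored], design,
                min_group_n=cfg.min_group_n,
            )
            invariance = {
                "run": True,
                "reason": None,
                "n_groups": list(inv.n_groups),
                "levels": [
                    {k: getattr(lv, k) for k in (
                        "level", "chi2", "df", "cfi", "rmsea", "converged",
                        "delta_cfi", "delta_rmsea", "delta_chi2", "delta_df",
                        "delta_p", "supported")}
                    for lv in inv.levels
                ],
                "metric_supported": inv.metric_supported,
                "scalar_supported": inv.scalar_supported,
            }
        except (ValueError, np.linalg.LinAlgError) as exc:
            invariance["reason"] = f"estimation failure: {exc}"
            warnings.append(f"invariance failed: {exc}")

    # --- stage 6: impact --------------------------------------------------
    impact: dict = {}
    perm: dict = {}
    scales = ["total"] + list(design.factors)
    if careless.n == 0:
        perm = {
            scale: {"observed_delta": 0.0, "p_two_sided": None,
                    "iterations": 0, "exhaustive": False}
            for scale in scales
        }
        warnings.append(
            "permutation tests skipped: no careless respondents flagged"
        )
    else:
        for scale in scales:
            scores = scale_scores(recoded, design, scale, cfg.score_statistic)
            res = permutation_nested_mean_test(
                scores, flags, B=cfg.permutations, seed=cfg.seed
            )
            perm[scale] = {
                "observed_delta": res.observed_delta,
                "p_two_sided": res.p_two_sided,
                "iterations": res.iterations,
                "exhaustive": res.exhaustive,
            }
    impact["permutation"] = perm

    if careless.n >= 2:
        tot = scale_scores(recoded, design, "total", cfg.score_statistic)
        es = cohens_d(
            tot.loc[list(screened.respondent_ids)],
            tot.loc[list(careless.respondent_ids)],
        )
        impact["attentive_vs_careless_d"] = {
            "cohens_d": es.cohens_d, "ci": list(es.ci),
            "welch_t": es.welch_t, "welch_df": es.welch_df,
            "welch_p": es.welch_p, "label": es.label,
        }
        impact["min_detectable_d"] = min_detectable_d(screened.n, careless.n)

    correlations: dict = {}
    if design.criterion_scales:
        focal_uns = scale_scores(
            ResponseMatrix(uns_items), design, "total", cfg.score_statistic
        )
        focal_scr = focal_uns.loc[list(screened.respondent_ids)]
        for cs in design.criterion_scales:
            crit_all = matrix.data[list(cs.items)].sum(axis=1)
            r1 = float(np.corrcoef(
                focal_uns, crit_all.loc[focal_uns.index])[0, 1])
            r2 = float(np.corrcoef(
                focal_scr, crit_all.loc[focal_scr.index])[0, 1])
            comp = fisher_q_compare(r1, unscreened.n, r2, screened.n)
            correlations[cs.name] = {
                "r_unscreened": r1,
                "r_screened": r2,
                "fisher_z": comp.fisher_z,
                "p": comp.p,
                "cohens_q": comp.cohens_q,
                "q_label": comp.q_label,
            }
    impact["correlations"] = correlations

    # --- stage 7: CSI ------------------------------------------------------
    stats_uns = compute_item_stats(uns_items, design, cfa_uns.loadings)
    stats_scr = compute_item_stats(scr_items, design, cfa_scr.loadings)
    table = csi_compute(stats_uns, stats_scr, design)
    csi_section: dict = {}
    try:
        table = csi_z(table)
        agreement = rank_agreement(table["rank"], table["rank_z"])
        csi_section["rank_agreement"] = agreement
    except ValueError as exc:
        warnings.append(f"CSI_z unavailable: {exc}")
    top = top_k_report(table, min(cfg.top_k, len(table)))
    csi_section.update(
        {
            "top_k": {
                "k": min(cfg.top_k, len(table)),
                "items": top["top_items"],
                "n_reverse": top.get("n_reverse_in_top_k"),
                "n_reverse_total": top.get("n_reverse_total"),
                "item_after_instructed": top.get("item_after_instructed"),
                "item_after_instructed_rank": top.get(
                    "item_after_instructed_rank"
                ),
            },
            "mean_components": {
                "dM": float(table["dM"].mean()),
                "dr": float(table["dr"].mean()),
                "dlam": float(table["dlam"].mean()),
            },
        }
    )

    payload = {
        "provenance": {
            "package": "carescreen",
            "version": __version__,
            "schema_version": REPORT_SCHEMA_VERSION,
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "score_statistic": cfg.score_statistic,
        },
        "flow": {
            "n_in": n_raw,
            "n_outliers_removed": n_outliers,
            "n_unscreened": unscreened.n,
            "n_screened": screened.n,
            "n_careless": careless.n,
        },
        "screening": {
            "definition": cfg.definition,
            "prevalence_primary_pct": screen.prevalence("primary"),
            "prevalence_extended_pct": screen.prevalence("extended"),
            "n_flagged_primary": int(screen.flag_primary.sum()),
            "n_flagged_extended": int(screen.flag_extended.sum()),
            "thresholds": screen.thresholds(),
        },
        "reliability": rel,
        "cfa": cfa,
        "invariance": invariance,
        "impact": impact,
        "csi": csi_section,
        "warnings": warnings,
    }
    payload = _round_nested(payload)
    flags_out = screen.table.copy()
    return RunReport(payload=payload, csi_table=table, flags=flags_out)


def validate_report(payload: dict) -> None:
    """Structural check of a report dictionary; raises on violation."""
    for key in REPORT_REQUIRED_KEYS:
        if key not in payload:
            raise ValueError(f"report missing section {key!r}")
    if payload["provenance"].get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError("report schema_version mismatch")


def write_report(report: RunReport, out_dir: str | Path) -> dict[str, Path]:
    """Write report.json, csi_table.csv, flags.csv and summary.md."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["report"] = out / "report.json"
    paths["report"].write_text(report.to_json() + "\n", encoding="utf-8")

    if report.csi_table is not None:
        paths["csi"] = out / "csi_table.csv"
        t = report.csi_table.copy()
        t.index.name = "item"
        t.to_csv(paths["csi"])
    if report.flags is not None:
        paths["flags"] = out / "flags.csv"
        f = report.flags.copy()
        f.index.name = "respondent_id"
        f.to_csv(paths["flags"])

    paths["summary"] = out / "summary.md"
    paths["summary"].write_text(_summary_md(report.payload), encoding="utf-8")
    return paths


def _fmt(x, nd=3):
    if x is None:
        return "—"
    if isinstance(x, bool):
        return "yes" if x else "no"
    if isinstance(x, float):
        return f"{x:.{nd}f}"
    return str(x)


def _summary_md(p: dict) -> str:
    flow = p["flow"]
    scr = p["screening"]
    lines = [
        "# Screening impact summary",
        "",
        f"Respondents in: {flow['n_in']}; outliers removed: "
        f"{flow['n_outliers_removed']}; unscreened N = {flow['n_unscreened']}; "
        f"screened n = {flow['n_screened']}; careless n = {flow['n_careless']}.",
        f"Careless prevalence: {_fmt(scr['prevalence_primary_pct'], 2)}% "
        f"(primary), {_fmt(scr['prevalence_extended_pct'], 2)}% (extended).",
        "",
        "## Reliability (alpha)",
    ]
    for scale in p["reliability"]["unscreened"]:
        a_u = p["reliability"]["unscreened"][scale]["alpha"]
        a_s = p["reliability"]["screened"][scale]["alpha"]
        lines.append(
            f"- {scale}: {_fmt(a_u)} (unscreened) vs {_fmt(a_s)} (screened), "
            f"delta = {_fmt(a_s - a_u)}"
        )
    lines += ["", "## CFA fit"]
    for smp in ("unscreened", "screened"):
        c = p["cfa"][smp]
        lines.append(
            f"- {smp}: chi2({c['df']}) = {_fmt(c['chi2'])}, CFI {_fmt(c['cfi'])}, "
            f"TLI {_fmt(c['tli'])}, RMSEA {_fmt(c['rmsea'])}, "
            f"SRMR {_fmt(c['srmr'])}"
        )
    inv = p["invariance"]
    lines += ["", "## Measurement invariance (attentive vs careless)"]
    if not inv.get("run"):
        lines.append(f"- not run: {inv.get('reason')}")
    else:
        for lv in inv["levels"]:
            if lv["supported"] is None:
                lines.append(
                    f"- {lv['level']}: chi2({lv['df']}) = {_fmt(lv['chi2'])}, "
                    f"CFI {_fmt(lv['cfi'])}, RMSEA {_fmt(lv['rmsea'])} (baseline)"
                )
            else:
                lines.append(
                    f"- {lv['level']}: dCFI {_fmt(lv['delta_cfi'])}, "
                    f"dRMSEA {_fmt(lv['delta_rmsea'])}, supported: "
                    f"{_fmt(lv['supported'])}"
                )
    lines += ["", "## Permutation tests (unscreened minus screened means)"]
    for scale, r in p["impact"]["permutation"].items():
        lines.append(
            f"- {scale}: delta = {_fmt(r['observed_delta'])}, "
            f"p = {_fmt(r['p_two_sided'])}"
        )
    top = p["csi"]["top_k"]
    lines += [
        "",
        "## Item sensitivity (CSI)",
        f"- top {top['k']} items: {', '.join(top['items'])}",
        f"- reverse-coded among top {top['k']}: {top['n_reverse']} of "
        f"{top['n_reverse_total']}",
    ]
    if p["warnings"]:
        lines += ["", "## Warnings"] + [f"- {w}" for w in p["warnings"]]
    return "\n".join(lines) + "\n"


def accession_alpha_check(
    responses_path: str | Path, design: SurveyDesign
) -> dict[str, float]:
    """Cronbach's alpha of the recoded focal items in the unscreened and
    screened samples of a deposited data file.

    Intended for optional checks against an archived study export the
    user has downloaded locally; expects the package's response-CSV
    dialect.
    """
    matrix, _ = read_responses(responses_path, design)
    recoded = recode_reverse(matrix, design)
    from .screen import flag_instructed  # local import; tiny helper

    flags = flag_instructed(matrix, design)
    items = recoded.data[list(design.scored_items)]
    return {
        "alpha_unscreened": cronbach_alpha(items),
        "alpha_screened": cronbach_alpha(items.loc[~flags]),
    }
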