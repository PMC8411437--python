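"""Full validation analysis on a rating table: a Table-1-style reliability
report (overall / per disease / per category / per item), PGA reliability,
construct validity on per-case means, and interitem redundancy screening.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from addikit.errors import DegenerateVarianceError, InputError
from addikit.instrument import InstrumentDefinition, canonical_addi
from addikit.psychometrics import (
    AlphaResult,
    CorrelationResult,
    IccResult,
    cronbach_alpha,
    estimate_icc_oneway,
    mean_per_case,
    spearman_with_ci,
    validate_rating_table,
)

__all__ = [
    "ValidationConfig",
    "NotEstimable",
    "ReliabilityReport",
    "run_validation",
    "write_report",
    "redundancy_screen",
]


@dataclass(frozen=True)
class ValidationConfig:
    min_raters: int = 3
    ci_alpha: float = 0.05
    redundancy_threshold: float = 0.7
    spearman_method: str = "fisher"
    spearman_seed: int = 0
    pga_reliability_gate: float = 0.6

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ValidationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class NotEstimable:
    """Placeholder for a report cell whose statistic is undefined."""

    reason: str


Cell = Union[IccResult, NotEstimable]


@dataclass(frozen=True)
class ReliabilityReport:
    overall: Cell
    per_disease: dict[str, Cell]
    per_category: dict[str, Cell]
    per_item: dict[str, Cell]
    pga_damage_icc: Cell
    pga_activity_icc: Cell
    construct_damage: Optional[CorrelationResult]
    construct_activity: Optional[CorrelationResult]
    alpha_overall: Union[AlphaResult, NotEstimable]
    alpha_per_category: dict[str, Union[AlphaResult, NotEstimable]]
    pga_gate_passed: bool
    exclusions: list[dict] = field(default_factory=list)
    construct_points: dict[str, dict[str, float]] = field(default_factory=dict)
    n_cases_used: int = 0
    n_ratings_used: int = 0


def _icc_cell(scores: dict, alpha_level: float) -> Cell:
    import warnings as _w

    try:
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            return estimate_icc_oneway(scores, alpha_level=alpha_level)
    except DegenerateVarianceError as exc:
        return NotEstimable(str(exc))
    except InputError as exc:
        return NotEstimable(str(exc))


def _scores_by_case(df: pd.DataFrame, column: str) -> dict[str, np.ndarray]:
    return {
        str(cid): grp.to_numpy(dtype=float)
        for cid, grp in df.groupby("case_id")[column]
    }


def run_validation(
    ratings: pd.DataFrame,
    instr: Optional[InstrumentDefinition] = None,
    config: Optional[ValidationConfig] = None,
) -> ReliabilityReport:
    """Compute every report cell from a validated rating table.

    Groups with fewer than ``config.min_raters`` responding raters are
    dropped (with their cases) before any estimation; degenerate cells are
    reported as not-estimable and the run continues.
    """
    instr = instr or canonical_addi()
    cfg = config or ValidationConfig()
    validate_rating_table(ratings, instr)

    exclusions: list[dict] = []
    raters_per_group = ratings.groupby("group_id")["rater_id"].nunique()
    bad_groups = sorted(raters_per_group[raters_per_group < cfg.min_raters].index)
    for gid in bad_groups:
        exclusions.append(
            {
                "scope": "group",
                "id": str(gid),
                "reason": f"only {int(raters_per_group[gid])} responding rater(s) "
                f"(< {cfg.min_raters})",
                "n_cases_lost": int(
                    ratings.loc[ratings["group_id"] == gid, "case_id"].nunique()
                ),
            }
        )
    df = ratings[~ratings["group_id"].isin(bad_groups)].copy()
    if df.empty:
        raise InputError("all groups dropped; nothing to analyse")

    a = cfg.ci_alpha
    overall = _icc_cell(_scores_by_case(df, "total"), a)
    per_disease = {
        d: _icc_cell(_scores_by_case(df[df["disease"] == d], "total"), a)
        if (df["disease"] == d).any()
        else NotEstimable("no cases for disease")
        for d in ("FMF", "CAPS", "TRAPS", "MKD")
    }
    # per-category scores: capped item sums per rating row
    cat_scores = {}
    for cat in instr.categories:
        col = np.minimum(cat.max_points, df[cat.item_ids].sum(axis=1))
        cat_scores[cat.category_id] = pd.Series(col, index=df.index)
    per_category = {
        cid: _icc_cell(
            {str(k): g.to_numpy(dtype=float) for k, g in s.groupby(df["case_id"])}, a
        )
        for cid, s in cat_scores.items()
    }
    per_item = {
        iid: _icc_cell(_scores_by_case(df, iid), a) for iid in instr.item_ids
    }
    pga_damage_icc = _icc_cell(_scores_by_case(df, "pga_damage"), a)
    pga_activity_icc = _icc_cell(_scores_by_case(df, "pga_activity"), a)

    # construct validity on per-case means (>= min_raters raters per case)
    construct_damage = construct_activity = None
    construct_points: dict[str, dict[str, float]] = {}
    try:
        mean_total = mean_per_case(df, "total", cfg.min_raters)
        mean_pga_d = mean_per_case(df, "pga_damage", cfg.min_raters)
        mean_pga_a = mean_per_case(df, "pga_activity", cfg.min_raters)
        cids = sorted(set(mean_total) & set(mean_pga_d) & set(mean_pga_a))
        xs = [mean_total[c] for c in cids]
        construct_points = {
            c: {
                "mean_addi": mean_total[c],
                "mean_pga_damage": mean_pga_d[c],
                "mean_pga_activity": mean_pga_a[c],
            }
            for c in cids
        }
        construct_damage = spearman_with_ci(
            xs,
            [mean_pga_d[c] for c in cids],
            method=cfg.spearman_method,
            seed=cfg.spearman_seed,
            alpha_level=a,
        )
        construct_activity = spearman_with_ci(
            xs,
            [mean_pga_a[c] for c in cids],
            method=cfg.spearman_method,
            seed=cfg.spearman_seed,
            alpha_level=a,
        )
    except InputError as exc:
        exclusions.append({"scope": "construct", "id": "-", "reason": str(exc)})

    gate = cfg.pga_reliability_gate
    pga_gate_passed = (
        isinstance(pga_damage_icc, IccResult)
        and isinstance(pga_activity_icc, IccResult)
        and pga_damage_icc.icc >= gate
        and pga_activity_icc.icc >= gate
    )

    alpha_overall = _alpha_cell(df, instr.item_ids, cfg.redundancy_threshold)
    alpha_per_category = {}
    for cat in instr.categories:
        if len(cat.item_ids) < 2:
            alpha_per_category[cat.category_id] = NotEstimable("single-item category")
        else:
            alpha_per_category[cat.category_id] = _alpha_cell(
                df, cat.item_ids, cfg.redundancy_threshold
            )

    return ReliabilityReport(
        overall=overall,
        per_disease=per_disease,
        per_category=per_category,
        per_item=per_item,
        pga_damage_icc=pga_damage_icc,
        pga_activity_icc=pga_activity_icc,
        construct_damage=construct_damage,
        construct_activity=construct_activity,
        alpha_overall=alpha_overall,
        alpha_per_category=alpha_per_category,
        pga_gate_passed=pga_gate_passed,
        exclusions=exclusions,
        construct_points=construct_points,
        n_cases_used=int(df["case_id"].nunique()),
        n_ratings_used=int(len(df)),
    )


def _alpha_cell(df, item_ids, threshold) -> Union[AlphaResult, NotEstimable]:
    import warnings as _w

    try:
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            return cronbach_alpha(df[list(item_ids)], redundancy_threshold=threshold)
    except InputError as exc:
        return NotEstimable(str(exc))


def redundancy_screen(
    ratings: pd.DataFrame,
    instr: Optional[InstrumentDefinition] = None,
    threshold: float = 0.7,
) -> list[tuple[str, str, float]]:
    """All item pairs whose interitem correlation exceeds ``threshold``."""
    instr = instr or canonical_addi()
    if not 0.0 < threshold < 1.0:
        raise InputError("threshold must be in (0, 1)")
    X = ratings[list(instr.item_ids)].to_numpy(dtype=float)
    keep = X.var(axis=0, ddof=1) > 0
    names = [iid for iid, k in zip(instr.item_ids, keep) if k]
    corr = np.corrcoef(X[:, keep], rowvar=False)
    flagged = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if corr[i, j] > threshold:
                flagged.append((names[i], names[j], float(corr[i, j])))
    return sorted(flagged, key=lambda t: -t[2])


# ---------------------------------------------------------------------------
# serialization

def _cell_row(scope: str, cell: Cell) -> dict:
    if isinstance(cell, NotEstimable):
        return {
            "scope": scope, "icc": "", "ci_lower": "", "ci_upper": "",
            "n_cases": "", "reason": cell.reason,
        }
    return {
        "scope": scope,
        "icc": f"{cell.icc:.6f}",
        "ci_lower": f"{cell.ci_lower:.6f}",
        "ci_upper": f"{cell.ci_upper:.6f}",
        "n_cases": cell.n_subjects,
        "reason": "",
    }


def _cell_json(cell: Cell) -> dict:
    if isinstance(cell, NotEstimable):
        return {"estimable": False, "reason": cell.reason}
    return {
        "estimable": True,
        "icc": cell.icc,
        "ci_lower": cell.ci_lower,
        "ci_upper": cell.ci_upper,
        "n_subjects": cell.n_subjects,
        "n_ratings": cell.n_ratings,
        "k0": cell.k0,
        "msb": cell.msb,
        "msw": cell.msw,
    }


def _corr_json(res: Optional[CorrelationResult]) -> Optional[dict]:
    if res is None:
        return None
    return {
        "rho": res.rho,
        "ci_lower": res.ci_lower,
        "ci_upper": res.ci_upper,
        "p_value": res.p_value,
        "n_pairs": res.n_pairs,
        "strength_band": res.strength_band,
        "method": res.method,
    }


def _alpha_json(res: Union[AlphaResult, NotEstimable]) -> dict:
    if isinstance(res, NotEstimable):
        return {"estimable": False, "reason": res.reason}
    return {
        "estimable": True,
        "alpha": res.alpha,
        "n_items": res.n_items,
        "item_names": list(res.item_names),
        "interitem": [[float(v) for v in row] for row in res.interitem],
        "redundant_pairs": [list(p) for p in res.redundant_pairs],
        "dropped_items": list(res.dropped_items),
    }


def write_report(
    report: ReliabilityReport,
    destination: Union[str, Path],
    instr: Optional[InstrumentDefinition] = None,
) -> list[Path]:
    """Write reliability.csv (Table-1 layout), construct.csv,
    construct_points.csv and report.json; byte-deterministic."""
    instr = instr or canonical_addi()
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)

    rows = [_cell_row("overall", report.overall)]
    rows += [
        _cell_row(f"disease:{d}", report.per_disease[d]) for d in report.per_disease
    ]
    rows += [
        _cell_row(f"category:{cid}", report.per_category[cid])
        for cid in instr.category_ids
    ]
    rows += [_cell_row(f"item:{iid}", report.per_item[iid]) for iid in instr.item_ids]
    rows.append(_cell_row("pga_damage", report.pga_damage_icc))
    rows.append(_cell_row("pga_activity", report.pga_activity_icc))
    reliability = dest / "reliability.csv"
    pd.DataFrame(rows).to_csv(reliability, index=False, lineterminator="\n")

    crows = []
    for name, res in (
        ("addi_vs_pga_damage", report.construct_damage),
        ("addi_vs_pga_activity", report.construct_activity),
    ):
        d = _corr_json(res) or {}
        crows.append({"comparison": name, **d})
    construct = dest / "construct.csv"
    pd.DataFrame(crows).to_csv(construct, index=False, lineterminator="\n")

    points = dest / "construct_points.csv"
    prows = [
        {"case_id": cid, **vals} for cid, vals in sorted(report.construct_points.items())
    ]
    pd.DataFrame(
        prows, columns=["case_id", "mean_addi", "mean_pga_damage", "mean_pga_activity"]
    ).to_csv(points, index=False, lineterminator="\n")

    payload = {
        "overall": _cell_json(report.overall),
        "per_disease": {d: _cell_json(c) for d, c in report.per_disease.items()},
        "per_category": {k: _cell_json(c) for k, c in report.per_category.items()},
        "per_item": {k: _cell_json(c) for k, c in report.per_item.items()},
        "pga_damage_icc": _cell_json(report.pga_damage_icc),
        "pga_activity_icc": _cell_json(report.pga_activity_icc),
        "construct": {
            "addi_vs_pga_damage": _corr_json(report.construct_damage),
            "addi_vs_pga_activity": _corr_json(report.construct_activity),
            "pga_gate_passed": report.pga_gate_passed,
        },
        "alpha_overall": _alpha_json(report.alpha_overall),
        "alpha_per_category": {
            k: _alpha_json(v) for k, v in report.alpha_per_category.items()
        },
        "exclusions": report.exclusions,
        "n_cases_used": report.n_cases_used,
        "n_ratings_used": report.n_ratings_used,
        "note": "p-values are descriptive; no multiple-testing adjustment applied",
    }
    report_json = dest / "report.json"
    report_json.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return [reliability, construct, points, report_json]
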