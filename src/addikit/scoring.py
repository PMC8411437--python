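"""Grading of clinical evidence into item points, eligibility filtering,
category capping and total computation.

Damage eligibility: a finding counts only if it has been present for at
least six months, is not attributed to ongoing disease activity and arose
after disease onset. A finding that met the six-month rule and later
resolved is still scored.

Each item can be scored in one of two modes:

* ``asserted`` -- the rater states a grade label directly ("present" for
  ungraded items, a level label such as "severe" for graded items);
* ``measured`` -- raw clinical measurements are supplied and routed through
  the ``grade_*`` function for that item (GFR thresholds, urine protein
  ratios, growth criteria, audiometry status, ...).
"""

from __future__ import annotations

import csv
import io
import json
from typing import Iterable, Literal, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

from addikit.errors import ApplicabilityError, InputError
from addikit.instrument import InstrumentDefinition

__all__ = [
    "Evidence",
    "CaseRecord",
    "ScoreCard",
    "is_damage_eligible",
    "grade_renal_insufficiency",
    "grade_proteinuria",
    "grade_growth_failure",
    "grade_hearing_loss",
    "grade_ocular",
    "grade_osteoporosis",
    "grade_amyloidosis",
    "score_item",
    "score_case",
    "ScoringIndex",
    "cases_to_json",
    "cases_from_json",
    "cases_to_csv",
    "cases_from_csv",
    "scorecards_to_csv",
    "scorecards_to_json",
]

ADULT_AGE_YEARS = 18.0
MIN_DAMAGE_DURATION_MONTHS = 6.0

Disease = Literal["FMF", "CAPS", "TRAPS", "MKD"]
Sex = Literal["female", "male"]
VisualStatus = Literal["none", "impaired", "legal_blindness"]

# measurement keys understood by the measured-mode router
MEASUREMENT_KEYS = (
    "gfr_ml_min_1.73m2",
    "dialysis_or_transplant",
    "urine_pcr_mg_mmol",
    "protein_g_24h",
    "urine_acr_mg_mmol",
    "height_below_p3",
    "velocity_below_p3",
    "crossed_2_centiles",
    "adult_short_stature",
    "hearing_impairment_confirmed",
    "hearing_aid_required",
    "ocular_damage_documented",
    "visual_impairment",
    "low_bone_density",
    "fracture_present",
    "organs_affected",
)


class Evidence(BaseModel):
    """One item's clinical evidence within a case."""

    model_config = ConfigDict(extra="forbid")

    item_id: str
    mode: Literal["asserted", "measured"] = "asserted"
    asserted_grade: Optional[str] = None
    measurements: dict[str, Union[bool, int, float, str]] = Field(default_factory=dict)
    duration_months: float = Field(ge=0)
    resolved: bool = False
    attributed_to_active_disease: bool = False
    onset_after_aid_onset: bool = True

    @model_validator(mode="after")
    def _check_mode(self) -> "Evidence":
        if self.mode == "asserted":
            if self.asserted_grade is None:
                raise ValueError(f"{self.item_id}: asserted evidence needs asserted_grade")
            if self.measurements:
                raise ValueError(f"{self.item_id}: asserted evidence cannot carry measurements")
        else:
            if not self.measurements:
                raise ValueError(f"{self.item_id}: measured evidence needs measurements")
            if self.asserted_grade is not None:
                raise ValueError(f"{self.item_id}: measured evidence cannot carry asserted_grade")
        return self


class CaseRecord(BaseModel):
    """One paper-clinical case: disease, demographics and per-item evidence."""

    model_config = ConfigDict(extra="forbid")

    case_id: str
    disease: Disease
    age_years: float = Field(ge=0)
    sex: Sex
    evidence: list[Evidence] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_unique_items(self) -> "CaseRecord":
        ids = [ev.item_id for ev in self.evidence]
        if len(set(ids)) != len(ids):
            raise ValueError(f"case {self.case_id}: duplicate evidence item_id")
        return self

    @property
    def is_adult(self) -> bool:
        return self.age_years >= ADULT_AGE_YEARS


class ScoreCard(BaseModel):
    """Per-item points, capped category subtotals and total for one case."""

    model_config = ConfigDict(extra="forbid")

    case_id: str
    item_points: dict[str, int]
    category_points: dict[str, int]
    total: int = Field(ge=0)
    exclusions: list[tuple[str, str]] = Field(default_factory=list)


# ---------------------------------------------------------------------------
# eligibility

def is_damage_eligible(ev: Evidence) -> tuple[bool, Optional[str]]:
    """Whether a finding qualifies as damage, with the failing rule if not.

    Resolution after >=6 months of presence does not disqualify.
    """
    if ev.duration_months < MIN_DAMAGE_DURATION_MONTHS:
        return False, "duration<6mo"
    if ev.attributed_to_active_disease:
        return False, "attributed_to_active_disease"
    if not ev.onset_after_aid_onset:
        return False, "onset_before_aid_onset"
    return True, None


# ---------------------------------------------------------------------------
# measurement graders

def grade_renal_insufficiency(
    gfr: Optional[float], dialysis_or_transplant: bool = False
) -> Optional[str]:
    """severe: GFR < 15 or dialysis/transplant; moderate: 15 <= GFR < 60."""
    if gfr is None:
        if not dialysis_or_transplant:
            raise InputError("renal_insufficiency: need GFR or dialysis/transplant flag")
        return "severe"
    if gfr < 0:
        raise InputError(f"negative GFR: {gfr}")
    if dialysis_or_transplant or gfr < 15:
        return "severe"
    if gfr < 60:
        return "moderate"
    return None


def grade_proteinuria(
    pcr_mg_mmol: Optional[float] = None,
    protein_g_24h: Optional[float] = None,
    acr_mg_mmol: Optional[float] = None,
) -> bool:
    """Strict thresholds: PCR > 20, 24 h protein > 0.3 g, ACR > 15."""
    if pcr_mg_mmol is None and protein_g_24h is None and acr_mg_mmol is None:
        raise InputError("proteinuria: no measurement supplied")
    if pcr_mg_mmol is not None and pcr_mg_mmol > 20:
        return True
    if protein_g_24h is not None and protein_g_24h > 0.3:
        return True
    if acr_mg_mmol is not None and acr_mg_mmol > 15:
        return True
    return False


def grade_growth_failure(
    criteria: Sequence[bool],
    adult: bool = False,
    adult_short_stature: bool = False,
) -> bool:
    """Paediatric: at least two of the three growth criteria; adult:
    pathological short stature."""
    if adult:
        return bool(adult_short_stature)
    if len(criteria) != 3:
        raise InputError("growth_failure: exactly three criteria expected")
    return sum(bool(c) for c in criteria) >= 2


def grade_hearing_loss(
    impairment_confirmed: bool, aid_or_implant: bool = False
) -> Optional[str]:
    if aid_or_implant and not impairment_confirmed:
        raise InputError("hearing_loss: aids/implant without confirmed impairment")
    if aid_or_implant:
        return "severe"
    if impairment_confirmed:
        return "moderate"
    return None


def grade_ocular(damage_documented: bool, visual: VisualStatus = "none") -> Optional[str]:
    if visual not in ("none", "impaired", "legal_blindness"):
        raise InputError(f"ocular: unknown visual status {visual!r}")
    if not damage_documented:
        if visual != "none":
            raise InputError("ocular: visual impairment without documented damage")
        return None
    if visual == "legal_blindness":
        return "severe"
    if visual == "impaired":
        return "moderate"
    return "mild"


def grade_osteoporosis(low_density: bool, fracture_or_collapse: bool) -> bool:
    """Both reduced density and fracture/collapse required."""
    return bool(low_density) and bool(fracture_or_collapse)


def grade_amyloidosis(organs_affected: int) -> Optional[str]:
    """limited: one organ; extensive: more than one."""
    if organs_affected < 0:
        raise InputError(f"negative organ count: {organs_affected}")
    if organs_affected == 0:
        return None
    return "limited" if organs_affected == 1 else "extensive"


def _grade_measured(ev: Evidence, case: CaseRecord) -> Optional[str]:
    """Route measured evidence to its grader; returns a grade label,
    ``"present"`` for boolean items, or ``None`` when criteria are not met."""
    m = ev.measurements
    iid = ev.item_id
    if iid == "renal_insufficiency":
        gfr = m.get("gfr_ml_min_1.73m2")
        return grade_renal_insufficiency(
            None if gfr is None else float(gfr),
            bool(m.get("dialysis_or_transplant", False)),
        )
    if iid == "proteinuria":
        present = grade_proteinuria(
            _opt_float(m.get("urine_pcr_mg_mmol")),
            _opt_float(m.get("protein_g_24h")),
            _opt_float(m.get("urine_acr_mg_mmol")),
        )
        return "present" if present else None
    if iid == "growth_failure":
        present = grade_growth_failure(
            (
                bool(m.get("height_below_p3", False)),
                bool(m.get("velocity_below_p3", False)),
                bool(m.get("crossed_2_centiles", False)),
            ),
            adult=case.is_adult,
            adult_short_stature=bool(m.get("adult_short_stature", False)),
        )
        return "present" if present else None
    if iid == "hearing_loss":
        return grade_hearing_loss(
            bool(m.get("hearing_impairment_confirmed", False)),
            bool(m.get("hearing_aid_required", False)),
        )
    if iid == "ocular_involvement":
        return grade_ocular(
            bool(m.get("ocular_damage_documented", False)),
            str(m.get("visual_impairment", "none")),  # type: ignore[arg-type]
        )
    if iid == "osteoporosis":
        present = grade_osteoporosis(
            bool(m.get("low_bone_density", False)),
            bool(m.get("fracture_present", False)),
        )
        return "present" if present else None
    if iid == "amyloidosis":
        return grade_amyloidosis(int(m.get("organs_affected", 0)))
    raise InputError(f"item {iid!r} does not support measured mode")


def _opt_float(v) -> Optional[float]:
    return None if v is None else float(v)


# ---------------------------------------------------------------------------
# item and case scoring

def check_applicability(instr: InstrumentDefinition, item_id: str, case: CaseRecord) -> None:
    item = instr.item(item_id)
    if item.pediatric_only and case.is_adult:
        raise ApplicabilityError(
            f"item {item_id!r} is paediatric-only but case {case.case_id} is adult"
        )
    if item.applicable_sex == "female_relevant" and case.sex != "female":
        raise ApplicabilityError(
            f"item {item_id!r} cannot be asserted for a {case.sex} case ({case.case_id})"
        )


def _evaluate_item(
    instr: InstrumentDefinition, ev: Evidence, case: CaseRecord
) -> tuple[int, Optional[str]]:
    try:
        item = instr.item(ev.item_id)
    except KeyError:
        raise InputError(f"unknown item_id {ev.item_id!r}") from None
    check_applicability(instr, ev.item_id, case)
    eligible, reason = is_damage_eligible(ev)
    if not eligible:
        return 0, reason
    if ev.mode == "asserted":
        try:
            return item.points_for(ev.asserted_grade), None  # type: ignore[arg-type]
        except KeyError:
            raise InputError(
                f"unknown grade {ev.asserted_grade!r} for item {ev.item_id!r}"
            ) from None
    label = _grade_measured(ev, case)
    if label is None:
        return 0, "criterion_not_met"
    return item.points_for(label), None


def score_item(instr: InstrumentDefinition, ev: Evidence, case: CaseRecord) -> int:
    """Points for one item's evidence (0 when ineligible or below criteria)."""
    points, _ = _evaluate_item(instr, ev, case)
    return points


def score_case(instr: InstrumentDefinition, case: CaseRecord) -> ScoreCard:
    """Score all evidence, cap category subtotals and total the case.

    ``exclusions`` lists every item that contributed no points together with
    the reason: eligibility failures, unmet measured criteria, missing
    evidence (``not_assessed``) or demographic inapplicability.
    """
    by_item = {ev.item_id: ev for ev in case.evidence}
    item_points: dict[str, int] = {}
    exclusions: list[tuple[str, str]] = []
    for item in instr.items:
        iid = item.item_id
        ev = by_item.pop(iid, None)
        if ev is None:
            try:
                check_applicability(instr, iid, case)
            except ApplicabilityError:
                item_points[iid] = 0
                exclusions.append((iid, "not_applicable"))
                continue
            item_points[iid] = 0
            exclusions.append((iid, "not_assessed"))
            continue
        try:
            points, reason = _evaluate_item(instr, ev, case)
        except InputError as exc:
            raise InputError(f"case {case.case_id}, item {iid}: {exc}") from exc
        item_points[iid] = points
        if reason is not None:
            exclusions.append((iid, reason))
    if by_item:
        raise InputError(
            f"case {case.case_id}: unknown item_id {sorted(by_item)[0]!r}"
        )
    category_points = {
        cat.category_id: min(
            cat.max_points, sum(item_points[iid] for iid in cat.item_ids)
        )
        for cat in instr.categories
    }
    total = sum(category_points.values())
    return ScoreCard(
        case_id=case.case_id,
        item_points=item_points,
        category_points=category_points,
        total=total,
        exclusions=exclusions,
    )


class ScoringIndex:
    """Precomputed lookup tables for fast repeated scoring of grade maps.

    Used by the simulator, where hundreds of thousands of perturbed rating
    sheets are pushed through the same capping arithmetic as
    :func:`score_case`.
    """

    def __init__(self, instr: InstrumentDefinition):
        self.instr = instr
        self.points: dict[str, dict[str, int]] = {}
        for item in instr.items:
            if item.levels:
                self.points[item.item_id] = {lv.label: lv.points for lv in item.levels}
            else:
                self.points[item.item_id] = {"present": item.base_points}
        self.caps = {c.category_id: c.max_points for c in instr.categories}
        self.cat_items = {c.category_id: list(c.item_ids) for c in instr.categories}
        self.item_ids = list(instr.item_ids)
        self.labels: dict[str, list[str]] = {
            item.item_id: ([lv.label for lv in item.levels] if item.levels else ["present"])
            for item in instr.items
        }

    def score(self, grades: dict) -> tuple[dict[str, int], dict[str, int], int]:
        """Grade-label map -> (item points, capped category points, total)."""
        pts = self.points
        item_points = {
            iid: (pts[iid][g] if (g := grades.get(iid)) is not None else 0)
            for iid in self.item_ids
        }
        category_points = {
            cid: min(cap, sum(item_points[iid] for iid in self.cat_items[cid]))
            for cid, cap in self.caps.items()
        }
        return item_points, category_points, sum(category_points.values())


# ---------------------------------------------------------------------------
# case and scorecard I/O

def cases_to_json(cases: Iterable[CaseRecord]) -> str:
    return json.dumps([c.model_dump(mode="json") for c in cases], indent=2) + "\n"


def cases_from_json(text: str) -> list[CaseRecord]:
    data = json.loads(text)
    if not isinstance(data, list):
        raise InputError("case JSON must be a list of case objects")
    return [CaseRecord.model_validate(d) for d in data]


_CASE_CSV_FIXED = [
    "case_id",
    "disease",
    "age_years",
    "sex",
    "item_id",
    "mode",
    "asserted_grade",
    "duration_months",
    "resolved",
    "attributed_to_active_disease",
    "onset_after_aid_onset",
]


def cases_to_csv(cases: Iterable[CaseRecord]) -> str:
    """Flat one-row-per-evidence CSV; evidence-free cases emit one stub row."""
    out = io.StringIO()
    writer = csv.DictWriter(out, fieldnames=_CASE_CSV_FIXED + list(MEASUREMENT_KEYS))
    writer.writeheader()
    for case in cases:
        base = {
            "case_id": case.case_id,
            "disease": case.disease,
            "age_years": case.age_years,
            "sex": case.sex,
        }
        if not case.evidence:
            writer.writerow({**base, "item_id": ""})
            continue
        for ev in case.evidence:
            row = {
                **base,
                "item_id": ev.item_id,
                "mode": ev.mode,
                "asserted_grade": ev.asserted_grade or "",
                "duration_months": ev.duration_months,
                "resolved": ev.resolved,
                "attributed_to_active_disease": ev.attributed_to_active_disease,
                "onset_after_aid_onset": ev.onset_after_aid_onset,
            }
            for key in MEASUREMENT_KEYS:
                if key in ev.measurements:
                    row[key] = ev.measurements[key]
            writer.writerow(row)
    return out.getvalue()


def _parse_cell(key: str, raw: str):
    if raw in ("True", "False"):
        return raw == "True"
    if key in ("visual_impairment",):
        return raw
    try:
        f = float(raw)
    except ValueError:
        return raw
    return int(f) if f == int(f) and "." not in raw else f


def cases_from_csv(text: str) -> list[CaseRecord]:
    reader = csv.DictReader(io.StringIO(text))
    grouped: dict[str, dict] = {}
    for lineno, row in enumerate(reader, start=2):
        cid = (row.get("case_id") or "").strip()
        if not cid:
            raise InputError(f"row {lineno}: missing case_id")
        rec = grouped.setdefault(
            cid,
            {
                "case_id": cid,
                "disease": row.get("disease"),
                "age_years": float(row["age_years"]),
                "sex": row.get("sex"),
                "evidence": [],
            },
        )
        iid = (row.get("item_id") or "").strip()
        if not iid:
            continue
        measurements = {
            k: _parse_cell(k, row[k])
            for k in MEASUREMENT_KEYS
            if row.get(k) not in (None, "")
        }
        try:
            rec["evidence"].append(
                Evidence(
                    item_id=iid,
                    mode=row.get("mode") or "asserted",
                    asserted_grade=(row.get("asserted_grade") or None),
                    measurements=measurements,
                    duration_months=float(row.get("duration_months") or 0),
                    resolved=(row.get("resolved") == "True"),
                    attributed_to_active_disease=(
                        row.get("attributed_to_active_disease") == "True"
                    ),
                    onset_after_aid_onset=(
                        row.get("onset_after_aid_onset", "True") != "False"
                    ),
                )
            )
        except ValueError as exc:
            raise InputError(f"row {lineno}: {exc}") from exc
    try:
        return [CaseRecord.model_validate(rec) for rec in grouped.values()]
    except ValueError as exc:
        raise InputError(str(exc)) from exc


def scorecards_to_csv(cards: Iterable[ScoreCard], instr: InstrumentDefinition) -> str:
    out = io.StringIO()
    fields = (
        ["case_id"]
        + [f"item_{iid}" for iid in instr.item_ids]
        + [f"category_{cid}" for cid in instr.category_ids]
        + ["total"]
    )
    writer = csv.writer(out)
    writer.writerow(fields)
    for card in cards:
        writer.writerow(
            [card.case_id]
            + [card.item_points[iid] for iid in instr.item_ids]
            + [card.category_points[cid] for cid in instr.category_ids]
            + [card.total]
        )
    return out.getvalue()


def scorecards_to_json(cards: Iterable[ScoreCard]) -> str:
    return json.dumps([c.model_dump(mode="json") for c in cards], indent=2) + "\n"


def max_damage_case(
    instr: InstrumentDefinition,
    case_id: str = "max_damage",
    disease: Disease = "CAPS",
) -> CaseRecord:
    """A paediatric female case asserting every item at its top grade --
    useful as the ceiling fixture (canonical instrument scores 27)."""
    evidence = []
    for item in instr.items:
        grade = item.levels[-1].label if item.levels else "present"
        evidence.append(
            Evidence(item_id=item.item_id, asserted_grade=grade, duration_months=12.0)
        )
    return CaseRecord(
        case_id=case_id, disease=disease, age_years=16.0, sex="female", evidence=evidence
    )
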