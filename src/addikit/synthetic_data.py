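"""Synthetic validation studies with known ground truth.

Generates case sets with per-disease item prevalence profiles, allocates
disjoint rater groups to disjoint case blocks (the nested design), and
simulates rater disagreement through a misclassification model whose scale
can be calibrated to hit a target reliability.

The prevalence profiles are invented for plausibility only -- they give the
simulator realistic enrichment patterns (e.g. hearing loss in CAPS,
amyloidosis in FMF) and are not estimates of registry epidemiology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from addikit.errors import CalibrationError, DegenerateVarianceError, GenerationError, InputError
from addikit.instrument import InstrumentDefinition
from addikit.psychometrics import estimate_icc_oneway, rating_table_columns
from addikit.scoring import (
    CaseRecord,
    Evidence,
    ScoringIndex,
    is_damage_eligible,
    score_case,
    _grade_measured,
)

__all__ = [
    "StudyDesign",
    "RaterModel",
    "GroundTruth",
    "DEFAULT_PREVALENCE",
    "generate_cases",
    "allocate_design",
    "simulate_ratings",
    "calibrate_noise_to_icc",
    "monte_carlo_icc",
    "true_grade_labels",
]

DISEASES = ("FMF", "CAPS", "TRAPS", "MKD")

# invented per-disease prevalence profiles (probability that a case carries
# the item); editable via StudyDesign.prevalence
DEFAULT_PREVALENCE: dict[str, dict[str, float]] = {
    "sub_infertility": {"FMF": 0.16, "CAPS": 0.10, "TRAPS": 0.10, "MKD": 0.10},
    "amenorrhea": {"FMF": 0.16, "CAPS": 0.14, "TRAPS": 0.14, "MKD": 0.14},
    "amyloidosis": {"FMF": 0.32, "CAPS": 0.12, "TRAPS": 0.20, "MKD": 0.10},
    "proteinuria": {"FMF": 0.30, "CAPS": 0.15, "TRAPS": 0.22, "MKD": 0.12},
    "renal_insufficiency": {"FMF": 0.22, "CAPS": 0.10, "TRAPS": 0.15, "MKD": 0.08},
    "growth_failure": {"FMF": 0.12, "CAPS": 0.20, "TRAPS": 0.12, "MKD": 0.26},
    "puberty_delay": {"FMF": 0.10, "CAPS": 0.14, "TRAPS": 0.10, "MKD": 0.20},
    "serosal_scarring": {"FMF": 0.30, "CAPS": 0.08, "TRAPS": 0.20, "MKD": 0.08},
    "developmental_delay": {"FMF": 0.10, "CAPS": 0.32, "TRAPS": 0.10, "MKD": 0.22},
    "cognitive_impairment": {"FMF": 0.06, "CAPS": 0.26, "TRAPS": 0.06, "MKD": 0.12},
    "elevated_intracranial_pressure": {"FMF": 0.05, "CAPS": 0.26, "TRAPS": 0.05, "MKD": 0.06},
    "cns_involvement": {"FMF": 0.06, "CAPS": 0.22, "TRAPS": 0.06, "MKD": 0.10},
    "hearing_loss": {"FMF": 0.06, "CAPS": 0.46, "TRAPS": 0.10, "MKD": 0.06},
    "ocular_involvement": {"FMF": 0.08, "CAPS": 0.30, "TRAPS": 0.16, "MKD": 0.08},
    "joint_restriction": {"FMF": 0.15, "CAPS": 0.16, "TRAPS": 0.15, "MKD": 0.20},
    "bone_deformity": {"FMF": 0.08, "CAPS": 0.22, "TRAPS": 0.08, "MKD": 0.08},
    "osteoporosis": {"FMF": 0.10, "CAPS": 0.10, "TRAPS": 0.12, "MKD": 0.10},
    "musculoskeletal_pain": {"FMF": 0.25, "CAPS": 0.22, "TRAPS": 0.25, "MKD": 0.25},
}

# graded-item level choice weights when a case carries the item
_LEVEL_WEIGHTS: dict[str, Sequence[float]] = {
    "amyloidosis": (0.6, 0.4),
    "renal_insufficiency": (0.6, 0.4),
    "hearing_loss": (0.5, 0.5),
    "ocular_involvement": (0.5, 0.3, 0.2),
}

# items the simulator may express as raw measurements instead of assertions
_MEASURABLE = (
    "amyloidosis",
    "proteinuria",
    "renal_insufficiency",
    "growth_failure",
    "hearing_loss",
    "ocular_involvement",
    "osteoporosis",
)


@dataclass(frozen=True)
class StudyDesign:
    """Shape of a validation study; defaults mirror a 110-case, 11x10,
    4-raters-per-group layout with every item represented >=4 times."""

    n_cases: int = 110
    diseases: dict[str, int] = field(
        default_factory=lambda: {"CAPS": 29, "TRAPS": 27, "FMF": 29, "MKD": 25}
    )
    n_groups: int = 11
    cases_per_group: int = 10
    raters_per_group: int = 4
    min_item_occurrences: int = 4
    pediatric_fraction: float = 0.6
    female_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups * self.cases_per_group != self.n_cases:
            raise InputError(
                f"n_groups x cases_per_group = {self.n_groups * self.cases_per_group}"
                f" != n_cases {self.n_cases}"
            )
        if sum(self.diseases.values()) != self.n_cases:
            raise InputError("disease counts must sum to n_cases")
        if self.n_cases > 0 and self.raters_per_group < 1:
            raise InputError("raters_per_group must be >= 1")


@dataclass(frozen=True)
class RaterModel:
    """Misclassification model standing in for expert disagreement.

    ``p_miss``: present item scored absent; ``p_false``: absent item scored
    present; ``p_grade_confusion``: graded item shifted one level.
    """

    p_miss: float = 0.10
    p_false: float = 0.02
    p_grade_confusion: float = 0.20
    pga_noise_sd: float = 0.7
    activity_coupling: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_miss", "p_false", "p_grade_confusion"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {p}")
        if self.pga_noise_sd < 0:
            raise InputError("pga_noise_sd must be >= 0")

    def scaled(self, scale: float, cap: float = 0.9) -> "RaterModel":
        """Jointly scale the three misclassification probabilities."""
        return replace(
            self,
            p_miss=min(self.p_miss * scale, cap),
            p_false=min(self.p_false * scale, cap),
            p_grade_confusion=min(self.p_grade_confusion * scale, cap),
        )


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to reproduce and check a simulated study."""

    design: StudyDesign
    rater_model: RaterModel
    cases: tuple
    scorecards: tuple
    sigma2_between: float
    sigma2_within: float
    icc: float


# ---------------------------------------------------------------------------
# case generation

def _draw_evidence(rng: np.random.Generator, instr, item, case_age: float) -> Evidence:
    graded = bool(item.levels)
    if graded:
        weights = np.asarray(_LEVEL_WEIGHTS.get(item.item_id, [1.0] * len(item.levels)))
        label = item.levels[int(rng.choice(len(item.levels), p=weights / weights.sum()))].label
    else:
        label = "present"
    # ~13% of generated findings deliberately fail an eligibility rule
    u = rng.random()
    if u < 0.06:
        duration = float(rng.uniform(0.5, 5.5))
    else:
        duration = 6.0 + float(rng.exponential(24.0))
    attributed = rng.random() < 0.05
    onset_after = rng.random() >= 0.03
    resolved = rng.random() < 0.08
    measured = item.item_id in _MEASURABLE and rng.random() < 0.5
    if not measured:
        return Evidence(
            item_id=item.item_id,
            mode="asserted",
            asserted_grade=label,
            duration_months=duration,
            resolved=resolved,
            attributed_to_active_disease=attributed,
            onset_after_aid_onset=onset_after,
        )
    m = _measurements_for(rng, item.item_id, label, case_age)
    return Evidence(
        item_id=item.item_id,
        mode="measured",
        measurements=m,
        duration_months=duration,
        resolved=resolved,
        attributed_to_active_disease=attributed,
        onset_after_aid_onset=onset_after,
    )


def _measurements_for(rng, item_id: str, label: str, case_age: float) -> dict:
    if item_id == "renal_insufficiency":
        if label == "severe":
            if rng.random() < 0.3:
                return {"dialysis_or_transplant": True}
            return {"gfr_ml_min_1.73m2": round(float(rng.uniform(4, 14.5)), 1)}
        return {"gfr_ml_min_1.73m2": round(float(rng.uniform(15, 59.5)), 1)}
    if item_id == "proteinuria":
        which = rng.integers(3)
        if which == 0:
            return {"urine_pcr_mg_mmol": round(float(rng.uniform(21, 200)), 1)}
        if which == 1:
            return {"protein_g_24h": round(float(rng.uniform(0.35, 3.0)), 2)}
        return {"urine_acr_mg_mmol": round(float(rng.uniform(16, 80)), 1)}
    if item_id == "growth_failure":
        if case_age >= 18:
            return {"adult_short_stature": True}
        flags = [True, True, rng.random() < 0.4]
        rng.shuffle(flags)
        return {
            "height_below_p3": flags[0],
            "velocity_below_p3": flags[1],
            "crossed_2_centiles": flags[2],
        }
    if item_id == "hearing_loss":
        return {
            "hearing_impairment_confirmed": True,
            "hearing_aid_required": label == "severe",
        }
    if item_id == "ocular_involvement":
        visual = {"mild": "none", "moderate": "impaired", "severe": "legal_blindness"}[label]
        return {"ocular_damage_documented": True, "visual_impairment": visual}
    if item_id == "osteoporosis":
        return {"low_bone_density": True, "fracture_present": True}
    if item_id == "amyloidosis":
        organs = 1 if label == "limited" else int(rng.integers(2, 5))
        return {"organs_affected": organs}
    raise InputError(f"no measurement template for {item_id!r}")


def generate_cases(
    design: StudyDesign,
    instr: InstrumentDefinition,
    prevalence: Optional[dict[str, dict[str, float]]] = None,
    max_retries: int = 60,
) -> list[CaseRecord]:
    """Draw a case set; rejection-resamples whole studies until every item
    occurs eligibly at least ``design.min_item_occurrences`` times."""
    if design.n_cases == 0:
        return []
    prev = prevalence or DEFAULT_PREVALENCE
    unknown = set(prev) - set(instr.item_ids)
    if unknown:
        raise InputError(f"prevalence table references unknown item(s): {sorted(unknown)}")
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(max_retries)
    deficit: dict[str, int] = {}
    for attempt in range(max_retries):
        rng = np.random.default_rng(children[attempt])
        cases = _draw_case_set(rng, design, instr, prev)
        counts = _eligible_counts(instr, cases)
        deficit = {
            iid: counts.get(iid, 0)
            for iid in instr.item_ids
            if counts.get(iid, 0) < design.min_item_occurrences
        }
        if not deficit:
            return cases
    raise GenerationError(
        "could not satisfy min_item_occurrences="
        f"{design.min_item_occurrences} after {max_retries} attempts; "
        f"deficient items: {deficit}"
    )


def _draw_case_set(rng, design, instr, prev) -> list[CaseRecord]:
    labels = [d for d in DISEASES for _ in range(design.diseases.get(d, 0))]
    order = rng.permutation(len(labels))
    cases = []
    for i in range(design.n_cases):
        disease = labels[order[i]]
        pediatric = rng.random() < design.pediatric_fraction
        age = float(rng.uniform(2, 17.5)) if pediatric else float(rng.uniform(18, 60))
        sex = "female" if rng.random() < design.female_fraction else "male"
        evidence = []
        for item in instr.items:
            if item.pediatric_only and age >= 18:
                continue
            if item.applicable_sex == "female_relevant" and sex != "female":
                continue
            p = prev.get(item.item_id, {}).get(disease, 0.1)
            if rng.random() < p:
                evidence.append(_draw_evidence(rng, instr, item, age))
        cases.append(
            CaseRecord(
                case_id=f"case_{i + 1:03d}",
                disease=disease,
                age_years=round(age, 1),
                sex=sex,
                evidence=evidence,
            )
        )
    return cases


def _eligible_counts(instr, cases) -> dict[str, int]:
    counts: dict[str, int] = {}
    for case in cases:
        card = score_case(instr, case)
        for iid, pts in card.item_points.items():
            if pts > 0:
                counts[iid] = counts.get(iid, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# design allocation

def allocate_design(
    cases: Sequence[CaseRecord], design: StudyDesign
) -> dict[str, tuple[list[str], list[str]]]:
    """Disjoint case blocks and disjoint rater sets per group."""
    if len(cases) != design.n_cases:
        raise InputError(f"expected {design.n_cases} cases, got {len(cases)}")
    allocation: dict[str, tuple[list[str], list[str]]] = {}
    for g in range(design.n_groups):
        gid = f"G{g + 1:02d}"
        block = [
            c.case_id
            for c in cases[g * design.cases_per_group : (g + 1) * design.cases_per_group]
        ]
        raters = [f"{gid}_R{r + 1}" for r in range(design.raters_per_group)]
        allocation[gid] = (block, raters)
    return allocation


# ---------------------------------------------------------------------------
# rating simulation

def true_grade_labels(instr: InstrumentDefinition, case: CaseRecord) -> dict[str, Optional[str]]:
    """Per-item true grade label (None = no eligible damage) for a case.

    Measured evidence is resolved through the same graders the scoring
    engine uses, so the simulator and engine cannot drift apart.
    """
    labels: dict[str, Optional[str]] = {iid: None for iid in instr.item_ids}
    for ev in case.evidence:
        eligible, _ = is_damage_eligible(ev)
        if not eligible:
            continue
        if ev.mode == "asserted":
            labels[ev.item_id] = ev.asserted_grade
        else:
            labels[ev.item_id] = _grade_measured(ev, case)
    return labels


def simulate_ratings(
    cases: Sequence[CaseRecord],
    allocation: dict[str, tuple[list[str], list[str]]],
    rater_model: RaterModel,
    instr: InstrumentDefinition,
) -> pd.DataFrame:
    """Perturb each case's true grades per rater and re-score through the
    engine's capping arithmetic; returns the long-format rating table."""
    index = ScoringIndex(instr)
    by_id = {c.case_id: c for c in cases}
    truth = {cid: true_grade_labels(instr, c) for cid, c in by_id.items()}
    true_totals = {cid: index.score(truth[cid])[2] for cid in by_id}
    rng = np.random.default_rng(rater_model.seed)

    # per-case latent disease activity, weakly coupled to damage
    cids = sorted(by_id)
    totals = np.array([true_totals[cid] for cid in cids], dtype=float)
    sd = totals.std()
    z = (totals - totals.mean()) / sd if sd > 0 else np.zeros_like(totals)
    c = rater_model.activity_coupling
    latent = c * z + np.sqrt(max(0.0, 1 - c * c)) * rng.standard_normal(len(cids))
    activity = {cid: 5.0 + 1.8 * latent[i] for i, cid in enumerate(cids)}

    rows = []
    max_total = instr.max_total
    for gid in sorted(allocation):
        case_ids, rater_ids = allocation[gid]
        for rater in rater_ids:
            for cid in case_ids:
                case = by_id[cid]
                perturbed = _perturb(rng, index, truth[cid], rater_model, case)
                item_points, _, total = index.score(perturbed)
                pga_d = 10.0 * true_totals[cid] / max_total
                pga_a = activity[cid]
                if rater_model.pga_noise_sd > 0:
                    # observation noise, then 10-point integer granularity
                    pga_d = round(pga_d + rng.normal(0, rater_model.pga_noise_sd))
                    pga_a = round(pga_a + rng.normal(0, rater_model.pga_noise_sd))
                row = {
                    "case_id": cid,
                    "rater_id": rater,
                    "group_id": gid,
                    "disease": case.disease,
                }
                row.update(item_points)
                row["total"] = total
                row["pga_damage"] = float(np.clip(pga_d, 0, 10))
                row["pga_activity"] = float(np.clip(pga_a, 0, 10))
                rows.append(row)
    df = pd.DataFrame(rows, columns=rating_table_columns(instr))
    return df


def _perturb(rng, index: ScoringIndex, truth: dict, model: RaterModel, case) -> dict:
    """One rater's reading of one case's true grade map."""
    seen: dict[str, Optional[str]] = {}
    for iid, label in truth.items():
        if label is not None:
            if rng.random() < model.p_miss:
                seen[iid] = None
                continue
            labels = index.labels[iid]
            if len(labels) > 1 and rng.random() < model.p_grade_confusion:
                pos = labels.index(label)
                shift = 1 if rng.random() < 0.5 else -1
                pos = min(max(pos + shift, 0), len(labels) - 1)
                seen[iid] = labels[pos]
            else:
                seen[iid] = label
        else:
            if rng.random() < model.p_false and _applicable(index.instr, iid, case):
                seen[iid] = index.labels[iid][0]
            else:
                seen[iid] = None
    return seen


def _applicable(instr, item_id: str, case) -> bool:
    item = instr.item(item_id)
    if item.pediatric_only and case.is_adult:
        return False
    if item.applicable_sex == "female_relevant" and case.sex != "female":
        return False
    return True


# ---------------------------------------------------------------------------
# calibration

def monte_carlo_icc(
    design: StudyDesign,
    rater_model: RaterModel,
    instr: InstrumentDefinition,
    n_reps: int = 20,
    seed: int = 0,
    vary_cases: bool = True,
    _study_cache: Optional[list] = None,
) -> dict[str, float]:
    """Mean ICC of totals and ANOVA variance components over ``n_reps``
    simulated studies.

    ``vary_cases=False`` regenerates only the rater noise, holding one case
    set fixed -- the validation-study situation, where the cases are a fixed
    panel and replication varies observers.
    """
    iccs, s2b, s2w = [], [], []
    studies = _study_cache if _study_cache is not None else _make_studies(
        design, instr, n_reps, seed, vary_cases
    )
    for rep, (cases, alloc, rater_seed) in enumerate(studies[:n_reps]):
        model = replace(rater_model, seed=rater_seed)
        ratings = simulate_ratings(cases, alloc, model, instr)
        scores = {
            cid: grp["total"].to_numpy() for cid, grp in ratings.groupby("case_id")
        }
        try:
            res = estimate_icc_oneway(scores)
        except DegenerateVarianceError:
            continue
        iccs.append(res.icc)
        s2w.append(res.msw)
        s2b.append(max(0.0, (res.msb - res.msw) / res.k0))
    if not iccs:
        raise DegenerateVarianceError("all replicates degenerate")
    return {
        "icc": float(np.mean(iccs)),
        "sigma2_between": float(np.mean(s2b)),
        "sigma2_within": float(np.mean(s2w)),
        "n_reps": float(len(iccs)),
    }


def _make_studies(design, instr, n_reps, seed, vary_cases=True):
    """Replicate studies (cases, allocation, rater seed), reusable across
    calibration evaluations so the bisection target function is smooth."""
    studies = []
    ss = np.random.SeedSequence([seed, design.seed])
    rater_seeds = ss.generate_state(n_reps)
    fixed = None
    if not vary_cases:
        cases = generate_cases(design, instr)
        fixed = (cases, allocate_design(cases, design))
    for rep in range(n_reps):
        if vary_cases:
            d = replace(design, seed=design.seed + 7919 * (rep + 1))
            cases = generate_cases(d, instr)
            alloc = allocate_design(cases, d)
        else:
            cases, alloc = fixed
        studies.append((cases, alloc, int(rater_seeds[rep])))
    return studies


def calibrate_noise_to_icc(
    target_icc: float,
    design: StudyDesign,
    instr: InstrumentDefinition,
    tol: float = 0.03,
    max_iter: int = 40,
    seed: int = 0,
    n_reps: int = 20,
    base_model: Optional[RaterModel] = None,
    vary_cases: bool = True,
) -> tuple[RaterModel, float]:
    """Bisect a single noise-scale multiplier until the Monte-Carlo mean ICC
    is within ``tol`` of ``target_icc``; returns (model, achieved ICC)."""
    if not 0.0 < target_icc < 1.0:
        raise InputError("target_icc must lie strictly inside (0, 1)")
    base = base_model or RaterModel(seed=seed)
    studies = _make_studies(design, instr, n_reps, seed, vary_cases)

    def f(scale: float) -> float:
        return monte_carlo_icc(
            design, base.scaled(scale), instr, n_reps=n_reps, seed=seed,
            _study_cache=studies,
        )["icc"]

    lo, hi = 0.0, 1.0
    f_hi = f(hi)
    while f_hi > target_icc:
        lo, hi = hi, hi * 2.0
        if hi > 512.0:
            raise CalibrationError(
                f"cannot reach target {target_icc}: ICC floor {f_hi:.3f} at scale {lo}"
            )
        f_hi = f(hi)
    best_scale, best_icc = hi, f_hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid - target_icc) < abs(best_icc - target_icc):
            best_scale, best_icc = mid, f_mid
        if abs(f_mid - target_icc) <= tol:
            return base.scaled(mid), f_mid
        if f_mid > target_icc:
            lo = mid
        else:
            hi = mid
    if abs(best_icc - target_icc) <= 2 * tol:
        warnings.warn(
            f"calibration stopped at |achieved-target| = {abs(best_icc - target_icc):.4f}",
            stacklevel=2,
        )
        return base.scaled(best_scale), best_icc
    raise CalibrationError(
        f"no noise scale within tol {tol} of target {target_icc} "
        f"after {max_iter} iterations (best {best_icc:.3f})"
    )


def build_ground_truth(
    design: StudyDesign,
    rater_model: RaterModel,
    instr: InstrumentDefinition,
    n_reps: int = 10,
) -> GroundTruth:
    cases = generate_cases(design, instr)
    cards = tuple(score_case(instr, c) for c in cases)
    mc = monte_carlo_icc(design, rater_model, instr, n_reps=n_reps, seed=design.seed)
    return GroundTruth(
        design=design,
        rater_model=rater_model,
        cases=tuple(cases),
        scorecards=cards,
        sigma2_between=mc["sigma2_between"],
        sigma2_within=mc["sigma2_within"],
        icc=mc["icc"],
    )
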