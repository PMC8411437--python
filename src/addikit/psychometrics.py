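"""Reliability and validity statistics for the nested rating design.

The rating design assigns a disjoint set of raters to each block of cases
("observer nested within subject"), so raters are not crossed with cases
and the one-way random-effects model is the only identifiable one. The
intraclass correlation implemented here is the single-measures,
absolute-agreement ICC of that model,

    ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW),

with MSB/MSW the between/within-case ANOVA mean squares and k0 the
effective ratings-per-case for unbalanced data,

    k0 = (N - sum(k_i^2) / N) / (n - 1).

Confidence intervals come from the F pivot MSB/MSW mapped through the same
ICC transform.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from addikit.errors import DegenerateVarianceError, InputError
from addikit.instrument import InstrumentDefinition
from addikit.scoring import ScoringIndex

__all__ = [
    "IccResult",
    "AlphaResult",
    "CorrelationResult",
    "estimate_icc_oneway",
    "cronbach_alpha",
    "spearman_with_ci",
    "mean_per_case",
    "rating_table_columns",
    "validate_rating_table",
    "load_rating_table",
    "save_rating_table",
    "strength_band",
]

PGA_SCALE_MAX = 10


@dataclass(frozen=True)
class IccResult:
    """One-way random-effects ICC point estimate with F-based 95% CI."""

    icc: float
    ci_lower: float
    ci_upper: float
    n_subjects: int
    n_ratings: int
    k0: float
    msb: float
    msw: float

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.icc + 1e-12 and self.icc <= self.ci_upper + 1e-12):
            raise ValueError("CI does not bracket the ICC estimate")


@dataclass(frozen=True)
class AlphaResult:
    """Cronbach's alpha plus the pairwise interitem correlation matrix."""

    alpha: float
    n_items: int
    interitem: np.ndarray
    item_names: tuple[str, ...]
    redundant_pairs: tuple[tuple[str, str, float], ...] = ()
    dropped_items: tuple[str, ...] = ()


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_pairs: int
    strength_band: str
    method: str = "fisher"


def strength_band(rho: float) -> str:
    """Descriptive band on |rho|: 0.1-0.3 weak, 0.3-0.5 moderate, >0.5 strong."""
    r = abs(rho)
    if r > 0.5:
        return "strong"
    if r >= 0.3:
        return "moderate"
    if r >= 0.1:
        return "weak"
    return "negligible"


# ---------------------------------------------------------------------------
# ICC

def estimate_icc_oneway(
    scores: Mapping[str, Sequence[float]], alpha_level: float = 0.05
) -> IccResult:
    """Single-measures one-way random-effects ICC on a case -> ratings map.

    Cases with fewer than two ratings are dropped with a warning (group-level
    minimum-rater filtering is applied upstream). Raw, possibly negative,
    estimates are returned unclipped.
    """
    groups: dict[str, np.ndarray] = {}
    for cid, vals in scores.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            warnings.warn(
                f"case {cid!r} has {arr.size} rating(s); dropped from ICC",
                stacklevel=2,
            )
            continue
        groups[cid] = arr
    n = len(groups)
    if n < 2:
        raise InputError(f"need >=2 cases with >=2 ratings, got {n}")
    sizes = np.array([g.size for g in groups.values()], dtype=float)
    N = float(sizes.sum())
    grand = sum(g.sum() for g in groups.values()) / N
    means = np.array([g.mean() for g in groups.values()])
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups.values()))
    msb = ssb / (n - 1)
    msw = ssw / (N - n)
    if msb <= 0 and msw <= 0:
        raise DegenerateVarianceError("all scores identical; ICC undefined")
    k0 = (N - float(np.sum(sizes**2)) / N) / (n - 1)

    def _to_icc(f_ratio: float) -> float:
        if np.isinf(f_ratio):
            return 1.0
        return (f_ratio - 1.0) / (f_ratio + k0 - 1.0)

    if msw == 0.0:
        return IccResult(1.0, 1.0, 1.0, n, int(N), k0, msb, msw)
    f_obs = msb / msw
    df1, df2 = n - 1, int(N) - n
    f_upper_crit = stats.f.ppf(1 - alpha_level / 2, df1, df2)
    f_lower_crit = stats.f.ppf(1 - alpha_level / 2, df2, df1)
    fl = f_obs / f_upper_crit
    fu = f_obs * f_lower_crit
    return IccResult(
        icc=_to_icc(f_obs),
        ci_lower=_to_icc(fl),
        ci_upper=_to_icc(fu),
        n_subjects=n,
        n_ratings=int(N),
        k0=k0,
        msb=msb,
        msw=msw,
    )


# ---------------------------------------------------------------------------
# Cronbach's alpha / interitem correlations

def cronbach_alpha(
    item_matrix: Union[pd.DataFrame, np.ndarray],
    item_names: Optional[Sequence[str]] = None,
    redundancy_threshold: float = 0.7,
) -> AlphaResult:
    """alpha = m/(m-1) * (1 - sum(var_i) / var(total)) with sample variances.

    Zero-variance items are excluded from the interitem matrix with a
    warning; pairs correlating above ``redundancy_threshold`` are flagged.
    """
    if isinstance(item_matrix, pd.DataFrame):
        names = list(item_matrix.columns.astype(str))
        X = item_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(item_matrix, dtype=float)
        names = list(item_names) if item_names is not None else [
            f"item_{j}" for j in range(X.shape[1])
        ]
    if X.ndim != 2:
        raise InputError("item matrix must be 2-D (cases x items)")
    n_cases, m_all = X.shape
    if n_cases < 3:
        raise InputError(f"need >=3 cases, got {n_cases}")
    variances = X.var(axis=0, ddof=1)
    keep = variances > 0
    dropped = tuple(str(names[j]) for j in range(m_all) if not keep[j])
    if dropped:
        warnings.warn(
            f"zero-variance item(s) excluded: {', '.join(dropped)}", stacklevel=2
        )
    X = X[:, keep]
    names = [names[j] for j in range(m_all) if keep[j]]
    m = X.shape[1]
    if m < 2:
        raise InputError("fewer than 2 items with variance; alpha undefined")
    total_var = X.sum(axis=1).var(ddof=1)
    alpha = (m / (m - 1)) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var)
    interitem = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(interitem, 1.0)
    flagged = []
    for i in range(m):
        for j in range(i + 1, m):
            if interitem[i, j] > redundancy_threshold:
                flagged.append((names[i], names[j], float(interitem[i, j])))
    return AlphaResult(
        alpha=float(alpha),
        n_items=m,
        interitem=interitem,
        item_names=tuple(names),
        redundant_pairs=tuple(flagged),
        dropped_items=dropped,
    )


# ---------------------------------------------------------------------------
# Spearman correlation with CI

def spearman_with_ci(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "fisher",
    seed: Optional[int] = None,
    alpha_level: float = 0.05,
    n_boot: int = 2000,
) -> CorrelationResult:
    """Spearman rho (Pearson on average ranks) with Fisher-z or bootstrap CI.

    The Fisher interval uses SE = 1.06/sqrt(n-3), the standard Spearman
    correction; the bootstrap interval is the percentile interval over
    ``n_boot`` case resamples driven by ``seed``.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise InputError("x and y must have equal length")
    n = xa.size
    if n < 4:
        raise InputError(f"need >=4 pairs, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise InputError("constant input vector; correlation undefined")
    rho = _rank_pearson(xa, ya)
    # two-sided p via the t approximation
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if method == "fisher":
        if abs(rho) >= 1.0 - 1e-15:
            lo = hi = rho
        else:
            z = np.arctanh(rho)
            se = 1.06 / np.sqrt(n - 3)
            zc = stats.norm.ppf(1 - alpha_level / 2)
            lo, hi = float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        reps.fill(np.nan)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            xb, yb = xa[idx], ya[idx]
            if np.ptp(xb) == 0 or np.ptp(yb) == 0:
                continue
            reps[b] = _rank_pearson(xb, yb)
        reps = reps[~np.isnan(reps)]
        if reps.size == 0:
            raise InputError("all bootstrap resamples degenerate")
        lo = float(np.percentile(reps, 100 * alpha_level / 2))
        hi = float(np.percentile(reps, 100 * (1 - alpha_level / 2)))
    else:
        raise InputError(f"unknown CI method {method!r}")
    return CorrelationResult(
        rho=float(rho),
        ci_lower=lo,
        ci_upper=hi,
        p_value=p,
        n_pairs=n,
        strength_band=strength_band(rho),
        method=method,
    )


def _rank_pearson(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    return float((rxc * ryc).sum() / denom)


# ---------------------------------------------------------------------------
# rating tables

def mean_per_case(
    ratings: pd.DataFrame, field: str, min_raters: int = 3
) -> dict[str, float]:
    """Per-case mean of ``field`` over raters; cases with fewer than
    ``min_raters`` ratings are excluded."""
    if field not in ("total", "pga_damage", "pga_activity"):
        raise InputError(f"unknown field {field!r}")
    if min_raters < 1:
        raise InputError("min_raters must be >= 1")
    grouped = ratings.groupby("case_id")[field]
    counts = grouped.count()
    means = grouped.mean()
    keep = counts[counts >= min_raters].index
    result = {str(cid): float(means[cid]) for cid in keep}
    if not result:
        raise InputError("no case has enough raters")
    return result


def rating_table_columns(instr: InstrumentDefinition) -> list[str]:
    return (
        ["case_id", "rater_id", "group_id", "disease"]
        + list(instr.item_ids)
        + ["total", "pga_damage", "pga_activity"]
    )


def validate_rating_table(df: pd.DataFrame, instr: InstrumentDefinition) -> None:
    """Schema + bounds check; raises :class:`InputError` naming the problem."""
    expected = rating_table_columns(instr)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise InputError(f"rating table missing column(s): {', '.join(missing)}")
    dup = df.duplicated(subset=["case_id", "rater_id"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["case_id", "rater_id"]].tolist()
        raise InputError(f"duplicate (case_id, rater_id) pair: {pair}")
    group_per_case = df.groupby("case_id")["group_id"].nunique()
    if (group_per_case > 1).any():
        bad = group_per_case[group_per_case > 1].index[0]
        raise InputError(f"case {bad!r} appears in more than one group")
    for iid in instr.item_ids:
        cap = instr.item(iid).max_points
        col = df[iid]
        if (col < 0).any() or (col > cap).any():
            raise InputError(f"item column {iid!r} out of bounds [0, {cap}]")
    for col in ("pga_damage", "pga_activity"):
        if (df[col] < 0).any() or (df[col] > PGA_SCALE_MAX).any():
            raise InputError(f"{col} out of bounds [0, {PGA_SCALE_MAX}]")


def load_rating_table(
    source: Union[str, "io.TextIOBase"], instr: InstrumentDefinition
) -> pd.DataFrame:
    """Read the long-format rating CSV, validate, and cross-check totals
    against the scoring engine's capping arithmetic (mismatches warn)."""
    df = pd.read_csv(source)
    validate_rating_table(df, instr)
    index = ScoringIndex(instr)
    recomputed = np.zeros(len(df), dtype=int)
    caps = index.caps
    for cid, items in index.cat_items.items():
        recomputed += np.minimum(caps[cid], df[items].sum(axis=1)).astype(int)
    mismatch = recomputed != df["total"].to_numpy()
    if mismatch.any():
        n_bad = int(mismatch.sum())
        warnings.warn(
            f"{n_bad} row(s) whose total disagrees with capped item sums",
            stacklevel=2,
        )
    return df


def save_rating_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
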