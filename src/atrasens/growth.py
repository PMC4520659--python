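"""Doubling times, growth-inhibition profiles, the ATRA score, and the
sensitivity stratifications (groups A–D, tertiles T1–T3).

The ATRA score quantifies sensitivity to the cytostatic action of
all-trans retinoic acid from a dose/time growth assay. For each tested
concentration c the normalized growth-rate inhibition between two assay
days t1 < t2 (default 3 and 6) is

    I_c = clip(1 - log2(OD_c(t2)/OD_c(t1)) / log2(OD_0(t2)/OD_0(t1)), 0, 1)

computed on replicate-mean optical densities, with concentration 0 the
vehicle. I_c = 0 means growth identical to vehicle; I_c = 1 means complete
cytostasis (or regression, clipped). The scalar score is the trapezoidal
mean of I_c over log10(concentration) across the tested nonzero doses:

    score = (∫ I d log10 c) / (log10 c_max - log10 c_min)  ∈ [0, 1]

Higher score = more sensitive. A dose-averaged growth-rate readout is used
instead of an IC50 because ATRA is growth-inhibitory rather than cytotoxic:
half-maximal kill concentrations are ill-defined for a cytostatic agent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data_model import (
    GrowthAssay,
    NonGrowthError,
    NormalizationError,
    ValidationError,
)

logger = logging.getLogger("atrasens")

GROUP_LABELS = "ABCD"


@dataclass
class GrowthParams:
    """Doubling time from a log-linear fit of mean OD versus day."""

    td_days: float
    fit_r2: float
    n_points: int


@dataclass
class AtraScoreResult:
    """Per-concentration inhibition profile and the scalar sensitivity score."""

    cell_line: str
    inhibition: dict[float, float]   # concentration (μM) -> I_c in [0, 1]
    score: float
    interval: tuple[float, float] = (3.0, 6.0)
    group: str = "unset"             # A (most sensitive) .. D, set by cohort stage
    tertile: str = "unset"           # T1 (most sensitive) .. T3


# ---------------------------------------------------------------------------
# Doubling time
# ---------------------------------------------------------------------------

def estimate_doubling_time(assay: GrowthAssay,
                           concentration: float = 0.0) -> GrowthParams:
    """Least-squares fit of log2(mean OD) against day; td = 1/slope.

    Raises :class:`NonGrowthError` if the fitted slope is not positive
    (no net growth, doubling time undefined).
    """
    days = [d for d in assay.days
            if not assay.data[
                (assay.data["concentration_uM"] == concentration)
                & (assay.data["day"] == d)].empty]
    if len(days) < 2:
        raise ValidationError(
            f"need >= 2 days with readings at concentration {concentration}"
        )
    means = np.array([assay.mean_od(concentration, d) for d in days])
    if (means <= 0).any():
        raise ValidationError("mean OD must be positive for a log-linear fit")
    x = np.asarray(days, dtype=float)
    y = np.log2(means)
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 1e-12:  # flat within numerical noise counts as non-growth
        raise NonGrowthError(
            f"{assay.cell_line!r}: no net growth at concentration "
            f"{concentration} (slope {slope:.3g} doublings/day)"
        )
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return GrowthParams(td_days=1.0 / slope, fit_r2=r2, n_points=len(days))


# ---------------------------------------------------------------------------
# Inhibition profile and score
# ---------------------------------------------------------------------------

def growth_inhibition_profile(assay: GrowthAssay, t1: float = 3.0,
                              t2: float = 6.0) -> dict[float, float]:
    """Vehicle-normalized growth-rate inhibition per concentration.

    Replicates are averaged before ratios are formed, mirroring how
    mean ± SD growth curves are drawn.
    """
    if not t1 < t2:
        raise ValidationError("need t1 < t2")
    for t in (t1, t2):
        if t not in assay.days:
            raise ValidationError(
                f"day {t} absent from assay for {assay.cell_line!r}"
            )
    od0_t1 = assay.mean_od(0.0, t1)
    od0_t2 = assay.mean_od(0.0, t2)
    if od0_t1 <= 0 or od0_t2 <= 0:
        raise ValidationError("vehicle mean OD must be positive")
    vehicle_growth = math.log2(od0_t2 / od0_t1)
    if vehicle_growth <= 0:
        raise NormalizationError(
            f"{assay.cell_line!r}: vehicle shows no net growth between "
            f"days {t1} and {t2}; inhibition profile undefined"
        )
    profile: dict[float, float] = {}
    for c in assay.concentrations:
        odc_t1 = assay.mean_od(c, t1)
        odc_t2 = assay.mean_od(c, t2)
        if odc_t1 <= 0:
            raise ValidationError(
                f"{assay.cell_line!r}: nonpositive OD at c={c}, day {t1}"
            )
        growth = math.log2(odc_t2 / odc_t1)
        inhibition = 1.0 - growth / vehicle_growth
        profile[c] = min(1.0, max(0.0, inhibition))
    profile[0.0] = 0.0  # vehicle inhibition is 0 by construction
    return profile


def score_from_profile(inhibition: Mapping[float, float]) -> float:
    """Trapezoidal mean of I_c over log10(concentration), nonzero doses only."""
    doses = sorted(c for c in inhibition if c > 0)
    if not doses:
        raise ValidationError("no nonzero concentrations in profile")
    if len(doses) == 1:
        logger.warning(
            "single nonzero dose: score falls back to the single I_c value"
        )
        return float(inhibition[doses[0]])
    x = np.log10(doses)
    y = np.array([inhibition[c] for c in doses], dtype=float)
    return float(np.trapezoid(y, x) / (x[-1] - x[0]))


def atra_score(assay: GrowthAssay, t1: float = 3.0,
               t2: float = 6.0) -> AtraScoreResult:
    """Compute the scalar ATRA-sensitivity score for one cell line.

    The score is bounded in [0, 1] and monotone nondecreasing in any
    pointwise increase of the inhibition profile.
    """
    profile = growth_inhibition_profile(assay, t1, t2)
    score = score_from_profile(profile)
    return AtraScoreResult(
        cell_line=assay.cell_line,
        inhibition=profile,
        score=score,
        interval=(t1, t2),
    )


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

def _contiguous_partition(sorted_values: np.ndarray, k: int) -> list[int]:
    """Optimal contiguous k-partition of sorted values minimizing the
    within-block sum of squared deviations. Returns block boundaries as the
    start index of each block (first is always 0). O(n^2 k) dynamic program;
    deterministic, ties resolved toward earlier boundaries.
    """
    n = len(sorted_values)
    prefix = np.concatenate([[0.0], np.cumsum(sorted_values)])
    prefix2 = np.concatenate([[0.0], np.cumsum(sorted_values ** 2)])

    def block_cost(i: int, j: int) -> float:
        # SSE of values[i:j]
        s = prefix[j] - prefix[i]
        s2 = prefix2[j] - prefix2[i]
        m = j - i
        return max(s2 - s * s / m, 0.0)

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for b in range(1, k + 1):
        for j in range(b, n + 1):
            best, arg = INF, b - 1
            for i in range(b - 1, j):
                c = cost[b - 1, i] + block_cost(i, j)
                if c < best:
                    best, arg = c, i
            cost[b, j] = best
            back[b, j] = arg
    bounds = [0] * k
    j = n
    for b in range(k, 0, -1):
        i = back[b, j]
        bounds[b - 1] = i
        j = i
    return bounds


def assign_sensitivity_groups(scores: Mapping[str, float],
                              k: int = 4) -> dict[str, str]:
    """Partition lines into k contiguous score blocks, labeled A (highest
    scores, most sensitive) through D (lowest).

    Deterministic optimal 1-D contiguous partitioning (within-group sum of
    squares) rather than seeded k-means, so repeated runs agree exactly.
    """
    if k < 1 or k > len(GROUP_LABELS):
        raise ValidationError(f"k must lie in 1..{len(GROUP_LABELS)}")
    lines = list(scores)
    if len(set(scores.values())) < k:
        raise ValidationError(f"need >= {k} distinct scores for {k} groups")
    order = sorted(range(len(lines)), key=lambda i: scores[lines[i]])
    values = np.array([scores[lines[i]] for i in order], dtype=float)
    bounds = _contiguous_partition(values, k) + [len(values)]
    labels: dict[str, str] = {}
    for b in range(k):
        # ascending block b gets label k-1-b from the end: lowest block -> last label
        label = GROUP_LABELS[k - 1 - b]
        for pos in range(bounds[b], bounds[b + 1]):
            labels[lines[order[pos]]] = label
    return labels


def assign_tertiles(scores: Mapping[str, float]) -> dict[str, str]:
    """Rank-based equal thirds: T1 = highest scores (ATRA sensitive),
    T3 = lowest (resistant). Sizes differ by at most one, with the larger
    thirds at the extremes first; ties keep stable input order.
    """
    lines = list(scores)
    n = len(lines)
    if n < 3:
        raise ValidationError("need >= 3 lines for tertiles")
    # stable sort: descending score, ties by input position
    order = sorted(range(n), key=lambda i: (-scores[lines[i]], i))
    q, r = divmod(n, 3)
    sizes = [q, q, q]
    if r >= 1:
        sizes[0] += 1
    if r == 2:
        sizes[2] += 1
    labels: dict[str, str] = {}
    pos = 0
    for t, size in enumerate(sizes, start=1):
        for i in order[pos: pos + size]:
            labels[lines[i]] = f"T{t}"
        pos += size
    return labels


def score_screen(assays: Mapping[str, GrowthAssay], t1: float = 3.0,
                 t2: float = 6.0) -> tuple[dict[str, AtraScoreResult],
                                           dict[str, Exception]]:
    """Score every line of a screen; failures are collected, not fatal."""
    results: dict[str, AtraScoreResult] = {}
    errors: dict[str, Exception] = {}
    for line, assay in assays.items():
        try:
            results[line] = atra_score(assay, t1, t2)
        except Exception as exc:  # noqa: BLE001 - per-line degradation
            logger.warning("scoring failed for %r: %s", line, exc)
            errors[line] = exc
    scores = {line: r.score for line, r in results.items()}
    if len(set(scores.values())) >= 4:
        groups = assign_sensitivity_groups(scores)
        for line, g in groups.items():
            results[line].group = g
    if len(scores) >= 3:
        tertiles = assign_tertiles(scores)
        for line, t in tertiles.items():
            results[line].tertile = t
    return results, errors
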