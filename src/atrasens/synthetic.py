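"""Seeded generators for growth assays, expression cohorts and slice cohorts.

Each generator is a pure function of its seed and emulates the statistical
structure the downstream stages assume:

* exponential cell growth with Hill-type dose-dependent growth-rate
  inhibition and multiplicative lognormal noise;
* expression cohorts with a chosen number of genes linearly associated
  with the sensitivity score;
* paired vehicle/ATRA slice profiles with subtype-specific planted log2
  treatment effects and binomially sampled Ki67 field counts.

Planted structure (informative gene ids, true effects) is returned next to
the data so tests can use it as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ExpressionMatrix,
    GrowthAssay,
    SampleAnnotation,
    SliceCohort,
    SlicePatient,
    ValidationError,
)

#: Default screen grid: vehicle plus five log-spaced ATRA doses (μM),
#: read-outs at days 3, 6 and 9.
DEFAULT_CONCENTRATIONS = (0.0, 0.001, 0.01, 0.1, 1.0, 10.0)
DEFAULT_DAYS = (3.0, 6.0, 9.0)


def hill_inhibition(c: np.ndarray | float, imax: float, ec50_um: float,
                    hill: float) -> np.ndarray | float:
    """Fractional growth-rate inhibition I(c) = imax * c^h / (ec50^h + c^h)."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        num = np.power(c, hill)
    out = imax * num / (ec50_um ** hill + num)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Growth assays
# ---------------------------------------------------------------------------

@dataclass
class GrowthSimParams:
    """Parameters of the exponential-growth / Hill-inhibition assay model.

    OD(c, t) = od0 * 2^(t * (1 - I(c)) / td_days), with
    I(c) = imax * c^hill / (ec50^hill + c^hill) and each reading multiplied
    by exp(N(0, cv)) noise (absorbance noise scales with signal and stays
    positive).
    """

    od0: float = 0.1           # initial optical density (absorbance units)
    td_days: float = 1.5       # doubling time, days
    imax: float = 0.8          # maximal fractional growth-rate inhibition
    ec50_um: float = 0.1       # half-effect ATRA concentration, μM
    hill: float = 1.0          # Hill coefficient
    cv: float = 0.0            # multiplicative noise coefficient of variation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od0 <= 0:
            raise ValidationError("od0 must be > 0")
        if self.td_days <= 0:
            raise ValidationError("td_days must be > 0")
        if not 0.0 <= self.imax <= 1.0:
            raise ValidationError("imax must lie in [0, 1]")
        if self.hill <= 0:
            raise ValidationError("hill must be > 0")
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")


def simulate_growth_assay(params: GrowthSimParams,
                          concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
                          days: Sequence[float] = DEFAULT_DAYS,
                          n_replicates: int = 3,
                          cell_line: str = "SIM") -> GrowthAssay:
    """Simulate one cell line's dose/time growth assay.

    With ``cv=0`` the generated ODs follow the closed form exactly, so the
    growth-inhibition profile of the output recovers I(c) at every dose.
    """
    if 0.0 not in set(float(c) for c in concentrations):
        raise ValidationError("concentrations must include the vehicle (0)")
    if not days:
        raise ValidationError("days must be nonempty")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rng = np.random.default_rng(params.seed)
    rows = []
    for c in concentrations:
        inhib = hill_inhibition(float(c), params.imax, params.ec50_um, params.hill)
        rate = (1.0 - inhib) / params.td_days  # doublings per day
        for t in days:
            clean = params.od0 * 2.0 ** (float(t) * rate)
            for r in range(n_replicates):
                noise = np.exp(rng.normal(0.0, params.cv)) if params.cv > 0 else 1.0
                rows.append((float(c), float(t), r, clean * noise))
    data = pd.DataFrame(rows, columns=["concentration_uM", "day", "replicate", "od"])
    return GrowthAssay(cell_line=cell_line, data=data)


def simulate_screen(params_per_line: Mapping[str, GrowthSimParams],
                    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
                    days: Sequence[float] = DEFAULT_DAYS,
                    n_replicates: int = 3) -> dict[str, GrowthAssay]:
    """Simulate a multi-line screen, one :class:`GrowthSimParams` per line."""
    return {
        line: simulate_growth_assay(p, concentrations, days, n_replicates, line)
        for line, p in params_per_line.items()
    }


# ---------------------------------------------------------------------------
# Cell-line expression cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSimParams:
    """Cohort with ``n_informative`` genes linearly tied to the score.

    Scores are Uniform(0, 1); an informative gene's expression is
    ``beta * score + N(0, noise_sd)``, a noise gene's is ``N(0, noise_sd)``.
    With the defaults (beta=1, noise_sd=0.385) the gene–score correlation is
    approximately 0.6, a moderate association a ranking method should
    recover without being trivial.
    """

    n_lines: int = 40
    n_genes: int = 2000
    n_informative: int = 20
    beta: float = 1.0
    noise_sd: float = 0.385
    lineage_threshold: float = 0.5  # score above -> Luminal, below -> Basal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValidationError("n_informative must be <= n_genes")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_lines < 1 or self.n_genes < 1:
            raise ValidationError("n_lines and n_genes must be positive")


@dataclass
class CohortSim:
    """A simulated cohort plus the planted truth used by test oracles."""

    expr: ExpressionMatrix
    scores: pd.Series                  # per-line sensitivity score
    annotation: SampleAnnotation
    informative_genes: list[str]       # planted gene ids


def simulate_cellline_cohort(params: CohortSimParams,
                             platform: str = "other") -> CohortSim:
    """Simulate an expression cohort whose first genes track the score.

    The lineage label mimics the enrichment of Basal lines among
    ATRA-resistant (low-score) lines: lines above ``lineage_threshold`` are
    labeled Luminal, the rest Basal.
    """
    rng = np.random.default_rng(params.seed)
    lines = [f"L{i:03d}" for i in range(params.n_lines)]
    genes = [f"G{i:05d}" for i in range(params.n_genes)]
    scores = rng.uniform(0.0, 1.0, size=params.n_lines)

    values = rng.normal(0.0, params.noise_sd,
                        size=(params.n_genes, params.n_lines))
    informative = genes[: params.n_informative]
    values[: params.n_informative, :] += params.beta * scores[None, :]

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=lines), platform=platform
    )
    score_series = pd.Series(scores, index=lines, name="atra_score")
    lineage = np.where(scores >= params.lineage_threshold, "Luminal", "Basal")
    annot = SampleAnnotation(pd.DataFrame({"lineage": lineage}, index=lines))
    return CohortSim(expr=expr, scores=score_series, annotation=annot,
                     informative_genes=list(informative))


def remeasure_cohort(cohort: CohortSim, noise_sd: float, seed: int,
                     platform: str = "other") -> CohortSim:
    """A second noisy measurement of the same cohort (new platform replicate).

    Fresh measurement noise is added on top of the original values; the
    planted structure and scores are unchanged. Used to study cross-platform
    reproducibility of signature discovery.
    """
    rng = np.random.default_rng(seed)
    noisy = cohort.expr.values + rng.normal(0.0, noise_sd,
                                            size=cohort.expr.values.shape)
    return CohortSim(
        expr=ExpressionMatrix(noisy, platform=platform),
        scores=cohort.scores.copy(),
        annotation=SampleAnnotation(cohort.annotation.table.copy()),
        informative_genes=list(cohort.informative_genes),
    )


# ---------------------------------------------------------------------------
# Tissue-slice cohorts
# ---------------------------------------------------------------------------

@dataclass
class SliceSimParams:
    """Paired vehicle/ATRA slice cohort with planted treatment effects.

    ``effects`` maps subtype -> {gene id -> planted log2 shift under ATRA}.
    ``ki67_drop`` maps subtype -> fractional decrease of the Ki67-positive
    probability under ATRA. Ki67 counts are Binomial(cells_per_field, p).
    The default cohort size (11 Luminal/ER+ and 5 TN patients) matches a
    realistic short-term slice-culture study.
    """

    n_lum: int = 11
    n_tn: int = 5
    n_genes: int = 1000
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    effect_sd: float = 0.3        # per-patient sd around a planted shift
    baseline_mean: float = 8.0    # log2 expression baseline
    baseline_sd: float = 2.0
    ki67_p_vehicle: float = 0.5   # Ki67-positive fraction under vehicle
    ki67_drop: Mapping[str, float] = field(default_factory=dict)
    fields: int = 5
    cells_per_field: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lum, self.n_tn) < 0 or self.n_lum + self.n_tn == 0:
            raise ValidationError("cohort must contain patients")
        if self.fields < 1 or self.cells_per_field < 1:
            raise ValidationError("fields and cells_per_field must be positive")
        if not 0.0 <= self.ki67_p_vehicle <= 1.0:
            raise ValidationError("ki67_p_vehicle must lie in [0, 1]")
        for st, drop in self.ki67_drop.items():
            if not 0.0 <= drop <= 1.0:
                raise ValidationError(f"ki67_drop[{st!r}] must lie in [0, 1]")


def simulate_slice_cohort(params: SliceSimParams) -> SliceCohort:
    """Simulate paired vehicle/ATRA slices with Ki67 counts.

    ATRA expression = vehicle expression + planted subtype shift (if any)
    + N(0, effect_sd). With ``effect_sd=0`` the per-patient log2 ratio of a
    planted gene equals its shift exactly.
    """
    rng = np.random.default_rng(params.seed)
    genes = pd.Index([f"G{i:05d}" for i in range(params.n_genes)], name="gene")
    patients: list[SlicePatient] = []
    roster = [("Lum", i) for i in range(params.n_lum)] + \
             [("TN", i) for i in range(params.n_tn)]
    for subtype, i in roster:
        pid = f"{subtype}{i + 1:02d}"
        vehicle = pd.Series(
            rng.normal(params.baseline_mean, params.baseline_sd, params.n_genes),
            index=genes,
        )
        shift = pd.Series(0.0, index=genes)
        for gene, eff in params.effects.get(subtype, {}).items():
            if gene not in shift.index:
                raise ValidationError(f"planted gene {gene!r} outside universe")
            shift[gene] = eff
        noise = (rng.normal(0.0, params.effect_sd, params.n_genes)
                 if params.effect_sd > 0 else np.zeros(params.n_genes))
        atra = vehicle + shift + noise

        p_veh = params.ki67_p_vehicle
        p_atra = p_veh * (1.0 - params.ki67_drop.get(subtype, 0.0))
        ki67 = {
            "vehicle": [
                (int(rng.binomial(params.cells_per_field, p_veh)),
                 params.cells_per_field)
                for _ in range(params.fields)
            ],
            "atra": [
                (int(rng.binomial(params.cells_per_field, p_atra)),
                 params.cells_per_field)
                for _ in range(params.fields)
            ],
        }
        patients.append(SlicePatient(
            patient_id=pid, subtype=subtype,
            expr_vehicle=vehicle, expr_atra=atra, ki67_fields=ki67,
        ))
    return SliceCohort(patients)
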