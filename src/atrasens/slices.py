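"""Short-term tissue-slice response analysis.

Patient tumor slices cultured 48 h with vehicle (DMSO) or ATRA are read
out two ways: Ki67 immunostaining (proliferation) and paired expression
profiling. This module provides

* per-patient Ki67 sensitivity calls — a one-sided two-sample t-test on
  per-field Ki67-positive percentages (decrease under ATRA);
* genome-wide paired differential expression — per-gene paired t-test on
  log2(ATRA) - log2(vehicle) across patients, partitioned up/down;
* the Venn partition of regulated genes between Luminal/ER+ and TN
  subtypes, with discordant (up in one, down in the other) genes kept in
  their own bucket;
* the two-stage retinoid-target analysis: targets regulated within a
  subtype at a stringent threshold, then tested for differential
  regulation between subtypes by a Welch test on per-patient log2 ratios.

Raw p-value thresholds are used throughout (defaults 0.05 / 0.005 / 0.001);
Benjamini–Hochberg adjustment is available via :func:`atrasens.stats.bh_adjust`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import GeneSet, SliceCohort, SlicePatient, ValidationError

logger = logging.getLogger("atrasens")

MIN_KI67_FIELDS = 5


@dataclass
class Ki67Result:
    patient: str
    pct_vehicle: float
    se_vehicle: float
    pct_atra: float
    se_atra: float
    p_one_sided: float
    sensitive: bool


@dataclass
class PairedDEResult:
    gene: str
    mean_log2_ratio: float  # ATRA / vehicle
    t_statistic: float
    p_paired: float
    direction: str  # "up" | "down"


@dataclass
class PairedDETable:
    """All tested genes plus the significant up/down sublists."""

    results: list[PairedDEResult]
    up: list[PairedDEResult] = field(default_factory=list)
    down: list[PairedDEResult] = field(default_factory=list)
    n_skipped_zero_variance: int = 0
    p_threshold: float = 0.005

    @property
    def significant(self) -> list[PairedDEResult]:
        return self.up + self.down


# ---------------------------------------------------------------------------
# Ki67
# ---------------------------------------------------------------------------

def ki67_response(patient: SlicePatient,
                  p_threshold: float = 0.05) -> Ki67Result:
    """Sensitivity call from per-field Ki67-positive percentages.

    ``sensitive`` requires both a one-sided p < threshold and a lower ATRA
    mean percentage — an increase is never called sensitive regardless of p.
    Fields are treated as unpaired between conditions.
    """
    if patient.ki67_fields is None:
        raise ValidationError(f"patient {patient.patient_id!r} has no Ki67 data")
    pct = {}
    for cond in ("vehicle", "atra"):
        fields = patient.ki67_fields.get(cond, [])
        if len(fields) < MIN_KI67_FIELDS:
            raise ValidationError(
                f"patient {patient.patient_id!r}: need >= {MIN_KI67_FIELDS} "
                f"Ki67 fields per condition, got {len(fields)} for {cond!r}"
            )
        for pos, tot in fields:
            if tot == 0:
                raise ValidationError(
                    f"patient {patient.patient_id!r}: zero-cell field in {cond!r}"
                )
        pct[cond] = np.array([100.0 * pos / tot for pos, tot in fields])

    veh, atr = pct["vehicle"], pct["atra"]
    if np.var(veh, ddof=1) == 0 and np.var(atr, ddof=1) == 0:
        p = 1.0 if atr.mean() >= veh.mean() else 0.0
    else:
        # Welch form: field-to-field variance need not match between
        # conditions, and the pooled test is anticonservative at 5 fields
        p = float(sps.ttest_ind(atr, veh, alternative="less",
                                equal_var=False).pvalue)
    sensitive = bool(p < p_threshold and atr.mean() < veh.mean())

    def sem(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(len(x)))

    return Ki67Result(
        patient=patient.patient_id,
        pct_vehicle=float(veh.mean()), se_vehicle=sem(veh),
        pct_atra=float(atr.mean()), se_atra=sem(atr),
        p_one_sided=p, sensitive=sensitive,
    )


# ---------------------------------------------------------------------------
# Paired differential expression
# ---------------------------------------------------------------------------

def paired_de(cohort: SliceCohort, subtype_filter: str | None = None,
              p_threshold: float = 0.005,
              gene_subset: GeneSet | None = None) -> PairedDETable:
    """Per-gene paired t-test of ATRA versus vehicle log2 expression.

    Genes whose paired differences have zero variance across patients are
    skipped (their count is logged); the remaining genes with p below the
    threshold are partitioned by the sign of the mean log2 ratio.
    """
    if subtype_filter is not None:
        cohort = cohort.filter_subtype(subtype_filter)
    if len(cohort.patients) < 3:
        raise ValidationError("need >= 3 patients for paired DE")
    diffs = cohort.log2_ratio_matrix()  # genes x patients
    if gene_subset is not None:
        present = [g for g in gene_subset.genes if g in diffs.index]
        if not present:
            raise ValidationError(
                f"gene set {gene_subset.name!r} does not intersect cohort genes"
            )
        diffs = diffs.loc[present]

    D = diffs.to_numpy(dtype=float)
    n = D.shape[1]
    mean = D.mean(axis=1)
    sd = D.std(axis=1, ddof=1)
    nonzero = sd > 0
    n_skipped = int((~nonzero).sum())
    if n_skipped:
        logger.info("paired DE: skipped %d zero-variance genes", n_skipped)

    t = np.full(len(mean), np.nan)
    t[nonzero] = mean[nonzero] / (sd[nonzero] / np.sqrt(n))
    p = np.full(len(mean), np.nan)
    p[nonzero] = 2.0 * sps.t.sf(np.abs(t[nonzero]), df=n - 1)

    results, up, down = [], [], []
    for i, gene in enumerate(diffs.index):
        if not nonzero[i]:
            continue
        res = PairedDEResult(
            gene=str(gene), mean_log2_ratio=float(mean[i]),
            t_statistic=float(t[i]), p_paired=float(p[i]),
            direction="up" if mean[i] > 0 else "down",
        )
        results.append(res)
        if res.p_paired < p_threshold:
            (up if res.direction == "up" else down).append(res)
    return PairedDETable(results=results, up=up, down=down,
                         n_skipped_zero_variance=n_skipped,
                         p_threshold=p_threshold)


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------

def venn_partition(lum_up, lum_down, tn_up, tn_down) -> dict:
    """Exact set algebra over the four regulated-gene lists.

    A gene up in one subtype and down in the other lands in the discordant
    bucket only, never in a common bucket. Buckets are pairwise disjoint and
    together cover the union of the inputs.
    """
    lum_up, lum_down = set(lum_up), set(lum_down)
    tn_up, tn_down = set(tn_up), set(tn_down)
    discordant = (lum_up & tn_down) | (lum_down & tn_up)
    buckets = {
        "common_up": (lum_up & tn_up) - discordant,
        "common_down": (lum_down & tn_down) - discordant,
        "lum_only_up": lum_up - tn_up - tn_down - discordant,
        "lum_only_down": lum_down - tn_up - tn_down - discordant,
        "tn_only_up": tn_up - lum_up - lum_down - discordant,
        "tn_only_down": tn_down - lum_up - lum_down - discordant,
        "discordant": discordant,
    }
    out = {}
    for name, genes in buckets.items():
        out[name] = {"count": len(genes), "genes": sorted(genes)}
    return out


# ---------------------------------------------------------------------------
# Retinoid-target subset
# ---------------------------------------------------------------------------

def target_subset_differential(cohort: SliceCohort, target_set: GeneSet,
                               p_within: float = 0.001,
                               p_between: float = 0.05,
                               subtypes: tuple[str, str] = ("Lum", "TN"),
                               ) -> dict:
    """Two-stage analysis of a curated target gene set.

    Stage 1: paired DE restricted to the target set at the stringent
    ``p_within`` threshold, separately per subtype; the union of the
    significant targets is reported. Stage 2: for each stage-1 gene, a
    Welch two-sample test compares the per-patient log2 ratios between the
    two subtypes; genes below ``p_between`` are flagged differentially
    regulated.
    """
    if not set(target_set.genes) & set(cohort.genes):
        raise ValidationError(
            f"target set {target_set.name!r} disjoint from cohort genes"
        )
    stage1: dict[str, PairedDETable] = {}
    for st in subtypes:
        stage1[st] = paired_de(cohort, subtype_filter=st,
                               p_threshold=p_within, gene_subset=target_set)
    significant = sorted(
        {r.gene for st in subtypes for r in stage1[st].significant}
    )

    ratios = {st: cohort.filter_subtype(st).log2_ratio_matrix()
              for st in subtypes}
    differential = []
    between_p: dict[str, float] = {}
    for gene in significant:
        a = ratios[subtypes[0]].loc[gene].to_numpy(dtype=float)
        b = ratios[subtypes[1]].loc[gene].to_numpy(dtype=float)
        if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        between_p[gene] = p
        if p < p_between:
            differential.append(gene)
    return {
        "stage1": stage1,
        "within_significant": significant,
        "between_p": between_p,
        "differential": differential,
    }
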