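"""Two-group comparisons and correlation analyses.

Used to link receptor/variant expression to phenotype (Luminal vs Basal,
ER status), to sensitivity strata (T1 vs T3), and protein levels to mRNA
variants. The default two-group test is Student's pooled-variance t-test;
Welch's unequal-variance form is available by flag, and a summary-only
Welch variant supports published mean ± SE tables where raw values are
not available. Raw p-values are reported by default (no multiplicity
correction); Benjamini–Hochberg adjustment is provided as a helper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionMatrix, SampleAnnotation, ValidationError


@dataclass
class GroupComparison:
    group_labels: tuple[str, str]
    n: tuple[int, int]
    mean: tuple[float, float]
    se: tuple[float, float]
    t_statistic: float
    df: float
    p_two_sided: float
    test: str  # "student" | "welch"
    flag: str | None = None  # e.g. "zero-variance-limit"


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    pearson_r: float | None
    r_squared: float | None
    n: int
    p_two_sided: float | None
    undefined: bool = False  # a member had zero variance


def _sem(x: np.ndarray) -> float:
    if len(x) < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def group_compare(values: Mapping[str, float] | pd.Series,
                  groups: Mapping[str, str] | pd.Series,
                  test: str = "student") -> GroupComparison:
    """Two-sample t-test of per-sample values between two group labels.

    ``student`` uses the pooled-variance statistic with df = n1 + n2 - 2;
    ``welch`` uses the unequal-variance statistic with Satterthwaite df.
    """
    if test not in {"student", "welch"}:
        raise ValueError(f"unknown test {test!r}")
    values = pd.Series(values, dtype=float)
    groups = pd.Series(groups)
    common = values.index.intersection(groups.index)
    values, groups = values[common], groups[common]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 group labels, got {labels}")
    a = values[groups == labels[0]].to_numpy()
    b = values[groups == labels[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("non-finite values in comparison")

    flag = None
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
            df = len(a) + len(b) - 2
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p, df = 0.0, len(a) + len(b) - 2
            flag = "zero-variance-limit"
    elif test == "student":
        t, p = sps.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p = res.statistic, res.pvalue
        df = float(res.df)
    return GroupComparison(
        group_labels=(str(labels[0]), str(labels[1])),
        n=(len(a), len(b)),
        mean=(float(a.mean()), float(b.mean())),
        se=(_sem(a), _sem(b)),
        t_statistic=float(t),
        df=float(df),
        p_two_sided=float(p),
        test=test,
        flag=flag,
    )


def group_compare_from_summaries(n1: int, mean1: float, se1: float,
                                 n2: int, mean2: float, se2: float,
                                 labels: tuple[str, str] = ("group1", "group2"),
                                 ) -> GroupComparison:
    """Welch-type t-test from published group summaries (mean ± SE, n).

    t = (mean1 - mean2) / sqrt(se1^2 + se2^2) with Satterthwaite df
    df = (se1^2 + se2^2)^2 / (se1^4/(n1-1) + se2^4/(n2-1)).
    Supports significance checks against tables that print only summaries.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 per group")
    if se1 < 0 or se2 < 0:
        raise ValidationError("standard errors must be >= 0")
    flag = None
    if se1 == 0 and se2 == 0:
        if mean1 == mean2:
            t, p, df = 0.0, 1.0, float(n1 + n2 - 2)
        else:
            t = np.inf if mean1 > mean2 else -np.inf
            p, df, flag = 0.0, float(n1 + n2 - 2), "zero-variance-limit"
    else:
        se_diff = np.sqrt(se1 ** 2 + se2 ** 2)
        t = (mean1 - mean2) / se_diff
        df = (se1 ** 2 + se2 ** 2) ** 2 / (
            se1 ** 4 / (n1 - 1) + se2 ** 4 / (n2 - 1)
        )
        p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison(
        group_labels=labels,
        n=(n1, n2),
        mean=(float(mean1), float(mean2)),
        se=(float(se1), float(se2)),
        t_statistic=float(t),
        df=float(df),
        p_two_sided=float(p),
        test="welch",
        flag=flag,
    )


def _pearson(x: np.ndarray, y: np.ndarray,
             pair: tuple[str, str]) -> CorrelationResult:
    n = len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(pair=pair, pearson_r=None, r_squared=None,
                                 n=n, p_two_sided=None, undefined=True)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(pair=pair, pearson_r=float(r),
                             r_squared=float(r) ** 2, n=n,
                             p_two_sided=float(p))


def coregulation(matrix: ExpressionMatrix,
                 pairs: Sequence[tuple[str, str]]) -> list[CorrelationResult]:
    """Pearson co-regulation of gene pairs across the sample panel.

    Pairs with a zero-variance member are returned flagged ``undefined``
    rather than propagating NaN.
    """
    if len(matrix.samples) < 3:
        raise ValidationError("need >= 3 samples for correlation")
    out = []
    for g1, g2 in pairs:
        for g in (g1, g2):
            if g not in matrix.values.index:
                raise KeyError(f"gene {g!r} not in matrix")
        x = matrix.values.loc[g1].to_numpy(dtype=float)
        y = matrix.values.loc[g2].to_numpy(dtype=float)
        out.append(_pearson(x, y, (g1, g2)))
    return out


def protein_mrna_correlation(protein: Mapping[str, float] | pd.Series,
                             variants: ExpressionMatrix,
                             ) -> list[CorrelationResult]:
    """Correlate a protein readout with each mRNA variant row.

    Only samples present in both inputs are used; results are sorted by
    descending r² (undefined rows last) so the best-explaining variant
    ranks first.
    """
    protein = pd.Series(protein, dtype=float)
    common = [s for s in variants.samples if s in protein.index]
    if len(common) < 3:
        raise ValidationError("need >= 3 overlapping samples")
    p = protein[common].to_numpy()
    results = []
    for gene in variants.genes:
        x = variants.values.loc[gene, common].to_numpy(dtype=float)
        results.append(_pearson(x, p, (gene, "protein")))
    results.sort(key=lambda r: (-(r.r_squared if not r.undefined else -1.0),
                                r.pair[0]))
    return results


def stratified_compare(matrix: ExpressionMatrix, annot: SampleAnnotation,
                       gene: str, compare: str, test: str = "student",
                       **filters: str) -> GroupComparison:
    """Filter samples by annotation, then compare ``gene`` between the two
    levels of annotation column ``compare`` (e.g. T1 vs T3 within Luminal).
    """
    if gene not in matrix.values.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    samples = annot.select(**filters) if filters else annot.samples
    samples = [s for s in samples if s in matrix.values.columns]
    values = matrix.values.loc[gene, samples]
    groups = annot.table.loc[samples, compare]
    keep = ~groups.isin(["unset", "unknown"])
    return group_compare(values[keep], groups[keep], test=test)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; raw p is the default
    reporting mode throughout the pipeline)."""
    return multipletests(list(pvalues), method="fdr_bh")[1]
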