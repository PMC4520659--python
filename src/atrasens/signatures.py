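"""Discovery of gene sets associated with ATRA sensitivity.

Genes are ranked by out-of-bag permutation importance from a Random Forest
regression of the per-line sensitivity score on basal expression — a
regime of p >> n (thousands of genes, tens of lines) where impurity-based
importance is biased and OOB permutation importance is the robust choice.
The top-ranked genes are split by the sign of their correlation with the
score into "up in sensitive" and "down in sensitive" sets, cross-platform
reproducibility is quantified with a hypergeometric overlap test, and the
ability of a gene set to separate sensitive (T1) from resistant (T3) lines
is measured by hierarchical clustering purity.

The forest is built as explicit bootstrap-aggregated regression trees so
the out-of-bag bookkeeping (which samples each tree never saw) is exact and
fully deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.tree import DecisionTreeRegressor

from .data_model import ExpressionMatrix, GeneSet, SampleAnnotation, ValidationError

logger = logging.getLogger("atrasens")


@dataclass
class RankedGeneList:
    """Importance-ranked genes with the forest's reproducibility metadata."""

    entries: pd.DataFrame  # columns: gene, importance, rank (1..n, no gaps)
    model_meta: dict

    @property
    def genes(self) -> list[str]:
        return list(self.entries["gene"])

    def top(self, k: int) -> list[str]:
        return list(self.entries["gene"].iloc[:k])


@dataclass
class SeparationReport:
    linkage: str
    distance: str
    purity: float
    labels_compared: tuple[str, str] = ("T1", "T3")
    n_samples: int = 0


# ---------------------------------------------------------------------------
# Random-Forest importance ranking
# ---------------------------------------------------------------------------

def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, mtry: int,
                min_leaf: int, seed: int):
    """Bagged regression trees with per-tree bootstrap index bookkeeping."""
    rng = np.random.default_rng(seed)
    n = len(y)
    trees, oob_masks = [], []
    for _ in range(n_trees):
        idx = rng.integers(0, n, size=n)
        tree = DecisionTreeRegressor(
            max_features=mtry,
            min_samples_leaf=min_leaf,
            random_state=int(rng.integers(0, 2 ** 31 - 1)),
        )
        tree.fit(X[idx], y[idx])
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        trees.append(tree)
        oob_masks.append(oob)
    return trees, oob_masks


def _oob_permutation_importance(trees, oob_masks, X: np.ndarray,
                                y: np.ndarray, seed: int) -> np.ndarray:
    """Mean OOB increase in squared error when a feature is permuted.

    Only features a tree actually splits on can change its predictions, so
    permutation is restricted to those; unused features contribute zero for
    that tree (the classic bagged-forest importance).
    """
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    importance = np.zeros(p)
    counts = len(trees)
    for tree, oob in zip(trees, oob_masks):
        if not oob.any():
            continue
        Xo, yo = X[oob], y[oob]
        base_err = np.mean((tree.predict(Xo) - yo) ** 2)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        perm = rng.permutation(len(yo))
        for j in used:
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            err = np.mean((tree.predict(Xp) - yo) ** 2)
            importance[j] += err - base_err
    return importance / counts


def rank_genes_by_importance(expr: ExpressionMatrix,
                             scores: pd.Series | dict,
                             n_trees: int = 1000,
                             seed: int = 0,
                             mtry: int | None = None,
                             min_leaf: int = 5) -> RankedGeneList:
    """Rank genes by OOB permutation importance for predicting the score.

    Samples are canonicalized by sorting on sample id so the ranking is
    invariant to input column order; zero-variance genes are dropped with a
    warning before fitting. ``mtry`` defaults to ceil(p/3), the regression
    forest convention.
    """
    scores = pd.Series(scores, dtype=float)
    samples = sorted(s for s in expr.samples if s in scores.index)
    if len(samples) < 10:
        raise ValidationError("need >= 10 samples with expression and score")
    values = expr.values[samples]
    variances = values.var(axis=1, ddof=0)
    if (variances == 0).all():
        raise ValidationError("all genes are constant across samples")
    if (variances == 0).any():
        n_drop = int((variances == 0).sum())
        logger.warning("dropping %d zero-variance genes before ranking", n_drop)
        values = values.loc[variances > 0]
    genes = list(values.index)
    X = values.to_numpy(dtype=float).T  # samples x genes
    y = scores[samples].to_numpy(dtype=float)
    if mtry is None:
        mtry = int(np.ceil(X.shape[1] / 3))

    trees, oob_masks = _fit_forest(X, y, n_trees, mtry, min_leaf, seed)

    # OOB R^2 from per-sample averaged out-of-bag predictions
    pred_sum = np.zeros(len(y))
    pred_n = np.zeros(len(y))
    for tree, oob in zip(trees, oob_masks):
        if oob.any():
            pred_sum[oob] += tree.predict(X[oob])
            pred_n[oob] += 1
    covered = pred_n > 0
    oob_r2 = float("nan")
    if covered.sum() >= 2:
        resid = y[covered] - pred_sum[covered] / pred_n[covered]
        ss_tot = np.sum((y[covered] - y[covered].mean()) ** 2)
        if ss_tot > 0:
            oob_r2 = 1.0 - float(np.sum(resid ** 2)) / float(ss_tot)

    importance = _oob_permutation_importance(trees, oob_masks, X, y,
                                             seed=seed + 1)
    order = sorted(range(len(genes)),
                   key=lambda i: (-importance[i], genes[i]))
    entries = pd.DataFrame({
        "gene": [genes[i] for i in order],
        "importance": importance[order],
        "rank": np.arange(1, len(genes) + 1),
    })
    meta = {"n_trees": n_trees, "mtry": mtry, "min_leaf": min_leaf,
            "seed": seed, "oob_r2": oob_r2, "n_samples": len(samples),
            "n_genes": len(genes)}
    return RankedGeneList(entries=entries, model_meta=meta)


# ---------------------------------------------------------------------------
# Direction split / overlap / clustering
# ---------------------------------------------------------------------------

def split_by_direction(ranked: RankedGeneList, expr: ExpressionMatrix,
                       scores: pd.Series | dict,
                       top_k: int = 100) -> tuple[GeneSet, GeneSet]:
    """Partition the top-k ranked genes by the sign of their Pearson
    correlation with the score: positive -> "up in sensitive", negative ->
    "down in sensitive" (zero-correlation ties go up with a warning).
    Correlation with the continuous score uses every sample, not just the
    extreme tertiles.
    """
    if top_k > len(ranked.entries):
        raise ValidationError("top_k exceeds ranked list length")
    scores = pd.Series(scores, dtype=float)
    samples = [s for s in expr.samples if s in scores.index]
    y = scores[samples].to_numpy(dtype=float)
    up, down = [], []
    for gene in ranked.top(top_k):
        x = expr.values.loc[gene, samples].to_numpy(dtype=float)
        r = np.corrcoef(x, y)[0, 1] if np.std(x) > 0 else 0.0
        if r == 0.0 or np.isnan(r):
            logger.warning("gene %r has zero correlation with score; "
                           "assigned to the up set", gene)
            up.append(gene)
        elif r > 0:
            up.append(gene)
        else:
            down.append(gene)
    return (GeneSet(name="up_in_sensitive", genes=up, direction="up"),
            GeneSet(name="down_in_sensitive", genes=down, direction="down"))


def overlap_count(set_a: GeneSet, set_b: GeneSet,
                  universe_size: int) -> dict:
    """Overlap of two gene sets with an upper-tail hypergeometric p-value:
    the probability of >= count common genes if the smaller set were drawn
    at random from the universe.
    """
    a, b = set(set_a.genes), set(set_b.genes)
    if universe_size < len(a | b):
        raise ValidationError(
            f"universe_size {universe_size} smaller than |A ∪ B| = {len(a | b)}"
        )
    count = len(a & b)
    # P(X >= count), X ~ Hypergeom(M=universe, n=|A|, N=|B|)
    p = float(sps.hypergeom.sf(count - 1, universe_size, len(a), len(b)))
    return {"count": count, "genes": sorted(a & b), "hypergeometric_p": p,
            "n_a": len(a), "n_b": len(b), "universe_size": universe_size}


def cluster_and_separate(expr: ExpressionMatrix, annot: SampleAnnotation,
                         labels: tuple[str, str] = ("T1", "T3"),
                         label_column: str = "tertile") -> SeparationReport:
    """Cluster samples on a gene set's expression and score T1/T3 separation.

    Genes are z-scored across samples first (the cross-cell-line
    normalization used for signature heat maps), samples are clustered by
    average-linkage agglomeration on 1 - Pearson correlation distance, the
    tree is cut at two clusters, and purity is the best cluster-to-label
    matching accuracy over the labeled samples only.
    """
    wanted = annot.table.index[annot.table[label_column].isin(labels)]
    samples = [s for s in expr.samples if s in wanted]
    lab = annot.table.loc[samples, label_column]
    for lbl in labels:
        if (lab == lbl).sum() < 2:
            raise ValidationError(f"need >= 2 samples labeled {lbl!r}")
    values = expr.values[samples]
    sd = values.std(axis=1, ddof=0)
    values = values.loc[sd > 0]
    z = values.sub(values.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)

    corr = np.corrcoef(z.to_numpy(dtype=float).T)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(Z, t=2, criterion="maxclust")

    truth = (lab == labels[0]).to_numpy()
    in_c1 = assignment == 1
    acc = max(
        (truth == in_c1).mean(),
        (truth == ~in_c1).mean(),
    )
    return SeparationReport(linkage="average", distance="1-pearson",
                            purity=float(acc), labels_compared=labels,
                            n_samples=len(samples))
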