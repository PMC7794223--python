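"""Downstream analyses: stemness scoring, permutation empirical p-values,
single-cell cycle-phase grouping, and pairwise group comparisons."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from extendscore.exprio import ExpressionMatrix, GeneWeightVector, ValidationError
from extendscore.scoring import GeneSignature, extend_score

logger = logging.getLogger(__name__)

PHASE_G1S = "G1-S"
PHASE_G2M = "G2-M"
PHASE_NONCYCLING = "non-cycling"
PHASE_AMBIGUOUS = "ambiguous"


@dataclass
class PermutationResult:
    observed_rho: float
    null_rhos: np.ndarray
    n_perm: int
    n_valid: int
    empirical_p: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed_rho": [self.observed_rho],
                "n_perm": [self.n_perm],
                "n_valid": [self.n_valid],
                "empirical_p": [self.empirical_p],
                "seed": [self.seed],
            }
        )


@dataclass
class PhaseAssignment:
    cell_ids: list[str]
    phase: np.ndarray
    g1s_score: np.ndarray
    g2m_score: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "g1s_score": self.g1s_score,
                "g2m_score": self.g2m_score,
                "phase": self.phase,
            }
        )


def stemness_score(expr: ExpressionMatrix, weights: GeneWeightVector) -> pd.Series:
    """Per-sample Spearman correlation between the gene-weight vector and the
    sample's expression vector, restricted to shared genes.

    Computed as Pearson correlation of midranked vectors (exactly Spearman
    with tie handling).  Samples whose shared expression vector is constant
    get NaN.
    """
    idx = expr.gene_index()
    w = weights.as_series()
    shared = [g for g in expr.gene_ids if g in w.index]
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} genes shared between matrix and weights; need >= 3"
        )
    rows = [idx[g] for g in shared]
    ranks = rankdata(expr.values[rows], method="average", axis=0)
    w_ranks = rankdata(w.loc[shared].to_numpy(), method="average")

    rc = ranks - ranks.mean(axis=0, keepdims=True)
    wc = w_ranks - w_ranks.mean()
    denom = np.sqrt((rc**2).sum(axis=0)) * np.sqrt((wc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (wc @ rc) / denom
    if np.ptp(w_ranks) == 0:
        raise ValidationError("weight vector is constant on shared genes")
    n_missing = int(np.isnan(rho).sum())
    if n_missing:
        logger.warning("%d samples have constant expression; stemness undefined", n_missing)
    return pd.Series(rho, index=expr.sample_ids, name="stemness")


def correlate_scores(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p between two per-sample score vectors.

    Pairs with missing values are dropped listwise; needs >= 4 complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("score vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValidationError(f"need >= 4 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant score vector; correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _empirical_p(observed: float, nulls: np.ndarray, pseudocount: bool = False) -> float:
    """Fraction of null statistics >= the observed one (optionally (c+1)/(n+1))."""
    nulls = np.asarray(nulls, dtype=float)
    valid = nulls[np.isfinite(nulls)]
    if valid.size == 0:
        raise ValidationError("no valid permutation draws")
    count = int((valid >= observed).sum())
    if pseudocount:
        return (count + 1) / (valid.size + 1)
    return count / valid.size


def permutation_empirical_p(
    expr: ExpressionMatrix,
    sig: GeneSignature,
    weights: GeneWeightVector,
    n_perm: int = 1000,
    seed: int = 0,
    pseudocount: bool = False,
) -> PermutationResult:
    """Empirical p for the correlation between telomerase and stemness scores.

    Each permutation shuffles the gene labels of the expression matrix once;
    the same shuffled matrix feeds both scorers so the paired structure is
    preserved.  empirical_p is the fraction of permutations whose correlation
    is >= the observed one; degenerate draws are recorded as NaN and excluded
    from the fraction.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    telo = extend_score(expr, sig, scale=False).raw_score
    stem = stemness_score(expr, weights).to_numpy()
    observed, _ = correlate_scores(telo, stem)

    rng = np.random.default_rng(seed)
    genes = np.asarray(expr.gene_ids, dtype=object)
    nulls = np.full(n_perm, np.nan)
    for i in range(n_perm):
        perm = rng.permutation(expr.n_genes)
        shuffled = ExpressionMatrix(
            list(genes[perm]), list(expr.sample_ids), expr.values
        )
        try:
            t = extend_score(shuffled, sig, scale=False).raw_score
            s = stemness_score(shuffled, weights).to_numpy()
            nulls[i], _ = correlate_scores(t, s)
        except ValidationError as exc:
            logger.warning("permutation %d degenerate, excluded: %s", i, exc)
    n_valid = int(np.isfinite(nulls).sum())
    p = _empirical_p(observed, nulls, pseudocount=pseudocount)
    return PermutationResult(
        observed_rho=observed,
        null_rhos=nulls,
        n_perm=n_perm,
        n_valid=n_valid,
        empirical_p=p,
        seed=seed,
    )


def classify_cell_cycle(
    expr: ExpressionMatrix,
    g1s_genes: list[str],
    g2m_genes: list[str],
    margin: float = 0.1,
    seed: int = 0,
    log_transform: bool = True,
) -> PhaseAssignment:
    """Partition cells into G1-S / G2-M / non-cycling by k-means on two
    per-cell signature means.

    Per-cell scores are means of log2(x+1) expression over the present marker
    genes of each list.  k-means (k=3, 10 restarts, seed-controlled) clusters
    the 2-D score pairs; clusters are labeled by centroid pattern.  Cells in a
    cycling cluster whose two scores differ by less than ``margin`` are
    labeled ambiguous.
    """
    idx = expr.gene_index()
    g1s_present = [g for g in g1s_genes if g in idx]
    g2m_present = [g for g in g2m_genes if g in idx]
    if len(g1s_present) < 5 or len(g2m_present) < 5:
        raise ValidationError(
            f"need >= 5 genes from each phase list present; got "
            f"{len(g1s_present)} G1-S and {len(g2m_present)} G2-M"
        )
    x = np.log2(expr.values + 1.0) if log_transform else expr.values
    g1s = x[[idx[g] for g in g1s_present]].mean(axis=0)
    g2m = x[[idx[g] for g in g2m_present]].mean(axis=0)
    pairs = np.column_stack([g1s, g2m])

    phase = np.full(expr.n_samples, PHASE_NONCYCLING, dtype=object)
    if np.unique(pairs, axis=0).shape[0] < 3:
        logger.warning("fewer than 3 distinct score pairs; all cells non-cycling")
        return PhaseAssignment(list(expr.sample_ids), phase, g1s, g2m)

    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(pairs)
    centroids = km.cluster_centers_
    noncycling = int(np.argmin(centroids.sum(axis=1)))
    cycling = [c for c in range(3) if c != noncycling]
    # of the two cycling clusters, the one with the larger g1s - g2m margin is G1-S
    diffs = centroids[cycling, 0] - centroids[cycling, 1]
    g1s_cluster = cycling[int(np.argmax(diffs))]
    g2m_cluster = cycling[1 - int(np.argmax(diffs))]

    labels = km.labels_
    phase[labels == g1s_cluster] = PHASE_G1S
    phase[labels == g2m_cluster] = PHASE_G2M
    ambiguous = (labels != noncycling) & (np.abs(g1s - g2m) < margin)
    phase[ambiguous] = PHASE_AMBIGUOUS
    return PhaseAssignment(list(expr.sample_ids), phase, g1s, g2m)


def compare_groups(scores, labels) -> pd.DataFrame:
    """All pairwise two-sided t-tests between groups, Bonferroni-adjusted.

    Groups with fewer than 2 samples are excluded with a warning.  Returns a
    frame with columns group_a, group_b, n_a, n_b, t, p, p_bonferroni.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must align")
    groups = {}
    for g in pd.unique(labels):
        vals = scores[labels == g]
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            logger.warning("group %r has <2 samples; excluded", g)
            continue
        groups[g] = vals
    names = list(groups)
    if len(names) < 2:
        raise ValidationError("need at least 2 groups with >= 2 samples")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        res = stats.ttest_ind(groups[a], groups[b], equal_var=True)
        t, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(t):  # both groups constant
            t, p = (0.0, 1.0) if groups[a].mean() == groups[b].mean() else (np.inf, 0.0)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": groups[a].size,
                "n_b": groups[b].size,
                "t": t,
                "p": p,
                "p_bonferroni": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)
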