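"""De novo signature derivation from a two-group cohort.

Pipeline: (1) one-sided differential upregulation filter (Welch t-test plus a
fold-change cutoff on group means), (2) anchor-gene Pearson co-expression scan
over a grid of correlation cutoffs, (3) elbow selection of the cutoff via the
percentage difference between consecutive gene counts, (4) intersection of the
two gene sets, (5) augmentation with a second constituent gene (TERC role).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from extendscore.exprio import ExpressionMatrix, ValidationError
from extendscore.scoring import GeneSignature

logger = logging.getLogger(__name__)

#: default correlation cutoff grid: 0.20 .. 0.70 inclusive, step 0.05
#: (11 cutoffs).
DEFAULT_THRESHOLDS = tuple(np.round(np.linspace(0.20, 0.70, 11), 2))

DEFAULT_P_THRESHOLD = 0.05
DEFAULT_FC_THRESHOLD = 1.5  # on the log2 fold-change scale


class DerivationError(ValueError):
    """Raised when the derivation pipeline cannot produce a signature."""


@dataclass
class DifferentialResult:
    """Per-gene one-sided upregulation test results (group A > group B)."""

    gene_ids: list[str]
    p_value: np.ndarray
    log2_fc: np.ndarray
    passed: np.ndarray
    p_threshold: float
    fc_threshold: float

    @property
    def passed_genes(self) -> list[str]:
        return [g for g, ok in zip(self.gene_ids, self.passed) if ok]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "p_value": self.p_value,
                "log2_fc": self.log2_fc,
                "passed": self.passed,
            }
        )


@dataclass
class ThresholdScan:
    """Anchor co-expression gene sets along an ascending cutoff grid."""

    anchor: str
    thresholds: np.ndarray
    gene_counts: np.ndarray
    gene_sets: list[list[str]]
    correlations: pd.Series = field(repr=False)
    pct_diff: np.ndarray | None = None
    selected: float | None = None
    selected_genes: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "gene_count": self.gene_counts})


def differential_upregulation(
    expr: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    log_transform: bool = True,
) -> DifferentialResult:
    """Per-gene Welch one-sided t-test for mean(A) > mean(B) plus FC filter.

    The t-test runs on log2(x+1)-transformed values by default (RSEM-style
    inputs are heavy-tailed); the fold change is the ratio of raw group means
    with a pseudo-count of 1, reported as log2.  A gene passes when
    p <= p_threshold and log2_fc > fc_threshold.
    """
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:10]}")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValidationError("each group needs at least 3 samples")
    a = expr.subset_samples(group_a).values
    b = expr.subset_samples(group_b).values

    ta = np.log2(a + 1.0) if log_transform else a
    tb = np.log2(b + 1.0) if log_transform else b
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant genes trigger a scipy precision warning; handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(ta, tb, axis=1, equal_var=False, alternative="greater")
        p = np.asarray(res.pvalue, dtype=float)

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    # zero variance in both groups: t undefined; decide by the group means
    undef = ~np.isfinite(p)
    if undef.any():
        p[undef] = np.where(mean_a[undef] > mean_b[undef], 0.0, 1.0)

    log2_fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    passed = (p <= p_threshold) & (log2_fc > fc_threshold)
    return DifferentialResult(
        gene_ids=list(expr.gene_ids),
        p_value=p,
        log2_fc=log2_fc,
        passed=passed,
        p_threshold=p_threshold,
        fc_threshold=fc_threshold,
    )


def coexpression_scan(
    expr: ExpressionMatrix,
    anchor_gene: str,
    samples: list[str] | None = None,
    thresholds: np.ndarray | tuple | None = None,
) -> ThresholdScan:
    """Genes Pearson-correlated with the anchor at each cutoff of the grid.

    Correlations are computed on the given samples (default: all).  Genes with
    zero variance get an undefined correlation and never enter a gene set.
    """
    sub = expr.subset_samples(samples) if samples is not None else expr
    if sub.n_samples < 3:
        raise ValidationError("co-expression scan needs at least 3 samples")
    idx = sub.gene_index()
    if anchor_gene not in idx:
        raise ValidationError(f"anchor gene {anchor_gene!r} not in matrix")
    x = sub.values
    anchor = x[idx[anchor_gene]]
    if np.ptp(anchor) == 0:
        raise ValidationError(f"anchor gene {anchor_gene!r} is constant; correlation undefined")

    grid = np.asarray(DEFAULT_THRESHOLDS if thresholds is None else thresholds, dtype=float)
    if grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise ValidationError("thresholds must be a strictly ascending grid")

    xc = x - x.mean(axis=1, keepdims=True)
    ac = anchor - anchor.mean()
    denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ ac) / denom
    corr = pd.Series(r, index=sub.gene_ids)

    gene_sets, counts = [], []
    for t in grid:
        genes = [
            g for g, v in corr.items() if g != anchor_gene and np.isfinite(v) and v >= t
        ]
        gene_sets.append(genes)
        counts.append(len(genes))
    return ThresholdScan(
        anchor=anchor_gene,
        thresholds=grid,
        gene_counts=np.array(counts, dtype=int),
        gene_sets=gene_sets,
        correlations=corr,
    )


def select_threshold(scan: ThresholdScan) -> float:
    """Elbow selection on the percentage difference of consecutive gene counts.

    pct_diff_k = 100 * (count_{k-1} - count_k) / count_{k-1}, indexed at the
    upper cutoff of each consecutive pair.  Returns the cutoff at the first
    position where pct_diff drops below its predecessor; if pct_diff never
    decreases, the last cutoff is returned.  The scan is truncated at the
    first zero count.
    """
    counts = np.asarray(scan.gene_counts, dtype=float)
    thresholds = np.asarray(scan.thresholds, dtype=float)
    nz = np.nonzero(counts == 0)[0]
    if nz.size:
        counts = counts[: nz[0]]
        thresholds = thresholds[: nz[0]]
        logger.info("scan truncated at first zero count (cutoff %.2f)", scan.thresholds[nz[0]])
    if counts.size < 3:
        raise DerivationError(
            "need at least 3 cutoffs with nonzero gene counts to select a threshold"
        )
    pct = 100.0 * (counts[:-1] - counts[1:]) / counts[:-1]
    scan.pct_diff = pct
    selected_idx = None
    for k in range(1, pct.size):
        if pct[k] < pct[k - 1]:
            selected_idx = k + 1  # pct[k] belongs to the pair ending at thresholds[k+1]
            break
    if selected_idx is None:
        selected_idx = counts.size - 1
        logger.info("percentage difference never decreased; using last cutoff")
    scan.selected = float(thresholds[selected_idx])
    grid_pos = int(np.nonzero(scan.thresholds == thresholds[selected_idx])[0][0])
    scan.selected_genes = list(scan.gene_sets[grid_pos])
    return scan.selected


def derive_signature(
    expr: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    anchor: str,
    terc_like: str,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    thresholds: np.ndarray | tuple | None = None,
    log_transform: bool = True,
    name: str = "derived",
) -> GeneSignature:
    """Full derivation: DE filter + co-expression elbow + intersection + TERC role.

    Markers are the anchor-co-expressed genes at the selected cutoff that also
    pass the upregulation filter, minus the constituent genes.  The returned
    signature carries the full audit trail under ``.audit``.
    """
    diff = differential_upregulation(
        expr, group_a, group_b, p_threshold, fc_threshold, log_transform
    )
    scan = coexpression_scan(expr, anchor, samples=group_a, thresholds=thresholds)
    select_threshold(scan)
    coexpressed = set(scan.selected_genes or [])
    upregulated = set(diff.passed_genes)
    markers = sorted((coexpressed & upregulated) - {anchor, terc_like})
    if not markers:
        raise DerivationError(
            f"empty marker set: {len(coexpressed)} co-expressed genes at cutoff "
            f"{scan.selected}, {len(upregulated)} upregulated genes, no overlap"
        )
    sig = GeneSignature(
        constituent=(anchor, terc_like),
        markers=markers,
        name=name,
        audit={"differential": diff, "scan": scan},
    )
    return sig
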