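"""Two-component rank-sum scoring of a telomerase gene signature.

Per sample i, with r_gi the within-sample midrank of gene g:

    V_const,i  = max(r_tert,i, r_terc,i)          (constituent component)
    V_marker,i = sum over marker genes of r_m,i   (marker component)
    ES_i       = (delta * V_const,i + V_marker,i) / (N_g * N_m)

where delta = 1 / (1 - rho), rho the Spearman correlation between the two
component vectors, computed once per dataset; N_g is the total gene count of
the input and N_m the number of signature genes detected in it.  Scores are
optionally min-max scaled to [0, 1] across samples.  Because every quantity
is rank-derived, scores are invariant to expression units and monotone
normalization, but they are dataset-relative: comparing scores across
datasets requires scoring them jointly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from extendscore.exprio import ExpressionMatrix, RankMatrix, ValidationError, rank_within_sample

logger = logging.getLogger(__name__)

#: bounds for the constituent adjustment factor; 0.5 is the analytic value of
#: 1/(1-rho) at rho = -1, and 20 corresponds to rho = 0.95 (the factor
#: diverges as rho -> 1).
DELTA_BOUNDS = (0.5, 20.0)


class SignatureError(ValueError):
    """Raised when a signature cannot be scored against an input matrix."""


class ConstituentAbsentError(SignatureError):
    """Neither constituent gene is detected; callers fall back to marker-only."""


@dataclass
class GeneSignature:
    """A scored signature: two constituent genes plus a marker gene list."""

    constituent: tuple[str, str]
    markers: list[str]
    name: str = ""
    audit: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.constituent = tuple(str(g) for g in self.constituent)
        self.markers = [str(g) for g in self.markers]
        if len(self.constituent) != 2:
            raise ValidationError("constituent component must name exactly 2 genes")
        if not self.markers:
            raise ValidationError("marker component must be non-empty")
        if len(set(self.markers)) != len(self.markers):
            raise ValidationError("duplicate marker genes")
        overlap = set(self.constituent) & set(self.markers)
        if overlap:
            raise ValidationError(f"constituent and marker sets overlap: {sorted(overlap)}")

    @property
    def genes(self) -> list[str]:
        return list(self.constituent) + list(self.markers)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneSignature":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        try:
            return cls(
                constituent=tuple(data["constituent"]),
                markers=list(data["markers"]),
                name=str(data.get("name", path.stem)),
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(
                f"{path}: signature file needs 'constituent' (2 ids) and 'markers' (list)"
            ) from exc

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = {
            "name": self.name,
            "constituent": list(self.constituent),
            "markers": list(self.markers),
        }
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))


def default_signature() -> GeneSignature:
    """The shipped 13-gene telomerase signature (2 constituent + 11 markers)."""
    with resources.files("extendscore.data").joinpath("default_signature.yaml").open() as fh:
        data = yaml.safe_load(fh)
    return GeneSignature(tuple(data["constituent"]), list(data["markers"]), data["name"])


@dataclass
class ComponentScores:
    """Per-sample constituent and marker component values."""

    v_const: np.ndarray
    v_marker: np.ndarray
    n_const_present: int
    n_marker_present: int


@dataclass
class ScoreResult:
    """Per-sample scores with the additive per-gene decomposition.

    ``contributions`` is a (signature genes present) x samples frame whose
    columns sum to ``raw_score``.
    """

    sample_ids: list[str]
    raw_score: np.ndarray
    scaled_score: np.ndarray
    delta: float
    n_g: int
    n_m: int
    components: ComponentScores
    contributions: pd.DataFrame
    constituent_present: list[str]
    markers_present: list[str]
    missing_genes: list[str]

    def to_frame(self) -> pd.DataFrame:
        const_rows = [g for g in self.constituent_present if g in self.contributions.index]
        const_contrib = (
            self.contributions.loc[const_rows].sum(axis=0).to_numpy()
            if const_rows
            else np.zeros(len(self.sample_ids))
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            const_fraction = np.where(self.raw_score > 0, const_contrib / self.raw_score, 0.0)
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "raw_score": self.raw_score,
                "scaled_score": self.scaled_score,
                "n_m_present": self.n_m,
                "const_fraction": const_fraction,
            }
        )


def _detected_constituents(expr: ExpressionMatrix, sig: GeneSignature) -> list[str]:
    # a constituent counts as detected only if present AND expressed somewhere;
    # an all-zero row (single-cell dropout) is indistinguishable from absence
    # for the purposes of Eq. 1 and triggers the marker-only fallback.
    idx = expr.gene_index()
    return [
        g
        for g in sig.constituent
        if g in idx and np.any(expr.values[idx[g]] > 0)
    ]


def constituent_score(
    ranks: RankMatrix, sig: GeneSignature, detected: Sequence[str] | None = None
) -> np.ndarray:
    """Per-sample max of the within-sample ranks of the present constituent genes."""
    idx = ranks.gene_index()
    genes = list(detected) if detected is not None else [g for g in sig.constituent if g in idx]
    missing = [g for g in genes if g not in idx]
    if missing:
        raise SignatureError(f"constituent genes not in rank matrix: {missing}")
    if not genes:
        raise ConstituentAbsentError(
            f"neither constituent gene {sig.constituent} is detected in the input"
        )
    rows = [idx[g] for g in genes]
    return ranks.ranks[rows].max(axis=0)


def marker_score(ranks: RankMatrix, sig: GeneSignature) -> tuple[np.ndarray, list[str]]:
    """Per-sample rank sum over the marker genes present in the matrix."""
    idx = ranks.gene_index()
    present = [g for g in sig.markers if g in idx]
    if not present:
        raise SignatureError(
            f"none of the {len(sig.markers)} marker genes are present; signature unusable"
        )
    rows = [idx[g] for g in present]
    return ranks.ranks[rows].sum(axis=0), present


def adjustment_factor(v_const: np.ndarray, v_marker: np.ndarray) -> float:
    """delta = 1/(1 - rho), rho the Spearman correlation of the two components.

    Clamped to ``DELTA_BOUNDS``; degenerate inputs (<3 samples or a constant
    component vector) fall back to delta = 1 with a warning.
    """
    v_const = np.asarray(v_const, dtype=float)
    v_marker = np.asarray(v_marker, dtype=float)
    if v_const.size != v_marker.size:
        raise ValidationError("component vectors must have equal length")
    if v_const.size < 3 or np.ptp(v_const) == 0 or np.ptp(v_marker) == 0:
        logger.warning(
            "adjustment factor undefined (<3 samples or constant component); using delta=1"
        )
        return 1.0
    rho = float(spearmanr(v_const, v_marker).statistic)
    if not np.isfinite(rho):
        logger.warning("Spearman correlation undefined; using delta=1")
        return 1.0
    lo, hi = DELTA_BOUNDS
    if rho >= 1.0:
        return hi
    delta = 1.0 / (1.0 - rho)
    return float(min(max(delta, lo), hi))


def _min_max_scale(raw: np.ndarray) -> np.ndarray:
    if raw.size == 1:
        logger.warning("single sample: min-max scaling skipped, returning raw score")
        return raw.copy()
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        logger.warning("all raw scores identical: scaled scores set to 0.5")
        return np.full_like(raw, 0.5)
    return (raw - lo) / (hi - lo)


def extend_score(
    expr: ExpressionMatrix,
    sig: GeneSignature | None = None,
    scale: bool = True,
    drop_zero_genes: bool = False,
) -> ScoreResult:
    """Score every sample of ``expr`` against ``sig`` (default shipped signature).

    When both constituent genes are undetected (absent rows or all-zero rows,
    as in sparse single-cell data) the constituent term is dropped and the
    score is computed from the marker component alone; the marker genes then
    carry the whole estimate.
    """
    if sig is None:
        sig = default_signature()
    if drop_zero_genes:
        expr = expr.drop_zero_genes()
    ranks = rank_within_sample(expr)
    n_g = expr.n_genes

    const_present = _detected_constituents(expr, sig)
    v_marker, markers_present = marker_score(ranks, sig)

    if const_present:
        v_const = constituent_score(ranks, sig, detected=const_present)
        delta = adjustment_factor(v_const, v_marker)
    else:
        logger.info("constituent genes undetected; marker-only scoring")
        v_const = np.zeros(expr.n_samples)
        delta = 1.0

    n_m = len(const_present) + len(markers_present)
    denom = float(n_g * n_m)
    raw = (delta * v_const + v_marker) / denom

    # additive per-gene decomposition: each marker contributes its rank; the
    # constituent term is attributed to the argmax gene (split equally on ties)
    idx = ranks.gene_index()
    contrib_rows: dict[str, np.ndarray] = {}
    if const_present:
        const_ranks = np.vstack([ranks.ranks[idx[g]] for g in const_present])
        is_max = const_ranks == const_ranks.max(axis=0, keepdims=True)
        shares = is_max / is_max.sum(axis=0, keepdims=True)
        for g, share in zip(const_present, shares):
            contrib_rows[g] = delta * const_ranks[const_present.index(g)] * share / denom
    for g in markers_present:
        contrib_rows[g] = ranks.ranks[idx[g]] / denom
    contributions = pd.DataFrame(contrib_rows).T
    contributions.columns = expr.sample_ids

    missing = [g for g in sig.genes if g not in set(const_present) | set(markers_present)]
    scaled = _min_max_scale(raw) if scale else raw.copy()
    return ScoreResult(
        sample_ids=list(expr.sample_ids),
        raw_score=raw,
        scaled_score=scaled,
        delta=float(delta),
        n_g=n_g,
        n_m=n_m,
        components=ComponentScores(v_const, v_marker, len(const_present), len(markers_present)),
        contributions=contributions,
        constituent_present=const_present,
        markers_present=markers_present,
        missing_genes=missing,
    )


def component_contribution(result: ScoreResult) -> pd.DataFrame:
    """Per-sample fractional share of the raw score for each signature gene.

    Returns a frame with one row per signature gene present plus a
    ``constituent`` summary row; per-gene fractions sum to 1 per sample.
    """
    raw = result.raw_score
    if np.any(raw <= 0):
        raise ValidationError("raw scores must be positive to form fractions")
    fractions = result.contributions / raw
    const_rows = [g for g in result.constituent_present if g in fractions.index]
    const_total = (
        fractions.loc[const_rows].sum(axis=0)
        if const_rows
        else pd.Series(0.0, index=fractions.columns)
    )
    out = fractions.copy()
    out.loc["constituent"] = const_total
    return out
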