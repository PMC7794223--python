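"""Expression-matrix I/O, validation, and within-sample rank transforms.

All scoring in this package operates on within-sample midranks, so inputs
may be in any non-negative expression unit (raw counts, TPM, RPKM, RSEM).
No normalization or log transform is applied before ranking: ranks are
invariant under any strictly increasing elementwise transform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise ValidationError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    Invariants enforced at construction: unique gene and sample identifiers,
    at least one gene and one sample, and all values finite and >= 0.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D genes x samples matrix")
        n_g, n_s = self.values.shape
        if n_g < 1 or n_s < 1:
            raise ValidationError("need at least 1 gene and 1 sample")
        if len(self.gene_ids) != n_g or len(self.sample_ids) != n_s:
            raise ValidationError(
                f"label/matrix shape mismatch: {len(self.gene_ids)} gene ids, "
                f"{len(self.sample_ids)} sample ids, matrix {self.values.shape}"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(
                "expression values must be finite; impute or filter missing "
                "values before loading"
            )
        if np.any(self.values < 0):
            raise ValidationError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:10]}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])

    def drop_zero_genes(self) -> "ExpressionMatrix":
        """Remove genes with zero expression in every sample."""
        keep = np.any(self.values > 0, axis=1)
        if keep.all():
            return self
        if not keep.any():
            raise ValidationError("all genes are zero in every sample")
        genes = [g for g, k in zip(self.gene_ids, keep) if k]
        logger.info("dropped %d all-zero genes", int((~keep).sum()))
        return ExpressionMatrix(genes, list(self.sample_ids), self.values[keep])


@dataclass
class RankMatrix:
    """Within-sample midranks (ascending with expression; lowest value -> 1)."""

    gene_ids: list[str]
    sample_ids: list[str]
    ranks: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.ranks.shape[0]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class GeneWeightVector:
    """Signed per-gene weights (e.g. a stemness signature)."""

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or len(self.gene_ids) != self.weights.size:
            raise ValidationError("weights must be 1-D with one value per gene id")
        _check_unique(self.gene_ids, "gene ids")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("weights must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.gene_ids)


def rank_within_sample(expr: ExpressionMatrix) -> RankMatrix:
    """Rank every gene within each sample, midranks for ties.

    The transform is applied per column; a sample's ranks never depend on
    other samples, and for every sample the ranks sum to N_g*(N_g+1)/2.
    """
    ranks = rankdata(expr.values, method="average", axis=0)
    return RankMatrix(list(expr.gene_ids), list(expr.sample_ids), ranks)


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

_DELIMS = {"tsv": "\t", "csv": ","}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx-triple"
    if suffix == ".csv":
        return "csv"
    return "tsv"


def _collapse_duplicate_genes(frame: pd.DataFrame) -> pd.DataFrame:
    if frame.index.has_duplicates:
        n = int(frame.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by maximum value", n)
        frame = frame.groupby(level=0, sort=False).max()
    return frame


def read_expression(
    path: str | Path,
    format: str | None = None,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples expression matrix.

    Dense ``tsv``/``csv``: first column gene ids, header row sample ids.
    ``mtx-triple``: MatrixMarket coordinate file plus one-per-line gene and
    sample label files (default ``<stem>.genes.txt`` / ``<stem>.samples.txt``).
    Duplicate gene rows are collapsed by maximum value; duplicate sample ids
    and negative values are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt in _DELIMS:
        # check the raw header: pandas would silently mangle duplicate names
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(_DELIMS[fmt])
        if len(set(header[1:])) != len(header[1:]):
            raise ValidationError(f"{path}: duplicate sample ids in header")
        try:
            frame = pd.read_csv(path, sep=_DELIMS[fmt], index_col=0)
        except Exception as exc:  # pandas raises several parser error types
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        if frame.empty:
            raise ParseError(f"{path}: no data rows")
        non_numeric = frame.columns[
            [not np.issubdtype(d, np.number) for d in frame.dtypes]
        ]
        if len(non_numeric):
            raise ParseError(
                f"{path}: non-numeric values in columns {list(non_numeric)[:5]}"
            )
        frame = _collapse_duplicate_genes(frame)
        return ExpressionMatrix(
            [str(g) for g in frame.index],
            [str(s) for s in frame.columns],
            frame.to_numpy(dtype=float),
        )
    if fmt == "mtx-triple":
        genes_path = Path(genes_path) if genes_path else path.with_suffix("").with_suffix(".genes.txt")
        samples_path = Path(samples_path) if samples_path else path.with_suffix("").with_suffix(".samples.txt")
        for p in (genes_path, samples_path):
            if not p.exists():
                raise FileNotFoundError(f"companion label file missing: {p}")
        try:
            mat = mmread(path)
        except Exception as exc:
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        mat = np.asarray(mat.toarray() if hasattr(mat, "toarray") else mat, dtype=float)
        genes = read_gene_list(genes_path)
        samples = read_gene_list(samples_path)
        frame = _collapse_duplicate_genes(
            pd.DataFrame(mat, index=genes)
        )
        if len(set(samples)) != len(samples):
            raise ValidationError(f"{samples_path}: duplicate sample ids")
        return ExpressionMatrix([str(g) for g in frame.index], samples, frame.to_numpy())
    raise ValueError(f"unknown format {fmt!r}; expected tsv, csv, or mtx-triple")


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if token and not token.startswith("#"):
            out.append(token)
    if not out:
        raise ParseError(f"{path}: empty gene list")
    return out


def read_gene_weights(path: str | Path) -> GeneWeightVector:
    """Gene weights from two-column TSV (gene, weight) or a JSON/YAML mapping."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".json", ".yaml", ".yml"}:
        text = path.read_text()
        data = json.loads(text) if suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParseError(f"{path}: expected a gene -> weight mapping")
        return GeneWeightVector(list(data.keys()), np.array(list(data.values()), dtype=float))
    try:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: expected two tab-separated columns (gene, weight)")
    # tolerate a header row
    if not np.issubdtype(frame.iloc[:, 1].dtype, np.number):
        frame = frame.iloc[1:]
        try:
            frame.iloc[:, 1] = frame.iloc[:, 1].astype(float)
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric weight column") from exc
    return GeneWeightVector(
        [str(g) for g in frame.iloc[:, 0]], frame.iloc[:, 1].to_numpy(dtype=float)
    )
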