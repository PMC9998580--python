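"""Marker data containers, genomic relationship matrices and marker PCA.

Samples are rows everywhere. Dosages are ALT-allele counts in {0, 1, 2}
(real-valued after mean imputation). All index sets are 0-based internally;
files carry string identifiers.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ridge added to the diagonal of a relationship matrix before any inversion
DEFAULT_RIDGE = 1e-6

_MISSING_CODES = {"", "na", "nan", "n/a", ".", "-9", "-", "null"}


@dataclass
class MarkerMatrix:
    """Genotype dosage matrix with sample and marker identifiers.

    Invariants: identifier lists are unique and match the dosage grid
    dimensions; after construction every column is polymorphic (zero-variance
    columns are the caller's responsibility to drop, see
    :func:`read_marker_table` / :func:`drop_monomorphic`).
    """

    sample_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array (samples x markers)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        for kind, ids in (("sample", self.sample_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {kind} ids")
        if self.ploidy != 2:
            raise ValueError("only diploid dosages are supported")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker ALT allele frequency p = mean(dosage) / 2."""
        return self.dosages.mean(axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def index_of(self, ids) -> np.ndarray:
        """Row indices of the given sample ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from exc

    def subset(self, ids) -> "MarkerMatrix":
        idx = self.index_of(ids)
        return MarkerMatrix(list(ids), list(self.marker_ids), self.dosages[idx])

    def centered(self) -> np.ndarray:
        """Column-centered dosage matrix (mean over all samples)."""
        return self.dosages - self.dosages.mean(axis=0, keepdims=True)


@dataclass
class RelationshipMatrix:
    """Symmetric genomic relationship matrix with sample identifiers."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape must match id list")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover
            raise KeyError(f"unknown id {exc.args[0]!r}") from exc

    def submatrix(self, row_ids, col_ids=None) -> np.ndarray:
        """Rectangular block A[rows, cols], order preserved."""
        r = self.index_of(row_ids)
        c = r if col_ids is None else self.index_of(col_ids)
        return self.values[np.ix_(r, c)]


@dataclass
class ScoreMatrix:
    """Principal-component scores of the centered dosage matrix."""

    sample_ids: list[str]
    component_scores: np.ndarray
    explained_variance_fraction: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.component_scores = np.asarray(self.component_scores, dtype=float)
        evf = np.asarray(self.explained_variance_fraction, dtype=float)
        if np.any(evf < -1e-12) or np.any(evf > 1 + 1e-12):
            raise ValueError("explained variance fractions must lie in [0, 1]")
        if np.any(np.diff(evf) > 1e-12):
            raise ValueError("components must be ordered by decreasing variance")
        self.explained_variance_fraction = evf

    @property
    def n(self) -> int:
        return self.component_scores.shape[0]

    @property
    def k(self) -> int:
        return self.component_scores.shape[1]

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)


def drop_monomorphic(markers: MarkerMatrix) -> MarkerMatrix:
    """Remove zero-variance marker columns; logs how many were dropped."""
    keep = markers.dosages.var(axis=0) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d monomorphic marker column(s)", dropped)
        return MarkerMatrix(
            list(markers.sample_ids),
            [mid for mid, k in zip(markers.marker_ids, keep) if k],
            markers.dosages[:, keep],
        )
    return markers


def _sniff_delimiter(path: str) -> str:
    with open(path, newline="") as handle:
        sample = handle.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def read_marker_table(path: str, dialect: str | None = None) -> MarkerMatrix:
    """Read a delimited dosage table: header row = marker ids, column 1 = sample ids.

    Missing cells (empty, NA, ``.`` ...) are imputed to the column mean;
    monomorphic columns are dropped with a logged count. Non-numeric or
    out-of-range dosages raise with the offending cell named.
    """
    sep = dialect or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    sample_ids = [str(s) for s in df.index]
    marker_ids = [str(c) for c in df.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample ids in {path}")
    if len(set(marker_ids)) != len(marker_ids):
        raise ValueError(f"duplicate marker ids in {path}")

    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        for i in range(raw.shape[0]):
            cell = raw[i, j]
            text = "" if cell is None else str(cell).strip()
            if text.lower() in _MISSING_CODES:
                values[i, j] = np.nan
                continue
            try:
                x = float(text)
            except ValueError:
                raise ValueError(
                    f"non-numeric dosage {text!r} at sample {sample_ids[i]!r}, "
                    f"marker {marker_ids[j]!r}"
                ) from None
            if not (0.0 <= x <= 2.0):
                raise ValueError(
                    f"dosage {x} outside [0, 2] at sample {sample_ids[i]!r}, "
                    f"marker {marker_ids[j]!r}"
                )
            values[i, j] = x

    # column-mean imputation
    col_means = np.nanmean(np.where(np.isnan(values), np.nan, values), axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(values))
    if nan_rows.size:
        values[nan_rows, nan_cols] = col_means[nan_cols]
        logger.info("imputed %d missing dosage cell(s) to column means", nan_rows.size)

    return drop_monomorphic(MarkerMatrix(sample_ids, marker_ids, values))


def read_marker_vcf(path: str) -> MarkerMatrix:
    """Read dosages (ALT allele counts) from a biallelic VCF.

    Multi-allelic records are skipped with a logged count. Missing genotypes
    are imputed to the column mean.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        gts = np.asarray(variant.gt_types, dtype=float)  # 0,1,3 -> dosage; 2=missing
        dosage = np.where(gts == 2, np.nan, np.where(gts == 3, 2.0, gts))
        marker_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        columns.append(dosage)
    if skipped:
        logger.info("skipped %d multi-allelic VCF record(s)", skipped)
    values = np.column_stack(columns)
    col_means = np.nanmean(values, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(values))
    if nan_rows.size:
        values[nan_rows, nan_cols] = col_means[nan_cols]
    return drop_monomorphic(MarkerMatrix(sample_ids, marker_ids, values))


def read_phenotype_table(path: str, dialect: str | None = None) -> pd.DataFrame:
    """Phenotype / genotypic-value table: column 1 = sample id, rest = traits."""
    sep = dialect or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.map(str)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return df


def write_marker_table(markers: MarkerMatrix, path: str, sep: str = ",") -> None:
    pd.DataFrame(
        markers.dosages, index=markers.sample_ids, columns=markers.marker_ids
    ).to_csv(path, sep=sep, index_label="sample_id")


def compute_grm(markers: MarkerMatrix) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    A = W W' / (2 * sum_j p_j (1 - p_j)), with W the dosage matrix centered
    column-wise by twice the allele frequency.
    """
    if markers.n < 2:
        raise ValueError("need at least two samples")
    if np.all(markers.dosages.var(axis=0) == 0):
        raise ValueError("all marker columns are monomorphic; GRM undefined")
    p = markers.allele_frequencies()
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all marker columns are monomorphic; GRM undefined")
    w = markers.dosages - 2.0 * p
    values = (w @ w.T) / denom
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    return RelationshipMatrix(list(markers.sample_ids), values)


def pca_scores(markers: MarkerMatrix, k: int) -> ScoreMatrix:
    """PCA scores of the column-centered dosage matrix.

    With k = n the pairwise Euclidean distances among score rows equal those
    among centered dosage rows (full-rank rotation).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(markers.n, markers.m):
        raise ValueError(f"k={k} exceeds min(n, m)={min(markers.n, markers.m)}")
    xc = markers.centered()
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    evf = var / total if total > 0 else np.zeros_like(var)
    scores = u * s
    n_avail = scores.shape[1]
    if k > n_avail:  # pragma: no cover - guarded above
        k = n_avail
    out_scores = np.zeros((markers.n, k))
    out_scores[:, : min(k, n_avail)] = scores[:, :k]
    out_evf = np.zeros(k)
    out_evf[: min(k, n_avail)] = evf[:k]
    return ScoreMatrix(list(markers.sample_ids), out_scores, out_evf)
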