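"""Domain containers and expression-matrix I/O shared by every analysis stage.

Expression is carried as TPM (transcripts per million) in gene x sample
orientation; differential expression consumes expected counts in the same
orientation. Matrices are thin validated wrappers around a pandas DataFrame
so that downstream modules can rely on unique ids and non-negative values.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse


class ValidationError(ValueError):
    """Input violates a container invariant (negative value, duplicate id...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending location."""


def _check_frame(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dups[:5]}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("matrix values must be numeric")
    if np.isnan(values).any():
        raise ValidationError("matrix contains NaN values")
    if (values < 0).any():
        gene = df.index[np.where(values < 0)[0][0]]
        raise ValidationError(f"negative value at gene {gene!r}")
    return df


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of non-negative TPM values."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _check_frame(self.data.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, sample_ids])

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[gene_ids])


@dataclass
class CountMatrix:
    """Gene x sample matrix of non-negative expected counts.

    RSEM-style expected counts are real-valued; rounding to integers happens
    only inside the exact test, never in storage.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _check_frame(self.data.astype(float))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[:, sample_ids])


class Condition(str, enum.Enum):
    HC = "HC"          # home cage
    NE = "NE"          # novel environment
    SALINE = "saline"
    PTZ = "PTZ"


class Stain(str, enum.Enum):
    FOS_POS = "FOS_POS"
    FOS_NEG = "FOS_NEG"
    UNKNOWN = "UNKNOWN"


@dataclass
class SampleMetadata:
    """Per-sample annotations: treatment condition, FOS immunostain, depth."""

    sample_id: str
    condition: Condition = Condition.NE
    stain: Stain = Stain.UNKNOWN
    mapped_reads: int = 0
    qc_pass: bool = True

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.stain = Stain(self.stain)
        if self.mapped_reads < 0:
            raise ValidationError("mapped_reads must be >= 0")


def metadata_to_frame(meta: list[SampleMetadata]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "condition": [m.condition.value for m in meta],
            "stain": [m.stain.value for m in meta],
            "mapped_reads": [m.mapped_reads for m in meta],
            "qc_pass": [m.qc_pass for m in meta],
        }
    ).set_index("sample_id", drop=False)


def metadata_from_frame(df: pd.DataFrame) -> list[SampleMetadata]:
    return [
        SampleMetadata(
            sample_id=str(row["sample_id"]),
            condition=Condition(row["condition"]),
            stain=Stain(row["stain"]),
            mapped_reads=int(row["mapped_reads"]),
            qc_pass=bool(row.get("qc_pass", True)),
        )
        for _, row in df.iterrows()
    ]


@dataclass
class DetectionMatrix:
    """Boolean gene x sample matrix; true iff TPM strictly exceeds threshold."""

    data: pd.DataFrame
    threshold: float = 1.0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_expression_matrix(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Load a gene x sample TPM matrix from TSV or MatrixMarket triplet files.

    TSV: header row of sample ids, first column gene ids. MatrixMarket: the
    ``path`` names the .mtx coordinate file; gene and sample ids are read
    from sidecar files ``<stem>.genes.txt`` and ``<stem>.samples.txt`` (one
    id per line, rows = genes, columns = samples).
    """
    return ExpressionMatrix(_load_frame(path, format))


def load_count_matrix(path: str | Path, format: str = "tsv") -> CountMatrix:
    return CountMatrix(_load_frame(path, format))


def _load_frame(path: str | Path, format: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # pandas reports the offending line
            raise ParseError(f"{path}: {exc}") from exc
        non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        if non_numeric:
            raise ParseError(f"{path}: non-numeric column(s) {non_numeric[:3]}")
        df.index = df.index.astype(str)
        return df
    if format in ("mtx", "mtx_triplet"):
        try:
            mat = scipy_io.mmread(path)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
        genes = _read_ids(path.with_suffix("").with_suffix(".genes.txt"))
        samples = _read_ids(path.with_suffix("").with_suffix(".samples.txt"))
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        if dense.shape != (len(genes), len(samples)):
            raise ParseError(
                f"{path}: matrix shape {dense.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        return pd.DataFrame(dense, index=genes, columns=samples)
    raise ValueError(f"unknown format {format!r}")


def _read_ids(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar name file {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def write_expression_matrix(
    m: ExpressionMatrix | CountMatrix, path: str | Path, format: str = "tsv"
) -> None:
    """Write a matrix as TSV or MatrixMarket coordinate + name sidecars."""
    path = Path(path)
    if format == "tsv":
        m.data.to_csv(path, sep="\t", float_format="%.10g")
        return
    if format in ("mtx", "mtx_triplet"):
        scipy_io.mmwrite(path, sparse.coo_matrix(m.data.to_numpy()))
        base = path.with_suffix("")
        base.with_suffix(".genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        base.with_suffix(".samples.txt").write_text("\n".join(m.sample_ids) + "\n")
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def log2p1(m: ExpressionMatrix) -> pd.DataFrame:
    """Elementwise log2(TPM + 1); zeros map to zero."""
    return pd.DataFrame(
        np.log2(m.data.to_numpy() + 1.0), index=m.data.index, columns=m.data.columns
    )


def detection_matrix(m: ExpressionMatrix, threshold: float = 1.0) -> DetectionMatrix:
    """Detection call per gene and sample: TPM strictly greater than threshold.

    The strict inequality means a gene at exactly the threshold (e.g. TPM 1.0
    at the default) is NOT detected.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    return DetectionMatrix(data=m.data > threshold, threshold=threshold)
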