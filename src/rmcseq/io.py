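"""Data model and file I/O for count matrices, sample metadata, and gene annotation.

The pipeline's substrate is an integer gene x sample count matrix
(:class:`CountMatrix`) plus a per-sample metadata table (:class:`SampleTable`)
carrying the case/control condition, age, batch, and the clinical covariates
used downstream (CAG repeat length, onset age, death age, Vonsattel grade).
Counts may come from featureCounts-style TSV, plain TSV/CSV (genes in rows,
header row of sample ids), or MatrixMarket MTX with sidecar row/column name
files. Gene annotation (symbol, biotype) comes from a GTF or a 3-column TSV.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "SampleTable",
    "GeneAnnotation",
    "read_counts",
    "write_counts",
    "read_samples",
    "read_annotation",
    "filter_protein_coding",
]

#: required featureCounts annotation columns, in dialect order
_FEATURECOUNTS_COLS = ["Geneid", "Chr", "Start", "End", "Strand", "Length"]

#: tolerance for accepting near-integer imported counts when rounding is enabled
_ROUND_TOL = 1e-6


class CountsValidationError(ValueError):
    """A count matrix violated an invariant (negative, non-integer, duplicates)."""


class ParseError(ValueError):
    """A file could not be parsed in the declared format."""


@dataclass
class CountMatrix:
    """Integer gene x sample counts with identifiers and optional gene metadata.

    Invariants: ``counts`` is non-negative and integral with shape
    ``(len(gene_ids), len(sample_ids))``; identifiers are unique.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    gene_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CountsValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CountsValidationError("duplicate gene_ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CountsValidationError("duplicate sample_ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.round(self.counts)
            if np.nanmax(np.abs(self.counts - rounded), initial=0.0) > _ROUND_TOL:
                raise CountsValidationError("counts are not integral")
            self.counts = rounded.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise CountsValidationError("negative counts")
        self.counts = self.counts.astype(np.int64, copy=False)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, gene_meta: pd.DataFrame | None = None
                   ) -> "CountMatrix":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)),
                   frame.to_numpy(), gene_meta)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountMatrix(list(self.gene_ids), list(sample_ids),
                           self.counts[:, idx], self.gene_meta)

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        meta = self.gene_meta.iloc[idx] if self.gene_meta is not None else None
        return CountMatrix(list(gene_ids), list(self.sample_ids), self.counts[idx], meta)


# optional clinical columns and their dtypes
_OPTIONAL_COLS = {"age": float, "batch": str, "cag": "Int64",
                  "onset_age": float, "death_age": float, "vonsattel": "Int64"}


@dataclass
class SampleTable:
    """Per-sample condition, age, batch, and clinical covariates.

    ``condition`` must be ``case`` or ``control`` for every sample; clinical
    fields may be missing and propagate as missing. When both are present,
    ``death_age >= onset_age`` (post-onset lifespan is non-negative).
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.data
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise ValueError("duplicate sample_id values")
        if "condition" not in df.columns or df["condition"].isna().any():
            raise ValueError("condition is required and must be non-missing")
        bad = set(df["condition"]) - {"case", "control"}
        if bad:
            raise ValueError(f"condition must be 'case' or 'control', got {sorted(bad)}")
        for col, dtype in _OPTIONAL_COLS.items():
            if col in df.columns:
                df[col] = df[col].astype(dtype)
        if {"onset_age", "death_age"} <= set(df.columns):
            both = df["onset_age"].notna() & df["death_age"].notna()
            if (df.loc[both, "death_age"] < df.loc[both, "onset_age"]).any():
                raise ValueError("death_age < onset_age for some samples")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def condition(self) -> pd.Series:
        return self.data["condition"]

    def is_case(self) -> np.ndarray:
        return (self.data["condition"] == "case").to_numpy()

    @property
    def cases(self) -> list[str]:
        return list(self.data.index[self.data["condition"] == "case"])

    @property
    def controls(self) -> list[str]:
        return list(self.data.index[self.data["condition"] == "control"])

    def lifespan(self) -> pd.Series:
        """Post-onset lifespan (death_age - onset_age); NaN where either is missing."""
        return self.data["death_age"] - self.data["onset_age"]

    def subset(self, sample_ids: list[str]) -> "SampleTable":
        return SampleTable(self.data.loc[list(sample_ids)].copy())


class GeneAnnotation:
    """gene_id -> (symbol, biotype) lookup with one entry per gene."""

    def __init__(self, table: pd.DataFrame):
        if "gene_id" in table.columns:
            table = table.set_index("gene_id")
        if table.index.duplicated().any():
            raise ValueError("duplicate gene_id in annotation")
        missing = {"symbol", "biotype"} - set(table.columns)
        if missing:
            raise ValueError(f"annotation lacks columns: {sorted(missing)}")
        self.table = table[["symbol", "biotype"]].copy()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    def symbol(self, gene_id: str) -> str:
        return self.table.at[gene_id, "symbol"]

    def biotype(self, gene_id: str) -> str:
        return self.table.at[gene_id, "biotype"]

    def symbols(self, gene_ids) -> list[str]:
        return [self.symbol(g) if g in self else g for g in gene_ids]


def strip_ensembl_version(gene_ids) -> list[str]:
    """Drop trailing '.N' version suffixes from Ensembl-style identifiers."""
    return [re.sub(r"\.\d+$", "", g) for g in gene_ids]


def read_counts(path: str, format: str = "tsv", *, round_tolerance: bool = False,
                strip_versions: bool = False) -> CountMatrix:
    """Read a count matrix.

    Parameters
    ----------
    path : str
        Input file. For ``mtx``, sidecar files ``<stem>.rownames.txt`` and
        ``<stem>.colnames.txt`` must sit next to it.
    format : {"featurecounts", "tsv", "csv", "mtx"}
        featureCounts dialect = optional ``#`` comment line, then columns
        Geneid/Chr/Start/End/Strand/Length followed by one column per sample;
        the annotation columns are kept in ``gene_meta``.
    round_tolerance : bool
        Accept near-integer values (|x - round(x)| <= 1e-6) by rounding.
    strip_versions : bool
        Normalize Ensembl version suffixes ('.15') off gene identifiers.
    """
    if format == "featurecounts":
        cm = _read_featurecounts(path)
    elif format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"could not parse {path!r} as {format}: {exc}") from exc
        cm = _frame_to_counts(df, round_tolerance)
    elif format == "mtx":
        cm = _read_mtx(path, round_tolerance)
    else:
        raise ValueError(f"unsupported format {format!r}")
    if strip_versions:
        cm.gene_ids = strip_ensembl_version(cm.gene_ids)
        if len(set(cm.gene_ids)) != len(cm.gene_ids):
            raise CountsValidationError("version stripping created duplicate gene_ids")
    return cm


def _frame_to_counts(df: pd.DataFrame, round_tolerance: bool,
                     gene_meta: pd.DataFrame | None = None) -> CountMatrix:
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise CountsValidationError("non-numeric count values")
    if not np.issubdtype(values.dtype, np.integer):
        rounded = np.round(values)
        tol = _ROUND_TOL if round_tolerance else 0.0
        if np.nanmax(np.abs(values - rounded), initial=0.0) > tol:
            raise CountsValidationError("non-integer count values")
        values = rounded.astype(np.int64)
    return CountMatrix(list(map(str, df.index)), list(map(str, df.columns)),
                       values, gene_meta)


def _read_featurecounts(path: str) -> CountMatrix:
    with open(path) as fh:
        first = fh.readline()
        skip = 1 if first.startswith("#") else 0
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    if list(df.columns[: len(_FEATURECOUNTS_COLS)]) != _FEATURECOUNTS_COLS:
        raise ParseError(
            "not a featureCounts table: header line "
            f"{list(df.columns[:6])!r} != {_FEATURECOUNTS_COLS!r}"
        )
    meta = df[_FEATURECOUNTS_COLS[1:]].copy()
    meta.index = df["Geneid"].astype(str)
    counts = df.drop(columns=_FEATURECOUNTS_COLS[1:]).set_index("Geneid")
    return _frame_to_counts(counts, round_tolerance=False, gene_meta=meta)


def _sidecar_paths(path: str) -> tuple[str, str]:
    stem = os.path.splitext(path)[0]
    return stem + ".rownames.txt", stem + ".colnames.txt"


def _read_mtx(path: str, round_tolerance: bool) -> CountMatrix:
    rows_path, cols_path = _sidecar_paths(path)
    for p in (rows_path, cols_path):
        if not os.path.exists(p):
            raise ParseError(f"MTX sidecar file missing: {p}")
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = [line.strip() for line in open(rows_path) if line.strip()]
    samples = [line.strip() for line in open(cols_path) if line.strip()]
    df = pd.DataFrame(mat, index=genes, columns=samples)
    return _frame_to_counts(df, round_tolerance)


def write_counts(cm: CountMatrix, path: str, format: str = "tsv") -> None:
    """Write a count matrix in any supported format (round-trips bit-exactly)."""
    if format == "tsv":
        cm.to_frame().to_csv(path, sep="\t")
    elif format == "csv":
        cm.to_frame().to_csv(path)
    elif format == "featurecounts":
        meta = cm.gene_meta
        if meta is None:
            meta = pd.DataFrame(
                {"Chr": "NA", "Start": 0, "End": 0, "Strand": "+", "Length": 1000},
                index=cm.gene_ids,
            )
        df = pd.concat([meta.reset_index(drop=True),
                        pd.DataFrame(cm.counts, columns=cm.sample_ids)], axis=1)
        df.insert(0, "Geneid", cm.gene_ids)
        with open(path, "w") as fh:
            fh.write("# Program:rmcseq\n")
            df.to_csv(fh, sep="\t", index=False)
    elif format == "mtx":
        rows_path, cols_path = _sidecar_paths(path)
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(cm.counts), field="integer")
        with open(rows_path, "w") as fh:
            fh.write("\n".join(cm.gene_ids) + "\n")
        with open(cols_path, "w") as fh:
            fh.write("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unsupported format {format!r}")


def read_samples(path: str) -> SampleTable:
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ParseError("sample table needs a 'sample_id' column")
    return SampleTable(df)


def read_annotation(path: str) -> GeneAnnotation:
    """Read gene annotation from a 3-column TSV (gene_id, symbol, biotype) or a GTF."""
    if path.endswith((".gtf", ".gtf.gz")):
        return _read_gtf(path)
    df = pd.read_csv(path, sep="\t")
    return GeneAnnotation(df)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _read_gtf(path: str) -> GeneAnnotation:
    records = {}
    opener = open
    if path.endswith(".gz"):  # pragma: no cover - convenience
        import gzip

        opener = gzip.open
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gid = attrs.get("gene_id")
            if gid:
                records[gid] = (attrs.get("gene_name", gid),
                                attrs.get("gene_biotype", "NA"))
    df = pd.DataFrame(
        {"gene_id": list(records),
         "symbol": [v[0] for v in records.values()],
         "biotype": [v[1] for v in records.values()]}
    )
    return GeneAnnotation(df)


def filter_protein_coding(genes, annotation: GeneAnnotation,
                          missing: str = "drop") -> list[str]:
    """Keep only protein-coding gene ids, preserving order.

    ``missing`` controls genes absent from the annotation: ``drop`` removes
    them, ``keep`` retains them, ``error`` raises.
    """
    if missing not in ("drop", "keep", "error"):
        raise ValueError(f"unknown missing policy {missing!r}")
    out = []
    for g in genes:
        if g not in annotation:
            if missing == "error":
                raise KeyError(f"gene {g!r} missing from annotation")
            if missing == "keep":
                out.append(g)
            continue
        if annotation.biotype(g) == "protein_coding":
            out.append(g)
    return out


def _data_path(name: str) -> str:
    return os.path.join(os.path.dirname(__file__), "data", name)


def load_blood_deg_panel() -> pd.DataFrame:
    """The published 20-gene blood DEG panel (id, symbol, log2FC, FDR, biotype)."""
    return pd.read_csv(_data_path("blood_deg_panel.tsv"), sep="\t")


def load_brain_target_panel() -> pd.DataFrame:
    """The published cortex target-gene panel with the clinical stratum each
    gene was associated with (CAG, onset age, Vonsattel grade, lifespan)."""
    return pd.read_csv(_data_path("brain_target_panel.tsv"), sep="\t")


def load_cortex_class_counts() -> pd.Series:
    """Published six-class gene counts for the cortex analysis."""
    df = pd.read_csv(_data_path("cortex_class_counts.tsv"), sep="\t")
    return df.set_index("class")["count"]
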