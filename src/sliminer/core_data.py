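"""Domain containers and file I/O for expression / dependency / feature matrices.

Everything downstream of the readers works on gene-by-sample matrices. All
matrices are stored genes-as-rows internally, whatever the input dialect, and
missing values are kept as explicit NaN so correlations can be computed on
pairwise-complete observations rather than on silently zero-filled gaps.

Supported dialects
------------------
``tsv_genes_by_samples``
    First column ``gene`` (optionally followed by a ``gene_id`` column),
    remaining columns are sample ids. UTF-8, no quoting.
``depmap_csv``
    Samples as rows, columns headed ``"SYMBOL (id)"``; transposed on read.
``gct``
    GCT 1.2: ``#1.2`` line, dimensions line, ``Name``/``Description`` columns.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneId",
    "Scale",
    "Cohort",
    "Modality",
    "ExpressionMatrix",
    "DependencyMatrix",
    "FeatureMatrix",
    "SurvivalTable",
    "read_expression_matrix",
    "read_dependency_matrix",
    "read_sample_annotations",
    "align_matrices",
    "write_matrix_tsv",
    "write_results_table",
]


class Scale(str, enum.Enum):
    """Expression value scale."""

    linear_tpm = "linear_tpm"
    log2_tpm_plus1 = "log2_tpm_plus1"
    log2_tpm_plus_1_16 = "log2_tpm_plus_1_16"  # log2(TPM + 0.0625)


class Cohort(str, enum.Enum):
    cell_line = "cell_line"
    tumor = "tumor"
    healthy = "healthy"


class Modality(str, enum.Enum):
    rna = "rna"
    protein = "protein"
    damaging_mutation = "damaging_mutation"
    hotspot_mutation = "hotspot_mutation"
    methylation = "methylation"


@dataclass(frozen=True, order=True)
class GeneId:
    """A gene identified by HGNC-style symbol plus optional external id.

    The external id is the numeric identifier DepMap-style headers carry in
    parentheses, e.g. ``"CDS1 (1040)"`` -> ``GeneId("CDS1", "1040")``.
    """

    symbol: str
    external_id: str | None = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - convenience
        if self.external_id is None:
            return self.symbol
        return f"{self.symbol} ({self.external_id})"


_DEPMAP_HEADER = re.compile(r"^\s*(?P<symbol>\S+)\s*\((?P<id>[^)]*)\)\s*$")


def parse_depmap_gene_header(header: str) -> GeneId:
    """Parse a DepMap column header ``"SYMBOL (id)"`` into a :class:`GeneId`."""
    m = _DEPMAP_HEADER.match(header)
    if m:
        ext = m.group("id").strip() or None
        return GeneId(m.group("symbol"), ext)
    return GeneId(header.strip())


def _check_unique_genes(genes: Sequence[GeneId]) -> None:
    seen: set[tuple[str, str | None]] = set()
    for g in genes:
        key = (g.symbol, g.external_id)
        if key in seen:
            raise ValueError(f"duplicate gene key {key!r}")
        seen.add(key)


def _check_unique(items: Sequence[str], what: str) -> None:
    if len(set(items)) != len(items):
        dupes = sorted({x for x in items if list(items).count(x) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class GeneMatrix:
    """Base gene-by-sample numeric matrix backed by a pandas DataFrame.

    ``data`` is indexed by gene symbol; ``genes`` keeps the full ids in the
    same row order.
    """

    genes: list[GeneId]
    data: pd.DataFrame  # rows = genes (index: symbol), cols = samples

    def __post_init__(self) -> None:
        _check_unique_genes(self.genes)
        _check_unique(list(self.data.columns), "sample ids")
        if len(self.genes) != self.data.shape[0]:
            raise ValueError(
                f"gene list length {len(self.genes)} != row count {self.data.shape[0]}"
            )
        if list(self.data.index) != [g.symbol for g in self.genes]:
            raise ValueError("data index must equal the gene symbols, in order")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def values_for(self, symbol: str) -> np.ndarray:
        """Row vector for one gene symbol (float, NaN for missing)."""
        return self.data.loc[symbol].to_numpy(dtype=float)

    def restrict_samples(self, samples: Sequence[str]) -> "GeneMatrix":
        out = self.__class__.__new__(self.__class__)
        for f in dc_fields(self):
            setattr(out, f.name, getattr(self, f.name))
        out.genes = list(self.genes)
        out.data = self.data.loc[:, list(samples)].copy()
        ann = getattr(out, "annotations", None)
        if ann is not None:
            out.annotations = ann.loc[ann.index.intersection(samples)].copy()
        return out


@dataclass
class ExpressionMatrix(GeneMatrix):
    scale: Scale = Scale.log2_tpm_plus1
    # per-sample annotation frame with columns 'lineage' and/or 'cohort'
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.scale == Scale.linear_tpm:
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("linear TPM values must be >= 0")

    def to_linear_tpm(self) -> "ExpressionMatrix":
        """Return a copy on the linear TPM scale (de-logging if needed)."""
        if self.scale == Scale.linear_tpm:
            data = self.data.copy()
        elif self.scale == Scale.log2_tpm_plus1:
            data = np.exp2(self.data) - 1.0
        else:  # log2(TPM + 0.0625)
            data = np.exp2(self.data) - 0.0625
        data = data.clip(lower=0.0)
        return ExpressionMatrix(
            genes=list(self.genes), data=data, scale=Scale.linear_tpm,
            annotations=self.annotations,
        )

    def to_scale(self, scale: Scale) -> "ExpressionMatrix":
        if scale == self.scale:
            return self
        lin = self.to_linear_tpm()
        if scale == Scale.linear_tpm:
            return lin
        pseudo = 1.0 if scale == Scale.log2_tpm_plus1 else 0.0625
        data = np.log2(lin.data + pseudo)
        return ExpressionMatrix(
            genes=list(self.genes), data=data, scale=scale,
            annotations=self.annotations,
        )


@dataclass
class DependencyMatrix(GeneMatrix):
    """Gene-effect scores (CERES or Chronos): -1 ~ core-essential, 0 ~ non-essential.

    Values outside [-2, 1] are unusual but legal; they are flagged via
    ``n_out_of_range`` rather than rejected.
    """

    score_kind: str = "ceres"
    n_out_of_range: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.data.to_numpy(dtype=float)
        self.n_out_of_range = int(np.sum((vals < -2) | (vals > 1)))


@dataclass
class FeatureMatrix(GeneMatrix):
    """Multi-modality gene-level features (rna/protein/mutation/methylation).

    One row per (gene, modality); the data index is ``"SYMBOL|modality"``.
    """

    modalities: list[Modality] = field(default_factory=list)

    def __post_init__(self) -> None:
        # index layout differs from GeneMatrix: symbol|modality keys
        if len(self.modalities) != len(self.genes):
            raise ValueError("one modality per feature row required")
        keys = [f"{g.symbol}|{m.value}" for g, m in zip(self.genes, self.modalities)]
        _check_unique(keys, "feature keys")
        _check_unique(list(self.data.columns), "sample ids")
        if list(self.data.index) != keys:
            raise ValueError("data index must be 'SYMBOL|modality' keys, in order")
        vals = self.data.to_numpy(dtype=float)
        for i, m in enumerate(self.modalities):
            row = vals[i]
            ok = row[~np.isnan(row)]
            if m in (Modality.damaging_mutation, Modality.hotspot_mutation):
                if not np.all(np.isin(ok, (0.0, 1.0))):
                    raise ValueError(f"mutation feature {keys[i]} must be binary 0/1")
            elif m == Modality.methylation:
                if ok.size and (ok.min() < 0 or ok.max() > 1):
                    raise ValueError(f"methylation feature {keys[i]} must lie in [0,1]")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @staticmethod
    def from_rows(
        rows: Iterable[tuple[GeneId, Modality, Sequence[float]]],
        samples: Sequence[str],
    ) -> "FeatureMatrix":
        rows = list(rows)
        genes = [g for g, _, _ in rows]
        mods = [m for _, m, _ in rows]
        data = pd.DataFrame(
            [list(v) for _, _, v in rows],
            index=[f"{g.symbol}|{m.value}" for g, m in zip(genes, mods)],
            columns=list(samples),
            dtype=float,
        )
        return FeatureMatrix(genes=genes, data=data, modalities=mods)


@dataclass
class SurvivalTable:
    """Right-censored survival data with a per-patient stratifier value."""

    frame: pd.DataFrame  # columns: patient_id, time, event, stratifier_value

    REQUIRED = ("patient_id", "time", "event")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.frame.columns:
                raise ValueError(f"survival table missing column {col!r}")
        if (self.frame["time"] <= 0).any():
            raise ValueError("survival times must be strictly positive")
        ev = set(self.frame["event"].unique())
        if not ev <= {0, 1}:
            raise ValueError(f"event indicator must be 0/1, got {sorted(ev)}")
        _check_unique(list(self.frame["patient_id"].astype(str)), "patient ids")

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _numeric_frame(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Coerce to float; raise naming the offending cell on failure."""
    try:
        return df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
            bad &= ~df[col].astype(str).str.upper().isin(("NA", "NAN", ""))
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValueError(
                    f"{path}: non-numeric value {df.loc[row, col]!r} "
                    f"at gene {row!r}, sample {col!r}"
                )
        return df.apply(pd.to_numeric, errors="coerce")


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv_genes_by_samples",
    scale: Scale | str = Scale.log2_tpm_plus1,
    annotations: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix in one of the supported dialects.

    The result is always genes-as-rows, whatever the file layout.
    """
    genes, data = _read_gene_matrix(path, dialect)
    return ExpressionMatrix(
        genes=genes, data=data, scale=Scale(scale), annotations=annotations
    )


def read_dependency_matrix(
    path: str | Path, dialect: str = "tsv_genes_by_samples", score_kind: str = "ceres"
) -> DependencyMatrix:
    genes, data = _read_gene_matrix(path, dialect)
    return DependencyMatrix(genes=genes, data=data, score_kind=score_kind)


def _read_gene_matrix(path: str | Path, dialect: str) -> tuple[list[GeneId], pd.DataFrame]:
    path = Path(path)
    if dialect == "tsv_genes_by_samples":
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", ""], keep_default_na=False)
        if df.columns[0] != "gene":
            raise ValueError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
        has_id = len(df.columns) > 1 and df.columns[1] == "gene_id"
        symbols = df.iloc[:, 0].astype(str)
        if has_id:
            ids = df.iloc[:, 1]
            genes = [
                GeneId(s, None if pd.isna(i) or i == "" else str(i))
                for s, i in zip(symbols, ids)
            ]
            body = df.iloc[:, 2:]
        else:
            genes = [GeneId(s) for s in symbols]
            body = df.iloc[:, 1:]
        body.index = list(symbols)
        data = _numeric_frame(body, path)
    elif dialect == "depmap_csv":
        df = pd.read_csv(path, index_col=0)
        genes = [parse_depmap_gene_header(c) for c in df.columns]
        data = df.T
        data.index = [g.symbol for g in genes]
        data.columns = [str(c) for c in df.index]
        data = _numeric_frame(data, path)
    elif dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ValueError(f"{path}: malformed GCT dimensions line")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", dtype=str, na_values=["NA", ""], keep_default_na=False)
        if list(df.columns[:2]) != ["Name", "Description"]:
            raise ValueError(f"{path}: GCT must start with Name/Description columns")
        if df.shape[0] != n_genes or df.shape[1] - 2 != n_samples:
            raise ValueError(
                f"{path}: GCT declares {n_genes}x{n_samples} but file has "
                f"{df.shape[0]}x{df.shape[1] - 2}"
            )
        genes = [GeneId(s) for s in df["Name"].astype(str)]
        body = df.iloc[:, 2:]
        body.index = list(df["Name"].astype(str))
        data = _numeric_frame(body, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_unique_genes(genes)
    return genes, data


def read_sample_annotations(path: str | Path) -> pd.DataFrame:
    """Read a `sample, lineage, cohort` TSV into a sample-indexed frame."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise ValueError(f"{path}: annotation TSV needs a 'sample' column")
    return df.set_index("sample")


def write_matrix_tsv(matrix: GeneMatrix, path: str | Path) -> None:
    """Write any gene matrix in the canonical TSV dialect (round-trippable)."""
    path = Path(path)
    has_ids = any(g.external_id is not None for g in matrix.genes)
    with open(path, "w") as fh:
        cols = "\t".join(matrix.samples)
        if has_ids:
            fh.write(f"gene\tgene_id\t{cols}\n")
        else:
            fh.write(f"gene\t{cols}\n")
        vals = matrix.data.to_numpy(dtype=float)
        for i, g in enumerate(matrix.genes):
            cells = "\t".join("" if math.isnan(v) else format(v, ".10g") for v in vals[i])
            if has_ids:
                fh.write(f"{g.symbol}\t{g.external_id or ''}\t{cells}\n")
            else:
                fh.write(f"{g.symbol}\t{cells}\n")


def align_matrices(a: GeneMatrix, b: GeneMatrix) -> tuple[GeneMatrix, GeneMatrix, dict]:
    """Restrict two matrices to their shared samples, identically ordered.

    Returns copies plus a report of how many samples were dropped per side.
    Idempotent: aligning already-aligned matrices changes nothing.
    """
    shared = [s for s in a.samples if s in set(b.samples)]
    if not shared:
        raise ValueError("no shared samples between matrices")
    report = {
        "n_shared": len(shared),
        "n_dropped_a": len(a.samples) - len(shared),
        "n_dropped_b": len(b.samples) - len(shared),
    }
    return a.restrict_samples(shared), b.restrict_samples(shared), report


def write_results_table(
    records: Sequence,
    path: str | Path,
    precision: int = 6,
    columns: Sequence[str] | None = None,
) -> None:
    """Write a homogeneous record list (dataclasses or dicts) as TSV.

    Columns follow the first record's field order; floats use ``precision``
    significant digits. An empty list yields a header-only file (pass
    ``columns`` to control the header when there are no records).
    """
    path = Path(path)
    dicts = []
    for rec in records:
        if hasattr(rec, "__dataclass_fields__"):
            d = {f.name: getattr(rec, f.name) for f in dc_fields(rec)}
        elif isinstance(rec, dict):
            d = dict(rec)
        else:
            raise TypeError(f"unsupported record type {type(rec)!r}")
        dicts.append(d)
    if dicts:
        cols = list(dicts[0].keys())
        for d in dicts[1:]:
            if list(d.keys()) != cols:
                raise ValueError("records have differing fields")
    else:
        cols = list(columns) if columns is not None else []
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        fmt = f".{precision}g"
        for d in dicts:
            cells = []
            for c in cols:
                v = d[c]
                if isinstance(v, float):
                    cells.append("" if math.isnan(v) else format(v, fmt))
                elif v is None:
                    cells.append("")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")
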