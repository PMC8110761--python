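"""Tabular IO for count matrices and sample designs, transcript-to-gene
aggregation, and the low-count expression filter.

All files are plain TSV (tab-separated, UTF-8, header row, no quoting).
Gene, transcript and sample identifiers are opaque strings.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LINES = ("P1", "P2", "H_fwd", "H_rev")

__all__ = [
    "LINES",
    "ParseError",
    "ValidationError",
    "CountMatrix",
    "SampleDesign",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_tx2gene",
    "aggregate_transcripts",
    "filter_low_counts",
]


class ParseError(ValueError):
    """A TSV file could not be parsed into a valid table."""


class ValidationError(ValueError):
    """A structurally valid table violates a domain invariant."""


class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    Wraps a :class:`pandas.DataFrame` whose index holds gene (or
    transcript) identifiers and whose columns hold sample identifiers.
    Identifiers must be unique; counts must be non-negative integers.
    """

    __slots__ = ("_df",)

    def __init__(self, counts: pd.DataFrame, *, allow_rounding: bool = False):
        df = pd.DataFrame(counts).copy()
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups[:5]}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        values = values.astype(float)
        if np.isnan(values).any():
            raise ValidationError("counts contain missing values")
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")
        frac = values != np.round(values)
        if frac.any():
            if not allow_rounding:
                raise ValidationError(
                    "counts must be integers (pass allow_rounding=True to round "
                    "estimated counts)"
                )
            values = np.round(values)
        self._df = pd.DataFrame(
            values.astype(np.int64), index=df.index.astype(str), columns=df.columns.astype(str)
        )

    # -- accessors ---------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self._df.index)

    @property
    def samples(self) -> list[str]:
        return list(self._df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    # -- subsetting --------------------------------------------------------
    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        genes = list(genes)
        missing = set(genes) - set(self._df.index)
        if missing:
            raise ValidationError(f"unknown genes: {sorted(missing)[:5]}")
        return CountMatrix(self._df.loc[genes])

    def subset_samples(self, samples: Iterable[str]) -> "CountMatrix":
        samples = list(samples)
        missing = set(samples) - set(self._df.columns)
        if missing:
            raise ValidationError(f"unknown samples: {sorted(missing)[:5]}")
        return CountMatrix(self._df[samples])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"CountMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


class SampleDesign:
    """Maps each sample to its line, tissue and replicate number.

    ``line`` is one of ``P1``, ``P2``, ``H_fwd``, ``H_rev`` (the two
    parental lines and the two reciprocal-cross hybrids).  A *condition*
    is a ``(line, tissue)`` pair.
    """

    __slots__ = ("_df",)

    REQUIRED = ("sample_id", "line", "tissue", "replicate")

    def __init__(self, table: pd.DataFrame):
        df = pd.DataFrame(table).copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"design missing columns: {missing}")
        df = df[list(self.REQUIRED)]
        df["sample_id"] = df["sample_id"].astype(str)
        df["line"] = df["line"].astype(str)
        df["tissue"] = df["tissue"].astype(str)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in design: {dups[:5]}")
        bad = sorted(set(df["line"]) - set(LINES))
        if bad:
            raise ValidationError(f"unknown line labels {bad}; expected one of {LINES}")
        reps = pd.to_numeric(df["replicate"], errors="coerce")
        if reps.isna().any() or (reps < 1).any() or (reps != reps.round()).any():
            raise ValidationError("replicate must be a positive integer")
        df["replicate"] = reps.astype(int)
        self._df = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self._df["sample_id"])

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self._df["tissue"]))

    @property
    def lines(self) -> list[str]:
        return list(dict.fromkeys(self._df["line"]))

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def condition_of(self, sample: str) -> tuple[str, str]:
        row = self._df[self._df["sample_id"] == sample]
        if row.empty:
            raise ValidationError(f"sample {sample!r} not in design")
        return (row["line"].iloc[0], row["tissue"].iloc[0])

    def condition_samples(self) -> dict[tuple[str, str], list[str]]:
        """Ordered mapping (line, tissue) -> sample ids."""
        out: dict[tuple[str, str], list[str]] = {}
        for _, row in self._df.iterrows():
            out.setdefault((row["line"], row["tissue"]), []).append(row["sample_id"])
        return out

    def for_tissue(self, tissue: str) -> "SampleDesign":
        sub = self._df[self._df["tissue"] == tissue]
        if sub.empty:
            raise ValidationError(f"tissue {tissue!r} not in design")
        return SampleDesign(sub)

    def validate_against(self, matrix: CountMatrix) -> None:
        """Every matrix sample must appear exactly once in the design."""
        design_samples = set(self.samples)
        matrix_samples = set(matrix.samples)
        missing = sorted(matrix_samples - design_samples)
        if missing:
            raise ValidationError(f"samples missing from design: {missing[:5]}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleDesign):
            return NotImplemented
        return self._df.equals(other._df)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, *, allow_rounding: bool = False) -> CountMatrix:
    """Read a genes x samples TSV count table.

    The first column holds gene identifiers and the header row holds
    sample identifiers.  Errors report 1-based file line numbers.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").rstrip("\r").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: header must contain a gene column and >=1 sample")
        sample_ids = header[1:]
        seen: set[str] = set()
        for sid in sample_ids:
            if sid in seen:
                raise ParseError(f"{path}: duplicate sample id {sid!r} in header (line 1)")
            seen.add(sid)
        n_fields = len(header)
        gene_ids: list[str] = []
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").rstrip("\r").split("\t")
            if len(fields) != n_fields:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n_fields} fields, found {len(fields)}"
                )
            gene_ids.append(fields[0])
            rows.append(fields[1:])

    if len(set(gene_ids)) != len(gene_ids):
        dup = next(g for i, g in enumerate(gene_ids) if g in gene_ids[:i])
        lineno = gene_ids.index(dup) + 2
        raise ParseError(f"{path}: duplicate gene id {dup!r} (first seen line {lineno})")

    raw = np.asarray(rows, dtype=object) if rows else np.empty((0, len(sample_ids)), object)
    values = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        col = pd.to_numeric(pd.Series(raw[:, j]), errors="coerce")
        bad = np.flatnonzero(col.isna().to_numpy())
        if bad.size:
            lineno = int(bad[0]) + 2
            raise ParseError(
                f"{path}: line {lineno}: non-numeric count {raw[bad[0], j]!r} "
                f"in sample {sample_ids[j]!r}"
            )
        values[:, j] = col.to_numpy()
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ParseError(
            f"{path}: line {int(i) + 2}: negative count {values[i, j]:g} "
            f"in sample {sample_ids[j]!r}"
        )
    frac = np.argwhere(values != np.round(values))
    if frac.size and not allow_rounding:
        i, j = frac[0]
        raise ParseError(
            f"{path}: line {int(i) + 2}: non-integer count {values[i, j]:g} in sample "
            f"{sample_ids[j]!r} (use allow_rounding to round estimated counts)"
        )
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return CountMatrix(df, allow_rounding=allow_rounding)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_design(path: str | Path) -> SampleDesign:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise ParseError(f"{path}: {exc}") from exc
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_tx2gene(path: str | Path) -> dict[str, str]:
    """Read a two-column (transcript_id, gene_id) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (transcript_id, gene_id)")
    tx, gene = df.columns[0], df.columns[1]
    if df[tx].duplicated().any():
        dups = df.loc[df[tx].duplicated(), tx].tolist()
        raise ValidationError(f"transcript mapped more than once: {dups[:5]}")
    return dict(zip(df[tx], df[gene]))


# ---------------------------------------------------------------------------
# Aggregation and filtering
# ---------------------------------------------------------------------------

def aggregate_transcripts(tx_counts: CountMatrix, tx2gene: Mapping[str, str]) -> CountMatrix:
    """Sum transcript-level counts to gene level.

    Every transcript in the matrix must be present in the map; per-sample
    totals are conserved exactly.  Gene order follows first appearance.
    """
    unmapped = [t for t in tx_counts.genes if t not in tx2gene]
    if unmapped:
        raise ValidationError(
            f"{len(unmapped)} transcripts missing from tx2gene map: {unmapped[:10]}"
        )
    df = tx_counts.to_frame()
    gene_of = pd.Series([tx2gene[t] for t in df.index], index=df.index)
    order = list(dict.fromkeys(gene_of))
    agg = df.groupby(gene_of, sort=False).sum().loc[order]
    return CountMatrix(agg)


def filter_low_counts(
    matrix: CountMatrix,
    design: SampleDesign,
    min_reads: int = 10,
    *,
    per_condition: bool = True,
) -> tuple[CountMatrix, list[str]]:
    """Drop genes weakly covered in *every* condition.

    A gene is removed iff, for every condition (line x tissue), the count
    summed over that condition's replicates is below ``min_reads``.  With
    ``per_condition=False`` the rule is applied per sample instead
    (removed iff every individual sample count is below the threshold).
    Returns the filtered matrix and the removal list.
    """
    design.validate_against(matrix)
    df = matrix.to_frame()
    if per_condition:
        groups = design.condition_samples()
        sums = pd.DataFrame(
            {f"{line}:{tissue}": df[[s for s in ss if s in df.columns]].sum(axis=1)
             for (line, tissue), ss in groups.items()}
        )
        keep = (sums >= min_reads).any(axis=1)
    else:
        keep = (df >= min_reads).any(axis=1)
    removed = list(df.index[~keep])
    return CountMatrix(df.loc[keep]), removed
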