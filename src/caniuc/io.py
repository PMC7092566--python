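"""Readers and writers for the external formats the pipeline touches.

Count matrices and all tabular outputs are plain tab-delimited text; gene
annotation is accepted either as Ensembl-flavoured GTF or as a minimal
4-column TSV dialect (gene_id, chrom, start, end); gene sets are GMT.
All genomic coordinates are held internally as 0-based half-open intervals;
GTF's 1-based inclusive convention is converted on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger("caniuc")

VALID_TISSUES = frozenset({"tumor", "normal"})
VALID_GROUPS = frozenset({"mut", "wt", "none"})


class CountMatrix:
    """Non-negative integer gene x sample expression counts.

    Wraps a pandas DataFrame (genes as index, samples as columns) and
    enforces: unique gene and sample identifiers, integer non-negative
    entries, at least one gene and two samples.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.shape[0] < 1 or frame.shape[1] < 2:
            raise ValueError(
                f"count matrix needs >=1 gene and >=2 samples, got {frame.shape}"
            )
        dup_genes = frame.index[frame.index.duplicated()].unique().tolist()
        if dup_genes:
            raise ValueError(f"duplicate gene identifiers: {dup_genes}")
        dup_samples = frame.columns[frame.columns.duplicated()].unique().tolist()
        if dup_samples:
            raise ValueError(f"duplicate sample identifiers: {dup_samples}")
        values = frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = _first_non_numeric(frame)
            raise ValueError(f"non-numeric count at gene {bad[0]!r}, sample {bad[1]!r}")
        if np.any(~np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite count at gene {frame.index[r]!r}, sample {frame.columns[c]!r}"
            )
        if np.any(values < 0):
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at gene {frame.index[r]!r}, sample {frame.columns[c]!r}"
            )
        if not np.allclose(values, np.round(values)):
            r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ValueError(
                f"non-integer count at gene {frame.index[r]!r}, sample {frame.columns[c]!r}"
            )
        self._frame = frame.astype(np.int64)
        self._frame.index = self._frame.index.astype(str)
        self._frame.columns = self._frame.columns.astype(str)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def gene_ids(self) -> list[str]:
        return self._frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._frame.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self._frame.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self._frame.loc[list(gene_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self._frame.equals(other._frame)

    def __repr__(self) -> str:
        return f"CountMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


def _first_non_numeric(frame: pd.DataFrame) -> tuple[str, str]:
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            return str(bad[0]), str(col)
    return "?", "?"


class TranscriptRecord(NamedTuple):
    """One transcript: gene id plus a 0-based half-open genomic interval."""

    gene_id: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class GeneSet:
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty member sets."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self):
        for name, gs in self.sets.items():
            if not gs.members:
                raise ValueError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers


def read_counts(path: str | Path, dialect: str = "tsv") -> CountMatrix:
    """Read a tab-delimited count matrix (first column gene ids, header row
    sample ids) into a validated :class:`CountMatrix`."""
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    frame.index = frame.index.astype(str)
    numeric = frame.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad_mask = numeric.isna() & frame.notna()
    if bad_mask.to_numpy().any():
        r, c = np.argwhere(bad_mask.to_numpy())[0]
        raise ValueError(
            f"non-numeric count at gene {frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing count at gene {frame.index[r]!r}, sample {frame.columns[c]!r}"
        )
    return CountMatrix(numeric)


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table (sample_id, tissue, group) and validate
    the tumor/normal and mutation-group labelling invariants."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    return validate_samples(table)


def validate_samples(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "tissue", "group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    dup = table["sample_id"][table["sample_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate sample ids: {dup}")
    bad_tissue = sorted(set(table["tissue"]) - VALID_TISSUES)
    if bad_tissue:
        raise ValueError(f"unknown tissue labels: {bad_tissue}")
    bad_group = sorted(set(table["group"]) - VALID_GROUPS)
    if bad_group:
        raise ValueError(f"unknown group labels: {bad_group}")
    normals = table[table["tissue"] == "normal"]
    if (normals["group"] != "none").any():
        raise ValueError("normal samples must have group='none'")
    tumors = table[table["tissue"] == "tumor"]
    if (~tumors["group"].isin({"mut", "wt"})).any():
        raise ValueError("tumor samples must have group in {'mut','wt'}")
    return table.reset_index(drop=True)


_GTF_ATTR_GENE = re.compile(r'gene_id\s+"([^"]+)"')


def read_annotation(path: str | Path, dialect: str = "gtf") -> list[TranscriptRecord]:
    """Read transcript annotation.

    ``gtf``: one record per line with feature type ``transcript``; 1-based
    inclusive coordinates are converted to 0-based half-open. ``tsv4col``:
    columns gene_id, chrom, start, end already in the internal convention.
    """
    path = Path(path)
    records: list[TranscriptRecord] = []
    if dialect == "gtf":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
                chrom, _source, feature, start, end, _score, _strand, _frame, attrs = fields
                if feature != "transcript":
                    continue
                m = _GTF_ATTR_GENE.search(attrs)
                if m is None:
                    raise ValueError(f"{path}:{lineno}: transcript record lacks gene_id attribute")
                start0, end0 = int(start) - 1, int(end)
                if end0 <= start0:
                    raise ValueError(f"{path}:{lineno}: empty interval after conversion")
                records.append(TranscriptRecord(m.group(1), chrom, start0, end0))
    elif dialect == "tsv4col":
        table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        required = ["gene_id", "chrom", "start", "end"]
        missing = set(required) - set(table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        for row in table.itertuples(index=False):
            start, end = int(row.start), int(row.end)
            if end <= start:
                raise ValueError(f"empty interval for gene {row.gene_id!r}: [{start}, {end})")
            if not str(row.chrom):
                raise ValueError(f"empty chromosome for gene {row.gene_id!r}")
            records.append(TranscriptRecord(str(row.gene_id), str(row.chrom), start, end))
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return records


def write_annotation(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    frame = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end"])
    write_table(frame, path)


def annotation_to_gtf_line(rec: TranscriptRecord) -> str:
    """Internal half-open interval back to a 1-based inclusive GTF line."""
    return "\t".join(
        [
            rec.chrom,
            "caniuc",
            "transcript",
            str(rec.start + 1),
            str(rec.end),
            ".",
            ".",
            ".",
            f'gene_id "{rec.gene_id}";',
        ]
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, tab-separated members)."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = GeneSet(desc, members)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.names()):
            gs = collection[name]
            fh.write("\t".join([name, gs.description, *sorted(gs.members)]) + "\n")


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chrom, length in bp) -> dict."""
    table = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    lengths = {str(r.chrom): int(r.length) for r in table.itertuples(index=False)}
    for chrom, length in lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom!r}")
    return lengths


# ---------------------------------------------------------------------------
# writers


def write_table(result, path: str | Path, index: bool = False) -> None:
    """Write a tabular result as TSV with header.

    Floats are written with 17 significant digits so that a read-back
    reproduces them exactly; row order is whatever the producing operation
    fixed (every producer in this package sorts deterministically).
    """
    if isinstance(result, CountMatrix):
        result.frame.to_csv(path, sep="\t", index=True, index_label="gene_id")
        return
    if not isinstance(result, pd.DataFrame):
        raise TypeError(f"cannot write object of type {type(result).__name__}")
    result.to_csv(path, sep="\t", index=index, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def match_genes(count_genes: Iterable[str], annotated_genes: Iterable[str]) -> list[str]:
    """Exact-string intersection of count-matrix and annotation gene ids,
    preserving count-matrix order; logs how many ids fail to match."""
    annotated = set(annotated_genes)
    count_genes = list(count_genes)
    matched = [g for g in count_genes if g in annotated]
    n_unmatched_counts = len(count_genes) - len(matched)
    n_unmatched_annot = len(annotated) - len(set(matched))
    if n_unmatched_counts or n_unmatched_annot:
        logger.warning(
            "gene id match: %d count-matrix ids lack annotation, "
            "%d annotated ids absent from counts; using %d shared genes",
            n_unmatched_counts,
            n_unmatched_annot,
            len(matched),
        )
    return matched
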