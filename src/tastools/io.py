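"""Readers, writers and core domain containers.

Every other module consumes and produces the types defined here: a sparse
gene x barcode :class:`CountMatrix`, per-read :class:`TaggedRecord` streams
parsed from SAM/BAM or TSV, and per-gene :class:`GeneAnnotation` tables.

The on-disk count-matrix convention is the familiar triplet: a Matrix Market
coordinate file (genes as rows, barcodes as columns, 1-based, integer
values) next to ``genes.tsv`` and ``barcodes.tsv``, one id per line.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("tastools")

MTX_NAME = "matrix.mtx"
GENES_NAME = "genes.tsv"
BARCODES_NAME = "barcodes.tsv"


class TastoolsError(Exception):
    """Base class for all toolkit errors."""


class FormatError(TastoolsError):
    """A file violated the expected on-disk format.

    Carries the offending path and, where known, the record that failed.
    """

    def __init__(self, message: str, *, path: str | os.PathLike | None = None,
                 record: object | None = None):
        detail = message
        if path is not None:
            detail = f"{path}: {detail}"
        if record is not None:
            detail = f"{detail} (offending record: {record!r})"
        super().__init__(detail)
        self.path = str(path) if path is not None else None
        self.record = record


class ConfigError(TastoolsError):
    """Invalid configuration or geometry."""


def _check_unique(ids: Iterable[str], what: str, path=None) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise FormatError(f"duplicate {what} id", path=path, record=dup)
    return ids


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts indexed (gene, barcode).

    Parameters
    ----------
    gene_ids, barcode_ids
        Ordered, unique identifier vectors.
    counts
        ``len(gene_ids) x len(barcode_ids)`` matrix of non-negative
        integers; any scipy sparse format or a dense ndarray is accepted
        and stored as CSR.
    """

    gene_ids: list[str]
    barcode_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.barcode_ids = _check_unique(self.barcode_ids, "barcode")
        m = self.counts
        if not sp.issparse(m):
            m = sp.csr_matrix(np.asarray(m))
        else:
            m = m.tocsr()
        if m.shape != (len(self.gene_ids), len(self.barcode_ids)):
            raise FormatError(
                f"count matrix shape {m.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcode_ids)} barcodes")
        if m.nnz and m.data.min() < 0:
            raise FormatError("negative count entry")
        if not np.issubdtype(m.dtype, np.integer):
            data = m.data
            if m.nnz and not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count entry")
            m = m.astype(np.int64)
        self.counts = m

    # -- basic views ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def barcode_index(self) -> dict[str, int]:
        return {b: i for i, b in enumerate(self.barcode_ids)}

    def barcode_totals(self) -> np.ndarray:
        """Total counts per barcode (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_max(self) -> np.ndarray:
        """Per-gene maximum count over barcodes."""
        if self.counts.nnz == 0:
            return np.zeros(len(self.gene_ids), dtype=np.int64)
        return np.asarray(self.counts.max(axis=1).todense()).ravel()

    def subset_barcodes(self, keep: Iterable[str]) -> "CountMatrix":
        keep = set(keep)
        idx = [i for i, b in enumerate(self.barcode_ids) if b in keep]
        return CountMatrix([*self.gene_ids],
                           [self.barcode_ids[i] for i in idx],
                           self.counts[:, idx])

    def subset_genes(self, keep: Iterable[str]) -> "CountMatrix":
        keep = set(keep)
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep]
        return CountMatrix([self.gene_ids[i] for i in idx],
                           [*self.barcode_ids],
                           self.counts[idx, :])

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def equals(self, other: "CountMatrix") -> bool:
        return (self.gene_ids == other.gene_ids
                and self.barcode_ids == other.barcode_ids
                and (self.counts != other.counts).nnz == 0)


@dataclass(frozen=True)
class TaggedRecord:
    """One alignment record annotated with cell barcode and gene.

    The UMI is carried through for bookkeeping but never used for
    deduplication: two reads sharing barcode, gene and UMI count twice.
    """

    read_id: str
    cell_barcode: str | None = None
    umi: str | None = None
    gene_id: str | None = None
    is_primary: bool = True
    is_mapped: bool = True


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene GC fraction and transcript length."""

    gene_id: str
    gc_fraction: float
    transcript_length: int

    def __post_init__(self):
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise FormatError("gc_fraction outside [0, 1]", record=self.gene_id)
        if self.transcript_length < 1:
            raise FormatError("transcript_length < 1", record=self.gene_id)


@dataclass(frozen=True)
class TagConfig:
    """Names of the SAM tags holding barcode / UMI / gene annotations."""

    cell_barcode: str = "CB"
    umi: str = "UB"
    gene: str = "GN"
    strict: bool = False


# ---------------------------------------------------------------------
# Count-matrix triplet I/O
# ---------------------------------------------------------------------

def write_count_matrix(matrix: CountMatrix, out_dir: str | os.PathLike) -> Path:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` into *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coo = matrix.counts.tocoo()
    scipy.io.mmwrite(str(out / MTX_NAME), coo, field="integer")
    (out / GENES_NAME).write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    (out / BARCODES_NAME).write_text("".join(f"{b}\n" for b in matrix.barcode_ids))
    return out


def _read_id_column(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError("file not found", path=path)
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_count_matrix(path: str | os.PathLike) -> CountMatrix:
    """Read a matrix triplet directory (or an explicit .mtx path).

    Raises :class:`FormatError` naming the offending file on dimension
    mismatches, negative/non-integer entries or duplicate ids.
    """
    p = Path(path)
    if p.is_dir():
        mtx, genes, barcodes = p / MTX_NAME, p / GENES_NAME, p / BARCODES_NAME
    else:
        mtx = p
        genes = p.parent / GENES_NAME
        barcodes = p.parent / BARCODES_NAME
    if not mtx.exists():
        raise FormatError("file not found", path=mtx)
    m = scipy.io.mmread(str(mtx))
    gene_ids = _read_id_column(genes)
    barcode_ids = _read_id_column(barcodes)
    if m.shape != (len(gene_ids), len(barcode_ids)):
        raise FormatError(
            f"matrix declares {m.shape[0]} genes x {m.shape[1]} barcodes but id "
            f"files have {len(gene_ids)} and {len(barcode_ids)} rows", path=mtx)
    try:
        return CountMatrix(gene_ids, barcode_ids, m)
    except FormatError as e:
        raise FormatError(str(e), path=mtx) from e


# ---------------------------------------------------------------------
# Tagged-record streams
# ---------------------------------------------------------------------

@dataclass
class StreamStats:
    """Tallies of a pass over a tagged-record stream."""

    yielded: int = 0
    skipped_secondary: int = 0
    missing_tags: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_tagged_records(path: str | os.PathLike,
                        tags: TagConfig = TagConfig(),
                        stats: StreamStats | None = None,
                        gene_map: dict[str, str] | None = None,
                        ) -> Iterator[TaggedRecord]:
    """Stream :class:`TaggedRecord` from a SAM/BAM file or a TSV table.

    SAM/BAM: one record per primary alignment line; secondary and
    supplementary alignments are skipped; unmapped records are yielded
    with ``is_mapped=False``. The gene id comes from the configured gene
    tag, or from the reference name via *gene_map* (a transcript-to-gene
    mapping; identity when the reference is already a gene) when the tag
    is absent.

    TSV: columns ``read_id, cell_barcode, umi, gene_id`` with empty
    fields read as missing.

    Under ``tags.strict`` a missing barcode tag on a mapped primary
    record raises; otherwise the record is yielded with null fields and
    counted in *stats*.
    """
    p = Path(path)
    if not p.exists():
        raise FormatError("file not found", path=p)
    if p.suffix.lower() in {".sam", ".bam"}:
        yield from _read_sam(p, tags, stats, gene_map)
    else:
        yield from _read_tsv_records(p, tags, stats)


def _read_sam(path: Path, tags: TagConfig, stats: StreamStats | None,
              gene_map: dict[str, str] | None) -> Iterator[TaggedRecord]:
    import pysam

    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for aln in fh:
            if aln.is_secondary or aln.is_supplementary:
                if stats:
                    stats.skipped_secondary += 1
                continue
            barcode = aln.get_tag(tags.cell_barcode) if aln.has_tag(tags.cell_barcode) else None
            umi = aln.get_tag(tags.umi) if aln.has_tag(tags.umi) else None
            gene = aln.get_tag(tags.gene) if aln.has_tag(tags.gene) else None
            mapped = not aln.is_unmapped
            if gene is None and mapped and aln.reference_name is not None:
                ref = aln.reference_name
                gene = gene_map.get(ref) if gene_map is not None else ref
            if barcode is None and mapped:
                if tags.strict:
                    raise FormatError(
                        f"missing mandatory tag {tags.cell_barcode}",
                        path=path, record=aln.query_name)
                if stats:
                    stats.missing_tags += 1
            if stats:
                stats.yielded += 1
            yield TaggedRecord(read_id=aln.query_name or "", cell_barcode=barcode,
                               umi=umi, gene_id=gene, is_primary=True,
                               is_mapped=mapped)


_TSV_COLS = ("read_id", "cell_barcode", "umi", "gene_id")


def _read_tsv_records(path: Path, tags: TagConfig,
                      stats: StreamStats | None) -> Iterator[TaggedRecord]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["read_id"]:
            raise FormatError(f"expected header starting with read_id, got {header[:1]}",
                              path=path)
        col = {c: i for i, c in enumerate(header)}
        missing = [c for c in _TSV_COLS if c not in col]
        if missing:
            raise FormatError(f"missing columns {missing}", path=path)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            get = lambda c: (parts[col[c]] or None) if col[c] < len(parts) else None
            barcode = get("cell_barcode")
            if barcode is None:
                if tags.strict:
                    raise FormatError("missing cell_barcode", path=path,
                                      record=get("read_id"))
                if stats:
                    stats.missing_tags += 1
            if stats:
                stats.yielded += 1
            is_mapped = True
            if "is_mapped" in col:
                is_mapped = get("is_mapped") not in ("0", "false", "False")
            yield TaggedRecord(read_id=get("read_id") or "", cell_barcode=barcode,
                               umi=get("umi"), gene_id=get("gene_id"),
                               is_primary=True, is_mapped=is_mapped)


def write_tagged_records(records: Iterable[TaggedRecord],
                         path: str | os.PathLike) -> Path:
    """Write records as the toolkit's TSV convention (round-trips the stream)."""
    p = Path(path)
    with open(p, "w") as fh:
        fh.write("\t".join(_TSV_COLS) + "\tis_mapped\n")
        for r in records:
            fh.write("\t".join([r.read_id, r.cell_barcode or "", r.umi or "",
                                r.gene_id or "", "1" if r.is_mapped else "0"]) + "\n")
    return p


# ---------------------------------------------------------------------
# Gene annotations, FASTQ, run summaries
# ---------------------------------------------------------------------

def read_gene_annotations(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV of (gene_id, gc_fraction, transcript_length), validated."""
    df = pd.read_csv(path, sep="\t")
    for c in ("gene_id", "gc_fraction", "transcript_length"):
        if c not in df.columns:
            raise FormatError(f"missing column {c}", path=path)
    for row in df.itertuples(index=False):
        GeneAnnotation(str(row.gene_id), float(row.gc_fraction),
                       int(row.transcript_length))
    _check_unique(df["gene_id"].astype(str), "gene", path=path)
    return df.set_index("gene_id")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike,
                quality_char: str = "I") -> Path:
    """Write (read_id, sequence) pairs as FASTQ with constant quality."""
    p = Path(path)
    with open(p, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")
    return p


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from an uncompressed FASTQ file."""
    with open(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            fh.readline()
            if not head.startswith("@"):
                raise FormatError("malformed FASTQ header", path=path, record=head)
            yield head[1:].rstrip("\n").split()[0], seq


@dataclass
class RunSummary:
    """Machine-readable summary of a CLI run."""

    command: str
    params: dict = field(default_factory=dict)
    counters: dict = field(default_factory=dict)

    def write(self, path: str | os.PathLike) -> Path:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")
        return p
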