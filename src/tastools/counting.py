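"""Barcode parsing, non-UMI gene counting, and hashtag demultiplexing.

Bead barcodes on nanowell platforms are built from several whitelisted
sections at fixed read offsets (three sections on BD Rhapsody beads, with
an 8-base UMI directly before the polyT stretch). Each section is matched
exactly against its whitelist or corrected to a unique Hamming-distance-1
neighbour; anything more ambiguous rejects the read.

Counting is deliberately non-UMI: the 8-base bead UMIs are too short to
avoid collision at realistic depths, so every primary mapped read
contributes one count to its (gene, barcode) cell. UMIs are carried
through for bookkeeping only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .io import ConfigError, CountMatrix, TaggedRecord


@dataclass(frozen=True)
class BarcodeSection:
    offset: int          # 0-based position in the read
    length: int
    whitelist: frozenset[str]


@dataclass(frozen=True)
class Linker:
    offset: int
    sequence: str
    max_mismatches: int = 0


@dataclass
class BarcodeGeometry:
    """Positional layout of barcode sections, UMI and optional linkers."""

    sections: list[BarcodeSection]
    umi_offset: int | None = None
    umi_length: int = 8
    linkers: list[Linker] = field(default_factory=list)
    allow_reframe: bool = False   # optional +/-1 nt linker-anchored shift

    def __post_init__(self) -> None:
        prev_end = -1
        for sec in self.sections:
            if sec.offset <= prev_end:
                raise ConfigError("barcode sections overlap or are out of order")
            if not sec.whitelist:
                raise ConfigError("empty whitelist")
            if any(len(w) != sec.length for w in sec.whitelist):
                raise ConfigError("whitelist entry length differs from section length")
            prev_end = sec.offset + sec.length - 1

    @property
    def min_read_length(self) -> int:
        end = max(s.offset + s.length for s in self.sections)
        if self.umi_offset is not None:
            end = max(end, self.umi_offset + self.umi_length)
        return end


@dataclass(frozen=True)
class BarcodeHit:
    """Result of parsing one barcode read."""

    barcode: str | None
    n_corrected_sections: int
    umi: str | None
    status: str  # exact | corrected | rejected
    reason: str | None = None

    def __post_init__(self):
        if (self.status == "rejected") != (self.barcode is None):
            raise ValueError("rejected status must coincide with null barcode")


_REJECT = lambda reason: BarcodeHit(None, 0, None, "rejected", reason)


def _hamming1_unique(query: str, whitelist: frozenset[str]) -> str | None:
    """The unique whitelist entry at Hamming distance 1, else None."""
    hit = None
    for w in whitelist:
        d = sum(a != b for a, b in zip(query, w))
        if d == 1:
            if hit is not None:
                return None
            hit = w
    return hit


def _linker_shift(read: str, geometry: BarcodeGeometry) -> int:
    """Best frame shift in {-1, 0, +1} by total linker mismatches."""
    best_shift, best_mm = 0, None
    for shift in (0, -1, 1):
        mm = 0
        for lk in geometry.linkers:
            start = lk.offset + shift
            obs = read[start:start + len(lk.sequence)] if start >= 0 else ""
            if len(obs) < len(lk.sequence):
                mm += len(lk.sequence)
            else:
                mm += sum(a != b for a, b in zip(obs, lk.sequence))
        if best_mm is None or mm < best_mm:
            best_shift, best_mm = shift, mm
    return best_shift


def parse_barcode(read_sequence: str, geometry: BarcodeGeometry) -> BarcodeHit:
    """Parse and error-correct one barcode read against its geometry.

    Each section must match its whitelist exactly or have a unique
    whitelist neighbour at Hamming distance 1; zero or multiple
    candidates reject the read. The UMI is extracted verbatim.
    """
    shift = 0
    if geometry.allow_reframe and geometry.linkers:
        shift = _linker_shift(read_sequence, geometry)
    if len(read_sequence) < geometry.min_read_length + shift:
        return _REJECT("read too short")
    parts: list[str] = []
    n_corrected = 0
    for sec in geometry.sections:
        start = sec.offset + shift
        obs = read_sequence[start:start + sec.length]
        if obs in sec.whitelist:
            parts.append(obs)
            continue
        corrected = _hamming1_unique(obs, sec.whitelist)
        if corrected is None:
            return _REJECT("no unique whitelist neighbour")
        parts.append(corrected)
        n_corrected += 1
    umi = None
    if geometry.umi_offset is not None:
        start = geometry.umi_offset + shift
        umi = read_sequence[start:start + geometry.umi_length]
    status = "corrected" if n_corrected else "exact"
    return BarcodeHit("".join(parts), n_corrected, umi, status)


# ---------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------

def _tally_to_matrix(tally: Counter, row_ids: Sequence[str] | None = None
                     ) -> CountMatrix:
    """Build a CountMatrix from a {(row_id, barcode): n} tally.

    Row and barcode ids are sorted lexicographically so the result is
    invariant to record order. *row_ids* pins the row universe (hashtag
    panels keep all-zero rows).
    """
    if row_ids is None:
        row_ids = sorted({g for g, _ in tally})
    else:
        row_ids = list(row_ids)
    barcodes = sorted({b for _, b in tally})
    gi = {g: i for i, g in enumerate(row_ids)}
    bi = {b: i for i, b in enumerate(barcodes)}
    rows, cols, vals = [], [], []
    for (g, b), n in tally.items():
        rows.append(gi[g])
        cols.append(bi[b])
        vals.append(n)
    counts = sp.coo_matrix((vals, (rows, cols)),
                           shape=(len(row_ids), len(barcodes)), dtype=np.int64)
    return CountMatrix(row_ids, barcodes, counts)


def count_genes(records: Iterable[TaggedRecord],
                valid_barcodes: set[str] | None = None,
                summary: dict | None = None) -> CountMatrix:
    """Tally primary mapped reads per (gene, barcode) without UMI collapse.

    Records lacking a barcode or gene, unmapped or non-primary records,
    and barcodes outside *valid_barcodes* (when given) are skipped and
    tallied into *summary*. The sum of all matrix entries plus skipped
    records equals the number of input records.
    """
    tally: Counter = Counter()
    skipped = Counter()
    n_in = 0
    for r in records:
        n_in += 1
        if not r.is_primary:
            skipped["not_primary"] += 1
        elif not r.is_mapped:
            skipped["unmapped"] += 1
        elif r.cell_barcode is None:
            skipped["no_barcode"] += 1
        elif r.gene_id is None:
            skipped["no_gene"] += 1
        elif valid_barcodes is not None and r.cell_barcode not in valid_barcodes:
            skipped["invalid_barcode"] += 1
        else:
            tally[(r.gene_id, r.cell_barcode)] += 1
    if summary is not None:
        summary["records_in"] = n_in
        summary["records_counted"] = sum(tally.values())
        summary["records_skipped"] = dict(skipped)
    return _tally_to_matrix(tally)


def count_hashtags(records: Iterable[TaggedRecord],
                   tag_panel: Sequence[str],
                   summary: dict | None = None) -> CountMatrix:
    """Tally hashtag reads per (tag, barcode) over a fixed tag panel.

    The record's gene field carries the tag id; off-panel ids go into an
    unmapped-tag bucket reported via *summary*, not into the matrix.
    """
    if not tag_panel:
        raise ConfigError("empty hashtag panel")
    panel = set(tag_panel)
    tally: Counter = Counter()
    unmapped = 0
    n_in = 0
    for r in records:
        n_in += 1
        if (not r.is_primary or not r.is_mapped or r.cell_barcode is None
                or r.gene_id is None):
            unmapped += 1
        elif r.gene_id not in panel:
            unmapped += 1
        else:
            tally[(r.gene_id, r.cell_barcode)] += 1
    if summary is not None:
        summary["records_in"] = n_in
        summary["unmapped_tag_records"] = unmapped
    return _tally_to_matrix(tally, row_ids=sorted(panel))


# ---------------------------------------------------------------------
# Hashtag demultiplexing
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class HashtagCall:
    barcode: str
    calls: dict
    label: str  # "singlet:<tag>" | "doublet" | "negative"


class HashtagDemultiplexer(BaseEstimator):
    """Threshold demultiplexer for cell-hashing tag counts.

    Per barcode, with top-two tag counts ``c1 >= c2``: the barcode is
    ``negative`` when ``c1 < min_total``, a singlet of the argmax tag
    when ``c1 / max(c2, 1) >= singlet_ratio``, otherwise a ``doublet``.
    Ties on the top count resolve to the lexicographically smallest tag.

    Parameters
    ----------
    min_total : int, default=10
        Minimum top-tag count to call anything but negative.
    singlet_ratio : float, default=3.0
        Minimum top-to-second ratio for a singlet call (must exceed 1).
    """

    def __init__(self, min_total: int = 10, singlet_ratio: float = 3.0):
        self.min_total = min_total
        self.singlet_ratio = singlet_ratio

    def _validate(self) -> None:
        if self.min_total < 1:
            raise ConfigError("min_total must be >= 1")
        if self.singlet_ratio <= 1:
            raise ConfigError("singlet_ratio must exceed 1")

    def fit(self, X: CountMatrix, y=None) -> "HashtagDemultiplexer":
        """Record the tag panel; the rule itself has no learned state."""
        self._validate()
        self.tag_ids_ = list(X.gene_ids)
        return self

    def predict(self, X: CountMatrix) -> list[HashtagCall]:
        """Label every barcode of a tags x barcodes count matrix."""
        self._validate()
        dense = X.to_dense()
        tags = X.gene_ids
        order = np.argsort(tags)  # lexicographic tag priority for ties
        calls = []
        for j, barcode in enumerate(X.barcode_ids):
            col = dense[:, j]
            # stable argsort over lexicographically ordered tags: ties on
            # count resolve to the smallest tag id
            ranked = sorted(order, key=lambda i: -col[i])
            c1 = int(col[ranked[0]]) if len(ranked) else 0
            c2 = int(col[ranked[1]]) if len(ranked) > 1 else 0
            if c1 < self.min_total:
                label = "negative"
            elif c1 / max(c2, 1) >= self.singlet_ratio:
                label = f"singlet:{tags[ranked[0]]}"
            else:
                label = "doublet"
            calls.append(HashtagCall(barcode, {t: int(c) for t, c in zip(tags, col)},
                                     label))
        return calls

    def fit_predict(self, X: CountMatrix, y=None) -> list[HashtagCall]:
        return self.fit(X).predict(X)


def demux_hashtags(tag_counts: CountMatrix, min_total: int = 10,
                   singlet_ratio: float = 3.0) -> list[HashtagCall]:
    """Classify each barcode as singlet/doublet/negative from tag counts."""
    return HashtagDemultiplexer(min_total, singlet_ratio).fit_predict(tag_counts)
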