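"""Seeded synthetic fixtures with ground-truth manifests.

Each generator is a pure function of (parameters, seed): regeneration is
bitwise identical. A single global seed fans out to per-generator child
seeds through :func:`child_seed`, which hashes the generator name into a
``SeedSequence`` so fixtures stay independent of invocation order.

The fixtures emulate the statistical regimes the pipeline targets —
whitelisted multi-section barcode reads with planted substitution
errors, the two-regime barcode-rank (knee) curve of cell-containing
versus ambient barcodes, per-gene signal/background mixed counts with
log2-scale Gaussian regimes (matching the mixture-after-transform model
the corrector assumes; a negative-binomial mode exists for robustness
checks), and paired platform matrices with planted per-gene extra
drop-out. They do not attempt read-level sequence realism.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .counting import BarcodeGeometry
from .io import ConfigError, CountMatrix

BASES = np.array(list("ACGT"))


def child_seed(seed: int, name: str) -> np.random.SeedSequence:
    """Deterministic per-generator seed: SeedSequence([seed, crc32(name)])."""
    return np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])


@dataclass
class Manifest:
    """Ground truth of one synthetic fixture; round-trips through JSON."""

    seed: int
    generator: str
    params: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def conv(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not serializable: {type(o)}")
        return json.dumps(dataclasses.asdict(self), default=conv, indent=2)

    def write(self, path) -> Path:
        p = Path(path)
        p.write_text(self.to_json() + "\n")
        return p

    @classmethod
    def from_json(cls, text: str) -> "Manifest":
        d = json.loads(text)
        return cls(d["seed"], d["generator"], d.get("params", {}),
                   d.get("truth", {}))

    @classmethod
    def read(cls, path) -> "Manifest":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------
# Barcode reads
# ---------------------------------------------------------------------

def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    out = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def generate_barcode_reads(geometry: BarcodeGeometry, n_reads: int,
                           error_rates: tuple[float, float, float] = (0.9, 0.08, 0.02),
                           seed: int = 0
                           ) -> tuple[list[tuple[str, str]], Manifest]:
    """Reads with 0/1/2 planted substitutions in proportions *error_rates*.

    Sections are drawn uniformly from their whitelists; all planted
    substitutions land inside a single randomly chosen section (so a
    2-error read is beyond Hamming-1 repair of that section). Linker and
    filler positions carry the configured linker sequence or random
    bases; the UMI is random. Returns (read_id, sequence) pairs plus a
    manifest with the true barcode, UMI and error count per read.
    """
    p = np.asarray(error_rates, dtype=float)
    if p.sum() > 1 + 1e-9 or (p < 0).any():
        raise ConfigError("error rates must be non-negative and sum to <= 1")
    p = p / p.sum()
    rng = np.random.default_rng(child_seed(seed, "barcode_reads"))
    read_len = geometry.min_read_length
    reads, truth = [], []
    for i in range(n_reads):
        template = rng.choice(BASES, size=read_len)
        sections = []
        for sec in geometry.sections:
            wl = sorted(sec.whitelist)
            choice = wl[rng.integers(0, len(wl))]
            sections.append(choice)
            template[sec.offset:sec.offset + sec.length] = list(choice)
        for lk in geometry.linkers:
            template[lk.offset:lk.offset + len(lk.sequence)] = list(lk.sequence)
        umi = None
        if geometry.umi_offset is not None:
            umi = "".join(rng.choice(BASES, size=geometry.umi_length))
            template[geometry.umi_offset:
                     geometry.umi_offset + geometry.umi_length] = list(umi)
        seq = "".join(template)
        n_err = int(rng.choice(3, p=p))
        err_section = -1
        if n_err:
            err_section = int(rng.integers(0, len(geometry.sections)))
            sec = geometry.sections[err_section]
            pos = sec.offset + rng.choice(sec.length, size=n_err, replace=False)
            seq = _mutate(seq, pos, rng)
        rid = f"read{i:06d}"
        reads.append((rid, seq))
        truth.append({"read_id": rid, "barcode": "".join(sections),
                      "umi": umi, "n_errors": n_err,
                      "error_section": err_section})
    manifest = Manifest(seed, "generate_barcode_reads",
                        {"n_reads": n_reads, "error_rates": list(error_rates)},
                        {"reads": truth})
    return reads, manifest


# ---------------------------------------------------------------------
# Barcode-rank (knee) curve
# ---------------------------------------------------------------------

def generate_rank_curve(n_cells: int = 3_000, n_ambient: int = 30_000,
                        cell_count_mean: float = 10_000.0,
                        ambient_count_mean: float = 50.0,
                        sigma: float = 0.35, n_genes: int = 10,
                        seed: int = 0) -> tuple[CountMatrix, Manifest]:
    """Two-regime barcode totals: cell-containing vs ambient barcodes.

    Totals are log-normal with median *cell_count_mean* for true cells
    and *ambient_count_mean* for ambient barcodes (natural-log sigma
    *sigma* for both); a median ratio of at least 20 is enforced so the
    regimes are separable. Totals are spread over *n_genes* genes
    uniformly at random. The manifest labels the true cell barcodes.
    """
    if n_cells < 1:
        raise ConfigError("need at least one true cell")
    if n_ambient and cell_count_mean / ambient_count_mean < 20:
        raise ConfigError("cell/ambient count-mean ratio must be >= 20")
    rng = np.random.default_rng(child_seed(seed, "rank_curve"))
    cell_totals = np.maximum(
        np.rint(np.exp(rng.normal(np.log(cell_count_mean), sigma, n_cells))), 1
    ).astype(np.int64)
    amb_totals = np.maximum(
        np.rint(np.exp(rng.normal(np.log(ambient_count_mean), sigma, n_ambient))), 1
    ).astype(np.int64)
    barcodes = ([f"cell-{i:05d}" for i in range(n_cells)]
                + [f"amb-{i:05d}" for i in range(n_ambient)])
    totals = np.concatenate([cell_totals, amb_totals])
    counts = np.empty((n_genes, len(barcodes)), dtype=np.int64)
    for j, t in enumerate(totals):
        counts[:, j] = rng.multinomial(t, np.full(n_genes, 1.0 / n_genes))
    matrix = CountMatrix([f"gene-{i:03d}" for i in range(n_genes)],
                         barcodes, sp.csr_matrix(counts))
    manifest = Manifest(seed, "generate_rank_curve",
                        {"n_cells": n_cells, "n_ambient": n_ambient,
                         "cell_count_mean": cell_count_mean,
                         "ambient_count_mean": ambient_count_mean,
                         "sigma": sigma, "n_genes": n_genes},
                        {"true_cells": barcodes[:n_cells]})
    return matrix, manifest


# ---------------------------------------------------------------------
# DBEC signal/background matrix
# ---------------------------------------------------------------------

def generate_dbec_matrix(n_genes: int = 200, n_cells: int = 1_000,
                         n_signal_genes: int = 50,
                         signal_cell_fraction: float = 0.3,
                         high_mean_log2: float = 10.0,
                         low_mean_log2: float = 2.0,
                         sd_log2: float = 0.7, seed: int = 0,
                         distribution: str = "lognormal2"
                         ) -> tuple[CountMatrix, Manifest]:
    """Counts with planted per-gene signal and diffusion-background regimes.

    Signal genes carry counts ``2^N(high, sd^2) - 1`` in a
    *signal_cell_fraction* of cells and ``2^N(low, sd^2) - 1`` elsewhere
    (rounded, clipped at 0); non-signal genes carry only the low regime.
    ``distribution="negbin"`` swaps each regime for a negative binomial
    with the same mean (robustness mode). The manifest labels every
    nonzero entry signal or background and records the true regime
    parameters.
    """
    if not 0.0 < signal_cell_fraction < 1.0:
        raise ConfigError("signal_cell_fraction must be in (0, 1)")
    if n_signal_genes and high_mean_log2 - low_mean_log2 < 4:
        raise ConfigError("high and low log2 means must differ by >= 4")
    if n_signal_genes > n_genes:
        raise ConfigError("more signal genes than genes")
    rng = np.random.default_rng(child_seed(seed, "dbec_matrix"))

    def draw(mean_log2: float, size: int) -> np.ndarray:
        if distribution == "lognormal2":
            z = rng.normal(mean_log2, sd_log2, size)
            return np.maximum(np.rint(2.0 ** z - 1.0), 0).astype(np.int64)
        if distribution == "negbin":
            mu = max(2.0 ** mean_log2 - 1.0, 1e-6)
            r = 4.0  # moderate overdispersion
            return rng.negative_binomial(r, r / (r + mu), size).astype(np.int64)
        raise ConfigError(f"unknown distribution {distribution!r}")

    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    signal_cells: dict[str, list[int]] = {}
    n_sig_cells = int(round(signal_cell_fraction * n_cells))
    gene_ids = [f"gene-{i:04d}" for i in range(n_genes)]
    for i, g in enumerate(gene_ids):
        if i < n_signal_genes:
            chosen = np.sort(rng.choice(n_cells, size=n_sig_cells, replace=False))
            row = draw(low_mean_log2, n_cells)
            row[chosen] = draw(high_mean_log2, n_sig_cells)
            counts[i] = row
            signal_cells[g] = chosen.tolist()
        else:
            counts[i] = draw(low_mean_log2, n_cells)
    matrix = CountMatrix(gene_ids, [f"cell-{j:04d}" for j in range(n_cells)],
                         sp.csr_matrix(counts))
    manifest = Manifest(
        seed, "generate_dbec_matrix",
        {"n_genes": n_genes, "n_cells": n_cells,
         "n_signal_genes": n_signal_genes,
         "signal_cell_fraction": signal_cell_fraction,
         "high_mean_log2": high_mean_log2, "low_mean_log2": low_mean_log2,
         "sd_log2": sd_log2, "distribution": distribution},
        {"signal_genes": gene_ids[:n_signal_genes],
         "signal_cells": signal_cells})
    return matrix, manifest


def entry_labels(matrix: CountMatrix, manifest: Manifest
                 ) -> dict[tuple[int, int], str]:
    """Signal/background label for every nonzero entry of a DBEC fixture."""
    signal_cells = {g: set(c) for g, c in manifest.truth["signal_cells"].items()}
    coo = matrix.counts.tocoo()
    labels = {}
    for i, j in zip(coo.row, coo.col):
        g = matrix.gene_ids[i]
        labels[(int(i), int(j))] = ("signal" if j in signal_cells.get(g, ())
                                    else "background")
    return labels


# ---------------------------------------------------------------------
# Cross-platform pair
# ---------------------------------------------------------------------

def generate_platform_pair(n_genes: int = 500, n_cells: int = 2_000,
                           dropout_boost=None,
                           detect_range: tuple[float, float] = (0.2, 0.9),
                           gc_means: dict | None = None,
                           length_medians: dict | None = None,
                           seed: int = 0
                           ) -> tuple[CountMatrix, CountMatrix, "object", Manifest]:
    """Paired matrices where platform B adds per-gene extra drop-out.

    Platform A entries are Bernoulli(p_g) detections (p_g uniform over
    *detect_range*) times 1 + Poisson(2) counts; B equals A with each
    nonzero entry independently zeroed at the gene's *dropout_boost*
    (scalar, per-gene array, or None for a 50/50 mix of 0 and 0.5).
    Annotations draw GC fraction and transcript length per planted
    detection class (defaults emulate the AT-rich, long-transcript bias
    of terminator-assisted chemistry). The manifest declares each gene's
    expected-delta class.
    """
    import pandas as pd

    rng = np.random.default_rng(child_seed(seed, "platform_pair"))
    p_detect = rng.uniform(*detect_range, size=n_genes)
    if dropout_boost is None:
        boost = np.where(rng.random(n_genes) < 0.5, 0.0, 0.5)
    else:
        boost = np.broadcast_to(np.asarray(dropout_boost, dtype=float),
                                (n_genes,)).copy()
    if (boost < 0).any() or (boost >= 1).any():
        raise ConfigError("dropout_boost must be in [0, 1) per gene")

    detected = rng.random((n_genes, n_cells)) < p_detect[:, None]
    mag = 1 + rng.poisson(2.0, size=(n_genes, n_cells))
    a = np.where(detected, mag, 0).astype(np.int64)
    dropped = rng.random((n_genes, n_cells)) < boost[:, None]
    b = np.where(dropped, 0, a)

    expected_delta = p_detect * boost
    classes = np.where(expected_delta >= 0.10, "a_favored", "common")
    gc_means = gc_means or {"a_favored": 0.44, "common": 0.52,
                            "b_favored": 0.55}
    length_medians = length_medians or {"a_favored": 4000.0, "common": 2000.0,
                                        "b_favored": 1500.0}
    gene_ids = [f"gene-{i:04d}" for i in range(n_genes)]
    gc = np.clip([rng.normal(gc_means[c], 0.03) for c in classes], 0.0, 1.0)
    length = np.maximum(np.rint(
        [np.exp(rng.normal(np.log(length_medians[c]), 0.3)) for c in classes]),
        1).astype(int)
    annotations = pd.DataFrame(
        {"gene_id": gene_ids, "gc_fraction": gc, "transcript_length": length}
    ).set_index("gene_id")

    barcodes = [f"cell-{j:05d}" for j in range(n_cells)]
    mat_a = CountMatrix(gene_ids, barcodes, sp.csr_matrix(a))
    mat_b = CountMatrix(list(gene_ids), list(barcodes), sp.csr_matrix(b))
    manifest = Manifest(
        seed, "generate_platform_pair",
        {"n_genes": n_genes, "n_cells": n_cells,
         "detect_range": list(detect_range)},
        {"p_detect": p_detect, "dropout_boost": boost,
         "expected_delta": expected_delta, "classes": classes.tolist()})
    return mat_a, mat_b, annotations, manifest
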