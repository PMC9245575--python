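"""QC filters, normalization, HVG selection and cross-platform statistics.

These are the downstream summaries the pipeline uses to compare
single-cell platforms: matrix-level QC filters (gene prevalence, genes
per cell, mitochondrial fraction), ln-CPM normalization at a 10^6 scale
factor, mean.var.plot ("mvp") highly-variable-gene selection, per-gene
detection-rate comparisons with GC/length bias tests, pseudo-bulk
aggregation at a 10^7 scale, and Kullback-Leibler divergence between
expression distributions.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, TastoolsError

logger = logging.getLogger("tastools")


# ---------------------------------------------------------------------
# Matrix filters
# ---------------------------------------------------------------------

def filter_matrix(matrix: CountMatrix, min_cells: int = 5,
                  min_genes: int = 500) -> CountMatrix:
    """Drop rarely detected genes, then sparsely covered cells.

    Genes detected (count > 0) in fewer than *min_cells* cells are
    removed first; cells with fewer than *min_genes* detected genes (in
    the reduced gene set) are removed second. The order is fixed.
    """
    if min_cells < 0 or min_genes < 0:
        raise TastoolsError("thresholds must be >= 0")
    binary = (matrix.counts > 0)
    gene_prevalence = np.asarray(binary.sum(axis=1)).ravel()
    keep_genes = gene_prevalence >= min_cells
    reduced = matrix.counts[keep_genes, :]
    genes_per_cell = np.asarray((reduced > 0).sum(axis=0)).ravel()
    keep_cells = genes_per_cell >= min_genes
    if not keep_genes.any() or not keep_cells.any():
        raise TastoolsError(
            f"filtering left nothing: {int(keep_genes.sum())}/{len(keep_genes)} "
            f"genes survived min_cells={min_cells}, "
            f"{int(keep_cells.sum())}/{len(keep_cells)} cells survived "
            f"min_genes={min_genes}")
    gidx = np.flatnonzero(keep_genes)
    cidx = np.flatnonzero(keep_cells)
    return CountMatrix([matrix.gene_ids[i] for i in gidx],
                       [matrix.barcode_ids[j] for j in cidx],
                       reduced[:, cidx])


@dataclass(frozen=True)
class QcRecord:
    barcode: str
    total_reads: int
    genes_detected: int
    mito_fraction: float
    ribo_protein_fraction: float
    rrna_fraction: float
    zero_total: bool = False


def _match_genes(gene_ids: Sequence[str], patterns: Iterable[str]) -> np.ndarray:
    regs = [re.compile(p) for p in patterns]
    return np.array([any(r.search(g) for r in regs) for g in gene_ids])


def qc_proportions(matrix: CountMatrix,
                   gene_sets: Mapping[str, Sequence[str]] | None = None
                   ) -> list[QcRecord]:
    """Per-cell totals and mito / ribosomal-protein / rRNA count fractions.

    *gene_sets* maps set names ("mito", "ribo_protein", "rrna") to regex
    lists matched against gene ids. Cells with zero total get fraction 0
    and a ``zero_total`` flag.
    """
    gene_sets = gene_sets or {"mito": ["^mt-", "^MT-"],
                              "ribo_protein": ["^Rp[sl]", "^RP[SL]"],
                              "rrna": ["^Rn[0-9]*s", "rRNA"]}
    for name, pats in gene_sets.items():
        if not pats:
            raise TastoolsError(f"empty pattern list for gene set {name!r}")
    totals = matrix.barcode_totals().astype(float)
    detected = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
    sums = {}
    for name in ("mito", "ribo_protein", "rrna"):
        mask = _match_genes(matrix.gene_ids, gene_sets.get(name, []))
        sums[name] = (np.asarray(matrix.counts[mask, :].sum(axis=0)).ravel()
                      if mask.any() else np.zeros(len(totals)))
    safe = np.where(totals > 0, totals, 1.0)
    records = []
    for j, b in enumerate(matrix.barcode_ids):
        zero = totals[j] == 0
        records.append(QcRecord(
            b, int(totals[j]), int(detected[j]),
            0.0 if zero else float(sums["mito"][j] / safe[j]),
            0.0 if zero else float(sums["ribo_protein"][j] / safe[j]),
            0.0 if zero else float(sums["rrna"][j] / safe[j]),
            zero_total=bool(zero)))
    return records


def filter_cells_mito(records: Sequence[QcRecord], matrix: CountMatrix,
                      threshold: float = 0.25) -> CountMatrix:
    """Remove cells whose mitochondrial fraction is strictly over *threshold*."""
    if not 0.0 < threshold <= 1.0:
        raise TastoolsError("threshold must be in (0, 1]")
    frac = {r.barcode: r.mito_fraction for r in records}
    keep = [b for b in matrix.barcode_ids if frac.get(b, 0.0) <= threshold]
    return matrix.subset_barcodes(keep)


# ---------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------

class LogCpmNormalizer(BaseEstimator, TransformerMixin):
    """Stateless ln(1 + count / cell_total * scale) normalization.

    With the default ``scale=1e6`` this is the ln-CPM convention used
    throughout the pipeline. Cells with zero total are an error and
    should be filtered beforehand.
    """

    def __init__(self, scale: float = 1_000_000.0):
        self.scale = scale

    def fit(self, X, y=None):
        return self

    def transform(self, X: CountMatrix) -> pd.DataFrame:
        totals = X.barcode_totals().astype(float)
        if (totals <= 0).any():
            bad = [b for b, t in zip(X.barcode_ids, totals) if t <= 0]
            raise TastoolsError(f"zero-total cells present: {bad[:5]}")
        dense = X.to_dense().astype(float)
        values = np.log1p(dense / totals[None, :] * self.scale)
        return pd.DataFrame(values, index=X.gene_ids, columns=X.barcode_ids)


def normalize_log_cpm(matrix: CountMatrix, scale: float = 1_000_000.0
                      ) -> pd.DataFrame:
    """Genes x cells DataFrame of ln(1 + CPM-scaled counts)."""
    return LogCpmNormalizer(scale).transform(matrix)


# ---------------------------------------------------------------------
# Highly variable genes (mean.var.plot recipe)
# ---------------------------------------------------------------------

class MvpGeneSelector(BaseEstimator, TransformerMixin):
    """Highly-variable-gene selection by binned, z-scored dispersion.

    On the de-logged normalized values (expm1 of the ln-normalized
    matrix) each gene gets a mean and a dispersion ln(variance / mean);
    genes are cut into ``n_bins`` equal-width bins of mean, dispersion is
    z-scored within each bin, and a gene is selected when its mean lies
    in ``mean_cutoff`` and its z-scored dispersion in
    ``dispersion_cutoff`` (closed lower bounds). Zero-variance genes are
    excluded; a single-gene or zero-spread bin yields z = 0.

    Attributes
    ----------
    stats_ : pd.DataFrame with mean, dispersion, dispersion_z per gene.
    selected_genes_ : list[str]
    """

    def __init__(self, mean_cutoff: tuple = (0.1, np.inf),
                 dispersion_cutoff: tuple = (0.5, np.inf), n_bins: int = 20):
        self.mean_cutoff = mean_cutoff
        self.dispersion_cutoff = dispersion_cutoff
        self.n_bins = n_bins

    def fit(self, X: pd.DataFrame, y=None) -> "MvpGeneSelector":
        delogged = np.expm1(X.to_numpy(dtype=float))
        mean = delogged.mean(axis=1)
        var = delogged.var(axis=1, ddof=1)
        # constant rows leave rounding residue in the two-pass variance;
        # anything this far below mean^2 is numerically zero variance
        zero_var = var <= np.maximum(mean, 1.0) ** 2 * 1e-24
        with np.errstate(divide="ignore", invalid="ignore"):
            disp = np.where(zero_var, -np.inf, np.log(var / mean))
        finite = np.isfinite(disp)
        if finite.sum() < self.n_bins:
            raise TastoolsError(
                f"need >= {self.n_bins} genes with finite dispersion, "
                f"got {int(finite.sum())}")
        # equal-width bins over the mean range of finite-dispersion genes
        fmean = mean[finite]
        lo, hi = fmean.min(), fmean.max()
        width = (hi - lo) or 1.0
        bin_idx = np.clip(((fmean - lo) / width * self.n_bins).astype(int),
                          0, self.n_bins - 1)
        z = np.zeros(len(mean))
        zf = np.zeros(finite.sum())
        disp_f = disp[finite]
        for b in np.unique(bin_idx):
            members = bin_idx == b
            sd = disp_f[members].std(ddof=1) if members.sum() > 1 else 0.0
            if sd > 0:
                zf[members] = (disp_f[members]
                               - disp_f[members].mean()) / sd
        z[finite] = zf
        self.stats_ = pd.DataFrame(
            {"mean": mean, "dispersion": disp, "dispersion_z": z,
             "finite_dispersion": finite}, index=X.index)
        lo_m = self.mean_cutoff[0]
        hi_m = self.mean_cutoff[1] if self.mean_cutoff[1] is not None else np.inf
        lo_d = self.dispersion_cutoff[0]
        hi_d = (self.dispersion_cutoff[1]
                if self.dispersion_cutoff[1] is not None else np.inf)
        sel = finite & (mean >= lo_m) & (mean < hi_m) \
            & (z >= lo_d) & (z < hi_d)
        self.selected_genes_ = list(X.index[sel])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[self.selected_genes_]


def find_variable_genes_mvp(norm_matrix: pd.DataFrame,
                            mean_cutoff: tuple = (0.1, np.inf),
                            dispersion_cutoff: tuple = (0.5, np.inf),
                            n_bins: int = 20) -> set[str]:
    """Gene ids selected by the mvp recipe on a normalized matrix."""
    sel = MvpGeneSelector(mean_cutoff, dispersion_cutoff, n_bins)
    return set(sel.fit(norm_matrix).selected_genes_)


# ---------------------------------------------------------------------
# Cross-platform detection statistics
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class GeneComparisonRecord:
    gene_id: str
    pct_a: float
    pct_b: float
    delta: float
    detection_class: str  # a_favored | b_favored | common
    gc_fraction: float = float("nan")
    transcript_length: float = float("nan")


def _detection_pct(matrix: CountMatrix) -> dict[str, float]:
    n = len(matrix.barcode_ids)
    pos = np.asarray((matrix.counts > 0).sum(axis=1)).ravel()
    return {g: p / n for g, p in zip(matrix.gene_ids, pos)}


def detection_stats(matrix_a: CountMatrix, matrix_b: CountMatrix,
                    annotations: pd.DataFrame | None = None,
                    delta_threshold: float = 0.10
                    ) -> list[GeneComparisonRecord]:
    """Per-gene detection-rate comparison between two platforms.

    ``pct`` is the fraction of cells with count > 0; genes absent from a
    matrix get pct 0. A gene is ``a_favored`` when delta = pct_a - pct_b
    is at least +0.10 or the gene is detected only in A, ``b_favored``
    symmetrically, and ``common`` otherwise.
    """
    pa, pb = _detection_pct(matrix_a), _detection_pct(matrix_b)
    genes = sorted(set(pa) | set(pb))
    records = []
    for g in genes:
        a, b = pa.get(g, 0.0), pb.get(g, 0.0)
        delta = a - b
        if a > 0 and b == 0:
            cls = "a_favored"
        elif b > 0 and a == 0:
            cls = "b_favored"
        elif delta >= delta_threshold:
            cls = "a_favored"
        elif delta <= -delta_threshold:
            cls = "b_favored"
        else:
            cls = "common"
        gc = length = float("nan")
        if annotations is not None and g in annotations.index:
            gc = float(annotations.loc[g, "gc_fraction"])
            length = float(annotations.loc[g, "transcript_length"])
        records.append(GeneComparisonRecord(g, a, b, delta, cls, gc, length))
    return records


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(pvalues, method="holm")[1]


def compare_annotation_bias(records: Sequence[GeneComparisonRecord]
                            ) -> dict:
    """GC-content and transcript-length bias between detection classes.

    Returns per-class medians/IQRs and two-sided Wilcoxon rank-sum
    p-values for every class pair, Holm-adjusted within each variable.
    Classes with fewer than two genes are omitted with a warning.
    """
    df = pd.DataFrame([r.__dict__ for r in records])
    summaries: dict[str, dict] = {}
    usable = []
    for cls, grp in df.groupby("detection_class"):
        if len(grp) < 2:
            warnings.warn(f"class {cls!r} has < 2 genes; omitted")
            continue
        usable.append(cls)
        summaries[cls] = {}
        for var in ("gc_fraction", "transcript_length"):
            vals = grp[var].dropna()
            q1, med, q3 = (np.percentile(vals, [25, 50, 75])
                           if len(vals) else (np.nan,) * 3)
            summaries[cls][var] = {"n": int(len(vals)), "median": float(med),
                                   "iqr": float(q3 - q1)}
    tests = []
    for var in ("gc_fraction", "transcript_length"):
        rows = []
        for i, ca in enumerate(usable):
            for cb in usable[i + 1:]:
                va = df.loc[df.detection_class == ca, var].dropna()
                vb = df.loc[df.detection_class == cb, var].dropna()
                if len(va) < 2 or len(vb) < 2:
                    continue
                p = scipy.stats.mannwhitneyu(va, vb,
                                             alternative="two-sided").pvalue
                rows.append({"variable": var, "class_a": ca, "class_b": cb,
                             "p_value": float(p)})
        if rows:
            adj = holm_adjust([r["p_value"] for r in rows])
            for r, pa in zip(rows, adj):
                r["p_holm"] = float(pa)
        tests.extend(rows)
    return {"summaries": summaries, "tests": pd.DataFrame(tests)}


# ---------------------------------------------------------------------
# Pseudo-bulk profiles and KL divergence
# ---------------------------------------------------------------------

PSEUDOBULK_TOTAL = 10_000_000.0


@dataclass
class PseudobulkProfile:
    """Per-label gene sums rescaled to a fixed 1e7 total."""

    label: str
    gene_ids: list[str]
    values: np.ndarray  # sums to 1e7
    n_cells: int = 0

    def log_density(self, bin_edges: np.ndarray) -> np.ndarray:
        """Normalized histogram of log10(value + 1) over given edges."""
        h, _ = np.histogram(np.log10(self.values + 1.0), bins=bin_edges)
        total = h.sum()
        return h / total if total else h.astype(float)


def pseudobulk(matrix: CountMatrix,
               cell_labels: Mapping[str, str] | Sequence[str]
               ) -> dict[str, PseudobulkProfile]:
    """Sum raw counts per label and rescale each profile to 1e7 reads."""
    if isinstance(cell_labels, Mapping):
        labels = [cell_labels.get(b) for b in matrix.barcode_ids]
        if any(l is None for l in labels):
            missing = [b for b, l in zip(matrix.barcode_ids, labels) if l is None]
            raise TastoolsError(f"unlabeled cells: {missing[:5]}")
    else:
        labels = list(cell_labels)
        if len(labels) != len(matrix.barcode_ids):
            raise TastoolsError("label vector length != number of cells")
    labels = np.asarray(labels, dtype=object)
    profiles = {}
    for label in sorted(set(labels)):
        cols = np.flatnonzero(labels == label)
        sums = np.asarray(matrix.counts[:, cols].sum(axis=1)).ravel().astype(float)
        total = sums.sum()
        if total == 0:
            warnings.warn(f"label {label!r} has zero total counts; skipped")
            continue
        profiles[label] = PseudobulkProfile(
            str(label), list(matrix.gene_ids),
            sums / total * PSEUDOBULK_TOTAL, n_cells=len(cols))
    return profiles


def kl_divergence_binned(p: np.ndarray, q: np.ndarray,
                         epsilon: float = 0.0) -> float:
    """KL(P || Q) in nats for two discrete distributions on shared bins.

    *epsilon* is added to every bin and both are renormalized first.
    """
    p = np.asarray(p, dtype=float) + epsilon
    q = np.asarray(q, dtype=float) + epsilon
    p = p / p.sum()
    q = q / q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def kl_divergence_profiles(p: PseudobulkProfile, q: PseudobulkProfile,
                           n_bins: int = 100, epsilon: float = 1e-9) -> float:
    """KL divergence between two pseudo-bulk expression distributions.

    Both profiles' per-gene log10(value + 1) are histogrammed over
    shared equal-width bins spanning the pooled range; epsilon-smoothed
    densities go into KL(P || Q), which is asymmetric by definition.
    """
    if p.gene_ids != q.gene_ids:
        raise TastoolsError("profiles have different gene universes")
    lp = np.log10(p.values + 1.0)
    lq = np.log10(q.values + 1.0)
    lo = min(lp.min(), lq.min())
    hi = max(lp.max(), lq.max())
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    hp, _ = np.histogram(lp, bins=edges)
    hq, _ = np.histogram(lq, bins=edges)
    return kl_divergence_binned(hp / hp.sum(), hq / hq.sum(), epsilon)


# ---------------------------------------------------------------------
# Composition correlation
# ---------------------------------------------------------------------

class CompositionCorrelation(NamedTuple):
    pearson_r: float
    r_squared: float
    slope: float
    intercept: float
    p_value: float


def composition_correlation(comp_a, comp_b) -> CompositionCorrelation:
    """Pearson correlation and OLS fit of composition A on composition B.

    Inputs are subset-fraction vectors over matching labels, either as
    aligned sequences or as label-keyed mappings (label sets must match
    exactly; unmatched labels raise).
    """
    if isinstance(comp_a, Mapping) or isinstance(comp_b, Mapping):
        if not (isinstance(comp_a, Mapping) and isinstance(comp_b, Mapping)):
            raise TastoolsError("mix of mapping and sequence compositions")
        if set(comp_a) != set(comp_b):
            raise TastoolsError(
                f"label mismatch: {sorted(set(comp_a) ^ set(comp_b))}")
        labels = sorted(comp_a)
        a = np.array([comp_a[l] for l in labels], dtype=float)
        b = np.array([comp_b[l] for l in labels], dtype=float)
    else:
        a = np.asarray(comp_a, dtype=float)
        b = np.asarray(comp_b, dtype=float)
        if len(a) != len(b):
            raise TastoolsError("composition vectors differ in length")
    if len(a) < 3:
        raise TastoolsError("need at least 3 matched labels")
    if np.allclose(a.var(), 0) or np.allclose(b.var(), 0):
        raise TastoolsError("zero-variance composition vector")
    r, p = scipy.stats.pearsonr(a, b)
    fit = scipy.stats.linregress(b, a)  # regress A on B
    return CompositionCorrelation(float(r), float(r ** 2),
                                  float(fit.slope), float(fit.intercept),
                                  float(p))
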