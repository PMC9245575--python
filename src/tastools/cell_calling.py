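"""Barcode-rank (knee-plot) cell calling.

The knee plot orders barcodes by total read count and plots log10(total)
against log10(rank). Cell-containing barcodes form a high plateau,
ambient barcodes a low tail, and the transition shows up as a steep drop.
Two landmarks are located on the curve after collapsing tied totals to
their average rank and running-median smoothing:

* the **knee** — the point of minimum signed curvature, where the plateau
  starts to roll off; and
* the **inflection** — the left end of the steepest-descent segment
  (most negative first finite difference dy/dx) at or right of the knee.

Barcodes whose total is at least the count at the chosen landmark are
called as valid cells (boundary configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CountMatrix, TastoolsError

MIN_DISTINCT_TOTALS = 10


@dataclass
class RankProfile:
    """Descending per-barcode totals with optional inflection landmarks."""

    barcode_ids: list[str]
    totals: np.ndarray                 # positive ints, non-increasing
    inflection_rank: int | None = None  # 1-based rank into `totals`
    inflection_count: int | None = None
    knee_rank: int | None = None
    knee_count: int | None = None
    smoothing_params: dict = field(default_factory=dict)

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(1, len(self.totals) + 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"rank": self.ranks, "barcode": self.barcode_ids,
                           "total": self.totals})
        if self.inflection_count is not None:
            df["called"] = df["total"] >= self.inflection_count
        return df


def rank_barcodes(matrix: CountMatrix) -> RankProfile:
    """Order barcodes by descending total count, dropping zero totals.

    Ties in totals are ordered by barcode id for determinism.
    """
    totals = matrix.barcode_totals()
    keep = totals > 0
    if not keep.any():
        raise TastoolsError("all barcode totals are zero; nothing to rank")
    barcodes = np.asarray(matrix.barcode_ids, dtype=object)[keep]
    totals = totals[keep]
    order = np.lexsort((barcodes, -totals))
    return RankProfile(list(barcodes[order]), totals[order].astype(np.int64))


def _running_median(y: np.ndarray, window: int) -> np.ndarray:
    """Centred running median with a symmetric, shrinking (odd) window.

    The window stays symmetric at the edges, so it is always odd and the
    filter is exactly the identity on monotone sequences.
    """
    if window <= 1:
        return y.copy()
    n = len(y)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = np.median(y[i - h:i + h + 1])
    return out


def find_inflection(profile: RankProfile, window: int = 5,
                    n_grid: int = 512, exclude_ranks: int = 10) -> RankProfile:
    """Locate inflection and knee on the log-log rank curve.

    Tied totals are collapsed to their average rank, the curve is
    resampled onto a uniform grid in log10(rank) (so near-vertical steps
    between adjacent high ranks cannot dominate the derivatives), and
    log10(total) is smoothed by a centred running median of width
    *window*. The **inflection** is the steepest-descent point: the
    minimum of the first finite difference dy/dx over the grid,
    ignoring the first *exclude_ranks* ranks, mapped back to the
    steepest raw segment it covers (ties toward the smaller rank). The
    **knee** is the minimum of signed curvature in the bounded stretch
    between the preceding slope maximum and the inflection, where the
    plateau rolls off. ``inflection_rank`` is the largest original rank
    sharing the inflection total, so the inclusive calling boundary
    keeps every tied barcode.
    """
    totals = profile.totals
    uniq = np.unique(totals)[::-1]  # descending distinct totals
    if len(uniq) < MIN_DISTINCT_TOTALS:
        raise TastoolsError(
            f"only {len(uniq)} distinct totals (< {MIN_DISTINCT_TOTALS}); "
            "apply a raw count threshold instead")
    ranks = np.arange(1, len(totals) + 1)
    # average rank and largest rank per distinct total (totals descending)
    avg_rank = np.zeros(len(uniq))
    last_rank = np.zeros(len(uniq), dtype=np.int64)
    start = 0
    for i, t in enumerate(uniq):
        n = int((totals == t).sum())
        avg_rank[i] = ranks[start:start + n].mean()
        last_rank[i] = ranks[start + n - 1]
        start += n

    x = np.log10(avg_rank)
    y = np.log10(uniq.astype(float))
    xg = np.linspace(x[0], x[-1], n_grid)
    yg = _running_median(np.interp(xg, x, y), window)

    d1 = np.diff(yg) / np.diff(xg)
    # skip grid cells that lie entirely within the excluded leading ranks
    skip = int(np.searchsorted(xg, np.log10(max(exclude_ranks, 1)),
                               side="right"))
    skip = min(max(skip - 1, 0), len(d1) - 1)
    right_cell = skip + int(np.argmin(d1[skip:]))

    def steepest_original(cell: int) -> int:
        """Raw segment with the steepest slope overlapping a grid cell."""
        cx0, cx1 = xg[cell], xg[cell + 1]
        ks = [k for k in range(len(x) - 1)
              if x[k + 1] > cx0 and x[k] < cx1]
        if not ks:
            return int(np.searchsorted(x, cx0, side="right")) - 1
        slopes = [(y[k + 1] - y[k]) / (x[k + 1] - x[k]) for k in ks]
        return ks[int(np.argmin(slopes))]

    infl_idx = steepest_original(right_cell)
    # the inflection is the upper end of the steepest drop, except when
    # that drop is the curve's terminal segment: with nothing below it
    # (no ambient tail) the whole population lies above, so take the
    # lower end and retain every barcode
    if infl_idx == len(x) - 2:
        infl_idx = len(x) - 1

    left_cell = int(np.argmax(d1[:right_cell + 1])) if right_cell else 0
    yp = np.gradient(yg, xg)
    ypp = np.gradient(yp, xg)
    curvature = ypp / np.power(1.0 + yp ** 2, 1.5)
    lo, hi = left_cell, max(right_cell, left_cell + 1)
    knee_cell = lo + int(np.argmin(curvature[lo:hi + 1]))
    knee_idx = min(int(np.searchsorted(x, xg[knee_cell], side="right")),
                   len(x) - 1)

    return RankProfile(
        profile.barcode_ids, profile.totals,
        inflection_rank=int(last_rank[infl_idx]),
        inflection_count=int(uniq[infl_idx]),
        knee_rank=int(last_rank[knee_idx]),
        knee_count=int(uniq[knee_idx]),
        smoothing_params={"window": window, "n_grid": n_grid,
                          "exclude_ranks": exclude_ranks,
                          "n_distinct": int(len(uniq))})


class KneeCellCaller(BaseEstimator, TransformerMixin):
    """Call valid cells at the knee-plot inflection point.

    ``fit`` builds the barcode-rank profile and locates the landmarks;
    ``transform`` keeps the barcodes whose total count clears the
    threshold (the gene set is unchanged).

    Parameters
    ----------
    window : int, default=5
        Running-median window on log10 totals.
    boundary : {"inclusive", "strict"}, default="inclusive"
        Keep barcodes with total >= threshold count ("inclusive", the
        default reading of calling cells *over* the inflection point,
        which retains the inflection barcode itself) or > it ("strict").
    use : {"inflection", "knee"}, default="inflection"
        Which landmark supplies the threshold.

    Attributes
    ----------
    profile_ : RankProfile
        Rank curve with both landmarks.
    threshold_count_ : int
        Count threshold applied by :meth:`transform`.
    """

    def __init__(self, window: int = 5, boundary: str = "inclusive",
                 use: str = "inflection"):
        self.window = window
        self.boundary = boundary
        self.use = use

    def fit(self, X: CountMatrix, y=None) -> "KneeCellCaller":
        if self.boundary not in ("inclusive", "strict"):
            raise TastoolsError(f"unknown boundary {self.boundary!r}")
        if self.use not in ("inflection", "knee"):
            raise TastoolsError(f"unknown landmark {self.use!r}")
        self.profile_ = find_inflection(rank_barcodes(X), window=self.window)
        self.threshold_count_ = (self.profile_.inflection_count
                                 if self.use == "inflection"
                                 else self.profile_.knee_count)
        return self

    def transform(self, X: CountMatrix) -> CountMatrix:
        totals = X.barcode_totals()
        if self.boundary == "inclusive":
            keep = totals >= self.threshold_count_
        else:
            keep = totals > self.threshold_count_
        idx = np.flatnonzero(keep)
        return CountMatrix(list(X.gene_ids),
                           [X.barcode_ids[i] for i in idx],
                           X.counts[:, idx])


def call_cells(matrix: CountMatrix, profile: RankProfile,
               boundary: str = "inclusive") -> CountMatrix:
    """Retain the barcodes whose total clears the profile's inflection count."""
    if profile.inflection_count is None:
        raise TastoolsError("profile carries no inflection; run find_inflection")
    caller = KneeCellCaller(boundary=boundary)
    caller.profile_ = profile
    caller.threshold_count_ = profile.inflection_count
    return caller.transform(matrix)
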