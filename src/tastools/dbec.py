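"""Distribution-based error correction (DBEC) of a count matrix.

Nanowell scRNA-seq counts carry gene-specific background from RNA that
diffuses between wells during cell lysis and reverse transcription. For
each strongly expressed gene the per-cell counts then look like a mixture
of a low "diffusion" component and one or two genuine expression
components. DBEC removes the background per gene:

1. select genes whose log2(max count + 1) exceeds 8;
2. variance-stabilize the nonzero counts with a maximum-likelihood
   biexponential transform ``f(x) = a*exp(b*x) - c*exp(-d*x) + f0``;
3. fit univariate Gaussian mixtures with a single shared variance
   ("model E") for K = 1..3 components by EM and pick K by BIC;
4. if the highest component mean exceeds 5.5 (shallow-sequenced data) or
   6 (deep), flag every component sitting more than 5 (shallow) or 5.5
   (deep) below it as background;
5. zero the counts of cells whose maximum-a-posteriori component is
   background. Zero counts are never touched and the output never
   exceeds the input.

Component-mean thresholds are calibrated to log2-like units (the same
scale as the selection rule), so by default component means are mapped
back through the fitted transform onto the log2(count+1) scale before
comparison; comparing on the raw transformed scale is available via
``threshold_scale="transformed"``.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ConfigError, CountMatrix

logger = logging.getLogger("tastools")

_VAR_FLOOR = 1e-8


@dataclass
class EmSettings:
    max_iter: int = 500
    tol: float = 1e-8          # relative log-likelihood change
    n_restarts: int = 5        # quantile init + (n_restarts - 1) random
    seed: int = 0


@dataclass
class DbecParams:
    """All DBEC thresholds, with the published defaults.

    ``comp_mean_gt`` / ``diff_gt`` default to the depth-mode values
    (shallow: 5.5 / 5; deep: 6 / 5.5) when left as None.
    """

    select_log2max_gt: float = 8.0
    depth_mode: str = "shallow"
    comp_mean_gt: float | None = None
    diff_gt: float | None = None
    k_range: tuple[int, ...] = (1, 2, 3)
    threshold_scale: str = "log2"   # or "transformed"
    include_zeros: bool = False
    em: EmSettings = field(default_factory=EmSettings)

    def __post_init__(self):
        if self.depth_mode not in ("shallow", "deep"):
            raise ConfigError(f"unknown depth_mode {self.depth_mode!r}")
        if not set(self.k_range) <= {1, 2, 3}:
            raise ConfigError("k_range must be within {1, 2, 3}")
        if self.select_log2max_gt <= 0:
            raise ConfigError("select_log2max_gt must be > 0")
        if self.threshold_scale not in ("log2", "transformed"):
            raise ConfigError(f"unknown threshold_scale {self.threshold_scale!r}")

    @property
    def effective_comp_mean_gt(self) -> float:
        if self.comp_mean_gt is not None:
            return self.comp_mean_gt
        return 5.5 if self.depth_mode == "shallow" else 6.0

    @property
    def effective_diff_gt(self) -> float:
        if self.diff_gt is not None:
            return self.diff_gt
        return 5.0 if self.depth_mode == "shallow" else 5.5


# ---------------------------------------------------------------------
# Gene selection
# ---------------------------------------------------------------------

def select_genes(matrix: CountMatrix, params: DbecParams) -> set[str]:
    """Genes with log2(max per-cell count + 1) strictly above the cutoff."""
    log2max = np.log2(matrix.gene_max().astype(float) + 1.0)
    return {g for g, v in zip(matrix.gene_ids, log2max)
            if v > params.select_log2max_gt}


# ---------------------------------------------------------------------
# Biexponential transform
# ---------------------------------------------------------------------

@dataclass
class BiexpTransform:
    """Flow-style biexponential display transform.

    The count axis is described by the strictly increasing growth map
    ``w(y) = a*exp(b*y) - c*exp(-d*y) + f0`` from display units *y* to
    counts *x*; the transform applied to data is its inverse,
    ``f(x) = alpha * w^{-1}(x)``, linear-like near zero and logarithmic
    at large counts. The affine factor *alpha* (which the fit cannot
    identify) is anchored so that f(0) = 0 and f(max) = log2(max + 1),
    keeping transformed units commensurate with the log2 scale of the
    selection and classification thresholds.

    ``kind="log2_fallback"`` marks the degenerate-input fallback, where
    the map is log2(x + 1) instead.
    """

    a: float
    b: float
    c: float
    d: float
    f0: float
    alpha: float = 1.0
    fit_loglik: float = float("nan")
    kind: str = "biexp"

    def _w(self, y):
        return (self.a * np.exp(self.b * y)
                - self.c * np.exp(-self.d * y) + self.f0)

    def _wprime(self, y):
        return (self.a * self.b * np.exp(self.b * y)
                + self.c * self.d * np.exp(-self.d * y))

    def _y_upper(self, xmax: float) -> float:
        return np.log((xmax + self.c + 1.0 - self.f0) / self.a) / self.b

    def _invert(self, x: np.ndarray) -> np.ndarray:
        """Vectorized w^{-1} via monotone interpolation + Newton polish."""
        xmax = float(x.max(initial=0.0))
        y_hi = max(self._y_upper(xmax), 1e-6)
        grid = np.linspace(0.0, y_hi, 256)
        y = np.interp(x, self._w(grid), grid)
        for _ in range(6):
            y = np.clip(y - (self._w(y) - x) / self._wprime(y), 0.0, y_hi)
        return y

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "log2_fallback":
            return np.log2(x + 1.0)
        return self.alpha * self._invert(x)

    def derivative(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "log2_fallback":
            return 1.0 / ((x + 1.0) * np.log(2.0))
        return self.alpha / self._wprime(self._invert(x))

    def inverse(self, t: float) -> float:
        """Back-map a transformed value to the count scale (closed form)."""
        if self.kind == "log2_fallback":
            return float(2.0 ** t - 1.0)
        return float(self._w(np.asarray(t, dtype=float) / self.alpha))


def _biexp_objective(u: np.ndarray, x: np.ndarray) -> float:
    """Negative profiled normal log-likelihood with the log-Jacobian term.

    u = (log b, log c, log d); a = 1 and f0 = c - 1 are fixed (w(0) = 0)
    because the objective cannot identify the affine scale of the
    display axis.
    """
    b, c, d = np.exp(u)
    w = BiexpTransform(1.0, b, c, d, c - 1.0)
    y = w._invert(x)
    s2 = y.var()
    if not np.isfinite(s2) or s2 <= 0:
        return 1e12
    n = len(x)
    # log f'(x) = -log w'(y); profiled normal loglik = -n/2 log s2 + const
    nll = 0.5 * n * np.log(s2) + np.log(w._wprime(y)).sum()
    return float(nll) if np.isfinite(nll) else 1e12


def fit_biexponential(values: np.ndarray, n_starts: int = 3) -> BiexpTransform:
    """Fit the display transform by bounded multistart maximum likelihood.

    The parameters maximize the normal log-likelihood of the transformed
    values including the log-Jacobian term, with bounded L-BFGS from a
    few spread starting points. Inputs with fewer than 20 observations
    or fewer than 3 distinct values fall back to log2(x + 1).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 20 or len(np.unique(x)) < 3:
        return BiexpTransform(0, 0, 0, 0, 0, kind="log2_fallback")
    xmax = x.max()
    # the likelihood shape is stable under thinning; cap the points the
    # optimizer sees (an even stride over the sorted sample keeps the
    # distribution) while the returned transform is exact for any x
    x_fit = x
    if len(x) > 512:
        xs = np.sort(x)
        x_fit = xs[np.linspace(0, len(xs) - 1, 512).astype(int)]
    bounds = [(np.log(0.01), np.log(10.0)),
              (np.log(1e-6), np.log(1e4)),
              (np.log(1e-3), np.log(10.0))]
    # b ~ ln2 makes the log region count doublings, the natural scale here
    starts = [(np.log(2.0), 1.0, 1.0),
              (0.2, 10.0, 0.5),
              (1.5, 0.1, 2.0)][:n_starts]
    best, best_val = None, np.inf
    for s in starts:
        res = scipy.optimize.minimize(
            _biexp_objective, np.log(s), args=(x_fit,), method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 60})
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    b, c, d = np.exp(best)
    raw = BiexpTransform(1.0, b, c, d, c - 1.0)
    # anchor the unidentified scale: f(0)=0 holds by w(0)=0; stretch so
    # the top of the data range lands at log2(xmax + 1)
    top = float(raw._invert(np.array([xmax]))[0])
    alpha = np.log2(xmax + 1.0) / top if top > 0 else 1.0
    trans = BiexpTransform(1.0, b, c, d, c - 1.0, alpha=alpha,
                           fit_loglik=-best_val)
    probe = trans(np.linspace(0, xmax, 64))
    if not np.all(np.diff(probe) > 0):
        logger.warning("biexponential fit not strictly increasing; using fallback")
        return BiexpTransform(0, 0, 0, 0, 0, kind="log2_fallback")
    return trans


# ---------------------------------------------------------------------
# Equal-variance Gaussian mixture ("model E") by EM
# ---------------------------------------------------------------------

@dataclass
class MixtureFitE:
    """Univariate Gaussian mixture with one shared variance."""

    K: int
    weights: np.ndarray
    means: np.ndarray
    shared_variance: float
    loglik: float
    bic: float
    responsibilities: np.ndarray          # n x K
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    n: int = 0

    def map_assign(self, values: np.ndarray) -> np.ndarray:
        """MAP component index for each value."""
        return np.argmax(self._log_resp(np.asarray(values, float)), axis=1)

    def _log_resp(self, x: np.ndarray) -> np.ndarray:
        lp = (np.log(np.maximum(self.weights, 1e-300))[None, :]
              - 0.5 * np.log(2 * np.pi * self.shared_variance)
              - 0.5 * (x[:, None] - self.means[None, :]) ** 2
              / self.shared_variance)
        return lp - logsumexp(lp, axis=1, keepdims=True)


def _bic(loglik: float, K: int, n: int) -> float:
    p = (K - 1) + K + 1  # free weights + means + shared variance
    return -2.0 * loglik + p * np.log(n)


def _em_run(x: np.ndarray, K: int, means0: np.ndarray, var0: float,
            weights0: np.ndarray, settings: EmSettings
            ) -> tuple:
    n = len(x)
    means = means0.astype(float).copy()
    var = max(float(var0), _VAR_FLOOR)
    weights = weights0.astype(float).copy()
    trace = []
    converged = False
    resp = np.full((n, K), 1.0 / K)
    for _ in range(settings.max_iter):
        lp = (np.log(np.maximum(weights, 1e-300))[None, :]
              - 0.5 * np.log(2 * np.pi * var)
              - 0.5 * (x[:, None] - means[None, :]) ** 2 / var)
        # manual log-sum-exp over the (small) component axis
        lpmax = lp.max(axis=1)
        norm = lpmax + np.log(np.exp(lp - lpmax[:, None]).sum(axis=1))
        loglik = float(norm.sum())
        trace.append(loglik)
        resp = np.exp(lp - norm[:, None])
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= (
                settings.tol * max(abs(trace[-2]), 1.0)):
            converged = True
            break
        nk = resp.sum(axis=0)
        safe = nk > 1e-12
        weights = np.maximum(nk, 1e-12) / n
        weights /= weights.sum()
        new_means = means.copy()
        new_means[safe] = (resp[:, safe] * x[:, None]).sum(axis=0) / nk[safe]
        means = new_means
        var = float((resp * (x[:, None] - means[None, :]) ** 2).sum() / n)
        if var < _VAR_FLOOR:
            logger.warning("mixture variance underflow; floored at %g", _VAR_FLOOR)
            var = _VAR_FLOOR
    return trace[-1], means, weights, var, resp, converged, np.array(trace)


def fit_mixture_model_e(values: np.ndarray, K: int,
                        settings: EmSettings | None = None) -> MixtureFitE:
    """EM fit of a K-component equal-variance univariate Gaussian mixture.

    K = 1 is the closed-form MLE (mean and 1/n variance). For K > 1 the
    EM is initialized from a quantile split plus seeded random restarts;
    the best log-likelihood wins. The per-iteration log-likelihood trace
    is non-decreasing, as EM guarantees.
    """
    settings = settings or EmSettings()
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 5 * K:
        raise ValueError(f"need at least {5 * K} observations for K={K}, got {n}")
    if K == 1:
        mean = float(x.mean())
        var = max(float(x.var()), _VAR_FLOOR)
        loglik = float(-0.5 * n * np.log(2 * np.pi * var)
                       - 0.5 * ((x - mean) ** 2).sum() / var)
        return MixtureFitE(1, np.array([1.0]), np.array([mean]), var, loglik,
                           _bic(loglik, 1, n), np.ones((n, 1)),
                           np.array([loglik]), True, n)

    inits = []
    xs = np.sort(x)
    chunks = np.array_split(xs, K)
    q_means = np.array([c.mean() for c in chunks])
    q_w = np.array([len(c) / n for c in chunks])
    q_var = max(float(np.mean([c.var() for c in chunks if len(c)])), _VAR_FLOOR)
    inits.append((q_means, q_var, q_w))
    rng = np.random.default_rng(settings.seed)
    for _ in range(max(settings.n_restarts - 1, 0)):
        means0 = rng.choice(x, size=K, replace=False) if len(np.unique(x)) >= K \
            else x[rng.integers(0, n, K)]
        inits.append((np.sort(means0), max(float(x.var()), _VAR_FLOOR),
                      np.full(K, 1.0 / K)))

    best = None
    for means0, var0, w0 in inits:
        out = _em_run(x, K, means0, var0, w0, settings)
        if best is None or out[0] > best[0]:
            best = out
    loglik, means, weights, var, resp, converged, trace = best
    order = np.argsort(means)  # components reported low-to-high
    return MixtureFitE(K, weights[order], means[order], var, loglik,
                       _bic(loglik, K, n), resp[:, order],
                       trace, converged, n)


def select_model_bic(fits: list[MixtureFitE]) -> MixtureFitE:
    """The fit with minimal BIC; ties resolve to the smaller K."""
    if not fits:
        raise ValueError("no fits to select from")
    best = None
    for fit in sorted(fits, key=lambda f: f.K):
        if best is None or fit.bic < best.bic:
            best = fit
    return best


# ---------------------------------------------------------------------
# Component classification and matrix correction
# ---------------------------------------------------------------------

def classify_components(fit: MixtureFitE, params: DbecParams,
                        transform: BiexpTransform | None = None) -> set[int]:
    """Indices of background components under the depth-mode thresholds.

    With the default ``threshold_scale="log2"`` and a transform given,
    component means are mapped back through the transform to the
    log2(count + 1) scale first. If the largest mean does not exceed the
    component-mean threshold the gene is left untouched (empty set);
    otherwise every component more than ``diff_gt`` below the largest
    mean is background.
    """
    means = np.asarray(fit.means, dtype=float)
    if params.threshold_scale == "log2" and transform is not None:
        means = np.array([np.log2(transform.inverse(m) + 1.0) for m in means])
    m_star = means.max()
    if not m_star > params.effective_comp_mean_gt:
        return set()
    return {j for j, m in enumerate(means)
            if m_star - m > params.effective_diff_gt}


@dataclass
class DbecDecision:
    """Per-gene record of what DBEC did and why."""

    gene_id: str
    selected: bool
    transform: BiexpTransform | None = None
    fit: MixtureFitE | None = None
    component_means: np.ndarray = field(default_factory=lambda: np.empty(0))
    background_components: set[int] = field(default_factory=set)
    n_entries_zeroed: int = 0
    fallback_transform: bool = False
    error: str | None = None


class DbecCorrector(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying DBEC to a count matrix.

    ``fit`` learns, per selected gene, the biexponential transform, the
    BIC-selected equal-variance mixture, and the background component
    set; ``transform`` zeroes the entries whose MAP component is
    background. Zero counts are never modified, non-selected genes pass
    through unchanged, and the output never exceeds the input
    elementwise. Per-gene fit failures are logged and leave the gene
    unchanged.

    Parameters mirror :class:`DbecParams`; ``random_state`` seeds the EM
    restarts (a per-gene child seed keeps results independent of gene
    order).

    Attributes
    ----------
    decisions_ : list[DbecDecision]
        One record per gene, in matrix order.
    selected_genes_ : set[str]
    """

    def __init__(self, select_log2max_gt: float = 8.0,
                 depth_mode: str = "shallow",
                 comp_mean_gt: float | None = None,
                 diff_gt: float | None = None,
                 k_range: tuple[int, ...] = (1, 2, 3),
                 threshold_scale: str = "log2",
                 include_zeros: bool = False,
                 em_max_iter: int = 500, em_tol: float = 1e-8,
                 em_n_restarts: int = 5, random_state: int = 0):
        self.select_log2max_gt = select_log2max_gt
        self.depth_mode = depth_mode
        self.comp_mean_gt = comp_mean_gt
        self.diff_gt = diff_gt
        self.k_range = k_range
        self.threshold_scale = threshold_scale
        self.include_zeros = include_zeros
        self.em_max_iter = em_max_iter
        self.em_tol = em_tol
        self.em_n_restarts = em_n_restarts
        self.random_state = random_state

    def _params(self) -> DbecParams:
        return DbecParams(
            select_log2max_gt=self.select_log2max_gt,
            depth_mode=self.depth_mode, comp_mean_gt=self.comp_mean_gt,
            diff_gt=self.diff_gt, k_range=tuple(self.k_range),
            threshold_scale=self.threshold_scale,
            include_zeros=self.include_zeros,
            em=EmSettings(self.em_max_iter, self.em_tol, self.em_n_restarts,
                          self.random_state))

    def _gene_seed(self, gene_id: str) -> int:
        return (int(self.random_state) * 2654435761
                + zlib.crc32(gene_id.encode())) % (2 ** 31)

    def fit(self, X: CountMatrix, y=None) -> "DbecCorrector":
        params = self._params()
        self.selected_genes_ = select_genes(X, params)
        dense_rows = X.counts.tocsr()
        decisions: list[DbecDecision] = []
        for i, gene in enumerate(X.gene_ids):
            if gene not in self.selected_genes_:
                decisions.append(DbecDecision(gene, selected=False))
                continue
            decisions.append(self._fit_gene(
                gene, np.asarray(dense_rows[i, :].todense()).ravel(), params))
        self.decisions_ = decisions
        return self

    def _fit_gene(self, gene: str, row: np.ndarray, params: DbecParams
                  ) -> DbecDecision:
        values = row.astype(float)
        if not params.include_zeros:
            values = values[values > 0]
        try:
            transform = fit_biexponential(values)
            fallback = transform.kind == "log2_fallback"
            t = transform(values)
            em = EmSettings(params.em.max_iter, params.em.tol,
                            params.em.n_restarts, self._gene_seed(gene))
            fits = [fit_mixture_model_e(t, K, em)
                    for K in sorted(params.k_range) if len(t) >= 5 * K]
            if not fits:
                raise ValueError("too few observations for any K")
            fit = select_model_bic(fits)
            background = classify_components(fit, params, transform)
            return DbecDecision(gene, True, transform, fit,
                                component_means=fit.means,
                                background_components=background,
                                fallback_transform=fallback)
        except Exception as exc:  # per-gene failure never aborts the matrix
            logger.warning("DBEC fit failed for gene %s: %s", gene, exc)
            return DbecDecision(gene, True, error=str(exc))

    def transform(self, X: CountMatrix) -> CountMatrix:
        out = X.counts.tocsr(copy=True)
        by_gene = {d.gene_id: d for d in self.decisions_}
        for i, gene in enumerate(X.gene_ids):
            d = by_gene.get(gene)
            if d is None or not d.selected or d.fit is None \
                    or not d.background_components:
                continue
            lo, hi = out.indptr[i], out.indptr[i + 1]
            vals = out.data[lo:hi].astype(float)
            if len(vals) == 0:
                continue
            comp = d.fit.map_assign(d.transform(vals))
            bg = np.isin(comp, sorted(d.background_components))
            out.data[lo:hi][bg] = 0
            d.n_entries_zeroed = int(bg.sum())
        out.eliminate_zeros()
        return CountMatrix(list(X.gene_ids), list(X.barcode_ids), out)


def apply_dbec(matrix: CountMatrix, params: DbecParams | None = None
               ) -> tuple[CountMatrix, list[DbecDecision]]:
    """Run DBEC on a called-cell matrix; returns (corrected, decisions)."""
    params = params or DbecParams()
    corr = DbecCorrector(
        select_log2max_gt=params.select_log2max_gt,
        depth_mode=params.depth_mode, comp_mean_gt=params.comp_mean_gt,
        diff_gt=params.diff_gt, k_range=params.k_range,
        threshold_scale=params.threshold_scale,
        include_zeros=params.include_zeros,
        em_max_iter=params.em.max_iter, em_tol=params.em.tol,
        em_n_restarts=params.em.n_restarts, random_state=params.em.seed)
    corrected = corr.fit(matrix).transform(matrix)
    return corrected, corr.decisions_
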