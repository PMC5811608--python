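"""FRET-efficiency histograms, Gaussian mixtures and AICc model selection.

The gated burst E values are histogrammed at fixed bin width and the counts
are fitted by nonlinear least squares to a sum of k Gaussians — histogram
curve fitting, the same procedure used on the experimental data — for
k = 1..k_max.  The number of populations is chosen by the corrected Akaike
information criterion

    AICc = n ln(RSS/n) + 2 k_p + 2 k_p (k_p + 1) / (n - k_p - 1)

with k_p = 3k + 1 free parameters (3 per component plus the residual
variance) and n the number of histogram bins inside the occupied support.
Population fractions are Gaussian areas, amplitude * sigma, normalized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .burst import ESPoint

logger = logging.getLogger("protconf")

DEFAULT_BIN_WIDTH = 0.025
DEFAULT_RANGE = (-0.1, 1.1)


@dataclass
class FretHistogram:
    """Uniform-width histogram of burst FRET efficiencies."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_total: int
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.counts = np.asarray(self.counts, float)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if int(self.counts.sum()) != self.n_total:
            raise ValueError("counts must sum to n_total")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def support(self) -> np.ndarray:
        """Boolean mask of bins between the first and last occupied bin."""
        nz = np.flatnonzero(self.counts > 0)
        m = np.zeros(len(self.counts), bool)
        if nz.size:
            m[nz[0] : nz[-1] + 1] = True
        return m


def build_histogram(
    points: Sequence[ESPoint] | np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    e_range: tuple[float, float] = DEFAULT_RANGE,
) -> FretHistogram:
    """Histogram burst E values; out-of-range values are clipped into the
    end bins and counted in ``n_clipped``."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = e_range
    if hi <= lo:
        raise ValueError("invalid range")
    e = np.asarray(
        [p.e for p in points] if len(points) and isinstance(points[0], ESPoint)
        else points, dtype=float)
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    n_clipped = int(np.sum((e < lo) | (e >= edges[-1])))
    eps = bin_width * 1e-9
    e_clip = np.clip(e, lo, edges[-1] - eps)
    counts, _ = np.histogram(e_clip, bins=edges)
    return FretHistogram(edges, counts.astype(float), len(e), n_clipped)


@dataclass(frozen=True)
class GaussianComponent:
    amplitude: float      # bursts (peak height)
    center: float         # efficiency
    sigma: float          # efficiency width

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((x - self.center) / self.sigma) ** 2)


@dataclass
class MixtureFit:
    """Sum-of-Gaussians least-squares fit plus AICc bookkeeping."""

    components: list[GaussianComponent]
    residual_ss: float
    n_bins: int
    k_params: int
    aicc: float
    converged: bool = True
    message: str = ""

    @property
    def k(self) -> int:
        return len(self.components)

    def model(self, x: np.ndarray) -> np.ndarray:
        return sum((c(x) for c in self.components), np.zeros_like(np.asarray(x, float)))


def _aicc(rss: float, n: int, k_params: int) -> float:
    if n - k_params - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * k_params + 2 * k_params * (k_params + 1) / (n - k_params - 1)


def _init_centers(hist: FretHistogram, k: int, rng: np.random.Generator,
                  jitter: float, strategy: str = "peaks") -> np.ndarray:
    """Seed component centers on the histogram.

    ``peaks``: greedy pick of the k tallest bins, enforcing a minimum
    separation so seeds land on distinct modes.  ``quantiles``: weighted
    quantiles of the count distribution.  Jitter diversifies restarts.
    """
    c = hist.centers
    w = hist.counts.copy()
    if w.sum() == 0:
        w[:] = 1.0
    if strategy == "peaks":
        from scipy.signal import find_peaks

        smooth = np.convolve(w, np.ones(3) / 3.0, mode="same")
        loc, props = find_peaks(smooth, distance=2, height=0.0)
        order = loc[np.argsort(props["peak_heights"])[::-1]]
        centers = [float(c[j]) for j in order[:k]]
        if len(centers) < k:
            # fewer modes than components: fill with weighted quantiles
            cdf = np.cumsum(w) / w.sum()
            qs = (np.arange(k - len(centers)) + 0.5) / (k - len(centers))
            centers.extend(np.interp(qs, cdf, c))
        centers = np.asarray(centers)
    else:
        cdf = np.cumsum(w) / w.sum()
        qs = (np.arange(k) + 0.5) / k
        centers = np.interp(qs, cdf, c)
    if jitter > 0:
        centers = centers + rng.normal(0.0, jitter, k)
    return np.sort(np.asarray(centers, float))


def fit_mixture(
    hist: FretHistogram,
    k: int,
    init: Sequence[float] | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> MixtureFit:
    """Least-squares fit of k Gaussians to the histogram counts.

    Deterministic when ``init`` (component centers) is given; otherwise
    multi-start from seeded local-maximum and weighted-quantile centers with
    jitter.  Residuals are weighted by 1/sqrt(count) (counting noise) and
    widths are bounded below at one bin width to exclude spike fits.  A
    non-convergent fit is returned flagged, never silently.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sup = hist.support()
    x = hist.centers[sup]
    y = hist.counts[sup]
    n = int(sup.sum())
    k_params = 3 * k + 1
    if n <= 3 * k + 1:
        return MixtureFit([], math.inf, n, k_params, math.inf, False,
                          f"too few occupied bins ({n}) for k={k}")

    min_sigma = hist.bin_width
    lo_e, hi_e = hist.bin_edges[0], hist.bin_edges[-1]
    amp0 = max(y.max(), 1.0)
    bounds_lo = [0.0, lo_e, min_sigma] * k
    bounds_hi = [np.inf, hi_e, (hi_e - lo_e)] * k
    # counting noise: weight bins by 1/sqrt(max(count, 1))
    w = 1.0 / np.sqrt(np.maximum(y, 1.0))

    def residual(theta: np.ndarray) -> np.ndarray:
        m = np.zeros_like(x)
        for j in range(k):
            a, mu, s = theta[3 * j : 3 * j + 3]
            m += a * np.exp(-0.5 * ((x - mu) / s) ** 2)
        return w * (m - y)

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if init is not None:
        if len(init) != k:
            raise ValueError("init must provide one center per component")
        centers0 = [np.sort(np.asarray(init, float))]
        n_restarts = 1
    else:
        centers0 = [_init_centers(hist, k, rng, 0.0, "peaks")]
        if n_restarts > 1:
            centers0.append(_init_centers(hist, k, rng, 0.0, "quantiles"))
        for j in range(n_restarts - 2):
            strat = "peaks" if j % 2 == 0 else "quantiles"
            centers0.append(_init_centers(hist, k, rng, 0.05, strat))
    for cen in centers0:
        theta0 = []
        for mu in cen:
            j = int(np.clip(np.searchsorted(x, mu), 0, len(x) - 1))
            theta0 += [max(y[j], 0.05 * amp0), float(np.clip(mu, lo_e, hi_e)), 0.05]
        starts.append(np.asarray(theta0))

    best = None
    for theta0 in starts:
        try:
            res = least_squares(residual, theta0, bounds=(bounds_lo, bounds_hi),
                                method="trf", xtol=1e-10, ftol=1e-10,
                                max_nfev=150 * k)
        except Exception:  # pragma: no cover - defensive
            continue
        rss = float(np.sum(res.fun ** 2))
        # status 0 = iteration cap: a redundant component pinned at an
        # amplitude bound stalls progress; the fit is still usable if finite
        usable = res.success or (res.status == 0 and np.isfinite(rss))
        if usable and (best is None or rss < best[0]):
            best = (rss, res.x)
        # weighted residuals: rss ~ chi^2; stop restarting once the fit is
        # already at the counting-noise floor
        if best is not None and best[0] <= 1.2 * n:
            break
    if best is None:
        return MixtureFit([], math.inf, n, k_params, math.inf, False,
                          f"no convergent fit for k={k} after {len(starts)} starts")
    rss, theta = best
    comps = sorted(
        (GaussianComponent(float(theta[3 * j]), float(theta[3 * j + 1]),
                           float(theta[3 * j + 2])) for j in range(k)),
        key=lambda c: c.center,
    )
    return MixtureFit(list(comps), rss, n, k_params, _aicc(rss, n, k_params))


def select_by_aicc(
    hist: FretHistogram,
    k_max: int = 4,
    n_restarts: int = 10,
    seed: int = 0,
    parsimony_margin: float = 2.0,
) -> tuple[MixtureFit, dict[int, MixtureFit]]:
    """Fit k = 1..k_max and select the component count by AICc.

    Models within ``parsimony_margin`` AICc units of the minimum are treated
    as equally supported (the conventional dAICc <= 2 equivalence band) and
    the smallest such k is returned; set the margin to 0 for the bare
    minimum-AICc rule.  All per-k fits are returned alongside.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    fits: dict[int, MixtureFit] = {}
    for k in range(1, k_max + 1):
        fit = fit_mixture(hist, k, n_restarts=n_restarts, seed=seed + k)
        fits[k] = fit
        if not math.isfinite(fit.aicc):
            logger.warning("k=%d skipped for model selection: %s", k,
                           fit.message or "AICc undefined")
    finite = {k: f for k, f in fits.items() if math.isfinite(f.aicc)}
    if not finite:
        raise RuntimeError("no k produced a finite AICc")
    min_aicc = min(f.aicc for f in finite.values())
    best_k = min(k for k, f in finite.items()
                 if f.aicc - min_aicc <= parsimony_margin)
    best = finite[best_k]
    delta = {k: f.aicc - best.aicc for k, f in finite.items()}
    logger.info("AICc selection: best k=%d; dAICc=%s", best_k,
                {k: round(v, 2) for k, v in delta.items()})
    return best, fits


@dataclass
class PopulationSummary:
    """Per-component center, width and area fraction."""

    centers: np.ndarray
    sigmas: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, float)
        self.sigmas = np.asarray(self.sigmas, float)
        self.fractions = np.asarray(self.fractions, float)
        if abs(self.fractions.sum() - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1")

    @property
    def dominant(self) -> int:
        return int(np.argmax(self.fractions))


def population_fractions(fit: MixtureFit) -> PopulationSummary:
    """Area fractions (amplitude * sigma, normalized) of a converged fit."""
    if not fit.converged or not fit.components:
        raise ValueError("population fractions require a converged fit")
    areas = np.array([c.amplitude * c.sigma for c in fit.components])
    if areas.sum() <= 0:
        raise ValueError("degenerate fit: all component areas are zero")
    return PopulationSummary(
        np.array([c.center for c in fit.components]),
        np.array([c.sigma for c in fit.components]),
        areas / areas.sum(),
    )
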