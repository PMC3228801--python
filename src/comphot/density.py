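"""Kernel density estimation, UCV bandwidth selection and variability bands.

Integration positions on the collapsed coordinate of one analysis unit are
modelled as an i.i.d. sample ``x_1..x_n`` from an unknown density ``f`` on
``[0, L)``.  The density is estimated with the Gaussian kernel estimator

    fhat(x) = (1/(n h)) sum_i K((x - x_i)/h),    K = standard normal pdf,

evaluated on an equally spaced grid and interpolated with a cubic spline.
No boundary correction is applied.

The bandwidth ``h`` is selected by unbiased (least-squares, leave-one-out)
cross-validation: minimise

    UCV(h) = int fhat^2 - (2/n) sum_i fhat_{-i}(x_i),

an unbiased estimate (up to an h-free constant) of the integrated squared
error.  For the Gaussian kernel both terms have closed forms in the
pairwise distances.

Around sqrt(fhat) a *variability band* with constant half width

    w = z_{(1+alpha)/2} * sqrt(R(K) / (4 n h)),   R(K) = int K^2 = 1/(2 sqrt(pi)),

is built; the square-root (variance-stabilising) transform makes the
approximate variance independent of the unknown density.  The edges are
transformed back as lower = max(sqrt(fhat) - w, 0)^2 and
upper = (sqrt(fhat) + w)^2.  This band reflects estimator variability but
ignores smoothing bias: it is NOT a confidence band and carries no nominal
coverage probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .blindmap import AnalysisUnit

logger = logging.getLogger("comphot.density")

#: R(K) = int K(u)^2 du for the standard Gaussian kernel
RK_GAUSSIAN = 1.0 / (2.0 * np.sqrt(np.pi))
#: default band level
DEFAULT_LEVEL = 0.99
#: default number of equally spaced grid points per analysis unit
DEFAULT_GRID_SIZE = 2 ** 14
#: units with fewer sites than this (for either vector) are skipped
MIN_SITES = 10

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)
# above this sample size the UCV pair sums are evaluated on an FFT-binned
# distance histogram instead of the dense pairwise matrix
_UCV_EXACT_MAX_N = 600
_UCV_FFT_BINS = 2 ** 17


class InsufficientDataError(ValueError):
    """Raised when a unit has too few sites for density estimation."""


@dataclass(frozen=True)
class IntegrationSiteSet:
    """One vector's integration positions on one unit's collapsed axis."""

    positions: np.ndarray  # sorted, in [0, domain_length)
    domain_length: float
    vector: str = ""
    unit: AnalysisUnit | None = None

    def __post_init__(self) -> None:
        pos = np.sort(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)
        if pos.size and (pos[0] < 0 or pos[-1] >= self.domain_length):
            raise ValueError("positions must lie in [0, domain_length)")

    @property
    def n(self) -> int:
        return int(self.positions.size)


@dataclass
class DensityEstimate:
    """Gaussian-kernel density estimate on an equally spaced grid."""

    grid: np.ndarray
    values: np.ndarray  # fhat at grid points, >= 0
    h: float
    n: int
    label: str = ""
    _spline: CubicSpline | None = field(default=None, repr=False)

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def __call__(self, x):
        """Evaluate fhat between grid points (natural cubic spline, clipped at 0)."""
        if self._spline is None:
            self._spline = CubicSpline(self.grid, self.values, bc_type="natural")
        return np.clip(self._spline(x), 0.0, None)

    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.grid))


@dataclass
class VariabilityBand:
    """Pointwise variability band around a density estimate.

    Not a confidence band: the half width accounts for estimator variance
    only, the smoothing bias is ignored.
    """

    estimate: DensityEstimate
    level: float
    half_width_sqrt_scale: float
    lower: np.ndarray
    upper: np.ndarray

    @property
    def grid(self) -> np.ndarray:
        return self.estimate.grid

    def band_at(self, x) -> tuple[np.ndarray, np.ndarray]:
        """Band edges between grid points, recomputed from interpolated fhat."""
        s = np.sqrt(self.estimate(x))
        w = self.half_width_sqrt_scale
        return np.maximum(s - w, 0.0) ** 2, (s + w) ** 2


@dataclass
class BandwidthResult:
    """Outcome of the UCV bandwidth search."""

    h_opt: float
    objective_trace: list[tuple[float, float]]
    search_range: tuple[float, float]


def _positions(sites) -> np.ndarray:
    if isinstance(sites, IntegrationSiteSet):
        return sites.positions
    return np.sort(np.asarray(sites, dtype=float))


def estimate_density(sites, h: float,
                     grid_size: int = DEFAULT_GRID_SIZE,
                     domain_length: float | None = None,
                     label: str | None = None) -> DensityEstimate:
    """Evaluate the Gaussian-kernel estimator on an equally spaced grid.

    ``grid_size`` left cell edges are placed on ``[0, L)``; evaluation
    between grid points goes through the estimate's cubic spline.
    """
    x = _positions(sites)
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 sites, got {n}")
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    if grid_size < 64:
        raise ValueError("grid_size must be >= 64")
    if domain_length is None:
        if isinstance(sites, IntegrationSiteSet):
            domain_length = sites.domain_length
        else:
            domain_length = float(x[-1]) + 1.0
    L = float(domain_length)
    grid = np.arange(grid_size, dtype=float) * (L / grid_size)
    values = np.zeros(grid_size)
    # chunk over sites to bound the (grid x sites) temporary
    chunk = max(1, int(4e6) // grid_size)
    for lo in range(0, n, chunk):
        u = (grid[:, None] - x[None, lo:lo + chunk]) / h
        values += np.exp(-0.5 * u * u).sum(axis=1)
    values *= _INV_SQRT_2PI / (n * h)
    return DensityEstimate(grid=grid, values=values, h=float(h), n=n,
                           label=label if label is not None
                           else getattr(sites, "vector", ""))


class _PairDistances:
    """Pairwise |x_i - x_j| sums of Gaussian kernels, reusable across h.

    Exact dense distances for small n; for large n a zero-padded FFT
    autocorrelation of binned positions gives the distance histogram, on
    which the kernel sums are evaluated (bin width << any admissible h).
    """

    def __init__(self, x: np.ndarray, exact: bool | None = None):
        self.n = x.size
        if exact is None:
            exact = self.n <= _UCV_EXACT_MAX_N
        self.exact = exact
        if exact:
            d = np.abs(x[:, None] - x[None, :])
            iu = np.triu_indices(self.n, k=1)
            self.d = d[iu]  # each unordered pair once
        else:
            span = float(x.max() - x.min())
            span = span if span > 0 else 1.0
            m = _UCV_FFT_BINS
            self.delta = span / (m - 1)
            idx = np.round((x - x.min()) / self.delta).astype(np.int64)
            counts = np.bincount(idx, minlength=m).astype(float)
            size = 1 << int(np.ceil(np.log2(2 * m)))
            f = np.fft.rfft(counts, size)
            ac = np.fft.irfft(f * np.conj(f), size)[:m]
            ac = np.round(ac)
            ac[0] = (ac[0] - self.n) / 2.0  # remove self pairs, halve to unordered
            self.lag_counts = ac  # lag 0 entry now counts distinct same-bin pairs
            self.lags = np.arange(m, dtype=float) * self.delta

    def sum_phi(self, scale: float) -> float:
        """sum over unordered pairs of phi(d / scale), phi = std normal pdf."""
        if self.exact:
            u = self.d / scale
            return float(np.exp(-0.5 * u * u).sum()) * _INV_SQRT_2PI
        u = self.lags / scale
        keep = u < 12.0
        vals = np.exp(-0.5 * u[keep] ** 2) * _INV_SQRT_2PI
        return float((self.lag_counts[keep] * vals).sum())


def _ucv_from_pairs(pairs: _PairDistances, h: float) -> float:
    n = pairs.n
    s1 = pairs.sum_phi(h)                    # sum_{i<j} phi(d/h)
    s2 = pairs.sum_phi(h * np.sqrt(2.0))     # sum_{i<j} phi(d/(h sqrt 2))
    int_f2 = (n * _INV_SQRT_2PI / np.sqrt(2.0) + 2.0 * s2 / np.sqrt(2.0)) / (n * n * h)
    loo = 2.0 * (2.0 * s1) / (n * (n - 1) * h)
    return int_f2 - loo


def ucv_objective(sites, h: float) -> float:
    """Unbiased cross-validation score UCV(h) (closed form, Gaussian kernel).

    ``UCV(h) = int fhat^2 - (2/n) sum_i fhat_{-i}(x_i)`` where
    ``fhat_{-i}`` is the estimator built without observation ``i``.
    """
    x = _positions(sites)
    if x.size < 2:
        raise InsufficientDataError(f"need at least 2 sites, got {x.size}")
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    return _ucv_from_pairs(_PairDistances(x, exact=True), h)


def silverman_bandwidth(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = max(np.abs(x).max(), 1.0)
    return 0.9 * scale * x.size ** (-0.2)


def default_search_range(sites, domain_length: float | None = None) -> tuple[float, float]:
    """``[2 * median nearest-neighbour spacing, L / 4]``."""
    x = _positions(sites)
    if domain_length is None:
        domain_length = (sites.domain_length if isinstance(sites, IntegrationSiteSet)
                         else float(x[-1] - x[0]) or 1.0)
    nn = np.diff(x)
    nn = nn[nn > 0]
    lo = 2.0 * (np.median(nn) if nn.size else 1.0)
    hi = domain_length / 4.0
    if lo >= hi:
        lo = hi / 100.0
    return float(lo), float(hi)


def select_bandwidth(sites, search_range: tuple[float, float] | None = None,
                     grid: int = 200) -> BandwidthResult:
    """Minimise UCV(h) over a log-spaced grid, then refine by golden section.

    Falls back to Silverman's rule (with a warning) when the objective is
    numerically flat over the whole grid.
    """
    x = _positions(sites)
    if x.size < 3:
        raise InsufficientDataError(f"need at least 3 sites, got {x.size}")
    if search_range is None:
        search_range = default_search_range(sites)
    lo, hi = float(search_range[0]), float(search_range[1])
    if not (0 < lo < hi):
        raise ValueError("invalid search range")
    pairs = _PairDistances(x)
    hs = np.geomspace(lo, hi, grid)
    scores = np.array([_ucv_from_pairs(pairs, h) for h in hs])
    trace = list(zip(hs.tolist(), scores.tolist()))
    if np.ptp(scores) < 1e-12:
        h = min(max(silverman_bandwidth(x), lo), hi)
        logger.warning("flat UCV objective; falling back to Silverman h=%.4g", h)
        return BandwidthResult(h_opt=float(h), objective_trace=trace,
                               search_range=(lo, hi))
    k = int(np.argmin(scores))
    blo = hs[max(k - 1, 0)]
    bhi = hs[min(k + 1, grid - 1)]
    if blo < bhi:
        res = minimize_scalar(lambda h: _ucv_from_pairs(pairs, h),
                              bounds=(blo, bhi), method="bounded",
                              options={"xatol": 1e-3 * hs[k]})
        h_opt, f_opt = float(res.x), float(res.fun)
        if f_opt > scores[k]:
            h_opt, f_opt = float(hs[k]), float(scores[k])
    else:
        h_opt, f_opt = float(hs[k]), float(scores[k])
    trace.append((h_opt, f_opt))
    return BandwidthResult(h_opt=h_opt, objective_trace=trace,
                           search_range=(lo, hi))


def band_half_width(n: int, h: float, level: float = DEFAULT_LEVEL) -> float:
    """Constant half width on the sqrt scale: ``z_{(1+a)/2} sqrt(R(K)/(4 n h))``."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = norm.ppf((1.0 + level) / 2.0)
    return float(z * np.sqrt(RK_GAUSSIAN / (4.0 * n * h)))


def variability_band(estimate: DensityEstimate,
                     level: float = DEFAULT_LEVEL) -> VariabilityBand:
    """Level-``alpha`` variability band around ``estimate``.

    Built on the square-root scale where the approximate variance does not
    depend on the unknown density; edges are back-transformed and the
    lower edge clipped at zero.
    """
    w = band_half_width(estimate.n, estimate.h, level)
    s = np.sqrt(estimate.values)
    lower = np.maximum(s - w, 0.0) ** 2
    upper = (s + w) ** 2
    return VariabilityBand(estimate=estimate, level=level,
                           half_width_sqrt_scale=w, lower=lower, upper=upper)
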