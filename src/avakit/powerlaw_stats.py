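"""Heavy-tailed model fitting for avalanche sizes and durations.

Implements the standard avalanche-statistics toolkit: logarithmically
binned probability densities, discrete (zeta-normalized) power-law and
discrete exponential (geometric) maximum likelihood, log-likelihood-ratio
model selection with a Vuong-style significance, KS-minimizing slope
estimation, and the sound-level scaling-collapse scan
P(s)*s^|alpha| versus s*L^b.

Sign conventions: alpha is the (negative) power-law slope, e.g. -2.23;
LLR = loglik(power law) - loglik(exponential), so LLR > 0 favors the
power law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import erfc, zeta

from .errors import (
    DegenerateSampleError,
    EmptyTailError,
    InvalidParameterError,
)

__all__ = [
    "BinnedPdf",
    "PowerLawFit",
    "CollapseResult",
    "log_bin_pdf",
    "fit_alpha_ks",
    "fit_models_mle",
    "collapse_scan",
    "discrete_powerlaw_logpmf",
    "discrete_exponential_logpmf",
]

DEFAULT_ALPHA_GRID = np.round(np.arange(-4.0, -1.01 + 1e-9, 0.01), 10)


@dataclass
class BinnedPdf:
    """Log-binned probability density: sum(density * bin width) = 1."""

    bin_edges: np.ndarray  # geometric sequence, len = n_bins + 1
    densities: np.ndarray  # probability per unit of the variable
    counts: np.ndarray
    n_samples: int

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin midpoints."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])


@dataclass
class PowerLawFit:
    """Result of power-law vs exponential model comparison on one sample."""

    alpha_hat: float
    x_min: int = 1
    x_max: int | None = None
    n: int = 0
    loglik_pl: float = float("nan")
    loglik_exp: float = float("nan")
    llr: float = float("nan")
    p_value: float = float("nan")
    ks_distance: float = float("nan")
    exp_rate: float = float("nan")  # fitted geometric decay exp(-rate)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "alpha_hat": self.alpha_hat,
            "x_min": self.x_min,
            "x_max": self.x_max,
            "n": self.n,
            "loglik_pl": self.loglik_pl,
            "loglik_exp": self.loglik_exp,
            "llr": self.llr,
            "p_value": self.p_value,
            "ks_distance": self.ks_distance,
            "notes": list(self.notes),
        }


@dataclass
class CollapseResult:
    """Scaling-collapse scan over the rescaling exponent b."""

    b_hat: float
    b_grid: np.ndarray
    errors: np.ndarray
    per_level_curves: dict  # level -> (log_x at b_hat, log_y)
    degenerate: bool = False


def log_bin_pdf(values: Sequence[float], bins_per_decade: int = 10) -> BinnedPdf:
    """Probability density on geometric bins spanning the observed range.

    Density in a bin is count / (n * bin width), so the density integrates
    to one over the support; empty bins are retained with density zero.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise InvalidParameterError("need at least one value")
    if np.any(v <= 0):
        raise InvalidParameterError("log binning requires strictly positive values")
    if bins_per_decade < 1:
        raise InvalidParameterError("bins_per_decade must be >= 1")

    lo, hi = v.min(), v.max()
    n_bins = max(1, int(np.ceil(np.log10(hi / lo) * bins_per_decade - 1e-12))) if hi > lo else 1
    edges = lo * 10.0 ** (np.arange(n_bins + 1) / bins_per_decade)
    edges[-1] = max(edges[-1], hi * (1 + 1e-12))  # make top edge inclusive

    counts, _ = np.histogram(v, bins=edges)
    widths = np.diff(edges)
    densities = counts / (v.size * widths)
    return BinnedPdf(bin_edges=edges, densities=densities, counts=counts, n_samples=v.size)


def _powerlaw_cdf(u: np.ndarray, alpha: float, x_min: int, x_max: int | None) -> np.ndarray:
    """P(X <= u) of the discrete power law s^alpha on [x_min, x_max]."""
    a = -alpha
    z0 = zeta(a, x_min)
    tail = zeta(a, u + 1.0)
    if x_max is None:
        return 1.0 - tail / z0
    zmax = zeta(a, x_max + 1.0)
    return (z0 - tail) / (z0 - zmax)


def fit_alpha_ks(
    values: Sequence[int],
    alpha_grid: np.ndarray | None = None,
    x_min: int = 1,
    x_max: int | None = None,
) -> PowerLawFit:
    """Slope by KS minimization over a grid of candidate exponents.

    Picks the alpha minimizing the Kolmogorov-Smirnov distance between the
    empirical CDF of values >= x_min and the discrete power-law CDF with
    that slope.  The default grid covers [-4.00, -1.01] in steps of 0.01.
    """
    if alpha_grid is None:
        alpha_grid = DEFAULT_ALPHA_GRID
    alpha_grid = np.asarray(alpha_grid, dtype=np.float64)
    v = np.asarray(values, dtype=np.int64)
    v = v[v >= x_min]
    if v.size == 0:
        raise EmptyTailError(f"no values >= x_min={x_min}")
    if v.size < 50:
        warnings.warn(f"only {v.size} values >= x_min; slope estimate is noisy", stacklevel=2)

    u, counts = np.unique(v, return_counts=True)
    ecdf = np.cumsum(counts) / v.size  # P(X <= u) at each observed value
    # both CDFs are step functions jumping at the same integers, so the KS
    # supremum is attained at observed values (right-continuous comparison)
    best_alpha, best_d = alpha_grid[0], np.inf
    for alpha in alpha_grid:
        tcdf = _powerlaw_cdf(u.astype(np.float64), alpha, x_min, x_max)
        d = float(np.max(np.abs(ecdf - tcdf)))
        if d < best_d:
            best_d, best_alpha = d, alpha
    return PowerLawFit(
        alpha_hat=float(best_alpha),
        x_min=x_min,
        x_max=x_max,
        n=int(v.size),
        ks_distance=float(best_d),
    )


def discrete_powerlaw_logpmf(x: np.ndarray, alpha: float, x_min: int = 1) -> np.ndarray:
    """log P(x) for the zeta-normalized discrete power law on x >= x_min."""
    a = -alpha
    return alpha * np.log(x) - np.log(zeta(a, x_min))


def discrete_exponential_logpmf(x: np.ndarray, rate: float, x_min: int = 1) -> np.ndarray:
    """log P(x) for the geometric law P(x) = (1-q) q^(x-x_min), q = exp(-rate)."""
    q = np.exp(-rate)
    return np.log1p(-q) - rate * (np.asarray(x, dtype=np.float64) - x_min)


def fit_models_mle(values: Sequence[int], x_min: int = 1) -> PowerLawFit:
    """Discrete power-law and exponential MLE with LLR model selection.

    Power law: numerical maximization of the zeta-normalized likelihood.
    Exponential: geometric MLE, closed form from the sample mean.
    LLR = loglik_pl - loglik_exp (> 0 favors the power law); its
    significance is a Vuong-style two-sided normal test on the normalized
    per-observation log-likelihood differences.
    """
    v = np.asarray(values, dtype=np.int64)
    v = v[v >= x_min]
    if v.size < 2:
        raise EmptyTailError(f"need >= 2 values >= x_min={x_min}")
    if np.all(v == v[0]):
        raise DegenerateSampleError("all values equal; LLR undefined")

    logx_sum = np.log(v).sum()
    n = v.size

    def negll(a: float) -> float:
        return a * logx_sum + n * np.log(zeta(a, x_min))

    res = minimize_scalar(negll, bounds=(1.000001, 25.0), method="bounded",
                          options={"xatol": 1e-7})
    a_hat = float(res.x)
    ll_pl_i = discrete_powerlaw_logpmf(v.astype(np.float64), -a_hat, x_min)

    m = float(v.mean() - x_min)
    q = m / (1.0 + m)  # geometric MLE on shifted support
    rate = -np.log(q) if q > 0 else np.inf
    ll_exp_i = discrete_exponential_logpmf(v, rate, x_min)

    d = ll_pl_i - ll_exp_i
    loglik_pl = float(ll_pl_i.sum())
    loglik_exp = float(ll_exp_i.sum())
    llr = loglik_pl - loglik_exp  # exactly the stored difference
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        p = 1.0
    else:
        z = llr / (sd * np.sqrt(n))
        p = float(erfc(abs(z) / np.sqrt(2.0)))

    u = np.unique(v).astype(np.float64)
    ecdf = np.searchsorted(np.sort(v), u, side="right") / n
    ks = float(np.max(np.abs(ecdf - _powerlaw_cdf(u, -a_hat, x_min, None))))

    return PowerLawFit(
        alpha_hat=-a_hat,
        x_min=x_min,
        n=n,
        loglik_pl=loglik_pl,
        loglik_exp=loglik_exp,
        llr=llr,
        p_value=p,
        ks_distance=ks,
        exp_rate=float(rate),
    )


def _curve(
    values: np.ndarray, alpha: float, bins_per_decade: int, min_count: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log10 s, log10 P(s)*s^|alpha|, counts) at sufficiently occupied bins."""
    pdf = log_bin_pdf(values, bins_per_decade)
    c = pdf.centers
    keep = pdf.counts >= max(1, min_count)
    y = pdf.densities[keep] * c[keep] ** (-alpha)
    return np.log10(c[keep]), np.log10(y), pdf.counts[keep].astype(np.float64)


def collapse_scan(
    values_by_level: Mapping[float, Sequence[float]],
    alpha: float,
    b_grid: tuple[float, float, float] = (-0.5, 0.5, 0.001),
    bins_per_decade: int = 10,
    n_interp: int = 50,
    min_count: int = 5,
    offset_invariant: bool = True,
) -> CollapseResult:
    """Scan the rescaling exponent b for P(s)*s^|alpha| vs s*L^b collapse.

    For each b on the grid, every level's log-binned compensated density is
    shifted in log-x by b*log10(L), linearly interpolated onto the common
    overlapping log-x support, and scored by the mean over level pairs of
    the squared difference of log-densities.  Two numerical safeguards make
    the minimum well identified: bins with fewer than ``min_count``
    observations are excluded, and each grid point is weighted by the
    inverse sampling variance of the log-density difference (the harmonic
    mean of the two bins' counts), so poorly measured tail bins cannot
    dominate the score.  With ``offset_invariant=True`` (default) each
    pair's constant vertical offset is removed first — a pure rescaling
    s -> s*L^b shifts compensated curves by a constant log-offset, so the
    score then measures shape mismatch only.  b_hat is the grid argmin
    (ties go to the b closest to zero).  A single level is degenerate:
    b_hat = 0.
    """
    lo, hi, step = b_grid
    if lo > hi or step <= 0:
        raise InvalidParameterError("b_grid must be (lo, hi, step) with lo <= hi, step > 0")
    grid = np.round(np.arange(lo, hi + step / 2, step), 9)

    levels = sorted(values_by_level)
    curves = {
        L: _curve(
            np.asarray(values_by_level[L], dtype=np.float64),
            alpha, bins_per_decade, min_count,
        )
        for L in levels
    }
    if len(levels) < 2:
        L = levels[0]
        return CollapseResult(
            b_hat=0.0, b_grid=grid, errors=np.zeros_like(grid),
            per_level_curves={L: curves[L][:2]}, degenerate=True,
        )

    logL = {L: np.log10(L) for L in levels}
    errors = np.empty(grid.size)
    for k, b in enumerate(grid):
        shifted = {
            L: (curves[L][0] + b * logL[L], curves[L][1], curves[L][2]) for L in levels
        }
        x_lo = max(s[0][0] for s in shifted.values())
        x_hi = min(s[0][-1] for s in shifted.values())
        if x_hi <= x_lo:
            errors[k] = np.inf
            continue
        xs = np.linspace(x_lo, x_hi, n_interp)
        ys = [np.interp(xs, shifted[L][0], shifted[L][1]) for L in levels]
        cs = [np.interp(xs, shifted[L][0], shifted[L][2]) for L in levels]
        err = 0.0
        n_pairs = 0
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                diff = ys[i] - ys[j]
                w = 1.0 / (1.0 / cs[i] + 1.0 / cs[j])
                if offset_invariant:
                    diff = diff - np.average(diff, weights=w)
                err += float(np.average(diff**2, weights=w))
                n_pairs += 1
        errors[k] = err / n_pairs

    finite = np.isfinite(errors)
    if not finite.any():
        raise InvalidParameterError("no b on the grid gives overlapping supports")
    min_err = errors[finite].min()
    candidates = np.flatnonzero(np.isclose(errors, min_err, rtol=0, atol=1e-15))
    b_hat = float(grid[candidates[np.argmin(np.abs(grid[candidates]))]])

    per_level = {
        L: (curves[L][0] + b_hat * logL[L], curves[L][1]) for L in levels
    }
    return CollapseResult(
        b_hat=b_hat, b_grid=grid, errors=errors, per_level_curves=per_level,
    )
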