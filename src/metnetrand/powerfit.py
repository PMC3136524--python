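"""Discrete power-law maximum-likelihood fitting and logarithmic binning.

The tail model is P(k) = k^-gamma / zeta(gamma, k_min) for integer
k >= k_min (Hurwitz-zeta normalization).  gamma is estimated by direct
maximization of the log-likelihood

    l(gamma) = -gamma * sum(ln k_i) - n_tail * ln zeta(gamma, k_min)

rather than by regression on binned data; k_min is either fixed or
chosen by scanning observed degrees for the minimal Kolmogorov-Smirnov
distance between the empirical and fitted tail CDFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import zeta

logger = logging.getLogger(__name__)

GAMMA_LO, GAMMA_HI = 1.01, 6.0
MIN_TAIL_POINTS = 10


class PowerFitError(ValueError):
    pass


@dataclass
class PowerLawFit:
    gamma: float
    k_min: int
    n_tail: int
    ks: float

    def loglik(self, degrees) -> float:
        k = _tail(np.asarray(degrees), self.k_min)
        return _loglik(self.gamma, k, self.k_min)


def _tail(degrees: np.ndarray, k_min: int) -> np.ndarray:
    return degrees[degrees >= k_min]


def _loglik(gamma: float, tail: np.ndarray, k_min: int) -> float:
    return -gamma * np.log(tail).sum() - len(tail) * np.log(zeta(gamma, k_min))


def _mle_gamma(tail: np.ndarray, k_min: int) -> float:
    res = minimize_scalar(
        lambda g: -_loglik(g, tail, k_min),
        bounds=(GAMMA_LO, GAMMA_HI),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def _ks_distance(tail: np.ndarray, k_min: int, gamma: float) -> float:
    ks, counts = np.unique(tail, return_counts=True)
    emp_cdf = np.cumsum(counts) / len(tail)
    z = zeta(gamma, k_min)
    # model CDF at k: 1 - zeta(gamma, k+1)/zeta(gamma, k_min)
    model_cdf = 1.0 - zeta(gamma, ks + 1.0) / z
    return float(np.max(np.abs(emp_cdf - model_cdf)))


def approximate_gamma(degrees, k_min: int) -> float:
    """Closed-form continuous approximation 1 + n / sum(ln(k_i/(k_min - 1/2))).

    Accurate for k_min of about 6 and above; used as an independent
    cross-check of the exact discrete MLE.
    """
    tail = _tail(np.asarray(degrees, dtype=float), k_min)
    return 1.0 + len(tail) / np.log(tail / (k_min - 0.5)).sum()


def fit_discrete_power_law(degrees, k_min: int | None = None) -> PowerLawFit:
    """MLE power-law fit of a degree tail.

    ``k_min=None`` scans every observed degree >= 2 that leaves at least
    ``MIN_TAIL_POINTS`` tail points and keeps the k_min of minimal KS
    distance (ties toward smaller k_min, i.e. the larger tail).
    """
    degrees = np.asarray(degrees)
    if degrees.size == 0:
        raise PowerFitError("empty degree sample")
    if not np.issubdtype(degrees.dtype, np.integer):
        as_int = degrees.astype(int)
        if not np.all(as_int == degrees):
            raise PowerFitError("degrees must be positive integers")
        degrees = as_int
    if np.any(degrees < 1):
        raise PowerFitError("degrees must be >= 1")

    if k_min is not None:
        tail = _tail(degrees, k_min)
        if len(tail) < MIN_TAIL_POINTS:
            raise PowerFitError(f"only {len(tail)} tail points at k_min={k_min}")
        gamma = _mle_gamma(tail, k_min)
        return PowerLawFit(gamma, int(k_min), len(tail), _ks_distance(tail, k_min, gamma))

    candidates = [int(k) for k in np.unique(degrees) if k >= 2 and (degrees >= k).sum() >= MIN_TAIL_POINTS]
    if not candidates:
        raise PowerFitError("no k_min candidate leaves enough tail points")
    best = None
    for km in candidates:
        tail = _tail(degrees, km)
        gamma = _mle_gamma(tail, km)
        ks = _ks_distance(tail, km, gamma)
        if best is None or ks < best.ks:  # strict: ties keep smaller k_min
            best = PowerLawFit(gamma, km, len(tail), ks)
    logger.debug("KS scan selected k_min=%d (ks=%.4f, gamma=%.3f)", best.k_min, best.ks, best.gamma)
    return best


def sample_power_law(gamma: float, k_min: int, n: int, rng=None) -> np.ndarray:
    """Draw n degrees from the discrete power law by inverse-CDF lookup."""
    rng = np.random.default_rng(rng)
    z = zeta(gamma, k_min)
    # CDF table out to where the remaining tail mass is negligible vs 1/n
    k_hi = 4 * k_min
    while zeta(gamma, k_hi + 1.0) / z > 1e-3 / n:
        k_hi *= 4
    ks = np.arange(k_min, k_hi + 1)
    cdf = 1.0 - zeta(gamma, ks + 1.0) / z
    u = rng.random(n)
    idx = np.minimum(np.searchsorted(cdf, u, side="left"), len(ks) - 1)
    return ks[idx]


def log_bin(degrees, bin_ratio: float = 2.0) -> pd.DataFrame:
    """Multiplicative binning of a degree sample for log-log display.

    Bins are [k0 r^j, k0 r^{j+1}) starting at the smallest degree;
    density = count / bin width, so sum(density * width) equals n exactly.
    """
    degrees = np.asarray(degrees, dtype=float)
    if degrees.size == 0:
        raise PowerFitError("empty degree sample")
    if bin_ratio <= 1:
        raise PowerFitError("bin_ratio must exceed 1")
    k0 = degrees.min()
    n_bins = max(1, int(np.ceil(np.log(degrees.max() / k0) / np.log(bin_ratio))) + 1)
    edges = k0 * bin_ratio ** np.arange(n_bins + 1)
    counts, _ = np.histogram(degrees, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    df = pd.DataFrame({
        "bin_center": centers,
        "bin_lo": edges[:-1],
        "bin_hi": edges[1:],
        "count": counts,
        "density": counts / widths,
    })
    return df[df["count"] > 0].reset_index(drop=True)
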