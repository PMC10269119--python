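"""Diel activity analysis on the 24-h circle.

Detection clock times are mapped to angles on [0, 2*pi) (0 = local
midnight), each species' activity density is estimated with a von Mises
kernel whose concentration follows the data-driven MISE-optimal rule
(maximum-likelihood concentration plugged into the asymptotic formula),
and pairwise activity overlap is summarised by the coefficient of
overlapping Delta = integral of min(f, g), estimated by Delta_1 (grid
integration), Delta_4 (bounded density ratios at the observed points) or
Delta_5 (empirical crossing probabilities), selected by sample size.
Confidence intervals come from a seeded smoothed bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ive

TWO_PI = 2.0 * np.pi
#: kernels sharper than this are indistinguishable from a point mass at the
#: default grid resolution; larger requested concentrations are capped.
KAPPA_MAX = 2000.0
ESTIMATORS = ("Dhat1", "Dhat4", "Dhat5")
#: default bandwidth adjustment per estimator (extra smoothing for the
#: grid-based estimator at small samples).
DEFAULT_ADJUST = {"Dhat1": 0.8, "Dhat4": 1.0, "Dhat5": 1.0}


@dataclass
class CircularSample:
    """Event times as angles on the diel circle."""

    times: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("circular sample must be one-dimensional")
        if np.any(self.times < 0) or np.any(self.times >= TWO_PI):
            raise ValueError("angles must lie in [0, 2*pi); use from_* constructors")

    @property
    def n(self) -> int:
        return self.times.size

    @classmethod
    def from_hours(cls, hours, label: str = "") -> "CircularSample":
        return cls((np.asarray(hours, float) % 24.0) / 24.0 * TWO_PI, label)

    @classmethod
    def from_timestamps(cls, timestamps, label: str = "") -> "CircularSample":
        ts = pd.to_datetime(pd.Series(list(timestamps)))
        return cls(np.array([to_radians(t) for t in ts]), label)


@dataclass
class DensityEstimate:
    """Von Mises kernel density on an equally spaced angular grid."""

    grid: np.ndarray
    values: np.ndarray
    kappa: float

    def integral(self) -> float:
        g = np.append(self.grid, TWO_PI)
        v = np.append(self.values, self.values[0])  # periodic closure
        return float(np.trapezoid(v, g))


def to_radians(timestamp) -> float:
    """Clock time -> angle: 2*pi * (seconds since local midnight) / 86400."""
    t = pd.Timestamp(timestamp)
    secs = t.hour * 3600 + t.minute * 60 + t.second
    return TWO_PI * secs / 86400.0


def records_to_sample(records: pd.DataFrame, species: str | Sequence[str], label=None):
    """Extract the diel angles of one species (or a list) from a record table."""
    names = [species] if isinstance(species, str) else list(species)
    sub = records[records["species"].isin(names)]
    lab = label if label is not None else "+".join(names)
    return CircularSample.from_timestamps(sub["timestamp"], label=lab)


def vonmises_kappa_mle(times: np.ndarray) -> float:
    """Maximum-likelihood von Mises concentration from the mean resultant
    length (solves I1(k)/I0(k) = Rbar)."""
    times = np.asarray(times, float)
    if times.size < 2:
        raise ValueError("need at least two observations")
    rbar = float(np.hypot(np.cos(times).mean(), np.sin(times).mean()))
    if rbar >= 1 - 1e-10:
        raise ValueError(
            "degenerate sample (all angles identical); supply a minimum "
            "concentration override instead of the ML rule"
        )
    if rbar < 1e-12:
        return 1e-8
    f = lambda k: ive(1, k) / ive(0, k) - rbar
    return float(brentq(f, 1e-10, 1e8, xtol=1e-12, rtol=1e-12))


def bandwidth_concentration(sample: CircularSample, adjust: float = 1.0) -> float:
    """Data-driven kernel concentration for circular density estimation.

    The ML concentration estimate kappa_hat is plugged into the asymptotic
    MISE-optimal smoothing rule

        kappa* = ( 3 n kappa_hat^2 I2(2 kappa_hat) /
                   (4 sqrt(pi) I0(kappa_hat)^2) )^(2/5),

    then multiplied by ``adjust``.  Bessel ratios are computed on the
    exponentially scaled form, so the rule is stable for sharp samples.
    """
    if adjust <= 0:
        raise ValueError("adjust must be positive")
    k = vonmises_kappa_mle(sample.times)
    # I2(2k)/I0(k)^2 = ive(2,2k)/ive(0,k)^2 (the e^{2k} factors cancel)
    ratio = ive(2, 2 * k) / ive(0, k) ** 2
    kappa_star = (3 * sample.n * k**2 * ratio / (4 * np.sqrt(np.pi))) ** 0.4
    return float(adjust * kappa_star)


def _vm_density_at(points: np.ndarray, data: np.ndarray, kappa: float) -> np.ndarray:
    """Kernel density evaluated at arbitrary angles (overflow-safe)."""
    if kappa > KAPPA_MAX:
        warnings.warn(
            f"kernel concentration {kappa:.3g} capped at {KAPPA_MAX:g}", stacklevel=2
        )
        kappa = KAPPA_MAX
    diff = points[:, None] - data[None, :]
    kern = np.exp(kappa * (np.cos(diff) - 1.0))
    return kern.mean(axis=1) / (TWO_PI * ive(0, kappa))


def kde_vonmises(sample: CircularSample, kappa: float, T: int = 512) -> DensityEstimate:
    """Von Mises kernel density of a sample on a T-point grid over [0, 2*pi)."""
    if kappa <= 0:
        raise ValueError("kernel concentration must be positive")
    if T < 64:
        raise ValueError("grid size must be at least 64")
    grid = np.linspace(0.0, TWO_PI, T, endpoint=False)
    return DensityEstimate(grid, _vm_density_at(grid, sample.times, min(kappa, KAPPA_MAX)), kappa)


def select_estimator(n1: int, n2: int) -> str:
    """Sample-size rule for the overlap estimator: Delta_4 above 75
    observations, Delta_5 between 50 and 75, otherwise Delta_1 with a
    warning (below the range the estimators were recommended for)."""
    m = min(n1, n2)
    if m > 75:
        return "Dhat4"
    if m > 50:
        return "Dhat5"
    warnings.warn(
        f"smallest sample has {m} observations (< 50); falling back to the "
        "grid estimator Dhat1",
        stacklevel=2,
    )
    return "Dhat1"


def overlap_delta(
    s1: CircularSample,
    s2: CircularSample,
    estimator: str = "Dhat1",
    T: int = 512,
    adjust: float | None = None,
) -> float:
    """Coefficient of overlapping Delta = integral of min(f, g) in [0, 1].

    Delta_1 integrates min of the two kernel densities on the grid;
    Delta_4 averages the bounded density ratios min{1, g/f} over the
    observed points of each sample; Delta_5 uses the empirical
    probabilities that one density lies below the other at the observed
    points.  The result is clamped to [0, 1].
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; expected one of {ESTIMATORS}")
    if s1.n < 2 or s2.n < 2:
        raise ValueError("overlap needs at least two observations per sample")
    adj = DEFAULT_ADJUST[estimator] if adjust is None else adjust
    k1 = min(bandwidth_concentration(s1, adj), KAPPA_MAX)
    k2 = min(bandwidth_concentration(s2, adj), KAPPA_MAX)
    if estimator == "Dhat1":
        grid = np.linspace(0.0, TWO_PI, T, endpoint=False)
        f = _vm_density_at(grid, s1.times, k1)
        g = _vm_density_at(grid, s2.times, k2)
        delta = (TWO_PI / T) * np.minimum(f, g).sum()
    else:
        f_at_x = _vm_density_at(s1.times, s1.times, k1)
        g_at_x = _vm_density_at(s1.times, s2.times, k2)
        f_at_y = _vm_density_at(s2.times, s1.times, k1)
        g_at_y = _vm_density_at(s2.times, s2.times, k2)
        if estimator == "Dhat4":
            delta = 0.5 * (
                np.minimum(1.0, g_at_x / f_at_x).mean()
                + np.minimum(1.0, f_at_y / g_at_y).mean()
            )
        else:  # Dhat5: Delta = P_f(f <= g) + P_g(g < f), estimated empirically
            delta = (f_at_x <= g_at_x).mean() + (g_at_y < f_at_y).mean()
    return float(np.clip(delta, 0.0, 1.0))


def classify_overlap(delta: float) -> str:
    """Categorical reading of Delta: low (< 0.5), moderate (0.5-0.75),
    high (> 0.75); boundaries belong to 'moderate'."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("Delta must lie in [0, 1]")
    if delta < 0.5:
        return "low"
    if delta <= 0.75:
        return "moderate"
    return "high"


@dataclass
class OverlapResult:
    """Overlap point estimate with bootstrap percentile interval."""

    delta: float
    estimator: str
    ci_low: float
    ci_high: float
    B: int
    classification: str
    seed: int
    n1: int
    n2: int
    label1: str = ""
    label2: str = ""


def bootstrap_overlap_ci(
    s1: CircularSample,
    s2: CircularSample,
    estimator: str | None = None,
    B: int = 1000,
    seed: int = 0,
    method: str = "smoothed",
    interval: str = "basic",
    T: int = 512,
    adjust: float | None = None,
) -> OverlapResult:
    """Seeded bootstrap 95% interval for Delta.

    The default ``smoothed`` method resamples each group from its fitted
    kernel density (a resampled data point plus von Mises kernel noise);
    ``method='resample'`` is a plain nonparametric bootstrap.  Kernel
    concentrations are re-estimated on every resample.  The same seed
    always yields the identical result.

    ``interval='basic'`` (default) recenters the bootstrap quantiles
    around the point estimate (2*Delta_hat - q), which corrects the
    upward small-sample bias the overlap estimators inherit from kernel
    smoothing; ``interval='percentile'`` reports the raw bootstrap
    quantiles.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for a usable bootstrap interval")
    if method not in ("smoothed", "resample"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    if interval not in ("basic", "percentile"):
        raise ValueError(f"unknown interval type {interval!r}")
    est = select_estimator(s1.n, s2.n) if estimator is None else estimator
    point = overlap_delta(s1, s2, est, T=T, adjust=adjust)
    adj = DEFAULT_ADJUST[est] if adjust is None else adjust
    kappas = [min(bandwidth_concentration(s, adj), KAPPA_MAX) for s in (s1, s2)]

    rng = np.random.default_rng(seed)
    deltas = np.empty(B)
    for b in range(B):
        resamples = []
        for s, kap in zip((s1, s2), kappas):
            x = s.times[rng.integers(0, s.n, s.n)]
            if method == "smoothed":
                x = (x + rng.vonmises(0.0, kap, s.n)) % TWO_PI
            resamples.append(CircularSample(x, s.label))
        try:
            deltas[b] = overlap_delta(resamples[0], resamples[1], est, T=T, adjust=adjust)
        except ValueError:  # degenerate resample (all angles equal)
            deltas[b] = np.nan
    qlo, qhi = np.nanpercentile(deltas, [2.5, 97.5])
    if interval == "basic":
        lo, hi = 2 * point - qhi, 2 * point - qlo
    else:
        lo, hi = qlo, qhi
    return OverlapResult(
        delta=point,
        estimator=est,
        ci_low=float(np.clip(lo, 0.0, 1.0)),
        ci_high=float(np.clip(hi, 0.0, 1.0)),
        B=B,
        classification=classify_overlap(point),
        seed=seed,
        n1=s1.n,
        n2=s2.n,
        label1=s1.label,
        label2=s2.label,
    )


def density_grid_frame(
    s1: CircularSample, s2: CircularSample, adjust: float = 1.0, T: int = 512
) -> pd.DataFrame:
    """Plot-ready table: angle, the two densities and their pointwise min."""
    k1 = min(bandwidth_concentration(s1, adjust), KAPPA_MAX)
    k2 = min(bandwidth_concentration(s2, adjust), KAPPA_MAX)
    grid = np.linspace(0.0, TWO_PI, T, endpoint=False)
    f = _vm_density_at(grid, s1.times, k1)
    g = _vm_density_at(grid, s2.times, k2)
    return pd.DataFrame(
        {
            "angle": grid,
            "hour": grid / TWO_PI * 24.0,
            f"density_{s1.label or 'a'}": f,
            f"density_{s2.label or 'b'}": g,
            "density_min": np.minimum(f, g),
        }
    )
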