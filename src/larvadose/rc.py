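"""Reverberation-chamber characterization from multi-position S11 sweeps.

A mode-stirred reverberation chamber is "well stirred" at a frequency when
the stirrer-position ensemble of the reflection coefficient behaves like a
circular complex Gaussian: the magnitude of the stirred component
``S11_st = S11 - <S11>`` is then Rayleigh distributed and successive stirrer
positions are uncorrelated.  This module implements the three statistics used
to decide that — an Anderson-Darling goodness-of-fit test against the
Rayleigh distribution with maximum-likelihood scale, the lag-1
autocorrelation of ``|S11_st|`` over stirrer positions, and the coefficient
of variation sigma/mu (0.523 for an ideal Rayleigh ensemble) — together with
the Weyl cavity mode-count estimate used to predict the lowest usable
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import AD_THRESHOLD, C0, R1_THRESHOLDS, RAYLEIGH_CV

__all__ = [
    "S11Sweep",
    "StirredSweep",
    "ADTestResult",
    "Lag1Result",
    "CVSeries",
    "CavityGeometry",
    "UniformityReport",
    "stirred_component",
    "subset_positions",
    "rayleigh_ad_test",
    "lag1_autocorrelation",
    "cv_series",
    "mode_count",
    "theoretical_luf",
    "characterize",
    "ad_statistic_rayleigh",
    "monte_carlo_a2m_percentile",
    "r1_threshold",
]

_F_CLAMP = 1e-12  # keep CDF values away from {0, 1} before taking logs


@dataclass
class S11Sweep:
    """Complex one-port reflection coefficients, frequency x stirrer position.

    Parameters
    ----------
    frequencies : array of float
        Strictly increasing frequencies [Hz].
    positions : list of (int, int)
        Stirrer-position labels as (stirrer-1 angle index, stirrer-2 angle
        index) pairs.
    values : complex array, shape (n_positions, n_frequencies)
        Linear (not dB) complex reflection coefficients.
    """

    frequencies: np.ndarray
    positions: list[tuple[int, int]]
    values: np.ndarray

    #: tolerance on |S11| <= 1 for a passive one-port
    passivity_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        self.positions = [tuple(p) for p in self.positions]
        if self.frequencies.ndim != 1 or len(self.frequencies) < 1:
            raise ValueError("frequencies must be a 1-D non-empty array")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.values.shape != (len(self.positions), len(self.frequencies)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.positions)}, {len(self.frequencies)})"
            )
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("values must be finite")
        if np.any(np.abs(self.values) > 1.0 + self.passivity_tol):
            raise ValueError("|S11| exceeds 1: not a passive one-port")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def stirrer_grid(self) -> tuple[list[int], list[int]]:
        """Sorted unique angle indices of each stirrer."""
        s1 = sorted({p[0] for p in self.positions})
        s2 = sorted({p[1] for p in self.positions})
        return s1, s2


@dataclass
class StirredSweep:
    """Stirred components ``S11_st = S11 - <S11>`` with zero position-mean."""

    frequencies: np.ndarray
    positions: list[tuple[int, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        resid = np.abs(self.values.mean(axis=0))
        scale = np.abs(self.values).max() if self.values.size else 1.0
        if np.any(resid > 1e-9 * max(scale, 1.0)):
            raise ValueError("stirred values must average to zero per frequency")

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class ADTestResult:
    """Anderson-Darling test of Rayleigh fit with ML-estimated scale."""

    a2: float
    a2m: float
    n: int
    scale: float
    threshold: float = AD_THRESHOLD
    estimator: str = "ml"

    @property
    def rayleigh_compatible(self) -> bool:
        """True when the sample is compatible with a Rayleigh distribution.

        Standard AD convention: large statistics reject the hypothesized
        distribution, so compatibility means ``a2m <= threshold``.
        """
        return self.a2m <= self.threshold


@dataclass
class Lag1Result:
    """First-order autocorrelation of the position series."""

    r1: float
    n: int
    threshold: float

    @property
    def independent(self) -> bool:
        return self.r1 < self.threshold


@dataclass
class CVSeries:
    """Per-frequency coefficient of variation of |S11_st| with its band interval."""

    frequencies: np.ndarray
    cv: np.ndarray
    cutoff_frequency: float
    interval_lo: float
    interval_hi: float


@dataclass
class CavityGeometry:
    """Interior dimensions of a rectangular cavity [m]."""

    a: float
    b: float
    d: float
    c0: float = C0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.d) <= 0:
            raise ValueError("cavity dimensions must be positive")


@dataclass
class UniformityReport:
    """Well-stirred verdict with the per-frequency statistics behind it."""

    frequencies: np.ndarray
    a2m: np.ndarray
    r1: np.ndarray
    cv: np.ndarray
    a2m_smooth: np.ndarray
    r1_smooth: np.ndarray
    cv_smooth: np.ndarray
    a2m_poly: np.ndarray  # polynomial coefficients (numpy order)
    r1_poly: np.ndarray
    ad_threshold: float
    r1_threshold: float
    cv_interval: tuple[float, float]
    cv_cutoff: float
    configuration: str
    n_positions: int
    target_frequency: float
    usable_band: list[tuple[float, float]] = field(default_factory=list)
    verdict: bool = False

    def to_dict(self) -> dict:
        return {
            "configuration": self.configuration,
            "n_positions": self.n_positions,
            "target_frequency_hz": self.target_frequency,
            "verdict": bool(self.verdict),
            "ad_threshold": self.ad_threshold,
            "r1_threshold": self.r1_threshold,
            "cv_cutoff_hz": self.cv_cutoff,
            "cv_interval": list(self.cv_interval),
            "usable_band_hz": [list(b) for b in self.usable_band],
        }


def stirred_component(sweep: S11Sweep) -> StirredSweep:
    """Subtract the complex position-mean per frequency.

    The subtraction is done on complex linear S11 so that the residual is the
    circularly-distributed stirred field; magnitudes are taken only
    afterwards.
    """
    if sweep.n_positions < 2:
        raise ValueError("need at least 2 stirrer positions for a stirred ensemble")
    stirred = sweep.values - sweep.values.mean(axis=0, keepdims=True)
    return StirredSweep(sweep.frequencies, sweep.positions, stirred)


def subset_positions(sweep: S11Sweep, n1: int, n2: int) -> S11Sweep:
    """Take an n1 x n2 sub-grid of stirrer positions with uniformly spaced angles.

    Deterministic: angle indices start at 0 and stride by (available / n).
    """
    s1, s2 = sweep.stirrer_grid()
    if n1 <= 0 or n2 <= 0:
        raise ValueError("subset counts must be positive")
    if len(s1) % n1 or len(s2) % n2:
        raise ValueError(
            f"requested {n1}x{n2} does not divide available {len(s1)}x{len(s2)}"
        )
    keep1 = set(s1[:: len(s1) // n1])
    keep2 = set(s2[:: len(s2) // n2])
    idx = [
        i
        for i, (p1, p2) in enumerate(sweep.positions)
        if p1 in keep1 and p2 in keep2
    ]
    return S11Sweep(
        sweep.frequencies,
        [sweep.positions[i] for i in idx],
        sweep.values[idx],
    )


def ad_statistic_rayleigh(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized AD statistic against Rayleigh with ML scale, last axis = sample.

    Returns ``(a2, scale)`` where ``a2`` has the leading shape of *samples*.
    """
    x = np.asarray(samples, dtype=float)
    n = x.shape[-1]
    scale2 = (x**2).sum(axis=-1) / (2.0 * n)  # ML sigma^2
    xs = np.sort(x, axis=-1)
    f = 1.0 - np.exp(-(xs**2) / (2.0 * scale2[..., None]))
    f = np.clip(f, _F_CLAMP, 1.0 - _F_CLAMP)
    i = np.arange(1, n + 1)
    a2 = -n - ((2 * i - 1) * (np.log(f) + np.log(1.0 - f[..., ::-1]))).sum(axis=-1) / n
    return a2, np.sqrt(scale2)


def rayleigh_ad_test(samples, threshold: float = AD_THRESHOLD) -> ADTestResult:
    """Anderson-Darling goodness-of-fit of a Rayleigh distribution.

    The Rayleigh scale is estimated by maximum likelihood,
    ``sigma_hat = sqrt(sum(x^2) / (2 N))``, the AD statistic is computed on
    the ordered sample, and the small-sample modification
    ``A2m = A2 * (1 + 0.6/N)`` is applied before comparing with *threshold*
    (1.341, the 5% point of the estimated-scale table).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("need a 1-D sample of at least 4 values")
    if np.any(x <= 0):
        raise ValueError("Rayleigh samples must be strictly positive")
    a2, scale = ad_statistic_rayleigh(x)
    n = len(x)
    a2m = float(a2) * (1.0 + 0.6 / n)
    return ADTestResult(a2=float(a2), a2m=a2m, n=n, scale=float(scale), threshold=threshold)


def monte_carlo_a2m_percentile(
    n: int = 64,
    reps: int = 50_000,
    q: float = 95.0,
    seed: int | None = 0,
) -> float:
    """Monte-Carlo percentile of A2m under the Rayleigh null with ML scale."""
    rng = np.random.default_rng(seed)
    draws = rng.rayleigh(scale=1.0, size=(reps, n))
    a2, _ = ad_statistic_rayleigh(draws)
    a2m = a2 * (1.0 + 0.6 / n)
    return float(np.percentile(a2m, q))


def r1_threshold(n: int) -> float:
    """t2 threshold for the lag-1 autocorrelation at N stirrer positions.

    Tabulated values for N in {8, 64, 256}; otherwise the 1.96/sqrt(N)
    normal approximation (matches 0.123 at N = 256).
    """
    return R1_THRESHOLDS.get(n, 1.96 / np.sqrt(n))


def lag1_autocorrelation(
    samples,
    threshold: float | None = None,
    circular: bool = True,
) -> Lag1Result:
    """First-order autocorrelation r(1) of the stirrer-position series.

    The summation runs over k = 1..N with circular indexing
    ``x(N+1) = x(1)`` (the default); ``circular=False`` gives the
    conventional k <= N-1 variant.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D series of at least 2 values")
    n = len(x)
    d = x - x.mean()
    denom = (d**2).sum()
    if denom == 0:
        raise ValueError("constant series: autocorrelation undefined")
    if circular:
        num = (d * np.roll(d, -1)).sum()
    else:
        num = (d[:-1] * d[1:]).sum()
    thr = r1_threshold(n) if threshold is None else threshold
    return Lag1Result(r1=float(num / denom), n=n, threshold=thr)


def cv_series(stirred: StirredSweep, cutoff: float = 3.6e9) -> CVSeries:
    """Coefficient of variation sd/mean of |S11_st| over positions per frequency.

    The band summary interval is mean(CV) +/- 2 sd(CV) over frequencies at or
    above *cutoff*; for an ideal Rayleigh ensemble CV -> sqrt(4/pi - 1) =
    0.523.
    """
    mags = stirred.magnitudes
    if mags.shape[0] < 2:
        raise ValueError("need at least 2 positions per frequency")
    mean = mags.mean(axis=0)
    if np.any(mean == 0):
        raise ValueError("zero mean magnitude at some frequency")
    cv = mags.std(axis=0, ddof=1) / mean
    band = cv[stirred.frequencies >= cutoff]
    if band.size == 0:
        band = cv
    lo = float(band.mean() - 2.0 * band.std(ddof=1 if band.size > 1 else 0))
    hi = float(band.mean() + 2.0 * band.std(ddof=1 if band.size > 1 else 0))
    return CVSeries(
        frequencies=stirred.frequencies,
        cv=cv,
        cutoff_frequency=cutoff,
        interval_lo=lo,
        interval_hi=hi,
    )


def mode_count(geom: CavityGeometry, f) -> np.ndarray | float:
    """Smooth Weyl estimate of the cumulative cavity mode count below f.

    ``N(f) = (8 pi / 3) a b d (f/c)^3 - (a + b + d)(f/c) + 1/2``, monotone
    nondecreasing over the usable range.
    """
    fr = np.asarray(f, dtype=float)
    if np.any(fr <= 0):
        raise ValueError("frequency must be positive")
    k = fr / geom.c0
    n = (8.0 * np.pi / 3.0) * geom.a * geom.b * geom.d * k**3 - (geom.a + geom.b + geom.d) * k + 0.5
    return float(n) if np.isscalar(f) or np.ndim(f) == 0 else n


def theoretical_luf(geom: CavityGeometry, n_modes: float = 100.0) -> float:
    """Lowest usable frequency: root of mode_count(f) = n_modes [Hz].

    Bracketing root-find to better than 1 MHz; ~100 modes is the usual
    well-stirred operating criterion.
    """
    if n_modes <= 0:
        raise ValueError("n_modes must be positive")
    lo, hi = 1e6, 1e12
    while mode_count(geom, hi) < n_modes:
        hi *= 2
    return float(optimize.brentq(lambda f: mode_count(geom, f) - n_modes, lo, hi, xtol=1e5))


def _moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    w = min(window, len(x))
    kernel = np.ones(w) / w
    # centered moving mean with edge shrinkage
    num = np.convolve(x, kernel, mode="same")
    norm = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / norm


def _bands_from_mask(freqs: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    bands = []
    start = None
    for f, ok in zip(freqs, mask):
        if ok and start is None:
            start = f
        elif not ok and start is not None:
            bands.append((start, prev))
            start = None
        prev = f
    if start is not None:
        bands.append((start, freqs[-1]))
    return bands


def characterize(
    sweep: S11Sweep,
    target: float,
    subset: tuple[int, int] | None = None,
    ad_threshold: float = AD_THRESHOLD,
    r1_thresh: float | None = None,
    cv_cutoff: float = 3.6e9,
    a2m_poly_order: int = 8,
    r1_poly_order: int = 6,
    cv_window: int = 100,
) -> UniformityReport:
    """Full well-stirred characterization of a chamber at a target frequency.

    Computes the stirred component, then per frequency the modified AD
    statistic, lag-1 autocorrelation and CV of |S11_st|; smooths A2m and r(1)
    with least-squares polynomial fits (orders 8 and 6) and CV with a
    100-point moving mean; the usable band collects frequencies where both
    smoothed A2m < 1.341 and smoothed r(1) < t2, and the verdict is that
    condition at *target*.
    """
    if subset is not None:
        sweep = subset_positions(sweep, *subset)
    freqs = sweep.frequencies
    if not (freqs[0] <= target <= freqs[-1]):
        raise ValueError(
            f"target {target:.4g} Hz outside measured range "
            f"[{freqs[0]:.4g}, {freqs[-1]:.4g}] Hz"
        )
    stirred = stirred_component(sweep)
    mags = stirred.magnitudes  # (n_pos, n_freq)
    n_pos = mags.shape[0]

    a2, _ = ad_statistic_rayleigh(mags.T)
    a2m = a2 * (1.0 + 0.6 / n_pos)
    r1 = np.array([lag1_autocorrelation(mags[:, j]).r1 for j in range(mags.shape[1])])
    cvs = cv_series(stirred, cutoff=cv_cutoff)

    # smoothing per the characterization protocol
    span = float(np.ptp(freqs))
    fscaled = (freqs - freqs.mean()) / (span if span else 1.0)
    a2m_poly = np.polyfit(fscaled, a2m, min(a2m_poly_order, len(freqs) - 1))
    r1_poly = np.polyfit(fscaled, r1, min(r1_poly_order, len(freqs) - 1))
    a2m_smooth = np.polyval(a2m_poly, fscaled)
    r1_smooth = np.polyval(r1_poly, fscaled)
    cv_smooth = _moving_mean(cvs.cv, cv_window)

    t2 = r1_threshold(n_pos) if r1_thresh is None else r1_thresh
    ok = (a2m_smooth < ad_threshold) & (r1_smooth < t2)
    bands = _bands_from_mask(freqs, ok)
    j = int(np.argmin(np.abs(freqs - target)))
    verdict = bool(ok[j])

    s1, s2 = sweep.stirrer_grid()
    return UniformityReport(
        frequencies=freqs,
        a2m=a2m,
        r1=r1,
        cv=cvs.cv,
        a2m_smooth=a2m_smooth,
        r1_smooth=r1_smooth,
        cv_smooth=cv_smooth,
        a2m_poly=a2m_poly,
        r1_poly=r1_poly,
        ad_threshold=ad_threshold,
        r1_threshold=t2,
        cv_interval=(cvs.interval_lo, cvs.interval_hi),
        cv_cutoff=cv_cutoff,
        configuration=f"{len(s1)}x{len(s2)}",
        n_positions=n_pos,
        target_frequency=target,
        usable_band=bands,
        verdict=verdict,
    )
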