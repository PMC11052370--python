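"""Diffracted X-ray blinking (DXB) pipeline.

Per-pixel photon-count time series from ring ROIs are condensed into
intensity autocorrelation functions, ACF = <I(t) I(t+tau)> / <I(t)^2>, each
fitted with a single exponential k + A exp(-T tau). Accepted decay constants
(k > 0, A > 0, T > 0) are summarised as five-number box statistics, decomposed
into low/high mobility groups by a two-Gaussian histogram fit, and compared
across conditions with the Wilcoxon rank-sum test. A first-half/second-half
split of the movie provides the radiation-damage check.

Estimator conventions: the ACF numerator at lag m averages the n - m
available pairs while the denominator is the full-trace mean of I^2, so
ACF(0) = 1 exactly; lag 0 is excluded from exponential fits.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .geometry import InvalidInputError, RingROI

__all__ = [
    "PixelTrace",
    "ACFCurve",
    "ACFFit",
    "DecaySample",
    "GaussianPair",
    "FiveNumber",
    "ComparisonResult",
    "DamageReport",
    "DegenerateTraceError",
    "InsufficientDataError",
    "MixtureFitError",
    "extract_pixel_traces",
    "compute_acf",
    "acf_matrix",
    "fit_acf_exponential",
    "fit_averaged_acf",
    "decay_stats",
    "fit_two_gaussians",
    "compare_distributions",
    "significance_tier",
    "radiation_damage_check",
]


class DegenerateTraceError(ValueError):
    """Trace is identically zero; its ACF is undefined."""


class InsufficientDataError(ValueError):
    """Not enough traces/curves/frames for the requested statistic."""


class MixtureFitError(RuntimeError):
    """Two-Gaussian histogram fit failed to converge after multi-start."""


@dataclass(frozen=True)
class PixelTrace:
    """Photon counts of one detector pixel over the movie."""

    pixel: tuple[int, int]
    intensity: np.ndarray  # integer counts per frame
    frame_interval_s: float

    def __post_init__(self) -> None:
        if len(self.intensity) < 2:
            raise InvalidInputError("trace needs at least 2 frames")
        if np.any(np.asarray(self.intensity) < 0):
            raise InvalidInputError("photon counts must be >= 0")


@dataclass(frozen=True)
class ACFCurve:
    """Normalized intensity ACF sampled at lags m * frame_interval, m >= 0."""

    lags: np.ndarray  # seconds, starting at 0
    values: np.ndarray
    n_pairs: np.ndarray  # averaging count per lag


@dataclass(frozen=True)
class ACFFit:
    """Parameters of k + A exp(-T tau) fitted to one ACF curve."""

    k: float
    A: float
    T: float
    accepted: bool
    residual_norm: float
    converged: bool


@dataclass(frozen=True)
class DecaySample:
    """Accepted decay constants (1/s) for one probe/domain under one condition."""

    values: np.ndarray
    condition: str = ""
    domain_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and np.any(v <= 0):
            raise InvalidInputError("decay constants must be > 0")
        object.__setattr__(self, "values", v)


class FiveNumber(NamedTuple):
    minimum: float
    q25: float
    median: float
    q75: float
    maximum: float


@dataclass(frozen=True)
class GaussianPair:
    """Two-Gaussian decomposition of a decay-constant histogram.

    Component 1 is the low-mobility group (smaller mean decay constant);
    ``pct`` values are percentages of the total fitted area.
    """

    mu1: float
    sigma1: float
    w1: float
    mu2: float
    sigma2: float
    w2: float
    pct1: float
    pct2: float
    bin_centers: np.ndarray = field(repr=False, default=None)
    bin_counts: np.ndarray = field(repr=False, default=None)

    def component_curves(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g1 = self.w1 / (self.sigma1 * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((x - self.mu1) / self.sigma1) ** 2
        )
        g2 = self.w2 / (self.sigma2 * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((x - self.mu2) / self.sigma2) ** 2
        )
        return g1, g2

    def sum_curve(self, x: np.ndarray) -> np.ndarray:
        """Overlay curve: the sum of the two fitted Gaussians."""
        g1, g2 = self.component_curves(x)
        return g1 + g2


class ComparisonResult(NamedTuple):
    statistic: float  # rank-sum W of the first sample
    p_value: float
    tier: str  # "n.s." | "*" | "**" | "***"
    method: str  # "exact" | "normal"


@dataclass(frozen=True)
class DamageReport:
    first_half: DecaySample
    second_half: DecaySample
    comparison: ComparisonResult
    damaged: bool


def extract_pixel_traces(
    image_stack: np.ndarray, roi: RingROI, frame_interval_s: float = 1.0
) -> list[PixelTrace]:
    """One trace per ROI pixel, in deterministic row-major pixel order."""
    stack = np.asarray(image_stack)
    if stack.ndim != 3:
        raise InvalidInputError("image stack must be 3-D (frames, rows, cols)")
    if stack.shape[0] < 2:
        raise InvalidInputError("need at least 2 frames")
    n_rows, n_cols = stack.shape[1:]
    if np.any(roi.pixels[:, 0] >= n_rows) or np.any(roi.pixels[:, 1] >= n_cols):
        raise InvalidInputError("ROI pixels outside stack dimensions")
    order = np.lexsort((roi.pixels[:, 1], roi.pixels[:, 0]))
    pixels = roi.pixels[order]
    return [
        PixelTrace(
            pixel=(int(r), int(c)),
            intensity=stack[:, r, c],
            frame_interval_s=frame_interval_s,
        )
        for r, c in pixels
    ]


def compute_acf(trace: PixelTrace, max_lag_frames: int | None = None) -> ACFCurve:
    """Normalized non-centered ACF of one pixel trace.

    ACF(m * dt) = mean_t[I(t) I(t+m)] / mean_t[I(t)^2]; the lag-0 value is 1
    by construction. Default ``max_lag_frames`` is n // 4 (longer lags are
    pair-starved).
    """
    intens = np.asarray(trace.intensity, dtype=float)
    n = len(intens)
    if not np.any(intens):
        raise DegenerateTraceError(f"pixel {trace.pixel}: all-zero trace")
    if max_lag_frames is None:
        max_lag_frames = max(1, n // 4)
    if not 1 <= max_lag_frames < n:
        raise InvalidInputError("max_lag_frames must satisfy 1 <= m < n")
    values, n_pairs = _acf_1d(intens, max_lag_frames)
    lags = np.arange(max_lag_frames + 1) * trace.frame_interval_s
    return ACFCurve(lags=lags, values=values, n_pairs=n_pairs)


def _acf_1d(intens: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(intens)
    den = np.mean(intens**2)
    values = np.empty(max_lag + 1)
    n_pairs = np.empty(max_lag + 1, dtype=int)
    values[0] = 1.0
    n_pairs[0] = n
    for m in range(1, max_lag + 1):
        values[m] = np.mean(intens[: n - m] * intens[m:]) / den
        n_pairs[m] = n - m
    return values, n_pairs


def acf_matrix(
    intensities: np.ndarray, max_lag_frames: int, frame_interval_s: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised ACF for a (n_traces, n_frames) array.

    Returns ``(lags, values, degenerate_mask)`` where ``values`` has shape
    (n_traces, max_lag + 1); rows of all-zero traces are NaN and flagged in
    ``degenerate_mask``.
    """
    x = np.asarray(intensities, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError("intensities must be 2-D (traces, frames)")
    n = x.shape[1]
    if not 1 <= max_lag_frames < n:
        raise InvalidInputError("max_lag_frames must satisfy 1 <= m < n")
    den = np.mean(x**2, axis=1)
    degenerate = den == 0
    den_safe = np.where(degenerate, 1.0, den)
    values = np.empty((x.shape[0], max_lag_frames + 1))
    values[:, 0] = 1.0
    for m in range(1, max_lag_frames + 1):
        values[:, m] = np.mean(x[:, : n - m] * x[:, m:], axis=1) / den_safe
    values[degenerate] = np.nan
    lags = np.arange(max_lag_frames + 1) * frame_interval_s
    return lags, values, degenerate


def fit_acf_exponential(
    curve: ACFCurve, *, n_starts: int = 5, seed: int = 0
) -> ACFFit:
    """Nonlinear least-squares fit of k + A exp(-T tau) over lags tau > 0.

    Initialisation: k0 = min(ACF), A0 = ACF(first lag) - k0, T0 from the lag
    where the curve falls to A0/e above k0 (mid-span fallback). Up to
    ``n_starts`` jittered restarts are attempted; a fit that never converges
    is returned with ``accepted=False`` rather than raising. The acceptance
    flag applies the k > 0, A > 0, T > 0 criteria.
    """
    tau = np.asarray(curve.lags, dtype=float)[1:]
    y = np.asarray(curve.values, dtype=float)[1:]
    if len(tau) < 4:
        raise InvalidInputError("need at least 4 nonzero lags to fit")
    return _fit_exponential(tau, y, sigma=None, n_starts=n_starts, seed=seed)


def _fit_exponential(
    tau: np.ndarray,
    y: np.ndarray,
    sigma: np.ndarray | None,
    n_starts: int,
    seed: int,
) -> ACFFit:
    k0 = float(np.min(y))
    a0 = float(y[0] - k0)
    if a0 <= 0:
        a0 = max(abs(a0), 1e-3)
    target = k0 + a0 / math.e
    below = np.nonzero(y <= target)[0]
    t_char = tau[below[0]] if below.size else 0.5 * (tau[0] + tau[-1])
    t0 = 1.0 / max(t_char, tau[0])

    rng = np.random.default_rng(seed)
    initial = [np.array([k0, a0, t0])]
    if y[-1] > y[0]:
        # rising curve: the optimum may have T < 0 (then rejected by the
        # acceptance criteria); give the solver a growing-exponential start
        span = tau[-1] - tau[0]
        initial.append(
            np.array([y[0], max(y[-1] - y[0], 1e-3), -1.0 / span])
        )
    best: tuple[float, np.ndarray] | None = None
    for i in range(len(initial) + n_starts - 1):
        if i < len(initial):
            p0 = initial[i]
        else:
            jitter = rng.uniform(0.3, 3.0, size=3)
            p0 = np.array([k0 * jitter[0], a0 * jitter[1], t0 * jitter[2]])
        try:
            popt, _ = optimize.curve_fit(
                lambda t, k, A, T: k + A * np.exp(-T * t),
                tau,
                y,
                p0=p0,
                sigma=sigma,
                maxfev=5000,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        resid = y - (popt[0] + popt[1] * np.exp(-popt[2] * tau))
        if sigma is not None:
            resid = resid / sigma
        rnorm = float(np.linalg.norm(resid))
        if best is None or rnorm < best[0]:
            best = (rnorm, popt)
        if i == len(initial) - 1 and best is not None:
            break  # a deterministic start converged; no jittered restarts
    if best is None:
        return ACFFit(k=math.nan, A=math.nan, T=math.nan, accepted=False,
                      residual_norm=math.inf, converged=False)
    rnorm, (k, a, t) = best
    accepted = bool(k > 0 and a > 0 and t > 0)
    return ACFFit(k=float(k), A=float(a), T=float(t), accepted=accepted,
                  residual_norm=rnorm, converged=True)


def fit_averaged_acf(
    accepted_curves: Sequence[ACFCurve], *, n_starts: int = 5, seed: int = 0
) -> tuple[ACFFit, ACFCurve, np.ndarray]:
    """Weighted fit of the pixel-averaged ACF.

    The per-lag mean and standard error across curves define weights
    w_m = 1 / SE_m^2 for the exponential fit (lags with SE = 0 get the
    largest finite weight present). Returns (fit, mean curve, SE per lag).
    """
    if len(accepted_curves) < 2:
        raise InsufficientDataError("need >= 2 accepted curves to average")
    lags = np.asarray(accepted_curves[0].lags, dtype=float)
    for c in accepted_curves[1:]:
        if len(c.lags) != len(lags) or not np.allclose(c.lags, lags):
            raise InvalidInputError("curves must share the same lag grid")
    stackv = np.vstack([c.values for c in accepted_curves])
    mean = stackv.mean(axis=0)
    se = stackv.std(axis=0, ddof=1) / math.sqrt(stackv.shape[0])

    se_fit = se[1:].copy()
    positive = se_fit > 0
    if positive.any():
        se_fit[~positive] = se_fit[positive].min()
    else:
        se_fit[:] = 1.0
    fit = _fit_exponential(lags[1:], mean[1:], sigma=se_fit, n_starts=n_starts,
                           seed=seed)
    mean_curve = ACFCurve(
        lags=lags, values=mean,
        n_pairs=np.full(len(lags), stackv.shape[0], dtype=int),
    )
    return fit, mean_curve, se


def decay_stats(sample: DecaySample) -> FiveNumber:
    """Five-number summary (min, q25, median, q75, max), type-7 quantiles."""
    v = np.asarray(sample.values, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("empty decay sample")
    q = np.quantile(v, [0.0, 0.25, 0.5, 0.75, 1.0])  # linear interpolation
    return FiveNumber(*map(float, q))


def _freedman_diaconis_bins(v: np.ndarray) -> int:
    iqr = np.subtract(*np.percentile(v, [75, 25]))
    if iqr <= 0:
        return max(10, int(math.sqrt(v.size)))
    h = 2.0 * iqr / v.size ** (1.0 / 3.0)
    return max(10, int(math.ceil((v.max() - v.min()) / h)))


def fit_two_gaussians(
    sample: DecaySample,
    n_bins: int | None = None,
    *,
    n_starts: int = 8,
    seed: int = 0,
) -> GaussianPair:
    """Least-squares two-Gaussian decomposition of the decay histogram.

    The histogram (Freedman-Diaconis binning unless ``n_bins`` is given) is
    fitted with a1*phi((x-mu1)/s1) + a2*phi((x-mu2)/s2) on bin centers;
    components are ordered mu1 <= mu2 (group-I = low mobility) and the
    percentages come from the analytic component areas, so pct1 + pct2 = 100
    exactly for any converged fit.
    """
    v = np.asarray(sample.values, dtype=float)
    if v.size < 50:
        raise InsufficientDataError("need >= 50 decay constants for a mixture fit")
    bins = n_bins if n_bins is not None else _freedman_diaconis_bins(v)
    counts, edges = np.histogram(v, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    def model(x, a1, mu1, s1, a2, mu2, s2):
        return a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2) + a2 * np.exp(
            -0.5 * ((x - mu2) / s2) ** 2
        )

    lo, hi = float(v.min()), float(v.max())
    spread = float(v.std())
    amp = float(counts.max())
    rng = np.random.default_rng(seed)
    starts = []
    q = np.percentile(v, [20, 30, 50, 70, 80])
    starts.append([amp, q[0], spread / 2, amp / 2, q[3], spread / 2])
    starts.append([amp / 2, q[1], spread / 3, amp / 2, q[4], spread / 3])
    while len(starts) < n_starts:
        starts.append(
            [
                amp * rng.uniform(0.2, 1.2),
                rng.uniform(lo, hi),
                spread * rng.uniform(0.1, 1.0),
                amp * rng.uniform(0.2, 1.2),
                rng.uniform(lo, hi),
                spread * rng.uniform(0.1, 1.0),
            ]
        )
    bounds = ([0, lo - spread, 1e-12, 0, lo - spread, 1e-12],
              [np.inf, hi + spread, np.inf, np.inf, hi + spread, np.inf])
    best = None
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                model, centers, counts, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        rnorm = float(np.linalg.norm(counts - model(centers, *popt)))
        if best is None or rnorm < best[0]:
            best = (rnorm, popt)
    if best is None:
        raise MixtureFitError(
            f"two-Gaussian fit failed after {n_starts} starts "
            f"(n={v.size}, bins={bins})"
        )
    a1, mu1, s1, a2, mu2, s2 = best[1]
    if mu1 > mu2:
        a1, mu1, s1, a2, mu2, s2 = a2, mu2, s2, a1, mu1, s1
    # analytic areas (amplitude * sigma * sqrt(2 pi)); bin width cancels in pct
    area1 = a1 * s1 * math.sqrt(2 * math.pi)
    area2 = a2 * s2 * math.sqrt(2 * math.pi)
    total = area1 + area2
    pct1 = 100.0 * area1 / total
    return GaussianPair(
        mu1=float(mu1), sigma1=float(s1), w1=float(area1 / width),
        mu2=float(mu2), sigma2=float(s2), w2=float(area2 / width),
        pct1=float(pct1), pct2=float(100.0 - pct1),
        bin_centers=centers, bin_counts=counts,
    )


def significance_tier(p: float) -> str:
    """Conventional star tiers; only the *** threshold (p < 0.001) is standard
    in this workflow, the lower tiers are the usual conventions."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumeration of all C(n, n_x) assignments.

    Ties carry midranks. Two-sided p = min(1, 2 * min(P(W <= w), P(W >= w)))
    under the permutation null.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    n = len(pooled)
    nx = len(x)
    w_obs = ranks[:nx].sum()
    sums = np.array(
        [sum(c) for c in itertools.combinations(ranks, nx)]
    )
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return float(w_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))


def compare_distributions(
    sample_a: DecaySample, sample_b: DecaySample, *, exact_max_n: int = 12
) -> ComparisonResult:
    """Wilcoxon rank-sum comparison of two decay-constant samples.

    Exact permutation enumeration when n_a + n_b <= ``exact_max_n``; otherwise
    the normal approximation with midrank tie correction and continuity
    correction. Two-sided throughout.
    """
    a = np.asarray(sample_a.values, dtype=float)
    b = np.asarray(sample_b.values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be nonempty")
    if a.size + b.size <= exact_max_n:
        w, p = _exact_ranksum_p(a, b)
        method = "exact"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        # convert U to the rank-sum W of sample a
        w = float(res.statistic + a.size * (a.size + 1) / 2.0)
        p = float(res.pvalue)
        method = "normal"
    return ComparisonResult(statistic=w, p_value=p, tier=significance_tier(p),
                            method=method)


def radiation_damage_check(
    image_stack: np.ndarray,
    roi: RingROI,
    frame_interval_s: float,
    *,
    max_lag_frames: int | None = None,
    p_threshold: float = 0.001,
    seed: int = 0,
) -> DamageReport:
    """First-half vs second-half decay-constant comparison.

    Splits the movie at the midpoint (first ceil(n/2) frames vs the rest),
    runs ACF -> exponential fit per pixel on each half independently, and
    flags damage when the two accepted-T distributions differ at
    p < ``p_threshold`` by the rank-sum test.
    """
    stack = np.asarray(image_stack)
    if stack.ndim != 3 or stack.shape[0] < 4:
        raise InvalidInputError("need a 3-D stack with at least 4 frames")
    n = stack.shape[0]
    half = (n + 1) // 2
    samples = []
    for name, part in (("first-half", stack[:half]), ("second-half", stack[half:])):
        ts = _accepted_decay_constants(
            part, roi, frame_interval_s, max_lag_frames=max_lag_frames, seed=seed
        )
        samples.append(DecaySample(values=ts, condition=name, domain_label=roi.label))
    comparison = compare_distributions(samples[0], samples[1])
    return DamageReport(
        first_half=samples[0],
        second_half=samples[1],
        comparison=comparison,
        damaged=bool(comparison.p_value < p_threshold),
    )


def _accepted_decay_constants(
    stack: np.ndarray,
    roi: RingROI,
    frame_interval_s: float,
    *,
    max_lag_frames: int | None,
    seed: int,
) -> np.ndarray:
    intens = stack[:, roi.pixels[:, 0], roi.pixels[:, 1]].T.astype(float)
    n = intens.shape[1]
    mlag = max_lag_frames if max_lag_frames is not None else max(1, n // 4)
    lags, values, degenerate = acf_matrix(intens, mlag, frame_interval_s)
    ts = []
    for i in range(values.shape[0]):
        if degenerate[i]:
            continue
        curve = ACFCurve(lags=lags, values=values[i],
                         n_pairs=np.arange(n, n - mlag - 1, -1))
        fit = fit_acf_exponential(curve, seed=seed)
        if fit.accepted:
            ts.append(fit.T)
    return np.asarray(ts)
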