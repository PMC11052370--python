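"""Diffracted X-ray tracking (DXT) pipeline.

Laue spots from pink-beam movies are detected, linked into trajectories,
routed to their probe ring, and decomposed into the two angular axes of the
method: twisting chi (azimuthal displacement about the beam axis) and bending
theta (tilt of the diffracting plane, half the change of the scattering angle
2-theta, since tilting a crystal by delta deflects the Bragg-reflected ray by
2 delta). Per-trajectory temporal MSD curves are fitted with the anomalous
diffusion model delta^2(t) = D_alpha t^alpha + 2 beta^2, and ensembles are
summarised as theta-chi motion histograms supporting peak/FWHM extraction,
hotspot superposition and normalized subtraction maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage, optimize

from .geometry import (
    AmbiguousAssignmentError,
    DetectorGeometry,
    InvalidInputError,
    RingROI,
    assign_ring,
)

__all__ = [
    "Spot",
    "SpotTrajectory",
    "AngularTrajectory",
    "MSDCurve",
    "MSDFit",
    "MotionHist2D",
    "normalize_i0",
    "detect_spots",
    "link_spots",
    "route_trajectories",
    "to_angular",
    "filter_by_lifetime",
    "compute_msd",
    "fit_msd",
    "ensemble_msd",
    "build_motion_hist",
    "peak_and_fwhm",
    "subtract_hists",
    "superpose_hotspots",
]


@dataclass(frozen=True)
class Spot:
    """A single detected diffraction spot in one frame."""

    frame: int
    position_px: tuple[float, float]  # (row, col), sub-pixel
    intensity: float
    radius_px: float
    azimuth_deg: float

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise InvalidInputError("spot intensity must be > 0")
        if self.radius_px <= 0:
            raise InvalidInputError("spot radius must be > 0")


@dataclass(frozen=True)
class SpotTrajectory:
    """A time-ordered linked track of one Laue spot."""

    spots: tuple[Spot, ...]
    ring_label: str = ""
    trajectory_id: int = -1

    def __post_init__(self) -> None:
        frames = [s.frame for s in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise InvalidInputError("spot frames must be strictly increasing")

    @property
    def lifetime_frames(self) -> int:
        return self.spots[-1].frame - self.spots[0].frame + 1

    @property
    def mean_radius_px(self) -> float:
        return float(np.mean([s.radius_px for s in self.spots]))


@dataclass(frozen=True)
class AngularTrajectory:
    """Cumulative (chi, theta) decomposition of one spot trajectory.

    Both angles start at 0 by convention; chi is the unwrapped azimuthal
    displacement, theta accumulates half the change in scattering angle.
    """

    time_s: np.ndarray
    chi_deg: np.ndarray
    theta_deg: np.ndarray
    ring_label: str = ""
    trajectory_id: int = -1

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class MSDCurve:
    lag_s: np.ndarray
    msd_deg2: np.ndarray
    n_frames: int
    axis: str  # "chi" | "theta" | "both"


@dataclass(frozen=True)
class MSDFit:
    """Anomalous-diffusion parameters delta^2(t) = D_alpha t^alpha + 2 beta^2."""

    D_alpha: float  # deg^2 / s^alpha
    alpha: float
    beta: float  # deg
    regime: str  # "subdiffusion" | "normal" | "superdiffusion"
    converged: bool
    residual_norm: float = math.nan

    @staticmethod
    def classify(alpha: float, rtol: float = 1e-6) -> str:
        if abs(alpha - 1.0) <= rtol:
            return "normal"
        return "subdiffusion" if alpha < 1.0 else "superdiffusion"


@dataclass(frozen=True)
class MotionHist2D:
    """Binned theta-chi motion map (one point per trajectory).

    ``density`` is normalized to unit sum; ``axis_statistic`` records which
    per-trajectory quantity was binned (and its units), since the axes of
    such maps are convention-dependent.
    """

    chi_edges: np.ndarray
    theta_edges: np.ndarray
    counts: np.ndarray  # shape (n_chi_bins, n_theta_bins)
    axis_statistic: str

    @property
    def density(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total

    def marginals(self) -> tuple[np.ndarray, np.ndarray]:
        """(chi marginal, theta marginal) counts."""
        return self.counts.sum(axis=1), self.counts.sum(axis=0)


def normalize_i0(image_stack: np.ndarray, i0_series: np.ndarray) -> np.ndarray:
    """Scale each frame by mean(I0) / I0(frame) so the stack mean is preserved."""
    stack = np.asarray(image_stack, dtype=float)
    i0 = np.asarray(i0_series, dtype=float)
    if stack.ndim != 3:
        raise InvalidInputError("image stack must be 3-D")
    if len(i0) != stack.shape[0]:
        raise InvalidInputError("I0 series length must equal the frame count")
    if np.any(i0 <= 0):
        raise InvalidInputError("all I0 values must be > 0")
    scale = i0.mean() / i0
    return stack * scale[:, None, None]


def detect_spots(
    frame: np.ndarray,
    geom: DetectorGeometry,
    *,
    min_intensity: float = 5.0,
    min_separation_px: int = 3,
    window: int = 7,
    frame_index: int = 0,
) -> list[Spot]:
    """Local-maximum spot detection with sub-pixel centroid refinement.

    The background is estimated as the median pixel value of the frame
    (diffuse scatter is flat at this scale) and subtracted; candidates are
    local maxima above ``min_intensity`` that survive a ``min_separation_px``
    suppression window. Each candidate is refined by an intensity-weighted
    centroid over a ``window`` x ``window`` region; two true spots closer
    than the separation window merge into one detection by construction.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise InvalidInputError("frame must be 2-D")
    if np.any(img < 0):
        raise InvalidInputError("frame must be nonnegative")
    resid = img - np.median(img)
    np.clip(resid, 0.0, None, out=resid)
    size = 2 * min_separation_px + 1
    maxf = ndimage.maximum_filter(resid, size=size, mode="constant")
    peaks = np.argwhere((resid == maxf) & (resid >= min_intensity))
    # ties in integer counts can yield two equal maxima inside one window;
    # keep the strongest (row-major on ties) of any pair closer than the
    # suppression distance
    if len(peaks) > 1:
        vals = resid[peaks[:, 0], peaks[:, 1]]
        order = np.lexsort((peaks[:, 1], peaks[:, 0], -vals))
        kept: list[np.ndarray] = []
        for i in order:
            p = peaks[i]
            if all(
                max(abs(p[0] - q[0]), abs(p[1] - q[1])) > min_separation_px
                for q in kept
            ):
                kept.append(p)
        peaks = np.array(kept)
    half = window // 2
    cr, cc = geom.beam_center_px
    spots: list[Spot] = []
    for r, c in peaks:
        r0, r1 = max(0, r - half), min(img.shape[0], r + half + 1)
        c0, c1 = max(0, c - half), min(img.shape[1], c + half + 1)
        patch = resid[r0:r1, c0:c1]
        total = patch.sum()
        if total <= 0:
            continue
        rows = np.arange(r0, r1)[:, None]
        cols = np.arange(c0, c1)[None, :]
        rc = float((patch * rows).sum() / total)
        cc_ = float((patch * cols).sum() / total)
        radius = math.hypot(rc - cr, cc_ - cc)
        azimuth = math.degrees(math.atan2(rc - cr, cc_ - cc))
        spots.append(
            Spot(frame=frame_index, position_px=(rc, cc_), intensity=float(total),
                 radius_px=radius, azimuth_deg=azimuth)
        )
    return spots


def link_spots(
    per_frame_spots: Sequence[Sequence[Spot]],
    *,
    max_disp_px: float = 5.0,
    memory_frames: int = 2,
    min_length: int = 2,
) -> list[SpotTrajectory]:
    """Greedy nearest-neighbour frame-to-frame linking with gap memory.

    Candidate (track, detection) pairs are taken in order of increasing
    Euclidean displacement; links longer than ``max_disp_px`` per elapsed
    frame are rejected. A track survives invisibility gaps up to
    ``memory_frames``; beyond that it is closed and a reappearing spot starts
    a new trajectory. Crossing-track disambiguation is out of scope for the
    greedy linker.
    """
    active: list[dict] = []
    finished: list[list[Spot]] = []
    for spots in per_frame_spots:
        spots = list(spots)
        if spots:
            frame = spots[0].frame
        else:
            frame = None
        # close tracks that exceeded the memory window
        if frame is not None:
            still = []
            for tr in active:
                if frame - tr["spots"][-1].frame - 1 > memory_frames:
                    finished.append(tr["spots"])
                else:
                    still.append(tr)
            active = still
        # candidate links, ascending distance
        pairs = []
        for ti, tr in enumerate(active):
            last = tr["spots"][-1]
            gap = spots[0].frame - last.frame if spots else 1
            limit = max_disp_px * max(gap, 1)
            for si, sp in enumerate(spots):
                d = math.dist(last.position_px, sp.position_px)
                if d <= limit:
                    pairs.append((d, ti, si))
        pairs.sort(key=lambda t: t[0])
        used_t: set[int] = set()
        used_s: set[int] = set()
        for d, ti, si in pairs:
            if ti in used_t or si in used_s:
                continue
            active[ti]["spots"].append(spots[si])
            used_t.add(ti)
            used_s.add(si)
        for si, sp in enumerate(spots):
            if si not in used_s:
                active.append({"spots": [sp]})
    finished.extend(tr["spots"] for tr in active)
    out = []
    tid = 0
    for spots in finished:
        if len(spots) < min_length:
            continue
        out.append(SpotTrajectory(spots=tuple(spots), trajectory_id=tid))
        tid += 1
    return out


def route_trajectories(
    trajectories: Sequence[SpotTrajectory],
    candidate_rois: Sequence[RingROI],
    tolerance_px: float = 2.0,
) -> tuple[list[SpotTrajectory], dict]:
    """Assign each trajectory to a ring by its mean radius.

    Unassigned or ambiguous trajectories are dropped and tallied in the
    returned report so the two probes are never pooled.
    """
    routed: list[SpotTrajectory] = []
    report = {"assigned": 0, "unassigned": 0, "ambiguous": 0}
    for traj in trajectories:
        try:
            roi = assign_ring(traj.mean_radius_px, candidate_rois, tolerance_px)
        except AmbiguousAssignmentError:
            report["ambiguous"] += 1
            continue
        if roi is None:
            report["unassigned"] += 1
            continue
        routed.append(replace(traj, ring_label=roi.label))
        report["assigned"] += 1
    return routed, report


def to_angular(traj: SpotTrajectory, geom: DetectorGeometry) -> AngularTrajectory:
    """Decompose a spot trajectory into cumulative (chi, theta) angles.

    chi accumulates the unwrapped azimuthal steps about the beam center;
    theta accumulates half the change of the scattering angle
    2theta(frame) = arctan(radius_mm / distance_mm). Both start at 0.
    """
    if len(traj.spots) < 2:
        raise InvalidInputError("trajectory must have length >= 2")
    radius_px = np.array([s.radius_px for s in traj.spots])
    if np.any(radius_px <= 0):
        raise InvalidInputError("zero radius: azimuth undefined at beam center")
    az = np.unwrap(np.radians([s.azimuth_deg for s in traj.spots]))
    chi = np.degrees(az - az[0])
    two_theta = np.degrees(
        np.arctan(radius_px * geom.pixel_pitch_mm / geom.distance_mm)
    )
    theta = 0.5 * (two_theta - two_theta[0])
    frames = np.array([s.frame for s in traj.spots])
    time_s = (frames - frames[0]) * geom.frame_interval_s
    return AngularTrajectory(
        time_s=time_s, chi_deg=chi, theta_deg=theta,
        ring_label=traj.ring_label, trajectory_id=traj.trajectory_id,
    )


def filter_by_lifetime(
    trajectories: Sequence[SpotTrajectory],
    min_frames: int = 0,
    max_frames: float = math.inf,
) -> list[SpotTrajectory]:
    """Keep trajectories with min_frames <= lifetime <= max_frames."""
    if min_frames > max_frames:
        raise InvalidInputError("min_frames must be <= max_frames")
    return [t for t in trajectories if min_frames <= t.lifetime_frames <= max_frames]


def compute_msd(traj: AngularTrajectory, axis: str = "both") -> MSDCurve:
    """Temporal (time-averaged, single-trajectory) MSD.

    delta^2(m dt) = mean_t [x(t + m dt) - x(t)]^2 for m = 1 .. n // 4; for
    ``axis="both"`` the chi and theta contributions add (squared 2-D angular
    displacement). Requires evenly sampled trajectories.
    """
    n = len(traj)
    if n < 3:
        raise InvalidInputError("trajectory too short for MSD (need >= 3 points)")
    if axis not in ("chi", "theta", "both"):
        raise InvalidInputError(f"unknown axis {axis!r}")
    dt_steps = np.diff(traj.time_s)
    dt = dt_steps[0]
    if not np.allclose(dt_steps, dt):
        raise InvalidInputError("MSD requires an evenly sampled trajectory")
    max_m = max(1, n // 4)
    if axis == "chi":
        comps = [traj.chi_deg]
    elif axis == "theta":
        comps = [traj.theta_deg]
    else:
        comps = [traj.chi_deg, traj.theta_deg]
    msd = np.zeros(max_m)
    for x in comps:
        for m in range(1, max_m + 1):
            d = x[m:] - x[:-m]
            msd[m - 1] += np.mean(d * d)
    return MSDCurve(lag_s=np.arange(1, max_m + 1) * dt, msd_deg2=msd,
                    n_frames=n, axis=axis)


def fit_msd(curve: MSDCurve, *, weighted: bool = True) -> MSDFit:
    """Fit delta^2(t) = D_alpha t^alpha + 2 beta^2 with D_alpha, beta^2 >= 0.

    Weights follow the standard relative-variance growth of the temporal MSD
    of a finite trajectory, sigma_m ~ delta^2(m) sqrt(m / (n - m)), which
    keeps the long, pair-starved lags from dominating the fit. The diffusion
    regime is classified from alpha (subdiffusion below 1, superdiffusion
    above, "normal" within numerical tolerance of 1).
    """
    t = np.asarray(curve.lag_s, dtype=float)
    y = np.asarray(curve.msd_deg2, dtype=float)
    if len(t) < 4:
        raise InvalidInputError("need >= 4 MSD points to fit")
    n = curve.n_frames
    if weighted:
        m = np.arange(1, len(t) + 1)
        sigma = np.maximum(y, y[y > 0].min() if np.any(y > 0) else 1.0) * np.sqrt(
            m / np.maximum(n - m, 1)
        )
        sigma = np.maximum(sigma, 1e-30)
    else:
        sigma = None

    # log-log slope initialisation over the later decade (beta floor at small t)
    pos = y > 0
    if pos.sum() >= 2:
        lt, ly = np.log(t[pos]), np.log(y[pos])
        alpha0 = float(np.clip(np.polyfit(lt, ly, 1)[0], 0.1, 2.5))
        d0 = float(np.exp(ly[-1] - alpha0 * lt[-1]))
    else:
        alpha0, d0 = 1.0, 1.0

    def model(tt, d, a, b2):
        return d * np.power(tt, a) + 2.0 * b2

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=[d0, alpha0, 0.0],
            sigma=sigma, absolute_sigma=False,
            bounds=([0.0, 1e-6, 0.0], [np.inf, 3.0, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return MSDFit(D_alpha=math.nan, alpha=math.nan, beta=math.nan,
                      regime="unclassified", converged=False)
    d, a, b2 = popt
    resid = y - model(t, *popt)
    if sigma is not None:
        resid = resid / sigma
    return MSDFit(D_alpha=float(d), alpha=float(a), beta=float(math.sqrt(b2)),
                  regime=MSDFit.classify(a), converged=True,
                  residual_norm=float(np.linalg.norm(resid)))


def ensemble_msd(curves: Sequence[MSDCurve]) -> MSDCurve:
    """Average per-trajectory temporal MSD curves on their common lag grid."""
    if not curves:
        raise InvalidInputError("no MSD curves to average")
    n_common = min(len(c.lag_s) for c in curves)
    lag = curves[0].lag_s[:n_common]
    for c in curves[1:]:
        if not np.allclose(c.lag_s[:n_common], lag):
            raise InvalidInputError("curves must share the lag grid")
    msd = np.mean([c.msd_deg2[:n_common] for c in curves], axis=0)
    return MSDCurve(lag_s=lag, msd_deg2=msd,
                    n_frames=min(c.n_frames for c in curves), axis=curves[0].axis)


def _trajectory_statistic(
    angular: AngularTrajectory, axis: str, statistic: str, lag_frames: int
) -> float:
    curve = compute_msd(angular, axis=axis)
    if statistic == "log_msd":
        idx = min(lag_frames, len(curve.msd_deg2)) - 1
        val = curve.msd_deg2[idx]
        return math.log10(val) if val > 0 else -math.inf
    if statistic == "net_displacement":
        x = angular.chi_deg if axis == "chi" else angular.theta_deg
        return float(x[-1] - x[0])
    if statistic == "D_alpha":
        return fit_msd(curve).D_alpha
    raise InvalidInputError(f"unknown axis statistic {statistic!r}")


def build_motion_hist(
    angulars: Sequence[AngularTrajectory],
    *,
    axis_statistic: str = "log_msd",
    lag_frames: int = 1,
    bins: int = 50,
    chi_edges: np.ndarray | None = None,
    theta_edges: np.ndarray | None = None,
) -> tuple[MotionHist2D, np.ndarray, np.ndarray]:
    """theta-chi motion map: one point per trajectory.

    The default per-trajectory statistic is log10 of the temporal MSD at
    ``lag_frames`` (per axis); alternatives are "net_displacement" and
    "D_alpha". Bin edges default to the 1st-99th percentile range of the
    pooled points; comparisons across conditions must pass shared edges.
    Returns (hist, chi marginal counts, theta marginal counts).
    """
    if not angulars:
        raise InvalidInputError("no trajectories to histogram")
    pts = np.array(
        [
            [
                _trajectory_statistic(a, "chi", axis_statistic, lag_frames),
                _trajectory_statistic(a, "theta", axis_statistic, lag_frames),
            ]
            for a in angulars
        ]
    )
    finite = np.isfinite(pts).all(axis=1)
    pts = pts[finite]
    if pts.size == 0:
        raise InvalidInputError("no finite statistic values to histogram")
    if chi_edges is None:
        lo, hi = np.percentile(pts[:, 0], [1, 99])
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        chi_edges = np.linspace(lo, hi, bins + 1)
    if theta_edges is None:
        lo, hi = np.percentile(pts[:, 1], [1, 99])
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        theta_edges = np.linspace(lo, hi, bins + 1)
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[chi_edges, theta_edges])
    hist = MotionHist2D(
        chi_edges=np.asarray(chi_edges),
        theta_edges=np.asarray(theta_edges),
        counts=counts,
        axis_statistic=f"{axis_statistic}(lag={lag_frames} frames)",
    )
    mchi, mtheta = hist.marginals()
    return hist, mchi, mtheta


def peak_and_fwhm(counts: np.ndarray, edges: np.ndarray) -> tuple[float, float]:
    """Peak position (3-point parabolic refinement) and FWHM of a 1-D histogram.

    The FWHM is measured by linear interpolation of the half-maximum
    crossings on each side of the peak; if a side never crosses (peak at the
    histogram edge) the crossing is clamped to that edge. A plateau maximum
    resolves to its leftmost bin. A single occupied bin yields FWHM = bin
    width by convention.
    """
    c = np.asarray(counts, dtype=float)
    e = np.asarray(edges, dtype=float)
    if len(c) < 3:
        raise InvalidInputError("need >= 3 bins")
    if not np.any(c > 0):
        raise InvalidInputError("histogram has no counts")
    centers = 0.5 * (e[:-1] + e[1:])
    width = e[1] - e[0]
    i = int(np.argmax(c))  # leftmost maximal bin on plateaus
    peak = centers[i]
    if 0 < i < len(c) - 1:
        y0, y1, y2 = c[i - 1], c[i], c[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            peak = centers[i] + 0.5 * width * (y0 - y2) / denom

    if np.count_nonzero(c) == 1:
        return float(peak), float(width)

    half = c[i] / 2.0
    # left crossing
    left = e[0]
    for j in range(i, 0, -1):
        if c[j - 1] < half <= c[j]:
            frac = (half - c[j - 1]) / (c[j] - c[j - 1])
            left = centers[j - 1] + frac * width
            break
    # right crossing
    right = e[-1]
    for j in range(i, len(c) - 1):
        if c[j] >= half > c[j + 1]:
            frac = (c[j] - half) / (c[j] - c[j + 1])
            right = centers[j] + frac * width
            break
    return float(peak), float(right - left)


def _check_shared_edges(a: MotionHist2D, b: MotionHist2D) -> None:
    if (
        a.chi_edges.shape != b.chi_edges.shape
        or a.theta_edges.shape != b.theta_edges.shape
        or not np.allclose(a.chi_edges, b.chi_edges)
        or not np.allclose(a.theta_edges, b.theta_edges)
    ):
        raise InvalidInputError("histograms must share bin edges (no resampling)")


def subtract_hists(hist_a: MotionHist2D, hist_b: MotionHist2D) -> np.ndarray:
    """Signed difference of unit-normalized densities (a minus b).

    The result sums to 0; positive mass marks bins enriched under condition a.
    """
    _check_shared_edges(hist_a, hist_b)
    return hist_a.density - hist_b.density


def superpose_hotspots(
    hists: Sequence[MotionHist2D], quantile: float = 0.90
) -> dict:
    """Hotspot bins (density above the given quantile of occupied bins) and
    their density-weighted centroids, per condition, plus pairwise centroid
    displacements (d_chi, d_theta)."""
    if not hists:
        raise InvalidInputError("no histograms")
    for h in hists[1:]:
        _check_shared_edges(hists[0], h)
    if not 0 <= quantile < 1:
        raise InvalidInputError("quantile must be in [0, 1)")
    results = []
    for h in hists:
        dens = h.density
        occupied = dens[dens > 0]
        if occupied.size == 0:
            raise InvalidInputError("empty histogram in hotspot superposition")
        thr = np.quantile(occupied, quantile)
        mask = dens >= thr
        chi_centers = 0.5 * (h.chi_edges[:-1] + h.chi_edges[1:])
        theta_centers = 0.5 * (h.theta_edges[:-1] + h.theta_edges[1:])
        w = dens * mask
        total = w.sum()
        centroid = (
            float((w.sum(axis=1) * chi_centers).sum() / total),
            float((w.sum(axis=0) * theta_centers).sum() / total),
        )
        results.append({"mask": mask, "centroid": centroid})
    displacements = {}
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            ci, cj = results[i]["centroid"], results[j]["centroid"]
            displacements[(i, j)] = (cj[0] - ci[0], cj[1] - ci[1])
    return {"hotspots": results, "centroid_displacements": displacements}
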