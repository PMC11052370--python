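"""Ground-truth-known synthetic DXB/DXT data.

No beamline data ship with this package, so every pipeline stage is exercised
against simulations whose generating parameters are the test oracle.

Physical model
--------------
A nanocrystal probe tethered to a protein undergoes rotational diffusion with
coefficient ``d_rot`` (rad^2/s) per angular axis, in the small-angle planar
approximation (independent tilt and azimuth axes; no full SO(3) treatment —
adequate for the sub-degree to few-degree motions of interest and it keeps
the chi/theta axes independent by construction).

* DXB (mono beam): the crystal's tilt modulates how close it sits to the
  Bragg condition. The diffracted rate into its ring pixel is
  ``mean_photons * exp(-tilt^2 / (2 w^2))`` with ``w`` the rocking half-width
  (a Gaussian acceptance standing in for mosaic spread + divergence; here an
  *effective* width — wide, because the probe wobbles on an antibody tether
  through a broad acceptance). Tilt follows a confined (Ornstein-Uhlenbeck)
  walk whose stationary spread equals ``w``: free diffusion would drift out
  of the acceptance for good, whereas a tethered probe revisits it — that is
  what makes blinking stationary. Short-time increments still have variance
  2 d_rot dt. The resulting pixel-intensity ACF has the closed form
  implemented in :func:`dxb_expected_acf`; it is nearly single-exponential
  with effective decay constant ~ 2 d_rot / w^2 (the exact effective rate is
  :func:`dxb_expected_decay_constant`, the correlation-time oracle).

* DXT (pink beam): each crystal produces a Laue spot; azimuthal motion moves
  the spot along the ring (chi) while tilt moves it radially (a tilt of
  delta deflects the reflected ray by 2 delta). Spots are born by a staggered
  arrival process, live geometric(lifetime_mean_frames) frames, and can be
  rendered into detector movies with a Gaussian PSF and Poisson noise.

Photon noise is Poisson only (photon-counting detector, no read noise).
All generators are reproducible given (seed, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .geometry import (
    ConfigError,
    DetectorGeometry,
    InvalidInputError,
    RingROI,
)
from .dxb import DecaySample
from .dxt import Spot, SpotTrajectory

__all__ = [
    "SimConfig",
    "dxb_protocol",
    "dxt_protocol",
    "simulate_orientation_walks",
    "simulate_confined_tilt",
    "render_dxb_movie",
    "dxb_expected_acf",
    "dxb_expected_decay_constant",
    "dxb_config_for_decay",
    "GroundTruthTrack",
    "simulate_laue_trajectories",
    "render_dxt_movie",
    "generate_decay_samples",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording.

    ``mixture`` optionally replaces the single ``d_rot`` with a two-population
    spec ``((d_rot_1, w_1), (d_rot_2, w_2))``, w_1 + w_2 = 1.
    """

    seed: int = 0
    n_frames: int = 2000
    frame_interval_s: float = 0.1
    d_rot: float = 0.011652  # rad^2/s; nominal ACF decay 2 d/w^2 ~ 0.085/s
    rocking_width_deg: float = 30.0
    mean_photons: float = 20.0
    background: float = 0.1  # expected counts/pixel/frame
    n_crystals: int = 200
    crystals_per_pixel: int = 1
    lifetime_mean_frames: float = 200.0
    psf_sigma_px: float = 1.2
    mixture: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if min(self.n_frames, self.n_crystals, self.crystals_per_pixel) <= 0:
            raise ConfigError("counts must be positive")
        if min(self.frame_interval_s, self.rocking_width_deg,
               self.mean_photons, self.lifetime_mean_frames) <= 0:
            raise ConfigError("rates and widths must be positive")
        if self.d_rot < 0 or self.background < 0:
            raise ConfigError("d_rot and background must be >= 0")
        if self.mixture is not None:
            (d1, w1), (d2, w2) = self.mixture
            if d1 < 0 or d2 < 0 or w1 < 0 or w2 < 0:
                raise ConfigError("mixture rates/weights must be >= 0")
            if not math.isclose(w1 + w2, 1.0):
                raise ConfigError("mixture weights must sum to 1")

    @property
    def rocking_width_rad(self) -> float:
        return math.radians(self.rocking_width_deg)

    def replace_with(self, **overrides) -> "SimConfig":
        return replace(self, **overrides)


def dxb_protocol(**overrides) -> SimConfig:
    """Standard DXB recording: 100 ms/frame, 2000 frames.

    The default ``d_rot`` puts the nominal ACF decay constant
    2 d_rot / w^2 at ~0.085/s, the scale measured for membrane-protein
    domains at this cadence.
    """
    return SimConfig(
        n_frames=2000, frame_interval_s=0.1, d_rot=0.011652,
        rocking_width_deg=30.0, mean_photons=20.0, background=0.1,
        n_crystals=200,
    ).replace_with(**overrides)


def dxt_protocol(**overrides) -> SimConfig:
    """Standard DXT recording: 12.5 ms/frame, 5000 frames.

    ``d_rot`` gives sub-degree angular drift over a typical spot lifetime so
    trajectories stay within the pink-beam acceptance band; a recording
    yields some hundreds of trajectories.
    """
    return SimConfig(
        n_frames=5000, frame_interval_s=0.0125, d_rot=5.0e-6,
        mean_photons=400.0, background=0.2, n_crystals=600,
        lifetime_mean_frames=200.0,
    ).replace_with(**overrides)


def simulate_orientation_walks(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Free planar orientation walks, shape (n_crystals, n_frames, 2) in degrees.

    Axis 0 is tilt, axis 1 azimuth; independent Gaussian increments with
    per-step variance 2 d_rot dt (small-angle regime), starting at 0.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    step_sd = math.sqrt(2.0 * cfg.d_rot * cfg.frame_interval_s)
    steps = rng.normal(0.0, step_sd, size=(cfg.n_crystals, cfg.n_frames, 2))
    steps[:, 0, :] = 0.0
    return np.degrees(np.cumsum(steps, axis=1))


def simulate_confined_tilt(
    n_steps: int,
    dt: float,
    d_rot: float,
    sigma_rad: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck tilt walk (radians).

    Relaxation rate lambda = d_rot / sigma^2 (Einstein relation), exact
    discretisation, initial value drawn from the stationary distribution.
    Increment variance approaches 2 d_rot dt for dt << 1/lambda.
    """
    return _confined_tilt_batch(1, n_steps, dt, d_rot, sigma_rad, rng)[0]


def _confined_tilt_batch(
    n_walks: int,
    n_steps: int,
    dt: float,
    d_rot: float,
    sigma_rad: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised stationary OU walks, shape (n_walks, n_steps), radians."""
    from scipy.signal import lfilter

    lam = d_rot / sigma_rad**2
    rho = math.exp(-lam * dt)
    innov_sd = sigma_rad * math.sqrt(1.0 - rho * rho)
    x0 = rng.normal(0.0, sigma_rad, size=(n_walks, 1))
    noise = rng.normal(0.0, innov_sd, size=(n_walks, n_steps - 1))
    driven = np.concatenate([x0, noise], axis=1)
    # AR(1): x_t = rho x_{t-1} + e_t with x_0 supplied as the first "shock"
    return lfilter([1.0], [1.0, -rho], driven, axis=1)


def _crystal_d_rots(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.mixture is None:
        return np.full(cfg.n_crystals, cfg.d_rot)
    (d1, w1), (d2, w2) = cfg.mixture
    pick = rng.random(cfg.n_crystals) < w1
    return np.where(pick, d1, d2)


def render_dxb_movie(
    cfg: SimConfig,
    roi: RingROI,
    geom: DetectorGeometry,
    *,
    rng: np.random.Generator | None = None,
    return_truth: bool = False,
    freeze_after_frame: int | None = None,
):
    """Poisson-sampled blinking movie on the full detector.

    ``freeze_after_frame`` holds every crystal's tilt at its value from that
    frame onward (all motion stops; photon noise continues) — the scenario a
    radiation-damage check must flag.

    ``n_crystals`` distinct ROI pixels are each illuminated by
    ``crystals_per_pixel`` independent nanocrystals (a ring pixel integrates
    the ensemble of probes whose azimuth maps onto it; mono-beam spots do not
    travel). Each crystal blinks with expected rate
    mean_photons * exp(-tilt^2 / (2 w^2)) on top of a flat background.
    Returns a (n_frames, n_rows, n_cols) uint32 stack, plus a ground-truth
    dict when ``return_truth`` (occupied pixels, per-pixel d_rot, and the
    nominal/effective decay constants of the generating model).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.n_crystals > len(roi.pixels):
        raise ConfigError(
            f"n_crystals={cfg.n_crystals} exceeds ROI size {len(roi.pixels)}"
        )
    idx = rng.choice(len(roi.pixels), size=cfg.n_crystals, replace=False)
    pixels = roi.pixels[idx]
    d_rots = _crystal_d_rots(cfg, rng)
    w = cfg.rocking_width_rad
    k = cfg.crystals_per_pixel
    rates = np.zeros((cfg.n_frames, cfg.n_crystals))
    for d in np.unique(d_rots):
        cols = np.nonzero(d_rots == d)[0]
        tilts = _confined_tilt_batch(
            len(cols) * k, cfg.n_frames, cfg.frame_interval_s, float(d), w, rng
        ).reshape(len(cols), k, cfg.n_frames)
        if freeze_after_frame is not None:
            tilts[:, :, freeze_after_frame:] = tilts[
                :, :, freeze_after_frame - 1 : freeze_after_frame
            ]
        pix_rate = (
            cfg.mean_photons * np.exp(-(tilts**2) / (2.0 * w * w))
        ).sum(axis=1)
        rates[:, cols] = pix_rate.T
    stack = rng.poisson(
        cfg.background, size=(cfg.n_frames, geom.n_rows, geom.n_cols)
    ).astype(np.uint32)
    signal = rng.poisson(rates).astype(np.uint32)
    stack[:, pixels[:, 0], pixels[:, 1]] += signal
    if not return_truth:
        return stack
    truth = {
        "crystal_pixels": pixels,
        "d_rot": d_rots,
        "nominal_decay_constant": 2.0 * d_rots / w**2,
        "expected_rates": rates,
    }
    return stack, truth


def dxb_expected_acf(cfg: SimConfig, lags_s: np.ndarray) -> np.ndarray:
    """Closed-form ACF of the blinking model at positive lags.

    For one OU tilt with stationary variance sigma^2 = w^2 (a = sigma^2/w^2
    = 1) and Gaussian acceptance, the bivariate-normal integral gives

        G1(tau) = <L(t) L(t+tau)> = M^2 / sqrt((1+a)^2 - a^2 rho^2),
        rho = e^(-lam tau),  lam = d_rot / sigma^2,

    with single-crystal mean m1 = M / sqrt(1+a) and zero-lag second moment
    G1(0) = M^2 / sqrt(1+2a). A pixel integrating n independent crystals
    plus flat background bg has

        <S(t)S(t+tau)> = n G1(tau) + n(n-1) m1^2 + 2 n m1 bg + bg^2,
        <I^2> = <S^2> + <S>          (Poisson shot noise at zero lag).

    This is the analytic correlation-time oracle for the rendered movies.
    """
    tau = np.asarray(lags_s, dtype=float)
    m, bg = cfg.mean_photons, cfg.background
    n = cfg.crystals_per_pixel
    a = 1.0  # stationary tilt spread equals the rocking width
    w = cfg.rocking_width_rad
    lam = cfg.d_rot / w**2
    u = np.exp(-2.0 * lam * tau)
    m1 = m / math.sqrt(1.0 + a)
    g1 = m**2 / np.sqrt((1.0 + a) ** 2 - a**2 * u)
    g1_0 = m**2 / math.sqrt(1.0 + 2.0 * a)
    cross = n * (n - 1) * m1**2 + 2.0 * n * m1 * bg + bg**2
    num = n * g1 + cross
    den = n * g1_0 + cross + n * m1 + bg
    return num / den


def dxb_expected_decay_constant(
    cfg: SimConfig, max_lag_frames: int | None = None
) -> float:
    """Effective single-exponential decay constant of the analytic ACF.

    Fits k + A exp(-T tau) to the noiseless closed-form curve on the same lag
    grid the pipeline uses (default n_frames // 4); close to the nominal
    2 d_rot / w^2, with the curvature of the exact model folded in.
    """
    mlag = max_lag_frames if max_lag_frames is not None else cfg.n_frames // 4
    tau = np.arange(1, mlag + 1) * cfg.frame_interval_s
    y = dxb_expected_acf(cfg, tau)
    t_nom = 2.0 * cfg.d_rot / cfg.rocking_width_rad**2
    popt, _ = optimize.curve_fit(
        lambda t, k, A, T: k + A * np.exp(-T * t),
        tau, y, p0=[float(y[-1]), float(y[0] - y[-1]), t_nom], maxfev=20000,
    )
    return float(popt[2])


def dxb_config_for_decay(
    t_decay: float,
    max_lag_frames: int | None = None,
    **overrides,
) -> SimConfig:
    """DXB protocol config whose *effective* ACF decay constant equals
    ``t_decay`` (1/s).

    The blinking model's intensity ACF is near- but not exactly exponential,
    so the rotational diffusion coefficient is calibrated by root-finding on
    :func:`dxb_expected_decay_constant` (monotone in d_rot) rather than by
    inverting the nominal small-correlation rate 2 d_rot / w^2.
    """
    base = dxb_protocol(**overrides)
    t_nom = t_decay * base.rocking_width_rad**2 / 2.0

    def objective(d: float) -> float:
        return (
            dxb_expected_decay_constant(
                base.replace_with(d_rot=d), max_lag_frames
            )
            - t_decay
        )

    from scipy.optimize import brentq

    d_star = brentq(objective, t_nom * 0.2, t_nom * 2.0, xtol=t_nom * 1e-6)
    return base.replace_with(d_rot=float(d_star))


@dataclass(frozen=True)
class GroundTruthTrack:
    """One simulated Laue-spot trajectory with its generating angular walk."""

    track_id: int
    ring_label: str
    birth_frame: int
    frames: np.ndarray
    chi_deg: np.ndarray  # absolute azimuth of the crystal, degrees
    tilt_deg: np.ndarray  # tilt relative to the nominal Bragg condition
    rows: np.ndarray
    cols: np.ndarray
    radius_px: np.ndarray

    @property
    def lifetime_frames(self) -> int:
        return len(self.frames)

    def to_spot_trajectory(self, geom: DetectorGeometry,
                           intensity: float = 1.0) -> SpotTrajectory:
        """Noise-free SpotTrajectory for driving the pipeline directly."""
        cr, cc = geom.beam_center_px
        spots = tuple(
            Spot(
                frame=int(f),
                position_px=(float(r), float(c)),
                intensity=intensity,
                radius_px=float(rad),
                azimuth_deg=math.degrees(math.atan2(r - cr, c - cc)),
            )
            for f, r, c, rad in zip(self.frames, self.rows, self.cols, self.radius_px)
        )
        return SpotTrajectory(spots=spots, ring_label=self.ring_label,
                              trajectory_id=self.track_id)


# usable azimuth arcs (degrees) keeping ring spots on the wide detector axis
_ARCS = ((-30.0, 30.0), (150.0, 210.0))


def _azimuth_slots(n_slots: int) -> np.ndarray:
    per_arc = n_slots // len(_ARCS)
    slots = []
    for lo, hi in _ARCS:
        slots.extend(np.linspace(lo, hi, per_arc, endpoint=False))
    return np.array(slots)


def simulate_laue_trajectories(
    cfg: SimConfig,
    rings: Sequence[RingROI],
    geom: DetectorGeometry,
    *,
    rng: np.random.Generator | None = None,
    ensure_separation: bool = True,
    slots_per_ring: int = 20,
) -> list[GroundTruthTrack]:
    """Ground-truth Laue-spot trajectories on two well-separated rings.

    Spots are born at staggered frames (the first at frame 0), live
    geometric(lifetime_mean_frames) frames truncated at the end of the
    record, and perform independent chi (azimuth) and tilt walks with
    per-step variance 2 d_rot dt. The azimuth moves the spot along its ring;
    tilt moves it radially via r = L tan(2 theta_B + 2 tilt) / pitch.

    With ``ensure_separation`` each ring offers ``slots_per_ring`` azimuth
    slots and a track occupies one for its whole life, which keeps the
    regime non-crossing for tracker validation; without it azimuths are
    drawn uniformly on the usable arcs.
    """
    if len(rings) != 2:
        raise InvalidInputError("need exactly two rings (one per probe)")
    if rings[0].label == rings[1].label:
        raise InvalidInputError("rings must be distinct")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_frames
    cr, cc = geom.beam_center_px
    step_sd = math.sqrt(2.0 * cfg.d_rot * cfg.frame_interval_s)

    births = np.linspace(0, max(1, int(0.7 * n)), cfg.n_crystals, endpoint=False)
    births = births.astype(int)
    births[0] = 0
    slots = {r.label: list(_azimuth_slots(slots_per_ring)) for r in rings}
    occupied: dict[str, list[tuple[int, float]]] = {r.label: [] for r in rings}

    tracks: list[GroundTruthTrack] = []
    for tid in range(cfg.n_crystals):
        ring = rings[int(rng.random() < 0.5)]
        birth = int(births[tid])
        if math.isinf(cfg.lifetime_mean_frames):
            life = n - birth
        else:
            life = int(rng.geometric(1.0 / cfg.lifetime_mean_frames))
            life = min(max(life, 2), n - birth)
        if life < 2:
            continue
        if ensure_separation:
            # free a slot: slots whose occupant track has already died
            occ = occupied[ring.label]
            occupied[ring.label] = [
                (end, az) for end, az in occ if end > birth
            ]
            free = [
                az for az in slots[ring.label]
                if all(abs(az - b) > 1e-9 for _, b in occupied[ring.label])
            ]
            if not free:
                continue  # recording saturated; spot not observable
            az0 = float(free[int(rng.integers(len(free)))])
            occupied[ring.label].append((birth + life, az0))
        else:
            lo, hi = _ARCS[int(rng.random() < 0.5)]
            az0 = float(rng.uniform(lo, hi))

        steps = rng.normal(0.0, step_sd, size=(life, 2))
        steps[0] = 0.0
        chi = math.radians(az0) + np.cumsum(steps[:, 0])
        tilt = np.cumsum(steps[:, 1])
        # nominal Bragg angle from the ring's central radius
        two_theta_b = math.atan(
            ring.radius_px * geom.pixel_pitch_mm / geom.distance_mm
        )
        two_theta = two_theta_b + 2.0 * tilt
        radius = geom.distance_mm * np.tan(two_theta) / geom.pixel_pitch_mm
        rows = cr + radius * np.sin(chi)
        cols = cc + radius * np.cos(chi)
        frames = np.arange(birth, birth + life)
        on = (
            (rows >= 1) & (rows <= geom.n_rows - 2)
            & (cols >= 1) & (cols <= geom.n_cols - 2)
        )
        if not on.all():
            last = int(np.argmin(on))  # truncate at first off-detector frame
            if last < 2:
                continue
            frames, chi, tilt = frames[:last], chi[:last], tilt[:last]
            radius, rows, cols = radius[:last], rows[:last], cols[:last]
        tracks.append(
            GroundTruthTrack(
                track_id=tid,
                ring_label=ring.label,
                birth_frame=birth,
                frames=frames,
                chi_deg=np.degrees(chi),
                tilt_deg=np.degrees(tilt),
                rows=rows,
                cols=cols,
                radius_px=radius,
            )
        )
    return tracks


def render_dxt_movie(
    tracks: Sequence[GroundTruthTrack],
    cfg: SimConfig,
    geom: DetectorGeometry,
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Poisson movie of Gaussian-PSF spots over a flat background.

    Each spot deposits ``mean_photons`` expected counts integrated over a
    Gaussian PSF of width ``psf_sigma_px`` at its sub-pixel position.
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    sig = cfg.psf_sigma_px
    half = max(3, int(math.ceil(4 * sig)))
    by_frame: dict[int, list[tuple[float, float]]] = {}
    for tr in tracks:
        for f, r, c in zip(tr.frames, tr.rows, tr.cols):
            by_frame.setdefault(int(f), []).append((r, c))
    stack = np.empty((cfg.n_frames, geom.n_rows, geom.n_cols), dtype=np.uint32)
    lam = np.empty((geom.n_rows, geom.n_cols))
    for f in range(cfg.n_frames):
        lam[:] = cfg.background
        for r, c in by_frame.get(f, ()):
            r0, r1 = int(r) - half, int(r) + half + 1
            c0, c1 = int(c) - half, int(c) + half + 1
            r0c, c0c = max(r0, 0), max(c0, 0)
            r1c, c1c = min(r1, geom.n_rows), min(c1, geom.n_cols)
            rows = np.arange(r0c, r1c)[:, None]
            cols = np.arange(c0c, c1c)[None, :]
            g = np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2 * sig * sig))
            lam[r0c:r1c, c0c:c1c] += cfg.mean_photons * g / (2 * math.pi * sig * sig)
        stack[f] = rng.poisson(lam)
    return stack


def generate_decay_samples(
    mixture: tuple[tuple[float, float, float], tuple[float, float, float]],
    n: int,
    seed: int,
    *,
    condition: str = "",
    domain_label: str = "",
) -> DecaySample:
    """IID draws from a two-Gaussian decay-constant mixture truncated at 0.

    ``mixture`` is ((mu1, sigma1, w1), (mu2, sigma2, w2)) with w1 + w2 = 1.
    Negative draws are resampled (truncation at 0: decay constants are
    positive).
    """
    (mu1, s1, w1), (mu2, s2, w2) = mixture
    if not math.isclose(w1 + w2, 1.0):
        raise ConfigError("mixture weights must sum to 1")
    if min(s1, s2) <= 0 or min(w1, w2) < 0:
        raise ConfigError("mixture sigmas must be > 0 and weights >= 0")
    rng = np.random.default_rng(seed)
    comp = rng.random(n) >= w1  # False -> component 1
    mu = np.where(comp, mu2, mu1)
    sd = np.where(comp, s2, s1)
    vals = rng.normal(mu, sd)
    bad = vals <= 0
    while bad.any():
        vals[bad] = rng.normal(mu[bad], sd[bad])
        bad = vals <= 0
    return DecaySample(values=vals, condition=condition, domain_label=domain_label)
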