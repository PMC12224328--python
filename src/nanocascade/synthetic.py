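"""Seeded synthetic-data generators.

Every input the analysis pipeline consumes can be generated here with
the statistical structure the analyses assume: cascade assay
time-courses, 2D Brownian particle tracks with optional drift, co-flow
fluorescence profiles with a lateral displacement, persistent-random-walk
cell tracks, linearly closing gap masks, exponential growth series, and
QPI phase images.  Each generator is a pure function of its arguments
and a seed: identical inputs give identical outputs.

Default conditions mirror the assay protocols the analyses target:
particle video at 25 fps for 60 s, cell imaging every 30 min for 24 h,
a 500 μm starting gap, 0.1 mg/mL catalyst and 3/6/9-min incubations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .cells import CellTrack, GrowthSeries, PhaseMap
from .kinetics import AssayTimeCourse, CascadeModel, simulate_cascade
from .motion import IntensityProfile, Trajectory

__all__ = [
    "NoiseSpec",
    "TrackSimSpec",
    "CellSimSpec",
    "gen_cascade_timecourse",
    "gen_brownian_tracks",
    "gen_flow_profiles",
    "gen_cell_tracks",
    "gen_gap_masks",
    "gen_growth_series",
    "gen_phase_image",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description.

    ``kind`` is ``"additive-gaussian"`` or ``"none"``.  ``sd`` is the
    standard deviation in signal units, or, with ``relative=True``, as
    a fraction of the local noiseless value (a multiplicative-
    equivalent additive perturbation).  ``kind="none"`` reproduces the
    noiseless model exactly.
    """

    kind: str = "none"
    sd: float = 0.0
    relative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("additive-gaussian", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.sd == 0:
            return np.asarray(values, dtype=float).copy()
        values = np.asarray(values, dtype=float)
        scale = self.sd * np.abs(values) if self.relative else self.sd
        return values + rng.normal(0.0, 1.0, size=values.shape) * scale


NO_NOISE = NoiseSpec()


@dataclass(frozen=True)
class TrackSimSpec:
    """Brownian track ensemble: D in μm²/s, frame_rate Hz, duration s, drift μm/s."""

    n_tracks: int = 250
    diffusion_coeff: float = 21.19
    frame_rate: float = 25.0
    duration: float = 60.0
    drift_velocity: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.diffusion_coeff < 0:
            raise ValueError("diffusion_coeff must be >= 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class CellSimSpec:
    """Persistent-random-walk cell ensemble: speed μm/h, persistence h, sampling h."""

    n_cells: int = 30
    mean_speed: float = 10.0
    persistence_time: float = 2.0
    sampling_interval: float = 0.5
    duration: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be >= 0")
        if self.persistence_time <= 0:
            raise ValueError("persistence_time must be > 0")
        if self.sampling_interval <= 0 or self.sampling_interval > self.duration:
            raise ValueError("need 0 < sampling_interval <= duration")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent per-generator stream derived from one top-level seed."""
    tag = zlib.crc32(stream.encode())  # stable across processes, unlike hash()
    return np.random.default_rng(np.random.SeedSequence((seed, tag)))


def gen_cascade_timecourse(
    model: CascadeModel,
    catalyst_conc: float,
    glucose0: float,
    h2o2_0: float,
    times,
    noise: NoiseSpec = NO_NOISE,
    seed: int = 0,
    glucose_depletion: bool = True,
) -> AssayTimeCourse:
    """Sample the cascade ODE at assay time points, with measurement noise.

    Times are minutes, strictly increasing, all >= 0 (a t=0 point is
    prepended automatically if absent so initial-rate estimation has
    its origin).  Noisy concentrations are clipped at zero.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0) or np.any(times < 0):
        raise ValueError("times must be strictly increasing and >= 0")
    if glucose0 < 0 or h2o2_0 < 0:
        raise ValueError("initial concentrations must be >= 0")
    if times[0] != 0.0:
        times = np.concatenate([[0.0], times])
    if glucose0 == 0 and h2o2_0 == 0:
        glucose = np.zeros_like(times)
        h2o2 = np.zeros_like(times)
    else:
        _, glucose, h2o2 = simulate_cascade(
            model, catalyst_conc, glucose0, h2o2_0,
            t_end=float(times[-1]) if times[-1] > 0 else 1e-6,
            glucose_depletion=glucose_depletion, t_eval=times,
        )
    rng = _rng(seed, "cascade-timecourse")
    glucose = np.clip(noise.apply(glucose, rng), 0.0, None)
    h2o2 = np.clip(noise.apply(h2o2, rng), 0.0, None)
    return AssayTimeCourse(times=times, glucose=glucose, h2o2=h2o2, catalyst_conc=catalyst_conc)


def gen_brownian_tracks(spec: TrackSimSpec) -> list[Trajectory]:
    """Simulate 2D Brownian trajectories with optional uniform drift.

    Each track has ``duration·frame_rate + 1`` points; per-axis frame
    displacements are Gaussian with variance 2·D·Δt plus a
    deterministic drift·Δt offset.
    """
    rng = _rng(spec.seed, "brownian-tracks")
    dt = 1.0 / spec.frame_rate
    n_steps = int(round(spec.duration * spec.frame_rate))
    times = dt * np.arange(n_steps + 1)
    sigma = np.sqrt(2.0 * spec.diffusion_coeff * dt)
    vx, vy = spec.drift_velocity
    tracks = []
    for i in range(spec.n_tracks):
        steps = rng.normal(0.0, sigma, size=(n_steps, 2)) if sigma > 0 else np.zeros((n_steps, 2))
        steps[:, 0] += vx * dt
        steps[:, 1] += vy * dt
        path = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        tracks.append(Trajectory(track_id=i, times=times, x=path[:, 0], y=path[:, 1]))
    return tracks


def gen_flow_profiles(
    true_shift: float,
    channel_width: float = 3000.0,
    stream_width: float = 1000.0,
    smoothing_length: float = 150.0,
    noise: NoiseSpec = NO_NOISE,
    grid_spacing: float = 5.0,
    seed: int = 0,
) -> tuple[IntensityProfile, IntensityProfile]:
    """Synthesize a (control, shifted) pair of co-flow intensity profiles.

    The base profile is a central plug of ``stream_width`` whose edges
    are diffusion-broadened into error functions of scale
    ``smoothing_length``; the condition profile is the base translated
    laterally by ``true_shift`` (μm, positive toward the solute inlet
    side — positions increase toward the solute).  Both profiles are
    normalized to unit maximum.
    """
    if smoothing_length <= 0:
        raise ValueError("smoothing_length must be > 0")
    if abs(true_shift) >= channel_width / 2:
        raise ValueError("|true_shift| must be < channel_width/2")
    if stream_width >= channel_width:
        raise ValueError("stream_width must be < channel_width")
    x = np.arange(0.0, channel_width + grid_spacing / 2, grid_spacing)
    center = channel_width / 2.0

    def plug(positions: np.ndarray, offset: float) -> np.ndarray:
        lo = center + offset - stream_width / 2.0
        hi = center + offset + stream_width / 2.0
        s = np.sqrt(2.0) * smoothing_length
        return 0.5 * (special.erf((positions - lo) / s) - special.erf((positions - hi) / s))

    rng = _rng(seed, "flow-profiles")
    profiles = []
    for offset in (0.0, true_shift):
        inten = np.clip(noise.apply(plug(x, offset), rng), 0.0, None)
        profiles.append(IntensityProfile(positions=x.copy(), intensity=inten))
    control, shifted = profiles
    return control, shifted


def _vonmises_kappa(mean_cos: float) -> float:
    """Concentration κ of a von Mises step-heading law with ⟨cos Δθ⟩ = mean_cos."""
    if mean_cos <= 0:
        return 0.0
    if mean_cos >= 1.0 - 1e-12:
        return np.inf
    if mean_cos > 0.999:
        return 1.0 / (2.0 * (1.0 - mean_cos))  # large-κ asymptotic
    f = lambda k: special.i1e(k) / special.i0e(k) - mean_cos
    return float(optimize.brentq(f, 1e-8, 1e8))


def gen_cell_tracks(spec: CellSimSpec) -> list[CellTrack]:
    """Simulate persistent-random-walk cell tracks.

    Fixed step length ``mean_speed·Δt``; heading increments are von
    Mises with concentration chosen so that the heading autocorrelation
    decays as exp(−Δt/persistence_time) — the standard exponential
    decorrelation of a persistent random walk.
    """
    rng = _rng(spec.seed, "cell-tracks")
    dt = spec.sampling_interval
    n_steps = int(round(spec.duration / dt))
    times = dt * np.arange(n_steps + 1)
    step = spec.mean_speed * dt
    kappa = _vonmises_kappa(np.exp(-dt / spec.persistence_time))
    tracks = []
    for i in range(spec.n_cells):
        heading0 = rng.uniform(0.0, 2.0 * np.pi)
        if np.isinf(kappa):
            increments = np.zeros(n_steps)
        else:
            increments = rng.vonmises(0.0, kappa, size=n_steps) if kappa > 0 else rng.uniform(
                -np.pi, np.pi, size=n_steps
            )
        headings = heading0 + np.concatenate([[0.0], np.cumsum(increments[:-1])])
        dx = step * np.cos(headings)
        dy = step * np.sin(headings)
        x = np.concatenate([[0.0], np.cumsum(dx)])
        y = np.concatenate([[0.0], np.cumsum(dy)])
        tracks.append(CellTrack(cell_id=i, times=times, x=x, y=y))
    return tracks


def gen_gap_masks(
    initial_gap: float = 500.0,
    closure_rate: float = 25.0,
    times=(0.0, 6.0, 12.0, 18.0, 24.0),
    frame: tuple[float, float] = (1500.0, 1500.0),
    pixel_size: float = 5.0,
    edge_roughness: float = 0.0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Binary masks (1 = gap) of a central vertical gap closing linearly.

    Gap width at time t is ``max(0, initial_gap − closure_rate·t)``.
    ``edge_roughness`` perturbs each row's edge positions with Gaussian
    noise smoothed over 10 rows, producing a ragged migration front.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    width, height = frame
    if initial_gap > width:
        raise ValueError("initial_gap must fit inside the frame width")
    n_cols = int(round(width / pixel_size))
    n_rows = int(round(height / pixel_size))
    cols = (np.arange(n_cols) + 0.5) * pixel_size
    rng = _rng(seed, "gap-masks")
    masks = []
    for t in np.asarray(times, dtype=float):
        gap = max(0.0, initial_gap - closure_rate * t)
        if gap == 0.0:
            masks.append(np.zeros((n_rows, n_cols), dtype=np.uint8))
            continue
        left = (width - gap) / 2.0
        right = (width + gap) / 2.0
        if edge_roughness > 0:
            kernel = np.ones(10) / 10.0
            def rough(edge):
                noise = rng.normal(0.0, edge_roughness, size=n_rows + 9)
                return edge + np.convolve(noise, kernel, mode="valid") * np.sqrt(10)
            left_edge = rough(left)
            right_edge = rough(right)
        else:
            left_edge = np.full(n_rows, left)
            right_edge = np.full(n_rows, right)
        mask = (cols[None, :] >= left_edge[:, None]) & (cols[None, :] < right_edge[:, None])
        masks.append(mask.astype(np.uint8))
    return masks


def gen_growth_series(
    n0: float,
    doubling_time: float,
    times,
    noise: NoiseSpec = NO_NOISE,
    seed: int = 0,
    kind: str = "count",
) -> GrowthSeries:
    """Exponential growth ``n0·2^(t/doubling_time)`` with measurement noise.

    Values are floored at a small positive fraction of ``n0`` so that
    log-domain fitting is always defined.
    """
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if doubling_time <= 0:
        raise ValueError("doubling_time must be > 0")
    times = np.asarray(times, dtype=float)
    clean = n0 * np.exp2(times / doubling_time)
    rng = _rng(seed, "growth-series")
    values = np.maximum(noise.apply(clean, rng), 1e-6 * n0)
    return GrowthSeries(times=times, values=values, kind=kind)


def gen_phase_image(
    cells: list[tuple[tuple[float, float], float, float]],
    wavelength: float = 0.65,
    alpha: float = 0.18,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 1.0,
) -> PhaseMap:
    """Synthesize a QPI phase image from disc-shaped cells.

    Each cell is ``((cx, cy) μm, radius μm, dry-mass density pg/μm²)``;
    inside a disc the phase is φ = 2π·α·m/λ (the dry-mass relation
    inverted), and overlapping discs add their phases.
    """
    if alpha <= 0 or wavelength <= 0:
        raise ValueError("alpha and wavelength must be > 0")
    phase = np.zeros(shape, dtype=float)
    rows = (np.arange(shape[0]) + 0.5) * pixel_size
    cols = (np.arange(shape[1]) + 0.5) * pixel_size
    yy, xx = np.meshgrid(rows, cols, indexing="ij")
    for (cx, cy), radius, density in cells:
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        phase[inside] += 2.0 * np.pi * alpha * density / wavelength
    return PhaseMap(phase=phase, wavelength=wavelength, alpha=alpha, pixel_size=pixel_size)
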