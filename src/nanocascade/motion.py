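"""Nanoparticle trajectory analytics.

Drift correction, time-averaged mean squared displacement (MSD),
linear MSD fits to an effective diffusion coefficient, enhancement
percentages, and lateral-shift quantification of microfluidic co-flow
fluorescence profiles.

Conventions: positions in μm, time in seconds; tracks are in-plane, so
MSD(τ) = 4·D·τ for Brownian motion and the fitted slope is divided by 4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Trajectory",
    "MSDCurve",
    "DiffusionFit",
    "IntensityProfile",
    "drift_correct",
    "compute_msd",
    "fit_diffusion",
    "percent_enhancement",
    "profile_shift",
]


@dataclass
class Trajectory:
    """A time-stamped 2D particle path (times s, positions μm)."""

    track_id: int | str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.times) < 2:
            raise ValueError(f"track {self.track_id}: need >= 2 points")
        if self.times.shape != self.x.shape or self.x.shape != self.y.shape:
            raise ValueError(f"track {self.track_id}: times/x/y length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"track {self.track_id}: times must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError(f"track {self.track_id}: non-finite positions")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class MSDCurve:
    """Ensemble-mean time-averaged MSD vs lag.

    ``track_msds`` (n_tracks × n_lags, NaN where a track is too short)
    preserves the per-track curves so downstream fits can quote
    between-track uncertainty.
    """

    lags: np.ndarray
    mean_msd: np.ndarray
    sem: np.ndarray
    n_contributing: np.ndarray
    track_msds: np.ndarray | None = None


@dataclass
class DiffusionFit:
    """Effective diffusion coefficient from a linear MSD fit (2D: slope/4)."""

    d_eff: float
    ci95: tuple[float, float]
    intercept: float
    fit_window: float
    dimensionality: int = 2
    negative_slope: bool = False


@dataclass
class IntensityProfile:
    """Normalized fluorescence intensity vs lateral position across a channel (μm)."""

    positions: np.ndarray
    intensity: np.ndarray
    analysis_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.positions.shape != self.intensity.shape:
            raise ValueError("positions/intensity length mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        peak = self.intensity.max()
        if peak > 0:
            self.intensity = np.clip(self.intensity, 0.0, None) / peak

    @property
    def grid_spacing(self) -> float:
        return float(np.median(np.diff(self.positions)))


def _frame_index(tracks: list[Trajectory]) -> tuple[np.ndarray, list[np.ndarray]]:
    """Map every timestamp onto a common frame clock shared by all tracks."""
    all_times = np.unique(np.concatenate([t.times for t in tracks]))
    idx = [np.searchsorted(all_times, t.times) for t in tracks]
    return all_times, idx


def drift_correct(tracks: list[Trajectory]) -> list[Trajectory]:
    """Remove common (ensemble-mean) frame-to-frame motion from all tracks.

    The per-frame drift increment is the mean displacement over tracks
    present in both of two consecutive frames; increments accumulate
    into a drift path subtracted from every trajectory.  Frames with
    fewer than 3 simultaneous displacement observations get their
    increment linearly interpolated from neighboring frames (warned).
    A single track is returned unchanged (drift is unidentifiable).
    """
    if not tracks:
        raise ValueError("no tracks given")
    if len(tracks) == 1:
        warnings.warn("single track: drift unidentifiable, returned unchanged", stacklevel=2)
        return list(tracks)
    frame_times, idx = _frame_index(tracks)
    n_frames = len(frame_times)
    sum_dx = np.zeros(n_frames - 1)
    sum_dy = np.zeros(n_frames - 1)
    counts = np.zeros(n_frames - 1, dtype=int)
    for tr, fi in zip(tracks, idx):
        consecutive = np.diff(fi) == 1
        at = fi[:-1][consecutive]
        np.add.at(sum_dx, at, np.diff(tr.x)[consecutive])
        np.add.at(sum_dy, at, np.diff(tr.y)[consecutive])
        np.add.at(counts, at, 1)
    good = counts >= 3
    with np.errstate(invalid="ignore"):
        inc_x = np.where(good, sum_dx / np.maximum(counts, 1), np.nan)
        inc_y = np.where(good, sum_dy / np.maximum(counts, 1), np.nan)
    if not good.all():
        warnings.warn(
            f"{int((~good).sum())} frame transitions have < 3 simultaneous tracks; "
            "drift interpolated there",
            stacklevel=2,
        )
        pos = np.arange(n_frames - 1)
        if good.any():
            inc_x = np.interp(pos, pos[good], inc_x[good])
            inc_y = np.interp(pos, pos[good], inc_y[good])
        else:
            inc_x = np.zeros(n_frames - 1)
            inc_y = np.zeros(n_frames - 1)
    drift_x = np.concatenate([[0.0], np.cumsum(inc_x)])
    drift_y = np.concatenate([[0.0], np.cumsum(inc_y)])
    out = []
    for tr, fi in zip(tracks, idx):
        out.append(
            Trajectory(
                track_id=tr.track_id,
                times=tr.times.copy(),
                x=tr.x - drift_x[fi],
                y=tr.y - drift_y[fi],
            )
        )
    return out


def compute_msd(tracks: list[Trajectory], max_lag: float) -> MSDCurve:
    """Ensemble-mean time-averaged MSD over all ordered point pairs.

    Per track, MSD(τ=kΔt) averages |r(t+τ)−r(t)|² over every start
    point; the ensemble curve is the unweighted mean over tracks with
    SEM across tracks.  Tracks are assumed uniformly sampled; the lag
    grid is the multiples of the (common) frame interval up to
    ``max_lag``.
    """
    if not tracks:
        raise ValueError("no tracks given")
    dt = float(np.median(np.diff(tracks[0].times)))
    max_k = int(round(max_lag / dt))
    if max_k < 1:
        raise ValueError("max_lag shorter than one frame interval")
    shortest = min(len(t.times) for t in tracks) - 1
    if max_k > shortest:
        raise ValueError(
            f"max_lag {max_lag} s exceeds shortest track ({shortest * dt:.3f} s)"
        )
    lags = dt * np.arange(1, max_k + 1)
    per_track = np.full((len(tracks), max_k), np.nan)
    for i, tr in enumerate(tracks):
        for k in range(1, max_k + 1):
            dx = tr.x[k:] - tr.x[:-k]
            dy = tr.y[k:] - tr.y[:-k]
            per_track[i, k - 1] = np.mean(dx * dx + dy * dy)
    n = np.sum(np.isfinite(per_track), axis=0)
    mean = np.nanmean(per_track, axis=0)
    if len(tracks) > 1:
        sem = np.nanstd(per_track, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    else:
        sem = np.zeros_like(mean)
    return MSDCurve(lags=lags, mean_msd=mean, sem=sem, n_contributing=n, track_msds=per_track)


def fit_diffusion(curve: MSDCurve, fit_window: float = 1.0) -> DiffusionFit:
    """Linear fit of mean MSD over lags in ``(0, fit_window]``; D = slope/4.

    The intercept is free (it absorbs static/dynamic localization
    offsets).  When per-track MSD curves are available the slope's
    standard error comes from the between-track scatter of per-track
    slopes (a t-interval over tracks); otherwise from the ordinary
    residual-based OLS formula.  A negative slope is reported as-is
    with ``negative_slope=True``, never clamped.
    """
    sel = curve.lags <= fit_window + 1e-12
    if np.sum(sel) < 3:
        raise ValueError("need >= 3 lags inside the fit window")
    tau = curve.lags[sel]
    msd = curve.mean_msd[sel]
    design = np.column_stack([np.ones_like(tau), tau])
    coef, *_ = np.linalg.lstsq(design, msd, rcond=None)
    intercept, slope = coef
    if curve.track_msds is not None:
        sub = curve.track_msds[:, sel]
        complete = np.all(np.isfinite(sub), axis=1)
        sub = sub[complete]
        pinv = np.linalg.pinv(design)
        track_slopes = sub @ pinv[1]
        n = len(track_slopes)
        slope = float(np.mean(track_slopes))
        intercept = float(np.mean(sub @ pinv[0]))
        se = float(np.std(track_slopes, ddof=1) / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
    else:
        resid = msd - design @ coef
        dof = len(tau) - 2
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(design.T @ design)
        se = float(np.sqrt(cov[1, 1]))
        tcrit = stats.t.ppf(0.975, dof)
    d_eff = slope / 4.0
    half = tcrit * se / 4.0
    return DiffusionFit(
        d_eff=float(d_eff),
        ci95=(float(d_eff - half), float(d_eff + half)),
        intercept=float(intercept),
        fit_window=fit_window,
        negative_slope=bool(slope < 0),
    )


def percent_enhancement(d_condition: float, d_control: float) -> float:
    """Percent change of D_eff relative to the control condition."""
    if d_control <= 0:
        raise ValueError("d_control must be > 0")
    return 100.0 * (d_condition - d_control) / d_control


def profile_shift(
    condition: IntensityProfile,
    control: IntensityProfile,
    window: tuple[float, float] | None = None,
) -> float:
    """Lateral displacement of a fluorescence profile (μm).

    Computed as the difference of intensity-weighted centroids,
    condition − control, over the analysis window (defaulting to the
    profiles' own windows, else their overlapping extent).  The two
    profiles are resampled onto a common grid by linear interpolation.
    Coordinate convention: the lateral position axis increases toward
    the solute inlet side of the channel, so a positive shift means
    the particle distribution migrated toward the solute, a negative
    one away from it.
    """
    lo = max(condition.positions[0], control.positions[0])
    hi = min(condition.positions[-1], control.positions[-1])
    for w in (condition.analysis_window, control.analysis_window, window):
        if w is not None:
            lo, hi = max(lo, w[0]), min(hi, w[1])
    if hi <= lo:
        raise ValueError("profiles do not overlap on the analysis window")
    step = min(condition.grid_spacing, control.grid_spacing)
    grid = np.arange(lo, hi + step / 2, step)

    def centroid(profile: IntensityProfile) -> float:
        inten = np.interp(grid, profile.positions, profile.intensity)
        total = inten.sum()
        if total <= 0:
            raise ValueError("zero total intensity in analysis window")
        return float(np.sum(grid * inten) / total)

    return centroid(condition) - centroid(control)
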