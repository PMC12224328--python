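"""File round-trip for the pipeline's exchange formats.

Tracks travel in the tracker-export delimited format (columns TRACK_ID,
FRAME, POSITION_X, POSITION_Y, POSITION_T), intensity profiles and
time-courses as two-/multi-column delimited text with unit-annotated
headers, masks and phase maps as single-channel TIFF with a JSON
sidecar carrying pixel size and imaging metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cells import CellTrack, GrowthSeries
from .kinetics import AssayTimeCourse
from .motion import IntensityProfile, Trajectory

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_profile",
    "write_profile",
    "read_timecourse",
    "write_timecourse",
    "read_growth_series",
    "write_growth_series",
    "read_mask",
    "write_mask",
    "read_phase_map",
    "write_phase_map",
]

TRACK_COLUMNS = ["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y", "POSITION_T"]


def read_tracks(path, kind: str = "particle") -> list[Trajectory] | list[CellTrack]:
    """Read a tracker-export delimited file into track objects.

    Rows are grouped by TRACK_ID and sorted by FRAME; row order in the
    file is irrelevant.  ``kind="particle"`` returns
    :class:`~nanocascade.motion.Trajectory` (μm, s); ``kind="cell"``
    returns :class:`~nanocascade.cells.CellTrack` (μm, h).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track file {path} is missing columns: {', '.join(missing)}")
    cls = {"particle": Trajectory, "cell": CellTrack}.get(kind)
    if cls is None:
        raise ValueError(f"unknown track kind {kind!r}")
    tracks = []
    for track_id, group in df.groupby("TRACK_ID", sort=True):
        group = group.sort_values("FRAME")
        frames = group["FRAME"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"track {track_id}: non-monotone or duplicate frames")
        ident = {"particle": "track_id", "cell": "cell_id"}[kind]
        tracks.append(
            cls(
                **{ident: track_id},
                times=group["POSITION_T"].to_numpy(dtype=float),
                x=group["POSITION_X"].to_numpy(dtype=float),
                y=group["POSITION_Y"].to_numpy(dtype=float),
            )
        )
    return tracks


def write_tracks(tracks, path) -> None:
    """Write tracks in the tracker-export delimited format."""
    rows = []
    for tr in tracks:
        ident = getattr(tr, "track_id", None)
        if ident is None:
            ident = tr.cell_id
        for frame, (t, x, y) in enumerate(zip(tr.times, tr.x, tr.y)):
            rows.append((ident, frame, x, y, t))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_profile(path) -> IntensityProfile:
    """Read a two-column (position μm, intensity a.u.) profile; normalizes on load."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"profile file {path} needs two columns (position, intensity)")
    pos = df.iloc[:, 0].to_numpy(dtype=float)
    inten = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(pos)
    return IntensityProfile(positions=pos[order], intensity=inten[order])


def write_profile(profile: IntensityProfile, path) -> None:
    pd.DataFrame(
        {"position_um": profile.positions, "intensity_norm": profile.intensity}
    ).to_csv(path, index=False)


def read_timecourse(path) -> AssayTimeCourse:
    df = pd.read_csv(path)
    if "time_min" not in df.columns:
        raise ValueError(f"time-course file {path} is missing column time_min")
    return AssayTimeCourse(
        times=df["time_min"].to_numpy(dtype=float),
        glucose=df["glucose_mM"].to_numpy(dtype=float) if "glucose_mM" in df else None,
        h2o2=df["h2o2_mM"].to_numpy(dtype=float) if "h2o2_mM" in df else None,
        catalyst_conc=float(df["catalyst_mg_per_mL"].iloc[0]) if "catalyst_mg_per_mL" in df else 0.1,
    )


def write_timecourse(course: AssayTimeCourse, path) -> None:
    data = {"time_min": course.times}
    if course.glucose is not None:
        data["glucose_mM"] = course.glucose
    if course.h2o2 is not None:
        data["h2o2_mM"] = course.h2o2
    data["catalyst_mg_per_mL"] = np.full_like(course.times, course.catalyst_conc)
    pd.DataFrame(data).to_csv(path, index=False)


def read_growth_series(path) -> GrowthSeries:
    df = pd.read_csv(path)
    if "time_h" not in df.columns or "value" not in df.columns:
        raise ValueError(f"growth file {path} needs columns time_h, value")
    kind = str(df["kind"].iloc[0]) if "kind" in df.columns else "count"
    return GrowthSeries(
        times=df["time_h"].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
        kind=kind,
    )


def write_growth_series(series: GrowthSeries, path) -> None:
    pd.DataFrame(
        {"time_h": series.times, "value": series.values, "kind": series.kind}
    ).to_csv(path, index=False)


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_mask(mask: np.ndarray, path, pixel_size: float) -> None:
    """Write a 0/1 uint8 mask as TIFF plus a JSON sidecar with the pixel size (μm)."""
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))
    _sidecar_path(path).write_text(json.dumps({"pixel_size_um": pixel_size}))


def read_mask(path) -> tuple[np.ndarray, float]:
    mask = tifffile.imread(path).astype(np.uint8)
    meta = json.loads(_sidecar_path(path).read_text())
    return mask, float(meta["pixel_size_um"])


def write_phase_map(phase_map, path) -> None:
    """Write a float32 radians TIFF plus a sidecar (pixel size, wavelength, alpha)."""
    tifffile.imwrite(path, phase_map.phase.astype(np.float32))
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "pixel_size_um": phase_map.pixel_size,
                "wavelength_um": phase_map.wavelength,
                "alpha_um3_per_pg": phase_map.alpha,
            }
        )
    )


def read_phase_map(path):
    from .cells import PhaseMap

    phase = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar_path(path).read_text())
    return PhaseMap(
        phase=phase,
        wavelength=float(meta["wavelength_um"]),
        alpha=float(meta["alpha_um3_per_pg"]),
        pixel_size=float(meta["pixel_size_um"]),
    )
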