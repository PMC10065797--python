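"""Data model and file I/O for single-cell intensity tracks, organ geometry
and run configuration.

Tracks are per-cell time series of two fluorescence channels: a JAK-STAT
activity reporter (dome-MESO-GFP, ``green``) marking blood progenitors and a
plasmatocyte-commitment reporter (eater-dsRed, ``red``).  Two CSV dialects
are supported:

* ``generic`` — columns ``cell_id, frame, time_min, x_um, y_um, z_um,
  green, red, label`` (positions, ``time_min`` and ``label`` optional);
* ``spotexport`` — the tracking-software spot-export table
  (``TRACK_ID, FRAME, POSITION_X/Y/Z, MEAN_INTENSITY_CH1/CH2``), with
  channel 1 mapped to green and channel 2 to red.

Geometry is a flat JSON file describing the heart-tube axis, the posterior
end of the lobe (where the niche sits) and the lobe boundary polygon.
All coordinates are continuous micrometres; frame 0 is the first acquired
frame and downstream time is always minutes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, FormatError, GeometryError

__all__ = [
    "IntensityTrack",
    "LGGeometry",
    "RunConfig",
    "read_tracks",
    "write_tracks",
    "load_config",
    "load_geometry",
    "save_geometry",
]

#: seconds between consecutive frames in the recordings this pipeline targets
DEFAULT_FRAME_INTERVAL_S = 15.0

GENERIC_COLUMNS = ["cell_id", "frame", "time_min", "x_um", "y_um", "z_um",
                   "green", "red", "label"]

_SPOT_EXPORT_MAP = {
    "TRACK_ID": "cell_id",
    "FRAME": "frame",
    "POSITION_X": "x_um",
    "POSITION_Y": "y_um",
    "POSITION_Z": "z_um",
    "MEAN_INTENSITY_CH1": "green",
    "MEAN_INTENSITY_CH2": "red",
}


@dataclass
class IntensityTrack:
    """One cell's two-channel intensity (and optional position) time series."""

    cell_id: str
    frames: np.ndarray           # integer frame indices, ascending
    times_min: np.ndarray        # minutes from frame 0
    green: np.ndarray            # mean intensity, a.u. (G_t)
    red: np.ndarray              # mean intensity, a.u. (R_t)
    positions: np.ndarray | None = None   # (n, 3) in um
    label: str | None = None     # ground-truth tag from the synthetic generator

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.times_min)
        if n < 2:
            raise DataError(f"track {self.cell_id}: needs >= 2 frames, got {n}")
        if not (len(self.green) == len(self.red) == len(self.frames) == n):
            raise DataError(f"track {self.cell_id}: channel/time length mismatch")
        if np.any(np.diff(self.times_min) <= 0):
            raise DataError(f"track {self.cell_id}: times not strictly increasing")
        for name, arr in (("green", self.green), ("red", self.red)):
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise DataError(
                    f"track {self.cell_id}: {name} intensities must be finite and >= 0")
        if self.positions is not None and self.positions.shape != (n, 3):
            raise DataError(f"track {self.cell_id}: positions must be (n, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class LGGeometry:
    """Landmark geometry of a lymph-gland primary lobe.

    The heart tube provides the reference axis for the cylindrical
    (rho, phi, z) frame used to classify mitosis orientation; the posterior
    end is the well-defined position where the niche (PSC) localizes.
    """

    tube_point: np.ndarray       # a point on the heart-tube axis, um
    tube_dir: np.ndarray         # unit vector of the heart-tube axis
    posterior_end: np.ndarray    # um
    z_dir: np.ndarray            # unit vector of the dorsal-ventral axis
    lobe_boundary: np.ndarray    # (k, 2) closed planar polygon, um

    def __post_init__(self) -> None:
        self.tube_point = np.asarray(self.tube_point, dtype=float)
        self.tube_dir = np.asarray(self.tube_dir, dtype=float)
        self.posterior_end = np.asarray(self.posterior_end, dtype=float)
        self.z_dir = np.asarray(self.z_dir, dtype=float)
        self.lobe_boundary = np.asarray(self.lobe_boundary, dtype=float)
        self.validate()

    def validate(self) -> None:
        for name, v in (("tube_dir", self.tube_dir), ("z_dir", self.z_dir)):
            if v.shape != (3,) or not math.isclose(float(np.linalg.norm(v)), 1.0,
                                                   rel_tol=0, abs_tol=1e-6):
                raise GeometryError(f"{name} must be a 3-vector of unit length")
        for name, v in (("tube_point", self.tube_point),
                        ("posterior_end", self.posterior_end)):
            if v.shape != (3,):
                raise GeometryError(f"{name} must be a 3-vector")
        b = self.lobe_boundary
        if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 3:
            raise GeometryError("lobe_boundary must be a (k>=3, 2) polygon")
        from shapely.geometry import Polygon
        if not Polygon(b).is_valid:
            raise GeometryError("lobe_boundary polygon is self-intersecting")


@dataclass
class RunConfig:
    """Tunable settings of the pipeline with the defaults used throughout.

    ``onset_offset_frames`` encodes the rule that mitosis onset is 40 frames
    (10 min at 15 s/frame) before the observed nuclear-envelope breakdown.
    """

    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    onset_offset_frames: int = 40
    grid_n: int = 5
    rho_z_angle_threshold_deg: float = 45.0
    aicc_margin: float = 2.0
    fast_phase_quantiles: tuple[float, float] = (0.1, 0.9)
    ratio_floor: float = 0.01
    smoothing_window: int = 1          # moving-average width; 1 = off
    blob_diameter_px: float = 13.0
    blob_quality_threshold: float = 0.2
    histocyto_sample_size: int = 2500
    g_threshold: float | None = None   # None -> Otsu on log10 intensities
    r_threshold: float | None = None
    fucci_presence_fraction: float = 0.2
    fucci_min_run_frames: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "frame_interval_s", "grid_n", "rho_z_angle_threshold_deg",
            "aicc_margin", "ratio_floor", "smoothing_window",
            "blob_diameter_px", "blob_quality_threshold",
            "histocyto_sample_size", "fucci_presence_fraction",
            "fucci_min_run_frames",
        ]
        for key in positive:
            v = getattr(self, key)
            if not (np.isscalar(v) and float(v) > 0):
                raise ConfigError(f"config key {key!r} must be > 0, got {v!r}")
        if not (isinstance(self.onset_offset_frames, (int, np.integer))
                and self.onset_offset_frames >= 0):
            raise ConfigError("onset_offset_frames must be a non-negative integer")
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ConfigError(f"seed must be a non-negative integer, got {self.seed!r}")
        lo, hi = self.fast_phase_quantiles
        if not (0 < lo < hi < 1):
            raise ConfigError("fast_phase_quantiles must satisfy 0 < lo < hi < 1")
        for key in ("g_threshold", "r_threshold"):
            v = getattr(self, key)
            if v is not None and not float(v) > 0:
                raise ConfigError(f"config key {key!r} must be > 0 when set")

    @property
    def onset_offset_min(self) -> float:
        return self.onset_offset_frames * self.frame_interval_s / 60.0


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON key-value document into a :class:`RunConfig`.

    Missing keys take the documented defaults; unknown keys are an error.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} is not a key-value document")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "fast_phase_quantiles" in doc:
        doc["fast_phase_quantiles"] = tuple(doc["fast_phase_quantiles"])
    return RunConfig(**doc)


def read_tracks(path: str | Path, dialect: str = "generic",
                frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
                ) -> list[IntensityTrack]:
    """Read per-cell intensity tracks from CSV.

    Parameters
    ----------
    path : file path
    dialect : {"generic", "spotexport"}
        Column schema (see module docstring).
    frame_interval_s : float
        Used to compute ``times_min = frame * interval / 60`` when the file
        carries no ``time_min`` column.

    Returns one track per distinct cell id, frames sorted ascending.
    Row order in the file does not matter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if dialect == "spotexport":
        missing = [c for c in _SPOT_EXPORT_MAP if c not in df.columns]
        if missing:
            raise FormatError(f"spot-export file missing column(s): {missing}")
        df = df.rename(columns=_SPOT_EXPORT_MAP)[list(_SPOT_EXPORT_MAP.values())]
    elif dialect == "generic":
        required = ["cell_id", "frame", "green", "red"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"generic track file missing column(s): {missing}")
    else:
        raise FormatError(f"unknown track dialect {dialect!r}")

    tracks: list[IntensityTrack] = []
    for cell_id, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("frame", kind="mergesort")
        frames = g["frame"].to_numpy(dtype=int)
        if len(np.unique(frames)) != len(frames):
            raise DataError(f"track {cell_id}: duplicate frame indices")
        if "time_min" in g.columns and g["time_min"].notna().all():
            times = g["time_min"].to_numpy(dtype=float)
        else:
            times = frames * frame_interval_s / 60.0
        positions = None
        if {"x_um", "y_um", "z_um"} <= set(g.columns) and g[["x_um", "y_um", "z_um"]].notna().all().all():
            positions = g[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
        label = None
        if "label" in g.columns:
            labels = g["label"].dropna().unique()
            if len(labels) == 1:
                label = str(labels[0])
        tracks.append(IntensityTrack(
            cell_id=str(cell_id), frames=frames, times_min=times,
            green=g["green"].to_numpy(dtype=float),
            red=g["red"].to_numpy(dtype=float),
            positions=positions, label=label))
    return tracks


def write_tracks(tracks: Sequence[IntensityTrack], path: str | Path) -> Path:
    """Write tracks as a generic-dialect CSV readable by :func:`read_tracks`."""
    path = Path(path)
    rows = []
    for t in tracks:
        for k in range(t.n_frames):
            pos = t.positions[k] if t.positions is not None else (np.nan,) * 3
            rows.append({
                "cell_id": t.cell_id, "frame": int(t.frames[k]),
                "time_min": float(t.times_min[k]),
                "x_um": pos[0], "y_um": pos[1], "z_um": pos[2],
                "green": float(t.green[k]), "red": float(t.red[k]),
                "label": t.label if t.label is not None else np.nan,
            })
    df = pd.DataFrame(rows, columns=GENERIC_COLUMNS)
    # %.17g guarantees bit-exact float round-trips through the CSV
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def load_geometry(path: str | Path) -> LGGeometry:
    """Load lobe geometry from the flat JSON layout documented in the README."""
    with open(path) as fh:
        doc = json.load(fh)
    required = {"tube_point", "tube_dir", "posterior_end", "z_dir", "lobe_boundary"}
    missing = required - set(doc)
    if missing:
        raise FormatError(f"geometry file missing key(s): {sorted(missing)}")
    return LGGeometry(
        tube_point=doc["tube_point"], tube_dir=doc["tube_dir"],
        posterior_end=doc["posterior_end"], z_dir=doc["z_dir"],
        lobe_boundary=doc["lobe_boundary"])


def save_geometry(geom: LGGeometry, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "tube_point": geom.tube_point.tolist(),
        "tube_dir": geom.tube_dir.tolist(),
        "posterior_end": geom.posterior_end.tolist(),
        "z_dir": geom.z_dir.tolist(),
        "lobe_boundary": geom.lobe_boundary.tolist(),
    }
    path.write_text(json.dumps(doc, indent=1))
    return path
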