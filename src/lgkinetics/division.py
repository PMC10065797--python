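"""Mitosis kinetics and orientation in the cylindrical organ frame.

Progenitor divisions are annotated events (nuclear-envelope breakdown time,
daughter-nuclei reformation time, daughter centroids); the operations here
turn them into the standard read-outs:

* duration — the breakdown-to-reformation interval plus a fixed onset offset
  (mitosis onset is taken as 40 frames, about 10 min, before the visible
  nucleus breakdown);
* orientation — the division axis is classified as rho-mitosis (radiating
  from the dorsal-ventral axis, i.e. lying in the plane of the
  anterior-posterior and left-right axes) or z-mitosis (along the
  dorsal-ventral axis) using a 45-degree cone about the z axis, and
  rho-mitoses get an angle theta in [0, 180) to the heart tube;
* a Q-Q normality report for the orientation sample;
* critical-size metrics (mother area 10 min pre-mitosis, combined daughter
  area at +3 h, per-daughter growth over 4 h);
* distances to the heart tube and the posterior end (niche position), and
  the mitotic index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError, InsufficientDataError, ValidationError
from .trackio import LGGeometry, RunConfig

__all__ = [
    "DivisionEvent",
    "QQReport",
    "division_duration",
    "classify_division_axis",
    "orientation_to_heart_tube",
    "qq_orientation_bias",
    "critical_size_metrics",
    "mitotic_index",
    "event_distances",
    "summarize_divisions",
]


@dataclass
class DivisionEvent:
    """One annotated progenitor mitosis."""

    event_id: str
    t_breakdown_min: float
    t_complete_min: float
    position_um: np.ndarray                  # event location (x, y, z), um
    axis_vec: np.ndarray                     # unit vector daughter1 -> daughter2
    mother_id: str | None = None
    daughter_ids: tuple[str, str] | None = None
    duration_min: float | None = None
    mother_area_pre_um2: float | None = None  # 10 min before mitosis
    daughter_areas_um2: tuple[np.ndarray, np.ndarray] | None = None
    daughter_area_times_min: np.ndarray | None = None  # minutes post-mitosis
    ring_pole_distances_um: tuple[float, float] | None = None
    axis_class: str | None = None            # {"rho", "z"}
    theta_deg: float | None = None           # orientation to heart tube
    dist_tube_um: float | None = None
    dist_posterior_um: float | None = None
    daughter_jakstat: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.position_um = np.asarray(self.position_um, dtype=float)
        self.axis_vec = np.asarray(self.axis_vec, dtype=float)
        nrm = float(np.linalg.norm(self.axis_vec))
        if nrm == 0:
            raise DataError(f"event {self.event_id}: zero-length division axis")
        self.axis_vec = self.axis_vec / nrm
        if self.t_complete_min <= self.t_breakdown_min:
            raise DataError(
                f"event {self.event_id}: completion must follow breakdown")


@dataclass
class QQReport:
    """Normal quantile-quantile summary of an orientation sample."""

    sample_quantiles: np.ndarray       # degrees, sorted
    theoretical_quantiles: np.ndarray  # degrees, N(mean, sd) at plotting positions
    line_intercept: float              # reference line through quartile pairs
    line_slope: float
    r_squared: float                   # linearity of the points, in [0, 1]


def division_duration(t_breakdown_min: float, t_complete_min: float,
                      config: RunConfig | None = None) -> float:
    """Mitosis duration: observed breakdown-to-reformation interval plus the
    onset offset (default 40 frames x 15 s = 10 min)."""
    config = config or RunConfig()
    if t_complete_min <= t_breakdown_min:
        raise DataError("t_complete must exceed t_breakdown")
    return (t_complete_min - t_breakdown_min) + config.onset_offset_min


def classify_division_axis(axis_vec: np.ndarray, geometry: LGGeometry,
                           config: RunConfig | None = None) -> str:
    """Classify a division axis as rho- or z-mitosis.

    The angle alpha = arccos(|axis . z_dir|) measures how far the axis tilts
    away from the dorsal-ventral axis; alpha <= threshold (default 45 deg,
    boundary inclusive) is a z-mitosis, anything flatter is a rho-mitosis.
    """
    config = config or RunConfig()
    v = np.asarray(axis_vec, dtype=float)
    nrm = float(np.linalg.norm(v))
    if nrm == 0:
        raise DataError("zero-length division axis")
    v = v / nrm
    cos_a = min(1.0, abs(float(np.dot(v, geometry.z_dir))))
    alpha = math.degrees(math.acos(cos_a))
    # alpha is the angle *to* z; small alpha = along the dorsal-ventral axis
    return "z" if alpha <= config.rho_z_angle_threshold_deg else "rho"


def orientation_to_heart_tube(axis_vec: np.ndarray,
                              geometry: LGGeometry) -> float:
    """Directed orientation theta in [0, 180) of a rho-mitosis axis relative
    to the heart tube.

    The axis (daughter1 -> daughter2) is projected onto the rho-phi plane
    (perpendicular to the dorsal-ventral axis) and the angle to the projected
    heart-tube direction is folded to [0, 180).  Relabelling the daughters
    maps theta to 180 - theta (mod 180).
    """
    z = geometry.z_dir
    tube_in_plane = geometry.tube_dir - np.dot(geometry.tube_dir, z) * z
    tnorm = float(np.linalg.norm(tube_in_plane))
    if tnorm < 1e-12:
        raise ValidationError("heart-tube axis is parallel to z; "
                              "in-plane orientation undefined")
    e1 = tube_in_plane / tnorm
    e2 = np.cross(z, e1)
    v = np.asarray(axis_vec, dtype=float)
    p = v - np.dot(v, z) * z
    if float(np.linalg.norm(p)) < 1e-6:
        raise DataError("division axis numerically vertical; "
                        "projection onto the rho-phi plane vanishes")
    phi = math.degrees(math.atan2(float(np.dot(p, e2)), float(np.dot(p, e1))))
    theta = abs(phi)            # unsigned angle of the directed axis
    return 0.0 if theta >= 180.0 else float(theta)


def qq_orientation_bias(theta_list_deg) -> QQReport:
    """Normal Q-Q report for a sample of orientation angles.

    Sample quantiles are plotted against N(mean, sd) quantiles at the usual
    plotting positions; the reference line passes through the first/third
    quartile pairs (the standard Q-Q line construction) and r_squared is the
    squared Pearson correlation of the quantile pairs.  A value near 1 is
    what a normally distributed (unbiased about its mean) orientation sample
    produces; multimodal or skewed samples fall visibly below.
    """
    theta = np.sort(np.asarray(theta_list_deg, dtype=float))
    n = len(theta)
    if n < 5:
        raise InsufficientDataError(f"need >= 5 angles, got {n}")
    if np.ptp(theta) == 0:
        raise DataError("all angles identical; Q-Q comparison degenerate")
    mean, sd = float(theta.mean()), float(theta.std(ddof=1))
    # Blom-type plotting positions, as used by standard qqnorm implementations
    a = 0.375 if n <= 10 else 0.5
    probs = (np.arange(1, n + 1) - a) / (n + 1 - 2 * a)
    theo = stats.norm.ppf(probs, loc=mean, scale=sd)
    q1s, q3s = np.quantile(theta, [0.25, 0.75])
    q1t, q3t = stats.norm.ppf([0.25, 0.75], loc=mean, scale=sd)
    slope = (q3s - q1s) / (q3t - q1t)
    intercept = q1s - slope * q1t
    r = float(np.corrcoef(theo, theta)[0, 1])
    return QQReport(sample_quantiles=theta, theoretical_quantiles=theo,
                    line_intercept=float(intercept), line_slope=float(slope),
                    r_squared=r * r)


def critical_size_metrics(event: DivisionEvent):
    """Critical-size quantities for one division.

    Returns ``(mother_area_pre_um2, combined_daughter_area_3h_um2,
    growth_fraction_4h)`` where the combined area sums the two daughter areas
    at the frame nearest +3 h and the growth fraction is
    ``(area(4 h) - area(0)) / area(0)`` per daughter.  Missing daughter
    series yield ``None`` for the affected fields rather than an error.
    """
    mother = event.mother_area_pre_um2
    combined = None
    growth = None
    if event.daughter_areas_um2 is not None and event.daughter_area_times_min is not None:
        tt = np.asarray(event.daughter_area_times_min, dtype=float)
        if tt.max() >= 180.0:
            k3 = int(np.argmin(np.abs(tt - 180.0)))
            combined = float(sum(np.asarray(d)[k3]
                                 for d in event.daughter_areas_um2))
        growths = []
        if tt.max() >= 240.0:
            k4 = int(np.argmin(np.abs(tt - 240.0)))
            k0 = int(np.argmin(np.abs(tt - 0.0)))
            for d in event.daughter_areas_um2:
                d = np.asarray(d, dtype=float)
                if d[k0] > 0:
                    growths.append((d[k4] - d[k0]) / d[k0])
            growth = tuple(growths) if growths else None
    return mother, combined, growth


def mitotic_index(n_ph3_pos_progenitors: int, n_progenitors: int) -> float:
    """Fraction of progenitors in mitosis: pH3+ dome+ over all dome+ cells."""
    if n_progenitors <= 0:
        raise ValidationError("mitotic index undefined for zero progenitors")
    if not 0 <= n_ph3_pos_progenitors <= n_progenitors:
        raise ValidationError(
            f"numerator {n_ph3_pos_progenitors} outside [0, {n_progenitors}]")
    return n_ph3_pos_progenitors / n_progenitors


def event_distances(event_position_um, geometry: LGGeometry):
    """Perpendicular distance to the heart-tube axis and Euclidean distance
    to the posterior end (niche position), both in micrometres."""
    p = np.asarray(event_position_um, dtype=float)
    d = p - geometry.tube_point
    perp = d - np.dot(d, geometry.tube_dir) * geometry.tube_dir
    dist_tube = float(np.linalg.norm(perp))
    dist_post = float(np.linalg.norm(p - geometry.posterior_end))
    return dist_tube, dist_post


def annotate_events(events, geometry: LGGeometry,
                    config: RunConfig | None = None) -> list[DivisionEvent]:
    """Fill duration, axis class, theta and distances in place for a cohort."""
    config = config or RunConfig()
    for ev in events:
        ev.duration_min = division_duration(
            ev.t_breakdown_min, ev.t_complete_min, config)
        ev.axis_class = classify_division_axis(ev.axis_vec, geometry, config)
        if ev.axis_class == "rho":
            ev.theta_deg = orientation_to_heart_tube(ev.axis_vec, geometry)
        ev.dist_tube_um, ev.dist_posterior_um = event_distances(
            ev.position_um, geometry)
    return list(events)


def summarize_divisions(events) -> dict:
    """Cohort summary: per-class counts and durations, rho fraction,
    pre-mitotic mother areas.

    The rho fraction is reported both as a fraction and as a percentage
    (the conventional headline statistic).
    """
    events = list(events)
    if not events:
        raise InsufficientDataError("no division events to summarize")
    durations = np.array([ev.duration_min for ev in events], dtype=float)
    classes = np.array([ev.axis_class for ev in events])
    n_rho = int(np.sum(classes == "rho"))
    n_z = int(np.sum(classes == "z"))
    out = {
        "n_events": len(events),
        "n_rho": n_rho,
        "n_z": n_z,
        "rho_fraction": n_rho / len(events),
        "rho_percent": 100.0 * n_rho / len(events),
        "duration_mean_min": float(np.mean(durations)),
        "duration_sd_min": float(np.std(durations, ddof=1)) if len(events) > 1 else 0.0,
    }
    for cls, name in (("rho", "rho"), ("z", "z")):
        sel = durations[classes == cls]
        out[f"duration_mean_{name}_min"] = float(sel.mean()) if len(sel) else None
    areas = [ev.mother_area_pre_um2 for ev in events
             if ev.mother_area_pre_um2 is not None]
    if areas:
        out["mother_area_mean_um2"] = float(np.mean(areas))
        out["mother_area_sd_um2"] = (float(np.std(areas, ddof=1))
                                     if len(areas) > 1 else 0.0)
    return out
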