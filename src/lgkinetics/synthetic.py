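"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure, explicitly seeded function so downstream stages
can be tested against known ground truth without microscopy recordings:

* dual-reporter differentiation tracks — sigmoid (slow phase, then a rapid
  switch) and linear (constant-rate ratio change) trajectories, in wild-type
  and infected variants (infected sigmoid: prolonged low/low intermediary
  phase; infected linear: early red rise and a ~50% higher final dsRed:GFP
  ratio);
* division cohorts — ~90% rho-axis orientation, durations and pre-mitotic
  mother areas drawn from left-truncated normals whose realized mean/SD match
  the stated values (57.74 +/- 27.58 min; 71.96 +/- 10.00 um^2), symmetric
  daughters growing 20-30% over 4 h;
* two-channel blob images of nuclei for the histo-cytometry detector;
* FUCCI traces following an explicit phase plan (both reporters drop during
  mitosis, mirroring nuclear-envelope breakdown).

Intensity noise is multiplicative Gaussian (``x * (1 + N(0, cv^2))``,
clipped at 0), approximating the heteroscedastic look of fluorescence
traces; the default cv of 0.1 is a choice, flagged in the config docs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from shapely.geometry import Point, Polygon

from .errors import ParameterError
from .trackio import DEFAULT_FRAME_INTERVAL_S, IntensityTrack, LGGeometry
from .division import DivisionEvent
from .fucci import PHASES, FucciTrace

__all__ = [
    "DifferentiationModel",
    "DivisionCohortModel",
    "simulate_differentiation_track",
    "simulate_differentiation_cohort",
    "simulate_division_cohort",
    "simulate_lg_image",
    "simulate_fucci_trace",
    "default_geometry",
    "DIFFERENTIATION_KINDS",
]

DIFFERENTIATION_KINDS = ("sigmoid_wt", "sigmoid_infected",
                         "linear_wt", "linear_infected")

#: default track lengths (frames at 15 s) per kind, mirroring the recorded
#: trajectory spans (~300 min for sigmoid cells, ~560 min for linear cells;
#: infected sigmoid cells need the longer window for their intermediary phase)
DEFAULT_N_FRAMES = {
    "sigmoid_wt": 1280,        # 320 min
    "sigmoid_infected": 1760,  # 440 min
    "linear_wt": 2240,         # 560 min
    "linear_infected": 2240,
}


def _logistic(t, t0, tau):
    return 1.0 / (1.0 + np.exp(-(t - t0) / tau))


@dataclass
class DifferentiationModel:
    """Parameters of one differentiation-trajectory generator.

    ``kind`` selects the construction; intensities are arbitrary units.
    Sigmoid kinds: green falls as a logistic at ``t_mid`` (timescale
    ``tau_green``) and red rises as a logistic delayed by ``delay`` (plus the
    ``intermediary_min`` low/low plateau for the infected variant) with
    timescale ``tau``.  Linear kinds: red rises early to its plateau (for the
    infected variant, to 1.5x the wild-type plateau) and green declines so
    the dsRed:GFP ratio changes at an exactly constant rate — the defining
    property of the linear trajectory.
    """

    kind: str
    G0: float = 100.0            # start green level
    G1: float = 25.0             # end green level
    R0: float = 5.0              # start red level
    R1: float = 90.0             # end red level
    t_mid: float = 100.0         # green-decline logistic midpoint, min
    tau: float = 15.0            # red-rise logistic timescale, min
    tau_green: float = 12.0      # green-decline timescale, min
    delay: float = 60.0          # red onset lag after green decline, min
    intermediary_min: float = 0.0   # low/low plateau (sigmoid_infected)
    noise_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in DIFFERENTIATION_KINDS:
            raise ParameterError(f"unknown trajectory kind {self.kind!r}")
        if self.tau <= 0 or self.tau_green <= 0:
            raise ParameterError("tau must be > 0")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if not self.G0 > self.G1:
            raise ParameterError("green must decline: G0 > G1 required")
        if self.kind.startswith("linear") and self.R0 < 0.5 * self.G0:
            raise ParameterError(
                "linear kinds start with red already high (R0 >= 0.5 * G0)")

    @classmethod
    def for_kind(cls, kind: str, noise_cv: float = 0.1) -> "DifferentiationModel":
        """Default parameterization of each trajectory kind."""
        if kind == "sigmoid_wt":
            return cls(kind=kind, G0=100, G1=25, R0=2, R1=90,
                       t_mid=100, tau=15, tau_green=12, delay=60,
                       noise_cv=noise_cv)
        if kind == "sigmoid_infected":
            # prolonged low/low intermediary phase and a slower switch
            return cls(kind=kind, G0=100, G1=25, R0=2, R1=90,
                       t_mid=100, tau=25, tau_green=12, delay=60,
                       intermediary_min=120, noise_cv=noise_cv)
        if kind == "linear_wt":
            return cls(kind=kind, G0=100, G1=30, R0=60, R1=60,
                       t_mid=8, tau=3, noise_cv=noise_cv)
        if kind == "linear_infected":
            # red rises early to a plateau 1.5x the wild-type level
            return cls(kind=kind, G0=100, G1=30, R0=60, R1=90,
                       t_mid=8, tau=3, noise_cv=noise_cv)
        raise ParameterError(f"unknown trajectory kind {kind!r}")

    # ---- noiseless constructions -------------------------------------

    def noiseless_curves(self, times_min: np.ndarray):
        """(green, red) noiseless intensity curves at the given times."""
        t = np.asarray(times_min, dtype=float)
        if self.kind.startswith("sigmoid"):
            green = self.G1 + (self.G0 - self.G1) * (
                1.0 - _logistic(t, self.t_mid, self.tau_green))
            red_mid = self.t_mid + self.delay + self.intermediary_min
            red = self.R0 + (self.R1 - self.R0) * _logistic(t, red_mid, self.tau)
            return green, red
        # linear kinds: red reaches its plateau early, then green declines so
        # that the dsRed:GFP ratio follows an exact constant-rate ramp once
        # the plateau is reached
        red = self.R1 + (self.R0 - self.R1) * (
            1.0 - _logistic(t, self.t_mid, self.tau))
        T = t[-1] - t[0]
        r_start = self.R1 / self.G0
        r_end = self.R1 / self.G1
        ratio_target = r_start + (r_end - r_start) * (t - t[0]) / T
        green = np.minimum(self.G0, self.R1 / ratio_target)
        return green, red

    def generative_rate(self, times_min: np.ndarray) -> float:
        """Nominal dsRed:GFP rate of the noiseless construction.

        Linear kinds: the constructed constant ratio slope.  Sigmoid kinds:
        the secant slope of the noiseless ratio curve between its 10% and 90%
        amplitude crossings (computed by interpolation, independently of any
        fitting).
        """
        t = np.asarray(times_min, dtype=float)
        green, red = self.noiseless_curves(t)
        ratio = red / green
        if self.kind.startswith("linear"):
            return float((self.R1 / self.G1 - self.R1 / self.G0) / (t[-1] - t[0]))
        lo = ratio.min() + 0.1 * np.ptp(ratio)
        hi = ratio.min() + 0.9 * np.ptp(ratio)
        t_lo = float(np.interp(lo, ratio, t))
        t_hi = float(np.interp(hi, ratio, t))
        return float((hi - lo) / (t_hi - t_lo))


def _apply_noise(rng: np.random.Generator, values: np.ndarray,
                 cv: float) -> np.ndarray:
    if cv == 0:
        return values.copy()
    return np.clip(values * (1.0 + rng.normal(0.0, cv, size=values.shape)),
                   0.0, None)


def simulate_differentiation_track(
        model: DifferentiationModel, n_frames: int, seed: int,
        frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
        cell_id: str | None = None) -> IntensityTrack:
    """One labeled synthetic dual-reporter track."""
    if n_frames < 10:
        raise ParameterError("n_frames must be >= 10")
    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames)
    times = frames * frame_interval_s / 60.0
    green, red = model.noiseless_curves(times)
    return IntensityTrack(
        cell_id=cell_id or f"{model.kind}_{seed}",
        frames=frames, times_min=times,
        green=_apply_noise(rng, green, model.noise_cv),
        red=_apply_noise(rng, red, model.noise_cv),
        label=model.kind)


def simulate_differentiation_cohort(
        kind: str, n_tracks: int, seed: int, noise_cv: float = 0.1,
        n_frames: int | None = None) -> list[IntensityTrack]:
    """A cohort of tracks of one kind, seeded per track."""
    model = DifferentiationModel.for_kind(kind, noise_cv=noise_cv)
    nf = n_frames or DEFAULT_N_FRAMES[kind]
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_tracks)
    return [simulate_differentiation_track(
        model, nf, int(s), cell_id=f"{kind}_{i}")
        for i, s in enumerate(seeds)]


# ---- division cohorts ------------------------------------------------


def _truncnorm_moment_matched(target_mean: float, target_sd: float,
                              lower: float):
    """Parent (mu, sigma) of a left-truncated normal whose realized mean and
    SD equal the targets.  Naive truncation of N(target_mean, target_sd^2)
    inflates the mean and shrinks the SD whenever the bound is within a few
    SD of the mean, which would de-calibrate the cohort."""
    if target_sd <= 0:
        return target_mean, max(target_sd, 1e-9)
    if target_mean - lower < 1e-9:
        raise ParameterError("target mean must exceed the truncation bound")

    def moments(params):
        mu, sigma = params
        sigma = abs(sigma)
        a = (lower - mu) / sigma
        lam = stats.norm.pdf(a) / max(stats.norm.sf(a), 1e-300)
        mean = mu + sigma * lam
        var = sigma ** 2 * (1 + a * lam - lam ** 2)
        return mean - target_mean, math.sqrt(max(var, 1e-300)) - target_sd

    sol, info, ok, _ = optimize.fsolve(
        moments, x0=[target_mean, target_sd], full_output=True)
    if ok != 1:
        # mild truncation: fall back to the naive parameters
        return target_mean, target_sd
    return float(sol[0]), float(abs(sol[1]))


def _sample_truncnorm(rng, target_mean, target_sd, lower, size):
    mu, sigma = _truncnorm_moment_matched(target_mean, target_sd, lower)
    a = (lower - mu) / sigma
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma,
                               size=size, random_state=rng)


@dataclass
class DivisionCohortModel:
    """Statistical model of a synthetic mitosis cohort.

    Defaults mirror the reported cohort statistics: duration
    57.74 +/- 27.58 min, pre-mitotic mother area 71.96 +/- 10.00 um^2,
    ~90% rho-axis divisions with orientations spread around 90 degrees to
    the heart tube.  Optional per-class duration means (rho vs z) reproduce
    the reported 53.90 vs 75.04 min split.
    """

    n_events: int
    p_rho: float = 0.9
    duration_mean_min: float = 57.74
    duration_sd_min: float = 27.58
    duration_mean_rho_min: float | None = None
    duration_mean_z_min: float | None = None
    critical_area_mean_um2: float = 71.96
    critical_area_sd_um2: float = 10.0
    angle_mean_deg: float = 90.0
    angle_sd_deg: float = 30.0
    lobe_half_axes_um: tuple[float, float, float] = (300.0, 150.0, 50.0)
    growth_fraction_range: tuple[float, float] = (0.20, 0.30)
    onset_offset_min: float = 10.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_rho <= 1:
            raise ParameterError("p_rho must be in [0, 1]")
        if self.duration_sd_min < 0 or self.critical_area_sd_um2 < 0:
            raise ParameterError("standard deviations must be >= 0")
        if self.n_events < 0:
            raise ParameterError("n_events must be >= 0")


def _sample_positions(rng, n, geometry: LGGeometry, half_axes):
    """Uniform positions inside the lobe boundary (x, y) with z within the
    dorsal-ventral half-thickness."""
    poly = Polygon(geometry.lobe_boundary)
    xmin, ymin, xmax, ymax = poly.bounds
    out = np.empty((n, 3))
    k = 0
    while k < n:
        m = max(4 * (n - k), 16)
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        for x, y in zip(xs, ys):
            if poly.covers(Point(x, y)):
                out[k, 0], out[k, 1] = x, y
                k += 1
                if k == n:
                    break
    out[:, 2] = rng.uniform(-half_axes[2], half_axes[2], n)
    return out


def simulate_division_cohort(model: DivisionCohortModel,
                             geometry: LGGeometry,
                             seed: int) -> list[DivisionEvent]:
    """A labeled cohort of annotated division events.

    rho-events lie (near) the plane perpendicular to the dorsal-ventral axis
    at a truncated-normal angle to the heart tube; z-events run along the
    dorsal-ventral axis with a small tilt.  Durations and pre-mitotic areas
    follow the calibrated truncated normals; each event carries symmetric
    daughters whose areas grow 20-30% over 4 h.
    """
    n = model.n_events
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    z = geometry.z_dir
    tube_in_plane = geometry.tube_dir - np.dot(geometry.tube_dir, z) * z
    e1 = tube_in_plane / np.linalg.norm(tube_in_plane)
    e2 = np.cross(z, e1)

    is_rho = rng.random(n) < model.p_rho
    # orientation to the heart tube for rho-events, truncated to [0, 180)
    a = (0.0 - model.angle_mean_deg) / model.angle_sd_deg
    b = (180.0 - model.angle_mean_deg) / model.angle_sd_deg
    thetas = stats.truncnorm.rvs(a, b, loc=model.angle_mean_deg,
                                 scale=model.angle_sd_deg, size=n,
                                 random_state=rng)
    tilt = np.clip(np.abs(rng.normal(0.0, 10.0, n)), 0.0, 30.0)  # deg off-plane/axis
    azim = rng.uniform(0, 2 * np.pi, n)

    lower = model.onset_offset_min + 0.5
    if model.duration_mean_rho_min is not None or model.duration_mean_z_min is not None:
        mean_rho = model.duration_mean_rho_min or model.duration_mean_min
        mean_z = model.duration_mean_z_min or model.duration_mean_min
        durations = np.where(
            is_rho,
            _sample_truncnorm(rng, mean_rho, model.duration_sd_min, lower, n),
            _sample_truncnorm(rng, mean_z, model.duration_sd_min, lower, n))
    else:
        durations = _sample_truncnorm(
            rng, model.duration_mean_min, model.duration_sd_min, lower, n)
    areas = _sample_truncnorm(
        rng, model.critical_area_mean_um2, model.critical_area_sd_um2, 0.0, n)
    positions = _sample_positions(rng, n, geometry, model.lobe_half_axes_um)
    t_breakdown = rng.uniform(0.0, 600.0, n)
    growth = rng.uniform(*model.growth_fraction_range, size=(n, 2))
    jak_base = rng.normal(100.0, 10.0, n)
    jak_split = rng.normal(0.0, 0.03, n)

    area_times = np.arange(0.0, 241.0, 15.0)
    events = []
    for i in range(n):
        th = math.radians(thetas[i])
        tl = math.radians(tilt[i])
        if is_rho[i]:
            in_plane = math.cos(th) * e1 + math.sin(th) * e2
            axis = math.cos(tl) * in_plane + math.sin(tl) * z
        else:
            perp = math.cos(azim[i]) * e1 + math.sin(azim[i]) * e2
            axis = math.cos(tl) * z + math.sin(tl) * perp
        half = areas[i] / 2.0
        d_areas = tuple(half * (1.0 + growth[i, j] * area_times / 240.0)
                        for j in range(2))
        radius = math.sqrt(areas[i] / math.pi)
        events.append(DivisionEvent(
            event_id=f"div_{i}",
            t_breakdown_min=float(t_breakdown[i]),
            t_complete_min=float(t_breakdown[i] + durations[i]
                                 - model.onset_offset_min),
            position_um=positions[i],
            axis_vec=axis,
            mother_id=f"mother_{i}",
            daughter_ids=(f"d{i}a", f"d{i}b"),
            mother_area_pre_um2=float(areas[i]),
            daughter_areas_um2=d_areas,
            daughter_area_times_min=area_times.copy(),
            ring_pole_distances_um=(radius, radius),
            daughter_jakstat=(float(jak_base[i] * (1 + jak_split[i])),
                              float(jak_base[i] * (1 - jak_split[i]))),
        ))
    return events


# ---- images ----------------------------------------------------------


def simulate_lg_image(cells, shape: tuple[int, int],
                      blob_sigma_px: float, noise_sd: float,
                      seed: int):
    """Two-channel image of Gaussian nuclei plus a ground-truth table.

    ``cells`` is a list of ``((row, col), green_peak, red_peak)``.  Each
    nucleus is an isotropic Gaussian spot with the given peak intensities;
    additive Gaussian background noise (SD ``noise_sd``) is clipped at 0.
    Identical centroids are allowed (their spots simply superpose).
    """
    if blob_sigma_px <= 0:
        raise ParameterError("blob_sigma_px must be > 0")
    h, w = shape
    img = np.zeros((2, h, w), dtype=float)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    truth = []
    for k, ((r, c), green, red) in enumerate(cells):
        if not (0 <= r < h and 0 <= c < w):
            raise ParameterError(f"centroid ({r}, {c}) outside image {shape}")
        spot = np.exp(-((rows - r) ** 2 + (cols - c) ** 2)
                      / (2.0 * blob_sigma_px ** 2))
        img[0] += green * spot
        img[1] += red * spot
        truth.append({"cell_id": k, "row": r, "col": c,
                      "green": green, "red": red})
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)
    return img, pd.DataFrame(truth, columns=["cell_id", "row", "col",
                                             "green", "red"])


# ---- FUCCI -----------------------------------------------------------

#: (green, red) reporter means per phase: E2f1-GFP high in G1/G2 and low in
#: S; CycB-RFP high in S/G2 and low in G1; both drop during M (nucleus
#: breakdown)
DEFAULT_FUCCI_LEVELS = {
    "G1": (100.0, 5.0),
    "S": (5.0, 100.0),
    "G2": (100.0, 100.0),
    "M": (5.0, 5.0),
}


def simulate_fucci_trace(phase_plan, levels=None, noise_cv: float = 0.0,
                         seed: int = 0,
                         frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
                         cell_id: str = "fucci") -> FucciTrace:
    """A FUCCI trace following an explicit ordered (phase, duration_min) plan."""
    levels = levels or DEFAULT_FUCCI_LEVELS
    greens, reds, truth = [], [], []
    for phase, duration_min in phase_plan:
        if phase not in PHASES:
            raise ParameterError(f"unknown phase label {phase!r}")
        if duration_min <= 0:
            raise ParameterError("phase durations must be > 0")
        n = int(round(duration_min * 60.0 / frame_interval_s))
        g, r = levels[phase]
        greens.extend([g] * n)
        reds.extend([r] * n)
        truth.extend([phase] * n)
    rng = np.random.default_rng(seed)
    green = _apply_noise(rng, np.asarray(greens, dtype=float), noise_cv)
    red = _apply_noise(rng, np.asarray(reds, dtype=float), noise_cv)
    times = np.arange(len(truth)) * frame_interval_s / 60.0
    return FucciTrace(cell_id=cell_id, times_min=times,
                      e2f_green=green, cycb_red=red, true_phases=truth)


# ---- default geometry ------------------------------------------------


def default_geometry(n_vertices: int = 64) -> LGGeometry:
    """A canonical synthetic primary-lobe geometry.

    Heart tube along y at x = 0, dorsal-ventral axis along z, niche
    (posterior end) at the posterior tip of the tube, and an elliptical lobe
    (semi-axes 150 x 140 um) to the right of the tube — proportions matching
    a primary lobe roughly 300 um long, 150 um wide and a few tens of um
    thick.
    """
    phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    boundary = np.column_stack([160.0 + 150.0 * np.cos(phi),
                                140.0 * np.sin(phi)])
    return LGGeometry(
        tube_point=np.array([0.0, 0.0, 0.0]),
        tube_dir=np.array([0.0, 1.0, 0.0]),
        posterior_end=np.array([0.0, -150.0, 0.0]),
        z_dir=np.array([0.0, 0.0, 1.0]),
        lobe_boundary=boundary)
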