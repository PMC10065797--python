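"""Normalization and classification of dual-reporter differentiation
trajectories.

A differentiating blood progenitor loses JAK-STAT reporter signal (green,
dome-MESO-GFP) while gaining the plasmatocyte-commitment reporter (red,
eater-dsRed).  Both channels of a track are min-max normalized *jointly*
(one minimum and one maximum taken across the two markers) so the relative
differences between the markers are preserved::

    Norm.G_t = (G_t - min(G, R)) / (max(G, R) - min(G, R))
    Norm.R_t = (R_t - min(G, R)) / (max(G, R) - min(G, R))

The dsRed:GFP ratio is computed from the raw intensities,
``R_t / max(G_t, floor)``, with the floor expressed as a fraction of the
track's joint maximum so the ratio is invariant to overall intensity scale.

Two trajectory shapes are distinguished:

* *sigmoid* — a slow phase followed by a rapid switch; the ratio curve is a
  rising logistic;
* *linear* — a constant-rate ratio change, starting from cells that already
  co-express both reporters.

In the original manual workflow the shape was categorized by eye; here the choice is
operationalized as corrected-AIC model selection between a 4-parameter
logistic ``b + A / (1 + exp(-(t - t0)/tau))`` and a straight line, with an
ambiguity margin and amplitude/midpoint sanity constraints on the logistic.
The differentiation rate is the slope dR/dT of the ratio: for linear tracks
the least-squares slope over the whole track, for sigmoid tracks the secant
slope of the fitted logistic across its fast phase (the 10-90% amplitude
window, duration ``ln(81) * tau``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateTrackError, InsufficientDataError, ValidationError
from .trackio import IntensityTrack, RunConfig

__all__ = [
    "NormalizedTrack",
    "TrajectoryFit",
    "normalize_dual_channel",
    "classify_trajectory",
    "fit_differentiation_rate",
    "fast_phase_bounds",
    "activation_fold_change",
    "logistic4",
]

logger = logging.getLogger(__name__)

LN81 = math.log(81.0)   # 10-90% rise of a logistic lasts ln(81) * tau


def logistic4(t: np.ndarray, b: float, A: float, t0: float, tau: float) -> np.ndarray:
    """Four-parameter logistic: baseline b, amplitude A, midpoint t0, timescale tau."""
    arg = np.clip(-(np.asarray(t, dtype=float) - t0) / tau, -700.0, 700.0)
    return b + A / (1.0 + np.exp(arg))


@dataclass
class NormalizedTrack:
    """Jointly min-max normalized channels plus the dsRed:GFP ratio series."""

    cell_id: str
    times_min: np.ndarray
    norm_green: np.ndarray      # Norm.G, unitless in [0, 1]
    norm_red: np.ndarray        # Norm.R, unitless in [0, 1]
    ratio: np.ndarray           # dsRed:GFP, raw red / floored raw green
    norm_min: float             # min(G, R) actually used, a.u.
    norm_max: float             # max(G, R) actually used, a.u.
    ratio_clipped: np.ndarray | None = None  # frames where the green floor engaged
    label: str | None = None

    @property
    def n_frames(self) -> int:
        return len(self.times_min)


@dataclass
class TrajectoryFit:
    """Result of sigmoid-vs-linear model selection on one ratio trajectory."""

    cell_id: str
    trajectory_class: str                 # {"sigmoid", "linear", "ambiguous"}
    logistic_params: tuple[float, float, float, float] | None  # (b, A, t0, tau)
    linear_params: tuple[float, float]    # (intercept, slope)
    delta_aicc: float                     # linear AICc - logistic AICc
    rate: float | None                    # dsRed:GFP ratio units per minute
    fast_phase: tuple[float, float] | None  # (t_start, t_end), min
    resid_sd: float                       # residual SD of the selected model
    label: str | None = None

    def summary(self) -> pd.Series:
        """One-row human-readable summary of the fit."""
        b, A, t0, tau = (self.logistic_params if self.logistic_params is not None
                         else (np.nan,) * 4)
        fs, fe = self.fast_phase if self.fast_phase is not None else (np.nan, np.nan)
        return pd.Series({
            "cell_id": self.cell_id,
            "class": self.trajectory_class,
            "b": b, "A": A, "t0": t0, "tau": tau,
            "intercept": self.linear_params[0], "slope": self.linear_params[1],
            "delta_aicc": self.delta_aicc,
            "rate_per_min": self.rate if self.rate is not None else np.nan,
            "fast_start_min": fs, "fast_end_min": fe,
            "resid_sd": self.resid_sd,
        })


def activation_fold_change(n_events_treated: int, n_videos_treated: int,
                           n_events_control: int, n_videos_control: int
                           ) -> float:
    """Fold change in the per-video differentiation-event rate between a
    treated (e.g. infected) and a control group."""
    for name, v in (("n_videos_treated", n_videos_treated),
                    ("n_videos_control", n_videos_control)):
        if v <= 0:
            raise ValidationError(f"{name} must be > 0")
    if n_events_control <= 0:
        raise ValidationError("control group has no events; fold undefined")
    return (n_events_treated / n_videos_treated) / \
        (n_events_control / n_videos_control)


def normalize_dual_channel(track: IntensityTrack,
                           ratio_floor: float = 0.01) -> NormalizedTrack:
    """Jointly min-max normalize the two channels of one track.

    The minimum and maximum are taken across *both* markers of the cell's own
    time course, so one frame attains 0 and one attains 1 across the two
    channels jointly and the between-channel differences are preserved.

    Raises :class:`DegenerateTrackError` when both channels are constant and
    equal (max(G, R) == min(G, R)).
    """
    lo = float(min(track.green.min(), track.red.min()))
    hi = float(max(track.green.max(), track.red.max()))
    if hi <= lo:
        raise DegenerateTrackError(
            f"track {track.cell_id}: max(G,R) == min(G,R); normalization undefined")
    span = hi - lo
    norm_g = (track.green - lo) / span
    norm_r = (track.red - lo) / span
    floor = ratio_floor * hi
    g_floored = np.maximum(track.green, floor)
    ratio = track.red / g_floored
    clipped = track.green < floor
    return NormalizedTrack(
        cell_id=track.cell_id, times_min=track.times_min.copy(),
        norm_green=norm_g, norm_red=norm_r, ratio=ratio,
        norm_min=lo, norm_max=hi, ratio_clipped=clipped, label=track.label)


def _aicc(rss: float, n: int, k: int) -> float:
    """Corrected AIC for a Gaussian least-squares fit with k parameters
    (error variance counted as one of them)."""
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def _fit_logistic(t: np.ndarray, y: np.ndarray):
    """Deterministic least-squares logistic fit; returns (params, rss) or None."""
    span = t[-1] - t[0]
    b0 = float(y.min())
    a0 = float(y.max() - y.min())
    if a0 <= 0:
        return None
    # midpoint guess: first crossing of the half amplitude
    above = np.nonzero(y >= b0 + a0 / 2)[0]
    t0_guess = float(t[above[0]]) if len(above) else float(t[len(t) // 2])
    best = None
    for tau0 in (span / 20, span / 6):
        try:
            popt, _ = curve_fit(
                logistic4, t, y, p0=[b0, a0, t0_guess, max(tau0, 1e-3)],
                method="lm", maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        popt = list(popt)
        if popt[3] < 0:
            # mirrored parameterization: flip to the equivalent tau > 0 form
            popt = [popt[0] + popt[1], -popt[1], popt[2], -popt[3]]
        rss = float(np.sum((y - logistic4(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (tuple(float(p) for p in popt), rss)
    return best


def classify_trajectory(norm: NormalizedTrack,
                        config: RunConfig | None = None) -> TrajectoryFit:
    """Classify one ratio trajectory as sigmoid, linear or ambiguous.

    Both a 4-parameter logistic and a straight line are least-squares fitted
    to ratio vs time; the class is chosen by corrected AIC with an ambiguity
    margin.  Selecting the logistic additionally requires its midpoint to lie
    inside the observed interval and its amplitude to exceed twice the
    residual SD — a near-flat or extrapolated "logistic" is not a switch.
    A non-convergent logistic falls back to the linear class with a warning.
    """
    config = config or RunConfig()
    t = np.asarray(norm.times_min, dtype=float)
    y = np.asarray(norm.ratio, dtype=float)
    usable = np.isfinite(y)
    if norm.ratio_clipped is not None:
        defined = usable & ~norm.ratio_clipped
    else:
        defined = usable
    if usable.sum() < 10:
        raise InsufficientDataError(
            f"track {norm.cell_id}: {int(usable.sum())} usable frames (< 10)")
    if defined.sum() < 0.8 * len(y):
        raise InsufficientDataError(
            f"track {norm.cell_id}: ratio defined on "
            f"{defined.sum()}/{len(y)} frames (< 80%)")
    t, y = t[usable], y[usable]
    if config.smoothing_window > 1:
        w = int(config.smoothing_window)
        kernel = np.ones(w) / w
        y = np.convolve(y, kernel, mode="same")
    n = len(y)

    slope, intercept = np.polyfit(t, y, 1)
    lin_pred = intercept + slope * t
    rss_lin = float(np.sum((y - lin_pred) ** 2))
    aicc_lin = _aicc(rss_lin, n, k=3)

    log_fit = _fit_logistic(t, y)
    if log_fit is None:
        logger.warning("track %s: logistic fit did not converge; "
                       "falling back to linear", norm.cell_id)
        fit = TrajectoryFit(
            cell_id=norm.cell_id, trajectory_class="linear",
            logistic_params=None, linear_params=(float(intercept), float(slope)),
            delta_aicc=float("-inf"), rate=None, fast_phase=None,
            resid_sd=math.sqrt(rss_lin / n), label=norm.label)
        fit.rate = fit_differentiation_rate(norm, fit)
        return fit

    (b, A, t0, tau), rss_log = log_fit
    aicc_log = _aicc(rss_log, n, k=5)
    delta = aicc_lin - aicc_log
    resid_sd_log = math.sqrt(rss_log / n)

    # A sigmoid call requires that the switch itself was observed: the fitted
    # fast phase must lie inside the recorded window (a near-straight logistic
    # with a huge tau extrapolates its crossings far outside) and the rising
    # amplitude must stand clear of the residual noise.  An inadmissible
    # logistic cannot compete, whatever its AICc.
    lo_c, hi_c = fast_phase_bounds_from_params(t0, tau, config)
    n_fast = int(np.sum((t >= lo_c) & (t <= hi_c)))
    admissible = (t[0] <= lo_c and hi_c <= t[-1]
                  and A > 2 * resid_sd_log and tau > 0 and n_fast >= 3)
    if not admissible:
        cls = "linear"
    elif abs(delta) < config.aicc_margin:
        cls = "ambiguous"
    else:
        cls = "sigmoid" if delta > 0 else "linear"

    fast = None
    if cls == "sigmoid":
        fast = fast_phase_bounds_from_params(t0, tau, config,
                                             window=(float(t[0]), float(t[-1])),
                                             cell_id=norm.cell_id)
    resid_sd = resid_sd_log if cls == "sigmoid" else math.sqrt(rss_lin / n)
    fit = TrajectoryFit(
        cell_id=norm.cell_id, trajectory_class=cls,
        logistic_params=(b, A, t0, tau),
        linear_params=(float(intercept), float(slope)),
        delta_aicc=float(delta), rate=None, fast_phase=fast,
        resid_sd=float(resid_sd), label=norm.label)
    if cls != "ambiguous":
        fit.rate = fit_differentiation_rate(norm, fit)
    return fit


def fast_phase_bounds_from_params(t0: float, tau: float,
                                  config: RunConfig | None = None,
                                  window: tuple[float, float] | None = None,
                                  cell_id: str = "?") -> tuple[float, float]:
    """Fast-phase bounds of a fitted logistic.

    The fast phase is the window between the quantile crossings of the fitted
    amplitude (default 10% and 90%: ``b + 0.1 A`` to ``b + 0.9 A``), so its
    duration is exactly ``ln(81) * tau`` at the defaults.  Crossings outside
    the observed time window are clipped to it with a warning.
    """
    config = config or RunConfig()
    lo_q, hi_q = config.fast_phase_quantiles
    t_start = t0 + tau * math.log(lo_q / (1 - lo_q))
    t_end = t0 + tau * math.log(hi_q / (1 - hi_q))
    if window is not None:
        w0, w1 = window
        if t_start < w0 or t_end > w1:
            logger.warning("track %s: fast phase [%.1f, %.1f] clipped to "
                           "observed window [%.1f, %.1f]",
                           cell_id, t_start, t_end, w0, w1)
        t_start = min(max(t_start, w0), w1)
        t_end = min(max(t_end, w0), w1)
    return (float(t_start), float(t_end))


def fast_phase_bounds(fit: TrajectoryFit,
                      config: RunConfig | None = None,
                      window: tuple[float, float] | None = None,
                      ) -> tuple[float, float]:
    """Fast-phase bounds for a sigmoid-classified fit (see
    :func:`fast_phase_bounds_from_params`)."""
    if fit.trajectory_class != "sigmoid" or fit.logistic_params is None:
        raise ValidationError(
            f"fast phase is defined for sigmoid fits only "
            f"(track {fit.cell_id} is {fit.trajectory_class})")
    _, _, t0, tau = fit.logistic_params
    return fast_phase_bounds_from_params(t0, tau, config, window, fit.cell_id)


def fit_differentiation_rate(norm: NormalizedTrack, fit: TrajectoryFit) -> float:
    """Differentiation rate dR/dT in ratio units per minute.

    Linear class: ordinary least-squares slope of ratio vs time over the
    whole track.  Sigmoid class: the secant slope of the fitted logistic
    across the fast phase, ``(f(t_end) - f(t_start)) / (t_end - t_start)``
    (equal to ``0.8 A / (ln(81) tau)`` when the 10-90% window is unclipped).
    """
    if fit.trajectory_class == "ambiguous":
        raise ValidationError(
            f"track {fit.cell_id}: rate undefined for ambiguous class")
    t = np.asarray(norm.times_min, dtype=float)
    y = np.asarray(norm.ratio, dtype=float)
    if fit.trajectory_class == "sigmoid":
        if fit.fast_phase is None:
            fit.fast_phase = fast_phase_bounds(
                fit, window=(float(t[0]), float(t[-1])))
        t_start, t_end = fit.fast_phase
        in_phase = (t >= t_start) & (t <= t_end)
        if in_phase.sum() < 3:
            raise InsufficientDataError(
                f"track {fit.cell_id}: fast phase covers "
                f"{int(in_phase.sum())} frames (< 3)")
        b, A, t0, tau = fit.logistic_params
        f0 = logistic4(np.array([t_start]), b, A, t0, tau)[0]
        f1 = logistic4(np.array([t_end]), b, A, t0, tau)[0]
        rate = (f1 - f0) / (t_end - t_start)
    else:
        slope, _ = np.polyfit(t, y, 1)
        rate = slope
    fit.rate = float(rate)
    return fit.rate
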