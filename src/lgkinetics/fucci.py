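"""Cell-cycle phase calling from two-channel FUCCI traces.

The fly FUCCI system expresses GFP- and RFP-tagged degrons of E2f1 and CycB:
E2f1-GFP is degraded at S-phase onset and CycB-RFP from mid-mitosis through
G1, so interphase cells read green-only in G1, red-only in S and yellow
(both) in G2.  Both reporters drop during mitosis because the nucleus breaks
down, so an M call is a both-low stretch flanked by a G2-like (both-present)
run before and a G1-like (green-only) run after.

Channel presence is judged relative to each trace's own maximum (raw FUCCI
intensity scales vary per cell), and phase runs shorter than a minimum
length are merged into the longer neighbour to suppress single-frame noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, ValidationError

__all__ = ["FucciTrace", "call_phase", "phase_proportions", "PHASES"]

logger = logging.getLogger(__name__)

PHASES = ("G1", "S", "G2", "M")


@dataclass
class FucciTrace:
    """One cell's FUCCI reporter time series with (optional) phase calls."""

    cell_id: str
    times_min: np.ndarray
    e2f_green: np.ndarray      # GFP.E2f1 intensity, a.u.
    cycb_red: np.ndarray       # RFP.CycB intensity, a.u.
    phases: list[str] | None = None   # per-frame {G1, S, G2, M, unknown}
    true_phases: list[str] | None = None  # generator ground truth, if any

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.e2f_green = np.asarray(self.e2f_green, dtype=float)
        self.cycb_red = np.asarray(self.cycb_red, dtype=float)
        if not (len(self.e2f_green) == len(self.cycb_red) == len(self.times_min)):
            raise ValidationError(f"trace {self.cell_id}: length mismatch")
        if np.any(self.e2f_green < 0) or np.any(self.cycb_red < 0):
            raise ValidationError(f"trace {self.cell_id}: negative intensities")

    @property
    def n_frames(self) -> int:
        return len(self.times_min)


def _runs(states: list[str]):
    """(state, start, stop) runs over a state sequence; stop is exclusive."""
    runs = []
    start = 0
    for k in range(1, len(states) + 1):
        if k == len(states) or states[k] != states[start]:
            runs.append([states[start], start, k])
            start = k
    return runs


def call_phase(trace: FucciTrace, presence_fraction: float = 0.2,
               min_run_frames: int = 4) -> list[str]:
    """Call per-frame cell-cycle phases for one FUCCI trace.

    A channel is "present" in a frame when its intensity is at least
    ``presence_fraction`` of that channel's per-trace maximum.  Green-only
    frames are G1, red-only S, both-present G2; both-absent stretches are M
    when flanked by a both-present run before and a green-only run after,
    otherwise unknown.  Runs shorter than ``min_run_frames`` are merged into
    the longer neighbour before the M/unknown decision.
    """
    if trace.n_frames < min_run_frames:
        raise InsufficientDataError(
            f"trace {trace.cell_id}: {trace.n_frames} frames "
            f"(< min_run_frames = {min_run_frames})")
    g, r = trace.e2f_green, trace.cycb_red
    if g.max() == 0 and r.max() == 0:
        logger.warning("trace %s: all-zero channels; phases unknown",
                       trace.cell_id)
        trace.phases = ["unknown"] * trace.n_frames
        return trace.phases
    g_present = g >= presence_fraction * g.max() if g.max() > 0 else np.zeros_like(g, bool)
    r_present = r >= presence_fraction * r.max() if r.max() > 0 else np.zeros_like(r, bool)
    raw = []
    for gp, rp in zip(g_present, r_present):
        raw.append("G2" if gp and rp else "G1" if gp else "S" if rp else "none")

    runs = _runs(raw)
    # merge short runs into the longer neighbour until stable
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, (state, start, stop) in enumerate(runs):
            if stop - start >= min_run_frames:
                continue
            neighbours = []
            if i > 0:
                neighbours.append(i - 1)
            if i < len(runs) - 1:
                neighbours.append(i + 1)
            target = max(neighbours, key=lambda j: runs[j][2] - runs[j][1])
            runs[target][1] = min(runs[target][1], start)
            runs[target][2] = max(runs[target][2], stop)
            del runs[i]
            # re-merge adjacent identical states
            j = 1
            while j < len(runs):
                if runs[j][0] == runs[j - 1][0]:
                    runs[j - 1][2] = runs[j][2]
                    del runs[j]
                else:
                    j += 1
            changed = True
            break

    phases = ["unknown"] * trace.n_frames
    for i, (state, start, stop) in enumerate(runs):
        if state == "none":
            before = runs[i - 1][0] if i > 0 else None
            after = runs[i + 1][0] if i < len(runs) - 1 else None
            label = "M" if (before == "G2" and after == "G1") else "unknown"
        else:
            label = state
        for k in range(start, stop):
            phases[k] = label
    trace.phases = phases
    return phases


def phase_proportions(population, at_time_min: float) -> dict[str, float]:
    """Population phase fractions at a queried time.

    For each trace whose time span covers ``at_time_min``, the phase at the
    nearest frame is taken; fractions are over called (non-unknown) cells and
    sum to 1.  Raises when no cell has a call at that time.
    """
    tally = {p: 0 for p in PHASES}
    n_called = 0
    for trace in population:
        if trace.phases is None:
            continue
        t = trace.times_min
        if not (t[0] <= at_time_min <= t[-1]):
            continue
        k = int(np.argmin(np.abs(t - at_time_min)))
        phase = trace.phases[k]
        if phase in tally:
            tally[phase] += 1
            n_called += 1
    if n_called == 0:
        raise InsufficientDataError(
            f"no called cells at t = {at_time_min} min")
    return {p: tally[p] / n_called for p in PHASES}
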