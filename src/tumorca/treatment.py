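"""Idealized therapy schedules targeting differentiated cancer cells only.

A plan combines an activity pattern (single pulse, continuous window, periodic
pulses, or periodic sustained phases) with a per-cell kill probability and an
optional gate that withholds treatment while the differentiated-cell count
sits below a fraction of the grid size.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional


class TreatmentMode(enum.Enum):
    NONE = "none"
    PULSE = "pulse"
    CONTINUOUS = "continuous"
    PERIODIC_PULSE = "periodic_pulse"
    PERIODIC_SUSTAINED = "periodic_sustained"


@dataclass(frozen=True)
class TreatmentPlan:
    mode: TreatmentMode = TreatmentMode.NONE
    start: int = 0
    end: Optional[int] = None  # None = unbounded
    period: Optional[int] = None
    pulse_duration: Optional[int] = None
    kill_prob: float = 0.0
    threshold_fraction: float = 0.0
    # Kill exactly floor(kill_prob · n_dcc) uniformly chosen cells instead of
    # an independent Bernoulli draw per cell.
    exact_fraction: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.mode, TreatmentMode):
            object.__setattr__(self, "mode", TreatmentMode(self.mode))
        if self.end is not None and self.end < self.start:
            raise ValueError("treatment end precedes start")
        if not 0.0 <= self.kill_prob <= 1.0:
            raise ValueError(f"kill_prob must lie in [0, 1], got {self.kill_prob!r}")
        if self.threshold_fraction < 0.0:
            raise ValueError("threshold_fraction must be non-negative")
        if self.mode in (TreatmentMode.PERIODIC_PULSE, TreatmentMode.PERIODIC_SUSTAINED):
            if self.period is None or self.period < 1:
                raise ValueError(f"{self.mode.value} requires period >= 1")
        if self.mode is TreatmentMode.PERIODIC_SUSTAINED:
            if self.pulse_duration is None or not 1 <= self.pulse_duration <= self.period:
                raise ValueError("pulse_duration must lie in [1, period]")


def in_active_phase(plan: TreatmentPlan, t: int) -> bool:
    """Whether iteration ``t`` falls inside the plan's schedule pattern."""
    if plan.mode is TreatmentMode.NONE:
        return False
    if t < plan.start or (plan.end is not None and t > plan.end):
        return False
    if plan.mode is TreatmentMode.PULSE:
        return t == plan.start
    if plan.mode is TreatmentMode.CONTINUOUS:
        return True
    offset = (t - plan.start) % plan.period
    if plan.mode is TreatmentMode.PERIODIC_PULSE:
        return offset == 0
    return offset < plan.pulse_duration  # PERIODIC_SUSTAINED


def should_apply(plan: TreatmentPlan, t: int, n_dcc: int, total_sites: int) -> bool:
    """Active-phase check plus the threshold gate (count ≥ fraction · sites)."""
    if not in_active_phase(plan, t):
        return False
    return n_dcc >= plan.threshold_fraction * total_sites


def apply_treatment(state, plan: TreatmentPlan) -> int:
    """Kill differentiated cancer cells per the plan; returns the kill count.

    Healthy cells and stem cells are never touched; freed sites empty
    immediately. The target list is sorted by cell id so runs are reproducible
    regardless of set-iteration order.
    """
    targets = sorted(state.dcc_ids)
    if not targets:
        return 0
    rng = state.rng
    cells = state.cells
    if plan.exact_fraction:
        n_kill = math.floor(plan.kill_prob * len(targets))
        doomed = rng.sample(targets, n_kill) if n_kill else []
    elif plan.kill_prob >= 1.0:
        doomed = targets
    else:
        p = plan.kill_prob
        doomed = [cid for cid in targets if rng.random() < p]
    for cid in doomed:
        state.kill(cells[cid], "treatment")
    return len(doomed)
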