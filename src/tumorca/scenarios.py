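"""Named experiment presets and growth/regrowth summary metrics.

Presets mirror the published experiments: a high-invasion scenario (g = 5)
with a one-shot 100% kill (``fig2``) or a continuous low-intensity window
(``fig3``), and threshold-gated scheduling comparisons at 5% stem-cell
seeding in the high-invasion (``fig4a``–``fig4d``) and high-mutation-rate
(m = 1000, ``fig5a``–``fig5d``) scenarios.

``scale`` shrinks the lattice side by a linear factor for fast replicate
runs; all probabilities and fractions are preserved. Iteration budgets and
treatment schedules are deliberately *not* scaled: the model's time constants
(mitosis delays, telomere budget, mutation rates) are independent of the
lattice size, so shrinking the schedule with the grid would fire treatments
before the tumor exists.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence

from .cell_model import Params
from .engine import SimState, initialize, run
from .observers_io import TimeSeriesRow
from .stem_cells import CscConfig, seed_cscs
from .treatment import TreatmentMode, TreatmentPlan

_HIGH_INVASION = {"g": 5.0}
_HIGH_MUTATION = {"m": 1000.0}


@dataclass(frozen=True)
class Scenario:
    name: str
    side: int
    params: Params
    csc_fraction: float
    plan: TreatmentPlan
    n_iterations: int
    scale_factor: float = 1.0

    @property
    def treatment_end(self) -> int:
        """Iteration after which regrowth is measured."""
        plan = self.plan
        if plan.mode is TreatmentMode.PULSE:
            return plan.start
        if plan.end is not None:
            return plan.end
        return plan.start


def _full_scale(name: str) -> Scenario:
    base = dict(name=name, side=50, csc_fraction=0.01, n_iterations=6000)
    gated = dict(threshold_fraction=0.01, start=0)
    if name == "fig2":
        params = Params(**_HIGH_INVASION)
        plan = TreatmentPlan(mode=TreatmentMode.PULSE, start=5000, kill_prob=1.0)
        return Scenario(params=params, plan=plan, **base)
    if name == "fig3":
        params = Params(**_HIGH_INVASION)
        plan = TreatmentPlan(
            mode=TreatmentMode.CONTINUOUS, start=5000, end=6000, kill_prob=0.01
        )
        base["n_iterations"] = 8000
        return Scenario(params=params, plan=plan, **base)

    overrides = _HIGH_INVASION if name.startswith("fig4") else _HIGH_MUTATION
    params = Params(**overrides)
    base.update(side=50, csc_fraction=0.05, n_iterations=6000)
    variant = name[-1]
    if variant == "a":
        kill = 0.01 if name.startswith("fig4") else 0.05
        plan = TreatmentPlan(mode=TreatmentMode.CONTINUOUS, kill_prob=kill, **gated)
    elif variant == "b":
        plan = TreatmentPlan(
            mode=TreatmentMode.PERIODIC_SUSTAINED,
            period=100,
            pulse_duration=60,
            kill_prob=0.10,
            **gated,
        )
    elif variant == "c":
        plan = TreatmentPlan(
            mode=TreatmentMode.PERIODIC_PULSE, period=100, kill_prob=0.50, **gated
        )
    elif variant == "d":
        plan = TreatmentPlan(
            mode=TreatmentMode.PERIODIC_PULSE, period=100, kill_prob=0.75, **gated
        )
    else:  # pragma: no cover - guarded by preset()
        raise AssertionError(name)
    return Scenario(params=params, plan=plan, **base)


PRESET_NAMES = ("fig2", "fig3", "fig4a", "fig4b", "fig4c", "fig4d",
                "fig5a", "fig5b", "fig5c", "fig5d")


def preset(name: str, scale: float = 1.0) -> Scenario:
    """Named scenario, optionally shrunk by a linear ``scale`` factor in (0, 1]."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown scenario {name!r}; valid names: {', '.join(PRESET_NAMES)}")
    scenario = _full_scale(name)
    if scale == 1.0:
        return scenario
    if not 0.0 < scale <= 1.0:
        raise ValueError(f"scale must lie in (0, 1], got {scale!r}")
    side = max(10, round(scenario.side * scale))
    return dataclasses.replace(scenario, side=side, scale_factor=scale)


def build_state(scenario: Scenario, seed: int) -> SimState:
    state = initialize(scenario.side, scenario.params, seed)
    seed_cscs(state, CscConfig(fraction=scenario.csc_fraction))
    return state


def run_scenario(
    scenario: Scenario, seed: int, n_iterations: Optional[int] = None, observers=()
) -> List[TimeSeriesRow]:
    state = build_state(scenario, seed)
    budget = scenario.n_iterations if n_iterations is None else n_iterations
    return run(state, budget, scenario.plan, observers)


def run_replicates(
    scenario: Scenario, n_replicates: int, seed_base: int = 0
) -> List[List[TimeSeriesRow]]:
    """Independent runs with consecutive seeds ``seed_base .. seed_base+n-1``."""
    return [run_scenario(scenario, seed_base + k) for k in range(n_replicates)]


class RegrowthTimes(NamedTuple):
    """Iterations to reach the occupancy target from t=0 and from treatment end;
    ``None`` marks a target never reached."""

    t_initial: Optional[int]
    t_regrow: Optional[int]


def regrowth_metrics(
    trajectory: Sequence[TimeSeriesRow],
    treatment_end: int,
    occupancy_target: float = 0.2,
) -> RegrowthTimes:
    """First-passage times of the differentiated-cell count to
    ``occupancy_target`` × total sites, before and after treatment."""
    if not trajectory:
        raise ValueError("empty trajectory")
    first = trajectory[0]
    total = first.n_healthy + first.n_dcc + first.n_csc + first.n_empty
    target = occupancy_target * total
    t_initial = None
    t_regrow = None
    for row in trajectory:
        if row.n_dcc >= target:
            if t_initial is None and row.iteration <= treatment_end:
                t_initial = row.iteration
            if row.iteration > treatment_end:
                t_regrow = row.iteration - treatment_end
                break
    return RegrowthTimes(t_initial, t_regrow)
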