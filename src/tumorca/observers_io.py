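"""Per-iteration metrics, snapshots, CSV/PGM/JSON input-output.

The trajectory format is a flat CSV with one row per iteration and a fixed,
documented column order (see ``TIMESERIES_COLUMNS``). Slices are written as
CSV matrices of category codes and optionally as ASCII (P2) PGM images.
Configuration is a strict JSON document: every key is checked, unknown keys
are rejected, and the RNG seed is mandatory.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from typing import TYPE_CHECKING, List, Optional, Sequence, Tuple

import numpy as np

from .cell_model import Params
from .stem_cells import CscConfig
from .treatment import TreatmentMode, TreatmentPlan

if TYPE_CHECKING:  # pragma: no cover
    from .engine import SimState

# Category codes used in slices and state dumps.
CAT_EMPTY = 0
CAT_HEALTHY = 1
CAT_DCC = 2
CAT_CSC = 3
CATEGORY_NAMES = ("empty", "healthy", "dcc", "csc")
# Grey levels for PGM rendering, one per category code.
_PGM_LEVELS = (0, 200, 100, 255)


@dataclass(frozen=True)
class TimeSeriesRow:
    iteration: int
    n_healthy: int
    n_dcc: int
    n_csc: int
    n_empty: int
    dcc_sg: int
    dcc_igi: int
    dcc_ea: int
    dcc_ei: int
    dcc_gi: int
    asymmetric_divisions: int
    symmetric_divisions: int
    treatment_kills: int
    deaths_random: int
    deaths_damage: int
    deaths_telomere: int
    deaths_competition: int


TIMESERIES_COLUMNS = tuple(f.name for f in dataclasses.fields(TimeSeriesRow))


def record_counts(state: "SimState", t: int) -> TimeSeriesRow:
    """Snapshot the registry counters for iteration ``t`` and reset the
    per-iteration tallies."""
    hm = state.hallmark_dcc
    deaths = state.it_deaths
    row = TimeSeriesRow(
        iteration=t,
        n_healthy=state.n_healthy,
        n_dcc=state.n_dcc,
        n_csc=state.n_csc,
        n_empty=state.n_empty,
        dcc_sg=hm[0],
        dcc_igi=hm[1],
        dcc_ea=hm[2],
        dcc_ei=hm[3],
        dcc_gi=hm[4],
        asymmetric_divisions=state.it_asym,
        symmetric_divisions=state.it_sym,
        treatment_kills=state.it_kills,
        deaths_random=deaths["random"],
        deaths_damage=deaths["damage"],
        deaths_telomere=deaths["telomere"],
        deaths_competition=deaths["competition"],
    )
    state.reset_iteration_counters()
    return row


def category_grid(state: "SimState") -> np.ndarray:
    """Full 3D array of category codes, shape (side, side, side)."""
    side = state.lattice.side
    grid = np.zeros(side ** 3, dtype=np.uint8)
    for cell in state.cells.values():
        if cell.is_csc:
            grid[cell.site] = CAT_CSC
        elif cell.genome.bits:
            grid[cell.site] = CAT_DCC
        else:
            grid[cell.site] = CAT_HEALTHY
    return grid.reshape(side, side, side)


@dataclass(frozen=True)
class SliceSnapshot:
    axis: str
    index: int
    categories: np.ndarray  # (side, side) uint8 of category codes


def central_slice(state: "SimState", axis: str) -> SliceSnapshot:
    """Category matrix of the plane through the grid center along ``axis``."""
    if axis not in ("x", "y", "z"):
        raise ValueError(f"axis must be one of x/y/z, got {axis!r}")
    side = state.lattice.side
    index = side // 2
    grid = category_grid(state)
    plane = {"x": grid[index, :, :], "y": grid[:, index, :], "z": grid[:, :, index]}[axis]
    return SliceSnapshot(axis=axis, index=index, categories=plane.copy())


# -- files ------------------------------------------------------------------


def write_timeseries(rows: Sequence[TimeSeriesRow], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(TIMESERIES_COLUMNS)
        for row in rows:
            writer.writerow(dataclasses.astuple(row))


def read_timeseries(path) -> List[TimeSeriesRow]:
    with open(path, newline="") as handle:
        reader = csv.reader(handle)
        header = tuple(next(reader))
        if header != TIMESERIES_COLUMNS:
            raise ValueError(f"unexpected trajectory header: {header}")
        return [TimeSeriesRow(*(int(v) for v in row)) for row in reader]


def write_slice(snapshot: SliceSnapshot, path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        for row in snapshot.categories:
            writer.writerow(int(v) for v in row)


def write_slice_pgm(snapshot: SliceSnapshot, path) -> None:
    """ASCII PGM (P2) with one fixed grey level per category."""
    mat = snapshot.categories
    with open(path, "w") as handle:
        handle.write(f"P2\n{mat.shape[1]} {mat.shape[0]}\n255\n")
        for row in mat:
            handle.write(" ".join(str(_PGM_LEVELS[v]) for v in row) + "\n")


def save_state_summary(state: "SimState", path) -> None:
    """Final-state dump: side, iteration, counts and the flat category grid."""
    payload = {
        "side": state.lattice.side,
        "iteration": state.iteration,
        "n_healthy": state.n_healthy,
        "n_dcc": state.n_dcc,
        "n_csc": state.n_csc,
        "n_empty": state.n_empty,
        "categories": category_grid(state).ravel().tolist(),
    }
    with open(path, "w") as handle:
        json.dump(payload, handle)


def load_state_summary(path) -> Tuple[int, int, np.ndarray]:
    """Returns (side, iteration, 3D category grid) from a state dump."""
    with open(path) as handle:
        payload = json.load(handle)
    side = int(payload["side"])
    grid = np.asarray(payload["categories"], dtype=np.uint8).reshape(side, side, side)
    return side, int(payload["iteration"]), grid


def slice_from_grid(grid: np.ndarray, axis: str) -> SliceSnapshot:
    if axis not in ("x", "y", "z"):
        raise ValueError(f"axis must be one of x/y/z, got {axis!r}")
    index = grid.shape[0] // 2
    plane = {"x": grid[index, :, :], "y": grid[:, index, :], "z": grid[:, :, index]}[axis]
    return SliceSnapshot(axis=axis, index=index, categories=plane.copy())


# -- configuration ----------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    seed: int
    side: int = 50
    iterations: int = 1000
    params: Params = dataclasses.field(default_factory=Params)
    csc: CscConfig = dataclasses.field(default_factory=CscConfig)
    treatment: TreatmentPlan = dataclasses.field(default_factory=TreatmentPlan)


_PARAM_KEYS = {
    "m", "a", "e", "g", "tl0", "p_s", "gi_factor", "boundary_fraction",
    "mitosis_delay", "cycle_hours", "neighborhood", "igi_failure_kills",
    "competition_kills_csc", "asym_daughter_mutates",
}
_CSC_KEYS = {"fraction", "p_s", "exempt_random_death"}
_TREATMENT_KEYS = {
    "mode", "start", "end", "period", "pulse_duration", "kill_prob",
    "threshold_fraction", "exact_fraction",
}
_TOP_KEYS = {"seed", "side", "iterations", "params", "csc", "treatment"}


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def config_from_dict(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("configuration root must be a JSON object")
    _check_keys(doc, _TOP_KEYS, "configuration")
    if "seed" not in doc:
        raise ConfigError("configuration is missing required field 'seed'")
    params_doc = dict(doc.get("params", {}))
    _check_keys(params_doc, _PARAM_KEYS, "'params'")
    for key in ("mitosis_delay", "cycle_hours"):
        if key in params_doc:
            params_doc[key] = tuple(params_doc[key])
    csc_doc = dict(doc.get("csc", {}))
    _check_keys(csc_doc, _CSC_KEYS, "'csc'")
    treat_doc = dict(doc.get("treatment", {}))
    _check_keys(treat_doc, _TREATMENT_KEYS, "'treatment'")
    try:
        params = Params(**params_doc)
        csc = CscConfig(**csc_doc)
        plan = TreatmentPlan(**treat_doc)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(
        seed=int(doc["seed"]),
        side=int(doc.get("side", 50)),
        iterations=int(doc.get("iterations", 1000)),
        params=params,
        csc=csc,
        treatment=plan,
    )


def config_to_dict(config: RunConfig) -> dict:
    params = dataclasses.asdict(config.params)
    params["mitosis_delay"] = list(params["mitosis_delay"])
    params["cycle_hours"] = list(params["cycle_hours"])
    treatment = dataclasses.asdict(config.treatment)
    treatment["mode"] = config.treatment.mode.value
    return {
        "seed": config.seed,
        "side": config.side,
        "iterations": config.iterations,
        "params": params,
        "csc": dataclasses.asdict(config.csc),
        "treatment": treatment,
    }


def load_config(path) -> RunConfig:
    with open(path) as handle:
        try:
            doc = json.load(handle)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"malformed JSON in {path}: {exc}") from exc
    return config_from_dict(doc)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as handle:
        json.dump(config_to_dict(config), handle, indent=2)
        handle.write("\n")
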