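"""Discrete-event simulation core.

A single binary heap orders pending mitosis events by ``(time, seq)``; ``seq``
is a global insertion counter so ties pop FIFO. Events are invalidated lazily:
an event whose cell id is no longer registered is discarded at pop time, which
is observationally equivalent to eager deletion because ids are never reused.

When an event pops, the cell runs the test cascade in this fixed order:
random death (1/a) → genetic damage (n/e, skipped under EA) → replicative
limit (telomere 0 kills unless EI) → growth-factor region (blocks unless SG)
→ free space (blocks unless IGI, which triggers the neighbor competition).
Stem-cell events are routed to :mod:`tumorca.stem_cells` instead.
"""

from __future__ import annotations

import enum
import random
from heapq import heappop, heappush
from typing import Callable, List, Optional, Sequence, Tuple

from .cell_model import (
    EA,
    EI,
    IGI,
    SG,
    Cell,
    Genome,
    Params,
    acquire_mutations,
)
from .lattice import EMPTY, Lattice

Event = Tuple[int, int, int]  # (time, seq, cell_id)

DEATH_CAUSES = ("random", "damage", "telomere", "competition")


class EventOutcome(enum.Enum):
    DIED_RANDOM = "died_random"
    DIED_DAMAGE = "died_damage"
    DIED_TELOMERE = "died_telomere"
    DIED_COMPETITION = "died_competition"
    DIVIDED = "divided"
    QUIESCENT_REQUEUED = "quiescent_requeued"


class SimState:
    """Full mutable simulation state; constructed via :func:`initialize`."""

    __slots__ = (
        "lattice",
        "params",
        "csc_config",
        "rng",
        "cells",
        "queue",
        "iteration",
        "n_healthy",
        "n_dcc",
        "n_csc",
        "hallmark_dcc",
        "dcc_ids",
        "it_asym",
        "it_sym",
        "it_kills",
        "it_deaths",
        "_seq",
        "_next_id",
    )

    def __init__(self, lattice: Lattice, params: Params, rng: random.Random):
        self.lattice = lattice
        self.params = params
        self.csc_config = None  # set by stem_cells.seed_cscs
        self.rng = rng
        self.cells: dict[int, Cell] = {}
        self.queue: List[Event] = []
        self.iteration = 0
        self.n_healthy = 0
        self.n_dcc = 0
        self.n_csc = 0
        # per-hallmark prevalence among non-stem cancer cells [SG, IGI, EA, EI, GI]
        self.hallmark_dcc = [0, 0, 0, 0, 0]
        self.dcc_ids: set[int] = set()
        self.it_asym = 0
        self.it_sym = 0
        self.it_kills = 0
        self.it_deaths = dict.fromkeys(DEATH_CAUSES, 0)
        self._seq = 0
        self._next_id = 0

    # -- registry & counters -------------------------------------------------

    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id

    def _count_add(self, cell: Cell) -> None:
        if cell.is_csc:
            self.n_csc += 1
        elif cell.genome.bits == 0:
            self.n_healthy += 1
        else:
            self.n_dcc += 1
            self.dcc_ids.add(cell.id)
            bits = cell.genome.bits
            hm = self.hallmark_dcc
            for k in range(5):
                if bits >> k & 1:
                    hm[k] += 1

    def _count_remove(self, cell: Cell) -> None:
        if cell.is_csc:
            self.n_csc -= 1
        elif cell.genome.bits == 0:
            self.n_healthy -= 1
        else:
            self.n_dcc -= 1
            self.dcc_ids.discard(cell.id)
            bits = cell.genome.bits
            hm = self.hallmark_dcc
            for k in range(5):
                if bits >> k & 1:
                    hm[k] -= 1

    def place(self, cell: Cell) -> None:
        """Register a cell and occupy its site (the site must be free)."""
        lat = self.lattice
        if lat._nbr is None:
            lat._build_tables()
        occ = lat.occ
        if occ[cell.site] != EMPTY:
            raise RuntimeError(f"site {cell.site} already occupied")
        occ[cell.site] = cell.id
        empty_nbr = lat.empty_nbr
        for j in lat._nbr[cell.site]:
            empty_nbr[j] -= 1
        self.cells[cell.id] = cell
        self._count_add(cell)

    def kill(self, cell: Cell, cause: str) -> None:
        """Remove a cell; its site becomes empty immediately."""
        self._count_remove(cell)
        del self.cells[cell.id]
        lat = self.lattice
        lat.occ[cell.site] = EMPTY
        empty_nbr = lat.empty_nbr
        for j in lat._nbr[cell.site]:
            empty_nbr[j] += 1
        if cause == "treatment":
            self.it_kills += 1
        else:
            self.it_deaths[cause] += 1

    def note_bits_gained(self, cell: Cell, old_bits: int, new_bits: int) -> None:
        """Update classification counters after a non-stem cell gained hallmarks."""
        if cell.is_csc or old_bits == new_bits:
            return
        if old_bits == 0:
            self.n_healthy -= 1
            self.n_dcc += 1
            self.dcc_ids.add(cell.id)
        gained = new_bits & ~old_bits
        hm = self.hallmark_dcc
        for k in range(5):
            if gained >> k & 1:
                hm[k] += 1

    def schedule(self, cell: Cell) -> Event:
        """Push a mitosis event at ``now + U{dmin..dmax}``."""
        lo, hi = self.params.mitosis_delay
        event = (self.iteration + self.rng.randint(lo, hi), self._seq, cell.id)
        self._seq += 1
        heappush(self.queue, event)
        return event

    def reset_iteration_counters(self) -> None:
        self.it_asym = 0
        self.it_sym = 0
        self.it_kills = 0
        self.it_deaths = dict.fromkeys(DEATH_CAUSES, 0)

    @property
    def n_empty(self) -> int:
        return self.lattice.n_sites - self.n_healthy - self.n_dcc - self.n_csc

    def __repr__(self) -> str:
        return (
            f"SimState(t={self.iteration}, healthy={self.n_healthy}, "
            f"dcc={self.n_dcc}, csc={self.n_csc})"
        )


def initialize(side: int, params: Optional[Params] = None, seed: int = 0) -> SimState:
    """Grid full of healthy cells, one scheduled mitosis per cell.

    Every cell starts with no hallmarks, telomere ``tl0`` and mutation
    denominator ``m``; initial events land at iterations ``[dmin, dmax]``.
    """
    params = params if params is not None else Params()
    lattice = Lattice(side, params.boundary_fraction, params.neighborhood)
    state = SimState(lattice, params, random.Random(seed))
    for site in range(lattice.n_sites):
        cell = Cell(state.new_id(), Genome(0, params.tl0, params.m), False, site)
        state.place(cell)
        state.schedule(cell)
    return state


def schedule_mitosis(state: SimState, cell: Cell) -> Event:
    if cell.id not in state.cells:
        raise RuntimeError("cannot schedule mitosis for a dead cell")
    return state.schedule(cell)


def divide(state: SimState, mother: Cell, target_site: int) -> Tuple[Cell, Cell]:
    """Copy the mother's genome to ``target_site``, mutate both cells, decrement
    both telomeres (floor 0) and schedule both."""
    if state.lattice.occ[target_site] != EMPTY:
        raise RuntimeError(f"division target {target_site} is occupied")
    params, rng = state.params, state.rng
    mg = mother.genome
    daughter_genome = Genome(mg.bits, mg.telomere, mg.m_denom)

    old_bits = mg.bits
    mother.genome = acquire_mutations(mg, params, rng)
    state.note_bits_gained(mother, old_bits, mother.genome.bits)
    daughter_genome = acquire_mutations(daughter_genome, params, rng)

    if mother.genome.telomere > 0:
        mother.genome.telomere -= 1
    if daughter_genome.telomere > 0:
        daughter_genome.telomere -= 1

    daughter = Cell(state.new_id(), daughter_genome, False, target_site)
    state.place(daughter)
    state.schedule(mother)
    state.schedule(daughter)
    return mother, daughter


def compete_igi(state: SimState, cell: Cell) -> EventOutcome:
    """Surrounded IGI cell fights a random neighbor; success probability 1/g.

    On success the neighbor dies and the daughter takes its site. On failure
    the dividing cell dies (default) or is requeued (``igi_failure_kills``
    False). Stem-cell neighbors are off-limits unless configured otherwise.
    """
    params, rng, lat = state.params, state.rng, state.lattice
    occ = lat.occ
    neighbors = lat.neighbors_flat(cell.site)
    if lat.empty_nbr[cell.site] != 0:
        raise RuntimeError("compete_igi called with free space available")
    if rng.random() < 1.0 / params.g:
        cells = state.cells
        candidates = [
            j
            for j in neighbors
            if params.competition_kills_csc or not cells[occ[j]].is_csc
        ]
        if candidates:
            victim_site = candidates[rng.randrange(len(candidates))]
            state.kill(cells[occ[victim_site]], "competition")
            divide(state, cell, victim_site)
            return EventOutcome.DIVIDED
    if params.igi_failure_kills:
        state.kill(cell, "competition")
        return EventOutcome.DIED_COMPETITION
    state.schedule(cell)
    return EventOutcome.QUIESCENT_REQUEUED


def process_event(state: SimState, event: Event) -> Optional[EventOutcome]:
    """Run the test cascade for one popped event; ``None`` means stale."""
    cell = state.cells.get(event[2])
    if cell is None:  # lazily-invalidated stale event
        return None
    rng = state.rng
    params = state.params

    if cell.is_csc:
        cfg = state.csc_config
        exempt = cfg.exempt_random_death if cfg is not None else True
        if not exempt and rng.random() < 1.0 / params.a:
            state.kill(cell, "random")
            return EventOutcome.DIED_RANDOM
        return _csc_divide(state, cell)

    if rng.random() < 1.0 / params.a:
        state.kill(cell, "random")
        return EventOutcome.DIED_RANDOM

    bits = cell.genome.bits
    if not bits & EA:
        n = bits.bit_count()
        if n and rng.random() < n / params.e:
            state.kill(cell, "damage")
            return EventOutcome.DIED_DAMAGE

    if cell.genome.telomere == 0 and not bits & EI:
        state.kill(cell, "telomere")
        return EventOutcome.DIED_TELOMERE

    lat = state.lattice
    if lat._in_region is None:
        lat._build_tables()
    if not lat._in_region[cell.site] and not bits & SG:
        state.schedule(cell)
        return EventOutcome.QUIESCENT_REQUEUED

    n_free = lat.empty_nbr[cell.site]
    if n_free == 0:
        if bits & IGI:
            return compete_igi(state, cell)
        state.schedule(cell)
        return EventOutcome.QUIESCENT_REQUEUED

    occ = lat.occ
    empties = [j for j in lat._nbr[cell.site] if occ[j] == EMPTY]
    target = empties[rng.randrange(len(empties))] if len(empties) > 1 else empties[0]
    divide(state, cell, target)
    return EventOutcome.DIVIDED


def run(
    state: SimState,
    n_iterations: int,
    plan=None,
    observers: Sequence[Callable] = (),
) -> list:
    """Advance ``n_iterations`` whole iterations and return one row per iteration.

    Per iteration: apply the treatment plan (if any), pop and process every
    event due at or before the iteration, then record counts and invoke
    observers. Rows are :class:`tumorca.observers_io.TimeSeriesRow`.
    """
    from .observers_io import record_counts
    from .treatment import TreatmentMode, apply_treatment, should_apply

    if n_iterations < 0:
        raise ValueError("n_iterations must be non-negative")
    rows = []
    queue = state.queue
    end = state.iteration + n_iterations
    for t in range(state.iteration + 1, end + 1):
        state.iteration = t
        if plan is not None and plan.mode is not TreatmentMode.NONE:
            if should_apply(plan, t, state.n_dcc, state.lattice.n_sites):
                apply_treatment(state, plan)
        while queue and queue[0][0] <= t:
            process_event(state, heappop(queue))
        row = record_counts(state, t)
        rows.append(row)
        for observer in observers:
            observer(state, row)
    return rows


# Imported at the end: stem_cells needs the names defined above.
from .stem_cells import csc_attempt_division as _csc_divide  # noqa: E402
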