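"""Cancer-stem-cell compartment: seeding and symmetric/asymmetric division.

Stem cells carry EA and EI permanently, never spend telomere, and by default
are exempt from the random-death test (their count is meant to stay flat over
a whole run unless symmetric divisions add to it). On division, with
probability ``p_s`` the daughter is a second stem cell; otherwise the daughter
is a differentiated cancer cell carrying exactly one uniformly chosen hallmark
and a fresh telomere.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cell_model import EA, EI, HALLMARK_MASKS, Cell, Genome, acquire_mutations
from .lattice import EMPTY

CSC_BITS = EA | EI


@dataclass(frozen=True)
class CscConfig:
    """Stem-compartment settings.

    ``fraction`` is the seeded share of total lattice sites; ``p_s`` the
    symmetric-division probability; ``exempt_random_death`` keeps the stem
    count stable against the 1/a background death channel.
    """

    fraction: float = 0.0
    p_s: float = 0.01
    exempt_random_death: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must lie in [0, 1], got {self.fraction!r}")
        if not 0.0 <= self.p_s <= 1.0:
            raise ValueError(f"p_s must lie in [0, 1], got {self.p_s!r}")


def make_csc(state, site: int) -> Cell:
    params = state.params
    genome = Genome(CSC_BITS, params.tl0, params.m)
    return Cell(state.new_id(), genome, True, site)


def seed_cscs(state, config: CscConfig):
    """Convert ``round(fraction · side³)`` random growth-region occupants into
    stem cells and schedule a mitosis for each.

    The replaced healthy cells simply disappear (their queued events go stale);
    total occupancy is unchanged.
    """
    state.csc_config = config
    n_sites = state.lattice.n_sites
    count = round(config.fraction * n_sites)
    region = state.lattice.growth_region_sites()
    if count > len(region):
        raise ValueError(
            f"cannot place {count} stem cells in a growth region of {len(region)} sites"
        )
    if count == 0:
        return state
    occ = state.lattice.occ
    for site in state.rng.sample(region, count):
        old = state.cells[occ[site]]
        state._count_remove(old)
        del state.cells[old.id]
        # in-place swap: the site stays occupied, so neighbor empty-counts
        # are untouched
        csc = make_csc(state, site)
        occ[site] = csc.id
        state.cells[csc.id] = csc
        state._count_add(csc)
        state.schedule(csc)
    return state


def csc_attempt_division(state, csc: Cell):
    """One popped stem-cell event: quiesce when surrounded, otherwise divide.

    Symmetric (probability ``p_s``): the daughter is a full stem-cell copy.
    Asymmetric: the daughter is a differentiated cell with one random hallmark,
    telomere ``tl0`` and the standard mutation denominator. The mother is
    untouched and always requeued.
    """
    from .engine import EventOutcome

    if not csc.is_csc:
        raise RuntimeError("csc_attempt_division called on a non-stem cell")
    lat = state.lattice
    if lat.empty_nbr[csc.site] == 0:
        state.schedule(csc)
        return EventOutcome.QUIESCENT_REQUEUED
    occ = lat.occ
    empties = [j for j in lat.neighbors_flat(csc.site) if occ[j] == EMPTY]

    rng = state.rng
    params = state.params
    cfg = state.csc_config
    p_s = cfg.p_s if cfg is not None else params.p_s
    target = empties[rng.randrange(len(empties))] if len(empties) > 1 else empties[0]

    if rng.random() < p_s:
        daughter = make_csc(state, target)
        state.it_sym += 1
    else:
        bits = HALLMARK_MASKS[rng.randrange(5)]
        genome = Genome(bits, params.tl0, params.m)
        if params.asym_daughter_mutates:
            genome = acquire_mutations(genome, params, rng)
        daughter = Cell(state.new_id(), genome, False, target)
        state.it_asym += 1

    state.place(daughter)
    state.schedule(daughter)
    state.schedule(csc)
    return EventOutcome.DIVIDED
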