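"""Per-cell state: hallmark genome, mutation, death probabilities, time mapping.

The five acquired capabilities are stored as a 5-bit mask on :class:`Genome`:

======  ===  ==========================================================
flag    bit  effect
======  ===  ==========================================================
SG        1  divide outside the growth-factor region
IGI       2  when surrounded, compete for a neighbor's site (prob 1/g)
EA        4  immune to the genetic-damage death test
EI        8  divide with telomere length 0
GI       16  amplified per-hallmark mutation probability
======  ===  ==========================================================

All probability helpers here are pure functions of a genome and a
:class:`Params`; the discrete-event machinery lives in :mod:`tumorca.engine`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

SG = 1
IGI = 2
EA = 4
EI = 8
GI = 16
ALL_HALLMARKS = SG | IGI | EA | EI | GI
HALLMARK_MASKS = (SG, IGI, EA, EI, GI)
HALLMARK_NAMES = ("sg", "igi", "ea", "ei", "gi")

#: Number of distinct hallmarks.
N_HALLMARKS = 5


@dataclass(frozen=True)
class HallmarkSet:
    """Immutable view of the five binary hallmark flags."""

    sg: bool = False
    igi: bool = False
    ea: bool = False
    ei: bool = False
    gi: bool = False

    @classmethod
    def from_bits(cls, bits: int) -> "HallmarkSet":
        return cls(
            sg=bool(bits & SG),
            igi=bool(bits & IGI),
            ea=bool(bits & EA),
            ei=bool(bits & EI),
            gi=bool(bits & GI),
        )

    def to_bits(self) -> int:
        bits = 0
        if self.sg:
            bits |= SG
        if self.igi:
            bits |= IGI
        if self.ea:
            bits |= EA
        if self.ei:
            bits |= EI
        if self.gi:
            bits |= GI
        return bits

    def count(self) -> int:
        return self.to_bits().bit_count()


@dataclass(frozen=True)
class Params:
    """Model parameters with the standard defaults.

    ``m``: per-hallmark mutation-rate denominator (probability 1/m per
    division); ``a``: random-death denominator (probability 1/a per event);
    ``e``: damage-death denominator (probability n/e for n active hallmarks);
    ``g``: competition denominator (success probability 1/g for a surrounded
    IGI cell); ``tl0``: initial telomere length; ``p_s``: probability of a
    symmetric stem-cell division; ``gi_factor``: multiplicative increase of
    the mutation probability while GI is active.
    """

    m: float = 100_000.0
    a: float = 1_000.0
    e: float = 10.0
    g: float = 30.0
    tl0: int = 50
    p_s: float = 0.01
    gi_factor: float = 100.0
    boundary_fraction: float = 0.95
    mitosis_delay: Tuple[int, int] = (5, 10)
    cycle_hours: Tuple[float, float] = (15.0, 24.0)
    neighborhood: str = "moore"
    # When a surrounded IGI cell loses the competition it stays quiescent and
    # is requeued (default); the alternative mode kills the dividing cell.
    # The requeue mode is required for tumor growth in a space-filled grid:
    # with loser-dies semantics a surrounded IGI clone has mean offspring
    # 2/g < 1 per attempt and always dies out.
    igi_failure_kills: bool = False
    # Whether a winning IGI competitor may displace a stem cell.
    competition_kills_csc: bool = False
    # Whether asymmetric stem-cell daughters also take the standard 1/m draw.
    asym_daughter_mutates: bool = False

    def __post_init__(self) -> None:
        for name in ("m", "a", "e", "g", "gi_factor"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value!r}")
        if not (isinstance(self.tl0, int) and self.tl0 > 0):
            raise ValueError(f"tl0 must be a positive integer, got {self.tl0!r}")
        if not 0.0 <= self.p_s <= 1.0:
            raise ValueError(f"p_s must lie in [0, 1], got {self.p_s!r}")
        if not 0.0 < self.boundary_fraction <= 1.0:
            raise ValueError(
                f"boundary_fraction must lie in (0, 1], got {self.boundary_fraction!r}"
            )
        lo, hi = self.mitosis_delay
        if not (isinstance(lo, int) and isinstance(hi, int) and 0 < lo <= hi):
            raise ValueError(f"mitosis_delay bounds must be ordered positive integers")
        clo, chi = self.cycle_hours
        if not 0 < clo <= chi:
            raise ValueError("cycle_hours bounds must be ordered and positive")
        if self.neighborhood not in ("moore", "von_neumann"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")


class Genome:
    """Heritable cell state: hallmark mask, telomere counter, mutation denominator."""

    __slots__ = ("bits", "telomere", "m_denom")

    def __init__(self, bits: int = 0, telomere: int = 50, m_denom: float = 100_000.0):
        self.bits = bits
        self.telomere = telomere
        self.m_denom = m_denom

    def copy(self) -> "Genome":
        return Genome(self.bits, self.telomere, self.m_denom)

    @property
    def n_active(self) -> int:
        return self.bits.bit_count()

    @property
    def hallmarks(self) -> HallmarkSet:
        return HallmarkSet.from_bits(self.bits)

    def has(self, mask: int) -> bool:
        return bool(self.bits & mask)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return (
            self.bits == other.bits
            and self.telomere == other.telomere
            and self.m_denom == other.m_denom
        )

    def __repr__(self) -> str:
        names = [n for n, m in zip(HALLMARK_NAMES, HALLMARK_MASKS) if self.bits & m]
        return f"Genome(hallmarks={'+'.join(names) or 'none'}, tl={self.telomere})"


class Cell:
    """A lattice occupant. ``site`` is the flat site index in the lattice."""

    __slots__ = ("id", "genome", "is_csc", "site")

    def __init__(self, cell_id: int, genome: Genome, is_csc: bool, site: int):
        self.id = cell_id
        self.genome = genome
        self.is_csc = is_csc
        self.site = site

    @property
    def kind(self) -> str:
        if self.is_csc:
            return "csc"
        return "healthy" if self.genome.bits == 0 else "dcc"

    def __repr__(self) -> str:
        return f"Cell(id={self.id}, kind={self.kind}, site={self.site})"


def effective_mutation_probability(genome: Genome, params: Params) -> float:
    """Per-hallmark activation probability at division.

    1/m normally; amplified by ``gi_factor`` (capped at 1) while GI is active.
    """
    m = genome.m_denom
    if genome.bits & GI:
        return min(1.0, params.gi_factor / m)
    if math.isinf(m):
        return 0.0
    return 1.0 / m


def acquire_mutations(genome: Genome, params: Params, rng) -> Genome:
    """Independently switch each inactive hallmark on with the effective probability.

    Active flags are never cleared. Returns the input object untouched when no
    flag changed, otherwise a fresh :class:`Genome` with the same telomere and
    denominator.
    """
    bits = genome.bits
    if bits == ALL_HALLMARKS:
        return genome
    p = effective_mutation_probability(genome, params)
    if p <= 0.0:
        return genome
    new_bits = bits
    for mask in HALLMARK_MASKS:
        if not new_bits & mask and rng.random() < p:
            new_bits |= mask
    if new_bits == bits:
        return genome
    return Genome(new_bits, genome.telomere, genome.m_denom)


def damage_death_probability(genome: Genome, params: Params) -> float:
    """Death probability from accumulated hallmark damage: n/e, zero under EA."""
    if genome.bits & EA:
        return 0.0
    return min(1.0, genome.n_active / params.e)


def random_death_probability(params: Params) -> float:
    """Background per-event death probability 1/a."""
    if math.isinf(params.a):
        return 0.0
    return 1.0 / params.a


def hours_per_iteration(params: Params) -> float:
    """Mean cell-cycle duration divided by mean mitosis delay (2.6 h by default)."""
    mean_cycle = (params.cycle_hours[0] + params.cycle_hours[1]) / 2.0
    mean_delay = (params.mitosis_delay[0] + params.mitosis_delay[1]) / 2.0
    return mean_cycle / mean_delay


def iterations_to_hours(k: float, params: Params) -> float:
    """Average real time, in hours, spanned by ``k`` iterations."""
    if k < 0:
        raise ValueError("iteration count must be non-negative")
    return k * hours_per_iteration(params)


def iterations_to_days(k: float, params: Params) -> float:
    return iterations_to_hours(k, params) / 24.0


def iterations_to_weeks(k: float, params: Params) -> float:
    return iterations_to_hours(k, params) / (24.0 * 7.0)
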