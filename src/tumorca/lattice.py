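"""3D cubic lattice: occupancy, neighborhoods, growth-factor region.

Sites are 0-based integer triples ``(x, y, z)``; internally they are flattened
to ``x*side² + y*side + z``. There are no periodic boundaries: neighborhoods
are clipped at the faces. The growth-factor region is the central sub-box
obtained by trimming ``growth_margin`` planes from every face.
"""

from __future__ import annotations

from typing import Iterable, List, Set, Tuple

Site = Tuple[int, int, int]

#: Sentinel stored at unoccupied sites.
EMPTY = -1

_MOORE_OFFSETS = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)
_VON_NEUMANN_OFFSETS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def growth_margin_for(side: int, boundary_fraction: float) -> int:
    """Per-face exclusion width for a boundary fraction f: max(1, round(side·(1−f)/2)),
    or 0 when f == 1 (no exclusion)."""
    if boundary_fraction == 1.0:
        return 0
    return max(1, int(round(side * (1.0 - boundary_fraction) / 2.0)))


def growth_region_volume_fraction(boundary_fraction: float) -> float:
    """Continuum volume fraction of a sub-box spanning ``boundary_fraction`` of
    each dimension: f³."""
    if not 0.0 < boundary_fraction <= 1.0:
        raise ValueError(f"boundary_fraction must lie in (0, 1], got {boundary_fraction!r}")
    return boundary_fraction ** 3


class Lattice:
    """Cubic occupancy grid of ``side³`` sites."""

    __slots__ = (
        "side",
        "growth_margin",
        "occ",
        "neighborhood",
        "_nbr",
        "_in_region",
        "empty_nbr",
    )

    def __init__(self, side: int, boundary_fraction: float = 0.95, neighborhood: str = "moore"):
        if not isinstance(side, int) or side < 3:
            raise ValueError(f"side must be an integer >= 3, got {side!r}")
        if not 0.0 < boundary_fraction <= 1.0:
            raise ValueError(
                f"boundary_fraction must lie in (0, 1], got {boundary_fraction!r}"
            )
        if neighborhood not in ("moore", "von_neumann"):
            raise ValueError(f"unknown neighborhood {neighborhood!r}")
        margin = growth_margin_for(side, boundary_fraction)
        if 2 * margin >= side:
            raise ValueError(
                f"growth margin {margin} leaves no growth region on a side-{side} lattice"
            )
        self.side = side
        self.growth_margin = margin
        self.neighborhood = neighborhood
        self.occ: List[int] = [EMPTY] * side ** 3
        self._nbr: List[Tuple[int, ...]] | None = None  # built lazily
        self._in_region: List[bool] | None = None
        # Per-site count of EMPTY neighbors, kept incrementally by the engine
        # (occupy/vacate); valid once _build_tables has run on an empty grid.
        self.empty_nbr: List[int] = []

    # -- geometry -----------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.side ** 3

    @property
    def n_occupied(self) -> int:
        return self.n_sites - self.occ.count(EMPTY)

    def index(self, site: Site) -> int:
        x, y, z = site
        s = self.side
        if not (0 <= x < s and 0 <= y < s and 0 <= z < s):
            raise ValueError(f"site {site!r} is outside a side-{s} lattice")
        return (x * s + y) * s + z

    def site_coords(self, index: int) -> Site:
        s = self.side
        x, rem = divmod(index, s * s)
        y, z = divmod(rem, s)
        return (x, y, z)

    def _build_tables(self) -> None:
        s = self.side
        offsets = _MOORE_OFFSETS if self.neighborhood == "moore" else _VON_NEUMANN_OFFSETS
        lo = self.growth_margin
        hi = s - 1 - self.growth_margin
        nbr: List[Tuple[int, ...]] = []
        region: List[bool] = []
        for x in range(s):
            for y in range(s):
                for z in range(s):
                    acc = []
                    for dx, dy, dz in offsets:
                        nx, ny, nz = x + dx, y + dy, z + dz
                        if 0 <= nx < s and 0 <= ny < s and 0 <= nz < s:
                            acc.append((nx * s + ny) * s + nz)
                    nbr.append(tuple(acc))
                    region.append(lo <= x <= hi and lo <= y <= hi and lo <= z <= hi)
        self._nbr = nbr
        self._in_region = region
        self.recount_empty_neighbors()

    def recount_empty_neighbors(self) -> None:
        """Rebuild ``empty_nbr`` from scratch out of the current occupancy."""
        if self._nbr is None:
            self._build_tables()
            return
        occ = self.occ
        self.empty_nbr = [
            sum(1 for j in nbrs if occ[j] == EMPTY) for nbrs in self._nbr
        ]

    def neighbors_flat(self, index: int) -> Tuple[int, ...]:
        if self._nbr is None:
            self._build_tables()
        return self._nbr[index]

    def in_region_flat(self, index: int) -> bool:
        if self._in_region is None:
            self._build_tables()
        return self._in_region[index]

    # -- public (coordinate) interface --------------------------------------

    def neighbors(self, site: Site) -> Set[Site]:
        """In-bounds sites at distance 1 under the configured neighborhood."""
        idx = self.index(site)
        return {self.site_coords(j) for j in self.neighbors_flat(idx)}

    def empty_neighbors(self, site: Site) -> Set[Site]:
        idx = self.index(site)
        occ = self.occ
        return {self.site_coords(j) for j in self.neighbors_flat(idx) if occ[j] == EMPTY}

    def in_growth_region(self, site: Site) -> bool:
        return self.in_region_flat(self.index(site))

    def growth_region_sites(self) -> List[int]:
        """Flat indices of all sites inside the growth-factor region."""
        if self._in_region is None:
            self._build_tables()
        return [i for i, inside in enumerate(self._in_region) if inside]

    def iter_sites(self) -> Iterable[Site]:
        s = self.side
        for x in range(s):
            for y in range(s):
                for z in range(s):
                    yield (x, y, z)

    def __repr__(self) -> str:
        return (
            f"Lattice(side={self.side}, occupied={self.n_occupied}/{self.n_sites}, "
            f"margin={self.growth_margin})"
        )


def make_lattice(side: int, boundary_fraction: float = 0.95, neighborhood: str = "moore") -> Lattice:
    """Build an all-empty lattice; see :class:`Lattice` for validation rules."""
    return Lattice(side, boundary_fraction, neighborhood)
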