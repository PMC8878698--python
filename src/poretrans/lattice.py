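"""2D lattice world: membrane slab, discretized conical pore, and chain geometry.

The translocating object is a chain-like body (CLB): an ordered sequence of
segments sitting on nodes of a square lattice (lattice constant 1).  The
membrane is a slab of thickness ``L`` occupying lattice columns
``0 <= x <= L - 1``; everything at ``x < 0`` is the cis half-plane and
everything at ``x >= L`` is the trans half-plane.  A conical pore is cut
through the slab: column ``k`` of the slab exposes ``w(k)`` free nodes
centred on the pore axis ``y = 0``, with ``w`` interpolated linearly between
the inlet width ``phi_cis`` and the outlet width ``phi_trans``.  Slab nodes
outside the pore are rigid walls.

Consecutive chain segments are joined by bonds whose Euclidean length must
stay within ``[delta_min, delta_max]`` (defaults 2 and 4): the shortest bond
spans two segments with one empty node between them, the longest contains
three empty nodes.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Default bond-length window: shortest bond leaves one empty node between
#: consecutive segments, longest leaves three.
DELTA_MIN = 2
DELTA_MAX = 4

LatticePoint = tuple[int, int]


class NodeStatus(enum.Enum):
    """Exhaustive classification of a lattice node relative to a pore region."""

    CIS_FREE = "CIS_FREE"
    PORE = "PORE"
    WALL = "WALL"
    TRANS_FREE = "TRANS_FREE"


class GeometryError(ValueError):
    """Raised when a pore geometry field is out of its admissible range."""


def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


@dataclass(frozen=True)
class PoreGeometry:
    """Conical-pore parameters, all counted in available lattice nodes.

    Parameters
    ----------
    phi_cis : int
        Inlet width (cis-side opening), at least 2.  A width-1 channel is
        impassable by construction because the minimal bond length of 2
        needs three nodes across.
    phi_trans : int
        Outlet width (trans-side opening), at least 2.
    length : int
        Membrane thickness ``L`` (number of slab columns), at least 1.
    """

    phi_cis: int
    phi_trans: int
    length: int

    def __post_init__(self) -> None:
        for name in ("phi_cis", "phi_trans", "length"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise GeometryError(f"{name} must be an integer, got {v!r}")
        if self.phi_cis < 2:
            raise GeometryError(f"phi_cis must be >= 2, got {self.phi_cis}")
        if self.phi_trans < 2:
            raise GeometryError(f"phi_trans must be >= 2, got {self.phi_trans}")
        if self.length < 1:
            raise GeometryError(f"length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class PoreRegion:
    """A pore geometry together with its discretized set of free slab nodes.

    ``column_widths[k]`` is the pore width in slab column ``x = k``;
    ``y_min[k] .. y_max[k]`` is the corresponding free window, centred on the
    axis ``y = 0`` with the surplus node (odd/even parity mismatch) on the
    negative-y side.
    """

    geometry: PoreGeometry
    column_widths: tuple[int, ...]
    y_min: tuple[int, ...]
    y_max: tuple[int, ...]
    allowed_pore_nodes: frozenset[LatticePoint] = field(repr=False)

    @property
    def length(self) -> int:
        return self.geometry.length


def build_pore_region(geometry: PoreGeometry) -> PoreRegion:
    """Discretize a conical pore into per-column free windows.

    For ``L >= 2`` the width profile is linear in depth,
    ``w(k) = round(phi_cis + (phi_trans - phi_cis) * k / (L - 1))`` with
    rounding half away from zero, so ``w(0) = phi_cis`` and
    ``w(L-1) = phi_trans``; for ``L = 1`` the single column has width
    ``phi_cis``.  Column ``k`` exposes the ``w(k)`` nodes
    ``y in [-floor(w/2), -floor(w/2) + w - 1]``.
    """
    g = geometry
    L = g.length
    if L == 1:
        widths = [g.phi_cis]
    else:
        widths = [
            _round_half_away(g.phi_cis + (g.phi_trans - g.phi_cis) * k / (L - 1))
            for k in range(L)
        ]
    y_min = [-(w // 2) for w in widths]
    y_max = [lo + w - 1 for lo, w in zip(y_min, widths)]
    nodes = frozenset(
        (k, y) for k, (lo, hi) in enumerate(zip(y_min, y_max)) for y in range(lo, hi + 1)
    )
    return PoreRegion(
        geometry=g,
        column_widths=tuple(widths),
        y_min=tuple(y_min),
        y_max=tuple(y_max),
        allowed_pore_nodes=nodes,
    )


def bond_ok(
    p: LatticePoint,
    q: LatticePoint,
    delta_min: int = DELTA_MIN,
    delta_max: int = DELTA_MAX,
    metric: str = "euclidean",
) -> bool:
    """True iff the bond ``p--q`` has length within ``[delta_min, delta_max]``.

    The default metric is Euclidean; ``metric="chebyshev"`` is available for
    sensitivity checks.  Comparisons are done on squared integer distances,
    so the predicate is exact.
    """
    if delta_min <= 0 or delta_min > delta_max:
        raise ValueError("need 0 < delta_min <= delta_max")
    dx = p[0] - q[0]
    dy = p[1] - q[1]
    if metric == "euclidean":
        d2 = dx * dx + dy * dy
    elif metric == "chebyshev":
        d = max(abs(dx), abs(dy))
        d2 = d * d
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return bool(delta_min * delta_min <= d2 <= delta_max * delta_max)


def node_status(p: LatticePoint, region: PoreRegion) -> NodeStatus:
    """Classify a lattice node as CIS_FREE, PORE, WALL or TRANS_FREE."""
    x, y = p
    if x < 0:
        return NodeStatus.CIS_FREE
    if x >= region.length:
        return NodeStatus.TRANS_FREE
    if region.y_min[x] <= y <= region.y_max[x]:
        return NodeStatus.PORE
    return NodeStatus.WALL


@dataclass
class ChainState:
    """An ordered CLB configuration: ``segments[0]`` is the head.

    Invariants (enforced by :func:`chain_valid`, not by the constructor):
    all segments occupy distinct nodes, consecutive segments satisfy
    :func:`bond_ok`, and no segment sits on a wall node.
    """

    segments: list[LatticePoint]
    delta_min: int = DELTA_MIN
    delta_max: int = DELTA_MAX

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        xs = np.array([p[0] for p in self.segments], dtype=np.int64)
        ys = np.array([p[1] for p in self.segments], dtype=np.int64)
        return xs, ys

    @classmethod
    def from_arrays(
        cls, xs: Iterable[int], ys: Iterable[int], delta_min: int = DELTA_MIN, delta_max: int = DELTA_MAX
    ) -> "ChainState":
        return cls([(int(x), int(y)) for x, y in zip(xs, ys)], delta_min, delta_max)


def chain_valid(chain: ChainState, region: PoreRegion, metric: str = "euclidean") -> bool:
    """Full validity predicate: self-avoidance, bond window, no wall overlap."""
    segs = chain.segments
    if len(set(segs)) != len(segs):
        return False
    for p, q in zip(segs, segs[1:]):
        if not bond_ok(p, q, chain.delta_min, chain.delta_max, metric):
            return False
    return all(node_status(p, region) is not NodeStatus.WALL for p in segs)


def pore_mask_lines(
    region: PoreRegion, pad: int = 2, chain: Sequence[LatticePoint] | None = None
) -> list[str]:
    """Render the slab (plus ``pad`` free columns on each side) as text.

    ``#`` wall, ``.`` free pore node, space for free cis/trans nodes and
    ``o`` for chain segments if a chain is given.  Rows run from the most
    negative to the most positive rendered y.
    """
    L = region.length
    ys = [y for lo, hi in zip(region.y_min, region.y_max) for y in (lo, hi)]
    y_lo, y_hi = min(ys) - pad, max(ys) + pad
    occupied = set(chain or ())
    lines = []
    for y in range(y_lo, y_hi + 1):
        row = []
        for x in range(-pad, L + pad):
            if (x, y) in occupied:
                row.append("o")
            else:
                s = node_status((x, y), region)
                row.append("#" if s is NodeStatus.WALL else "." if s is NodeStatus.PORE else " ")
        lines.append("".join(row))
    return lines
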