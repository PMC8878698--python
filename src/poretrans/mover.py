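"""Sequential-algorithm mover: biased single-segment moves with tension cascades.

A move is initiated by one randomly chosen segment (segments currently
inside the pore are up-weighted by ``bias_selection``); the initiator takes
one step drawn from its allowed neighbourhood displacements, with the
forward (+x) classes up-weighted by ``bias_direction`` while the initiator
is in the pore.  If the step stretches or compresses a bond outside the
``[delta_min, delta_max]`` window, tension propagates: consecutive
neighbours are forced to step, each choosing uniformly among steps that
restore the bond to the already-moved side, until the chain relaxes.  If a
tensioned segment has no restoring step the whole move is rejected and the
chain is restored exactly.

Time is counted in move *attempts* (accepted or rejected); an accepted-only
counter is recorded alongside for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine
from .lattice import (
    DELTA_MAX,
    DELTA_MIN,
    ChainState,
    NodeStatus,
    PoreGeometry,
    PoreRegion,
    build_pore_region,
    node_status,
)

OUTCOME_LABELS = {
    engine.TRANSLOCATED: "TRANSLOCATED",
    engine.RETRACTED: "RETRACTED",
    engine.STUCK: "STUCK",
}

NEIGHBORHOODS = {"moore": engine.MOORE, "von_neumann": engine.VON_NEUMANN}


class InitializationError(RuntimeError):
    """Chain growth failed: the geometry cannot host the requested chain."""


@dataclass(frozen=True)
class MoveConfig:
    """Parameters of the sequential mover.

    Parameters
    ----------
    n_segments : int
        Chain length N (segments), at least 2.
    bias_direction : float
        In ``[0, 1)``.  For an in-pore initiator, every allowed displacement
        with a positive x-component has its sampling weight multiplied by
        ``(1 + bias_direction) / (1 - bias_direction)``.  This is the small
        drag that distinguishes cis from trans.
    bias_selection : float
        Non-negative.  Additive selection weight of in-pore segments when
        drawing the move initiator (weight ``1 + bias_selection`` vs 1).
    neighborhood : str
        ``"moore"`` (8 displacements, default) or ``"von_neumann"`` (4).
    max_moves : int
        Stuck-detection cap on move attempts per run.
    seed : int or None
        Default RNG seed for :func:`run_translocation` when no generator is
        passed explicitly.
    """

    n_segments: int
    bias_direction: float = 0.05
    bias_selection: float = 0.5
    neighborhood: str = "moore"
    max_moves: int = 10_000_000
    seed: int | None = None
    delta_min: int = DELTA_MIN
    delta_max: int = DELTA_MAX
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError(f"n_segments must be >= 2, got {self.n_segments}")
        if not 0.0 <= self.bias_direction < 1.0:
            raise ValueError("bias_direction must be in [0, 1)")
        if self.bias_selection < 0.0:
            raise ValueError("bias_selection must be >= 0")
        if self.neighborhood not in NEIGHBORHOODS:
            raise ValueError(f"neighborhood must be one of {sorted(NEIGHBORHOODS)}")
        if self.max_moves < 1:
            raise ValueError("max_moves must be >= 1")
        if not 0 < self.delta_min <= self.delta_max:
            raise ValueError("need 0 < delta_min <= delta_max")
        if self.metric not in ("euclidean", "chebyshev"):
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def dirs(self) -> np.ndarray:
        return NEIGHBORHOODS[self.neighborhood]


@dataclass(frozen=True)
class MoveOutcome:
    accepted: bool
    steps_taken: int
    initiator: int


@dataclass(frozen=True)
class TranslocationResult:
    """Outcome of one translocation run.

    ``tau`` (translocation time, in move attempts) is meaningful only when
    ``outcome == "TRANSLOCATED"``; ``moves_accepted`` is the accepted-only
    counter kept for sensitivity analyses.
    """

    outcome: str
    tau: int | None
    moves_attempted: int
    moves_accepted: int
    seed: int


def _bond_displacements(delta_min: int, delta_max: int, metric: str) -> list[tuple[int, int]]:
    out = []
    for dx in range(-delta_max, delta_max + 1):
        for dy in range(-delta_max, delta_max + 1):
            if metric == "chebyshev":
                d = max(abs(dx), abs(dy))
                d2 = d * d
            else:
                d2 = dx * dx + dy * dy
            if delta_min**2 <= d2 <= delta_max**2:
                out.append((dx, dy))
    return out


def init_chain(config: MoveConfig, region: PoreRegion, rng: np.random.Generator) -> ChainState:
    """Grow an initial chain: head in the pore opening, body on the cis side.

    The head is placed on the inlet axis node ``(0, 0)`` (or the nearest
    allowed inlet node); segments 2..N are grown sequentially at ``x < 0``
    by uniform choice among bond-feasible, self-avoiding displacements,
    with backtracking on dead ends.
    """
    if region.y_min[0] <= 0 <= region.y_max[0]:
        head = (0, 0)
    else:  # nearest allowed inlet node to the axis
        head = (0, min(range(region.y_min[0], region.y_max[0] + 1), key=abs))
    disp = _bond_displacements(config.delta_min, config.delta_max, config.metric)
    segs: list[tuple[int, int]] = [head]
    occupied = {head}
    # stack of remaining (shuffled) candidate targets per grown segment
    stack: list[list[tuple[int, int]]] = []
    backtracks = 0
    max_backtracks = 200 * config.n_segments

    def _candidates() -> list[tuple[int, int]]:
        x0, y0 = segs[-1]
        cand = [
            (x0 + dx, y0 + dy)
            for dx, dy in disp
            if x0 + dx < 0 and (x0 + dx, y0 + dy) not in occupied
        ]
        order = rng.permutation(len(cand))
        return [cand[i] for i in order]

    stack.append(_candidates())
    while len(segs) < config.n_segments:
        if not stack[-1]:
            # dead end: drop the last grown segment and try its sibling targets
            stack.pop()
            if len(segs) == 1 or not stack:
                raise InitializationError(
                    f"cannot grow a {config.n_segments}-segment chain on the cis side"
                )
            occupied.discard(segs.pop())
            backtracks += 1
            if backtracks > max_backtracks:
                raise InitializationError(
                    f"chain growth exceeded {max_backtracks} backtracks "
                    f"(N={config.n_segments}, geometry {region.geometry})"
                )
            continue
        nxt = stack[-1].pop()
        segs.append(nxt)
        occupied.add(nxt)
        stack.append(_candidates())
    return ChainState(segs, config.delta_min, config.delta_max)


class MoverSession:
    """Mutable simulation state bound to one (chain, region, config) triple.

    Builds the dense occupancy grid once and exposes per-move and
    run-to-completion entry points; the wrapped :class:`ChainState` is kept
    in sync lazily through :attr:`chain`.
    """

    def __init__(self, chain: ChainState, region: PoreRegion, config: MoveConfig):
        if chain.n_segments != config.n_segments:
            raise ValueError("chain length does not match config.n_segments")
        self.region = region
        self.config = config
        self.xs, self.ys = chain.as_arrays()
        L = region.length
        N = config.n_segments
        reach = config.delta_max * N
        self._ox = reach + 8
        self._oy = reach + max(region.column_widths) + 16
        nx = L + 2 * (reach + 8)
        ny = 2 * self._oy + 1
        world = np.zeros((nx, ny), dtype=np.int32)
        for k in range(L):
            col = world[k + self._ox]
            col[:] = -1
            col[region.y_min[k] + self._oy : region.y_max[k] + 1 + self._oy] = 0
        for i, (x, y) in enumerate(zip(self.xs, self.ys)):
            gx, gy = x + self._ox, y + self._oy
            if not (0 <= gx < nx and 0 <= gy < ny) or world[gx, gy] != 0:
                raise ValueError(f"segment {i} at ({x}, {y}) is out of bounds or overlapping")
            world[gx, gy] = i + 1
        self.world = world
        self.counters = np.array(
            [int(np.sum(self.xs >= L)), int(np.sum(self.xs >= 0))], dtype=np.int64
        )

    @property
    def chain(self) -> ChainState:
        return ChainState.from_arrays(self.xs, self.ys, self.config.delta_min, self.config.delta_max)

    def _kernel_args(self):
        c = self.config
        return (
            self.xs,
            self.ys,
            self.world,
            self._ox,
            self._oy,
            self.region.length,
            self.counters,
            c.dirs,
            c.delta_min**2,
            c.delta_max**2,
            c.metric == "chebyshev",
            c.bias_direction,
            c.bias_selection,
        )

    def attempt(self, rng: np.random.Generator) -> MoveOutcome:
        seed = int(rng.integers(1, 2**31 - 1))
        acc, steps, init = engine.move_once(seed, *self._kernel_args())
        return MoveOutcome(bool(acc), int(steps), int(init))

    def run(self, rng: np.random.Generator) -> tuple[str, int, int, int]:
        seed = int(rng.integers(1, 2**31 - 1))
        outcome, attempts, accepted = engine.run_core(seed, *self._kernel_args(), self.config.max_moves)
        return OUTCOME_LABELS[outcome], int(attempts), int(accepted), seed


def allowed_steps(chain: ChainState, i: int, region: PoreRegion, config: MoveConfig | None = None) -> set[tuple[int, int]]:
    """Displacements segment ``i`` (1-based) may take: target free and not a wall.

    Bond feasibility is deliberately *not* filtered here; bond violations are
    what triggers tension propagation.
    """
    if not 1 <= i <= chain.n_segments:
        raise IndexError(f"segment index {i} out of range 1..{chain.n_segments}")
    dirs = (config.dirs if config is not None else engine.MOORE)
    x0, y0 = chain.segments[i - 1]
    occupied = set(chain.segments) - {(x0, y0)}
    out = set()
    for dx, dy in dirs:
        t = (x0 + dx, y0 + dy)
        if t in occupied or node_status(t, region) is NodeStatus.WALL:
            continue
        out.add((int(dx), int(dy)))
    return out


def attempt_move(
    chain: ChainState, region: PoreRegion, config: MoveConfig, rng: np.random.Generator
) -> MoveOutcome:
    """One move attempt on ``chain`` (mutated in place when accepted).

    Convenience wrapper building a fresh :class:`MoverSession`; sequences of
    moves on the same chain should use a session directly.
    """
    session = MoverSession(chain, region, config)
    outcome = session.attempt(rng)
    chain.segments[:] = session.chain.segments
    return outcome


def run_translocation(
    geometry: PoreGeometry, config: MoveConfig, rng: np.random.Generator | None = None
) -> TranslocationResult:
    """Run one full translocation through ``geometry``.

    The run terminates TRANSLOCATED once every segment has ``x >= L`` (tau =
    attempts so far), RETRACTED once every segment has returned to ``x < 0``,
    or STUCK after ``config.max_moves`` attempts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    region = build_pore_region(geometry)
    chain = init_chain(config, region, rng)
    session = MoverSession(chain, region, config)
    outcome, attempts, accepted, seed = session.run(rng)
    return TranslocationResult(
        outcome=outcome,
        tau=attempts if outcome == "TRANSLOCATED" else None,
        moves_attempted=attempts,
        moves_accepted=accepted,
        seed=seed,
    )
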