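"""Monte Carlo campaign orchestration over grids of pore geometries.

A campaign cell is one pore geometry ``(phi_cis, phi_trans, L)``.  Each cell
is run until ``sample_size`` successful translocations have been collected
(retractions and stuck runs are tallied but do not contribute tau samples)
or an attempt budget of ``attempt_budget_factor * sample_size`` total runs
is exhausted, in which case the cell is flagged incomplete and partial
results are kept.

Per-run randomness is derived deterministically from
``(base_seed, phi_cis, phi_trans, L, run_index)`` through
``numpy.random.SeedSequence`` spawn keys, so every cell — and every single
run — is individually reproducible regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .lattice import PoreGeometry
from .mover import MoveConfig, TranslocationResult, run_translocation

RAW_COLUMNS = [
    "phi_cis",
    "phi_trans",
    "length",
    "n_segments",
    "run_index",
    "seed",
    "outcome",
    "tau",
    "moves_attempted",
]


@dataclass(frozen=True)
class GridSpec:
    """A campaign definition: geometry grid, per-cell sample size, seeding."""

    phi_cis_values: tuple[int, ...]
    phi_trans_values: tuple[int, ...]
    lengths: tuple[int, ...]
    sample_size: int
    move_config: MoveConfig
    base_seed: int
    attempt_budget_factor: int = 50

    def __post_init__(self) -> None:
        for name in ("phi_cis_values", "phi_trans_values", "lengths"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.attempt_budget_factor < 1:
            raise ValueError("attempt_budget_factor must be >= 1")

    def cells(self) -> list[PoreGeometry]:
        return [
            PoreGeometry(pc, pt, L)
            for pc in self.phi_cis_values
            for pt in self.phi_trans_values
            for L in self.lengths
        ]


@dataclass(frozen=True)
class CaptureStats:
    """Capture fraction q with a Wilson 95% confidence interval."""

    q: float
    ci_low: float
    ci_high: float
    n_success: int
    n_retract: int


def capture_fraction(n_success: int, n_retract: int) -> CaptureStats:
    """Fraction of runs that thread rather than retract, with Wilson 95% CI."""
    total = n_success + n_retract
    if total < 1:
        raise ValueError("need at least one success or retraction")
    lo, hi = proportion_confint(n_success, total, alpha=0.05, method="wilson")
    return CaptureStats(
        q=n_success / total,
        ci_low=float(lo),
        ci_high=float(hi),
        n_success=n_success,
        n_retract=n_retract,
    )


@dataclass
class CellResult:
    """All runs of one grid cell, successful tau samples first-class."""

    geometry: PoreGeometry
    taus: list[int]
    n_retracted: int
    n_stuck: int
    runs: list[TranslocationResult]
    complete: bool

    @property
    def capture(self) -> CaptureStats:
        return capture_fraction(len(self.taus) + self.n_stuck, self.n_retracted)


def _run_rng(base_seed: int, geometry: PoreGeometry, run_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=base_seed,
        spawn_key=(geometry.phi_cis, geometry.phi_trans, geometry.length, run_index),
    )
    return np.random.default_rng(ss)


def run_cell(geometry: PoreGeometry, spec: GridSpec) -> CellResult:
    """Collect ``sample_size`` successful translocations for one geometry."""
    cfg = replace(spec.move_config, seed=None)
    taus: list[int] = []
    runs: list[TranslocationResult] = []
    n_retracted = 0
    n_stuck = 0
    budget = spec.attempt_budget_factor * spec.sample_size
    run_index = 0
    while len(taus) < spec.sample_size and run_index < budget:
        rng = _run_rng(spec.base_seed, geometry, run_index)
        result = run_translocation(geometry, cfg, rng)
        runs.append(result)
        if result.outcome == "TRANSLOCATED":
            taus.append(result.tau)
        elif result.outcome == "RETRACTED":
            n_retracted += 1
        else:
            n_stuck += 1
        run_index += 1
    return CellResult(
        geometry=geometry,
        taus=taus,
        n_retracted=n_retracted,
        n_stuck=n_stuck,
        runs=runs,
        complete=len(taus) >= spec.sample_size,
    )


@dataclass
class ExperimentTable:
    """Results of a whole campaign, keyed by (phi_cis, phi_trans, L)."""

    spec: GridSpec
    cells: dict[tuple[int, int, int], CellResult] = field(default_factory=dict)

    def raw_frame(self) -> pd.DataFrame:
        """One row per run, in deterministic cell-then-run order."""
        records = []
        for (pc, pt, L), cell in sorted(self.cells.items()):
            for idx, r in enumerate(cell.runs):
                records.append(
                    (pc, pt, L, self.spec.move_config.n_segments, idx, r.seed,
                     r.outcome, r.tau if r.tau is not None else -1, r.moves_attempted)
                )
        return pd.DataFrame.from_records(records, columns=RAW_COLUMNS)


def run_grid(spec: GridSpec, progress: bool = False) -> ExperimentTable:
    """Run every cell of the grid; deterministic for a fixed spec."""
    table = ExperimentTable(spec=spec)
    for geometry in spec.cells():
        cell = run_cell(geometry, spec)
        key = (geometry.phi_cis, geometry.phi_trans, geometry.length)
        table.cells[key] = cell
        if progress:
            mean = float(np.mean(cell.taus)) if cell.taus else float("nan")
            print(
                f"cell {key}: {len(cell.taus)} tau samples, mean {mean:.0f}, "
                f"{cell.n_retracted} retracted, {cell.n_stuck} stuck"
            )
    return table


def diameter_grid_spec(
    base_seed: int,
    *,
    phi_values: tuple[int, ...] = (3, 4, 6, 8, 12),
    lengths: tuple[int, ...] = (15,),
    sample_size: int = 60,
    n_segments: int = 50,
    max_moves: int = 2_000_000,
) -> GridSpec:
    """Desk-scale diameter campaign: every (phi_cis, phi_trans) pair at fixed L.

    This is the standard protocol behind the diameter regression: all 25
    diameter combinations from ``phi_values``, default bias parameters, one
    membrane thickness.  The defaults trade the full-scale study (N = 100,
    M = 1000 per cell, several thicknesses) for a campaign that runs in
    minutes while preserving the diameter-response structure.
    """
    return GridSpec(
        phi_cis_values=phi_values,
        phi_trans_values=phi_values,
        lengths=lengths,
        sample_size=sample_size,
        move_config=MoveConfig(n_segments=n_segments, max_moves=max_moves),
        base_seed=base_seed,
    )


SUMMARY_COLUMNS = [
    "phi_cis",
    "phi_trans",
    "length",
    "n_tau",
    "tau_mean",
    "tau_sd",
    "q",
    "q_ci_low",
    "q_ci_high",
    "n_retracted",
    "n_stuck",
    "complete",
]


def summarize(table: ExperimentTable) -> pd.DataFrame:
    """One row per cell: tau mean/sd (ddof=1), capture fraction, stuck count."""
    if not table.cells:
        raise ValueError("experiment table has no cells")
    rows = []
    for (pc, pt, L), cell in sorted(table.cells.items()):
        taus = np.asarray(cell.taus, dtype=float)
        cap = cell.capture
        rows.append(
            (
                pc,
                pt,
                L,
                taus.size,
                float(np.mean(taus)) if taus.size else float("nan"),
                float(np.std(taus, ddof=1)) if taus.size > 1 else float("nan"),
                cap.q,
                cap.ci_low,
                cap.ci_high,
                cell.n_retracted,
                cell.n_stuck,
                cell.complete,
            )
        )
    return pd.DataFrame.from_records(rows, columns=SUMMARY_COLUMNS)
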