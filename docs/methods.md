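# Methods

## The model

`poretrans` simulates the passage of a coarse-grained chain molecule — a
*chain-like body* (CLB) — through a conical pore cut into a thick membrane,
and provides the statistical layer used to characterise the translocation
time.

The world is a 2D square lattice (lattice constant 1).  The membrane is a
rigid slab occupying columns `0 <= x <= L-1`; `x < 0` is the cis
half-plane, `x >= L` the trans half-plane.  A pore is cut through the slab:
column `k` exposes `w(k)` free nodes centred on the axis `y = 0`, with

    w(k) = round(phi_cis + (phi_trans - phi_cis) * k / (L - 1)),

rounding half away from zero (for `L = 1`, the single column has width
`phi_cis`).  The parity-mismatch surplus node of each window is placed on
the negative-y side, a fixed deterministic convention.  Slab nodes outside
the windows are walls.  Widths below 2 are rejected at construction: the
minimal bond length of 2 needs three nodes across a channel, so a width-1
pore is impassable by construction.

The chain is an ordered sequence of `N` segments on distinct lattice nodes.
Consecutive segments are bonded; the Euclidean bond length must stay in
`[delta_min, delta_max] = [2, 4]`: the shortest bond leaves one empty node
between segments, the longest three.  Chebyshev distance is available as a
sensitivity option (`metric="chebyshev"`); all shipped defaults and
experiments use the Euclidean rule, which matches the axis-aligned reading
of the bond limits.

### Dynamics

Motion proceeds in *moves*.  One move:

1. **Initiator selection.** A segment is drawn with weight
   `1 + bias_selection` if it currently sits inside the pore and weight 1
   otherwise (default `bias_selection = 0.5`).
2. **Step selection.** The initiator steps to one of its free neighbouring
   nodes (Moore-8 neighbourhood by default, von-Neumann-4 optional).
   Occupied nodes and wall nodes are excluded; bond feasibility is *not*
   filtered at this stage.  While the initiator is inside the pore, every
   allowed displacement with a positive x-component has its sampling weight
   multiplied by `(1 + bias_direction) / (1 - bias_direction)` (default
   `bias_direction = 0.05`).  This weak in-pore drag is the only
   cis/trans asymmetry in the model.
3. **Tension propagation.** If a step pushes a bond outside `[2, 4]`, the
   strained neighbour must itself step, choosing uniformly among its free
   neighbouring nodes that restore the bond to the already-moved side.  The
   cascade propagates outward from the initiator (lower-index side first),
   each segment stepping at most once per move, until the chain relaxes.
4. **Atomic rejection.** If the initiator has no free step, or a strained
   segment has no restoring step, the whole move is rolled back exactly.

Time is counted in move attempts (accepted or rejected); an accepted-only
counter is recorded alongside so the sensitivity of any conclusion to this
bookkeeping choice can be checked.

A run starts with the chain head on the inlet axis node `(0, 0)` and the
remaining `N - 1` segments grown sequentially on the cis side (uniform
choice among bond-feasible self-avoiding placements, with backtracking).
The run ends

* `TRANSLOCATED` when every segment has `x >= L` — the translocation time
  `tau` is the number of move attempts used;
* `RETRACTED` when every segment has returned to `x < 0` (the chain backed
  out before committing); retracted runs are excluded from tau samples and
  enter the capture fraction `q` instead;
* `STUCK` when `max_moves` attempts elapse (default 1e7, config-exposed).

### Implementation notes

The inner loop operates on integer coordinate arrays and a dense occupancy
grid (free / wall / segment index) compiled with numba; the Python API
(`MoverSession`, `attempt_move`, `run_translocation`) wraps those kernels,
so there is a single implementation of the dynamics.  The grid extends
`4N + 8` columns beyond the slab on both sides and `4N + width/2 + 16` rows
above and below the axis.  For `L >= 5` a non-terminated chain always keeps
a segment inside the slab, so it can never reach the grid edge; for thinner
membranes a chain straddling the slab could in principle drift arbitrarily
far transversely, and steps beyond the grid edge are treated as blocked — a
far-field cutoff that only matters in that pathological regime.
Trajectories are a pure function of (geometry, configuration, seed): each
run draws its kernel seeds from a `numpy` `SeedSequence` keyed by
`(base_seed, phi_cis, phi_trans, L, run_index)`, so cells and runs are
reproducible independently of execution order.

## Campaigns

A campaign cell is one geometry `(phi_cis, phi_trans, L)`.  `sample_size`
(M) counts *successful translocations*; retractions and stuck runs are
tallied separately and capped by an attempt budget of `50 * M` runs, after
which the cell is flagged incomplete and its partial tau sample kept.  The
capture fraction `q = n_threaded / (n_threaded + n_retracted)` carries a
Wilson 95% interval (well-behaved at the boundaries 0 and 1).

With the default bias, capture fractions are small for narrow inlets
(q ~ 0.002 at `phi_cis = 3` up to ~0.13 at `phi_cis = 12`, N = 50, L = 15),
so the narrowest cells of a diameter campaign typically end with fewer than
M tau samples.  Their means are correspondingly noisier; the shortfall is
recorded in the summary (`n_tau`, `complete`).

## Statistics

**Moyal distribution.** Translocation times are right-skewed and are
modelled by the Moyal family

    psi(tau) = 1/(s*sqrt(2*pi)) * exp(-((tau-m)/s + exp(-(tau-m)/s)) / 2),

with location `m` at the density peak and scale `s > 0`.  Mean and standard
deviation relate to the parameters through `mean = m + s*(ln 2 + gamma)`
and `sd = s * pi / sqrt(2)` (gamma ~ 0.577, the Euler–Mascheroni constant);
both parameterizations are carried on every fit and the conversions are
verified against numerically integrated moments in the tests.  Fitting is
by maximum likelihood on `(m, log s)` (BFGS with analytic gradient,
moment-initialised, Nelder–Mead fallback).  Samples are drawn via
`-2 ln |Z|` with `Z` standard normal, which is exactly standard Moyal.

**Goodness of fit.** Cramér–von Mises (`W^2`) and Anderson–Darling (`A^2`)
statistics are computed from the probability-integral transform of the
sorted sample under the fitted distribution.  Because critical values for
the composite Moyal hypothesis are not tabulated, p-values come from a
parametric bootstrap that *refits* on every replicate (default 500
replicates, seeded; the replicate count is a parameter everywhere it is
used).  CDF values are clipped to `(1e-12, 1 - 1e-12)` with a warning if a
sample point lands numerically at 0 or 1.

**Power law.** The mean translocation time versus membrane thickness is
fitted with `tau_mean = a + b * L**xi` by least squares: the exponent is
profiled on a grid over `[0.5, 3]` (step 0.025, ties toward the smaller
exponent) with `(a, b)` solved linearly at each trial `xi`, refined by
bounded scalar minimisation and polished with a joint Levenberg–Marquardt
pass.  Noiseless inputs are recovered to 1e-6.

**Diameter regression.** At fixed L, cell means (or `log(sd)`, natural log
by default, base 10 optional) are regressed by OLS on the design
`(1, phi_cis, phi_trans, phi_cis/phi_trans)`; the ratio term is the
diameter interaction.  Reported quality figures: per-coefficient two-sided
t p-values (df = n - 4), R², the model standard error
`sqrt(SSE / (n - 4))` and the coefficient of variation (model standard
error divided by the mean response).  A constant response is reported with
R² = 0.  Rank-deficient designs (e.g., a single inlet width) raise an error
naming the collinear column.

## Default parameters

| parameter        | default | units  | meaning |
|------------------|---------|--------|---------|
| `delta_min/max`  | 2 / 4   | nodes  | bond-length window |
| `bias_direction` | 0.05    | —      | in-pore forward step up-weight |
| `bias_selection` | 0.5     | —      | in-pore initiator up-weight |
| `neighborhood`   | moore   | —      | 8 unit displacements |
| `max_moves`      | 1e7     | moves  | stuck cap per run |
| `sample_size`    | 1000    | runs   | successful translocations per cell |
| grid diameters   | {3,4,6,8,12} | nodes | inlet/outlet widths |
| grid thicknesses | {5,10,15,20,25,50,75,100} | nodes | membrane thicknesses |
| `n_segments`     | 100     | segments | chain length |

The magnitude of the movement bias is a free parameter of the model ("a
small bias"); 0.05/0.5 were fixed once as small interpretable defaults and
all shipped experiments use them.  Absolute time scales (and therefore the
absolute regression coefficients) depend on this choice; the structural
results — Moyal-distributed tau, power-law thickness dependence, the sign
pattern and interaction structure of the diameter regression — do not.

## Desk-scale protocols and what they show

The shipped experiments are scaled down from the full study (N = 100,
M = 1000 per cell, thicknesses up to 100) to sizes that run in minutes:

* **Diameter campaign** (`diameter_grid_spec`): N = 50, L = 15, M = 60, all
  25 diameter pairs from {3,4,6,8,12}².  The four-term diameter regression
  on cell means attains R² ≈ 0.90 (base seed 1), with negative diameter
  coefficients and a positive ratio coefficient.
* **Thickness trend**: N = 30, diameters (6,6), L ∈ {20, 40, 60, 80},
  M = 200.  Mean tau increases strictly with L.  For L ≲ 20 at these chain
  lengths the trend is flat in this model: the forward drive is
  proportional to the number of in-pore segments, which itself grows with
  L and offsets the longer path, so the monotone regime starts once L is
  comparable with the chain's spatial extent.
* **Direction asymmetry**: at matched L, entering the wide end
  (`phi_cis > phi_trans`) is slower than entering the narrow end — segments
  pile up when the exit feeds them out more slowly than the inlet admits
  them.
* **Clogging**: with `phi_trans = 2` and a wide inlet, threaded chains jam:
  at N = 100, L = 50, a practical move cap of 2e5 classifies roughly 10% of
  runs as STUCK, while the `phi = 2` cylinder produces none at the same cap
  (single-file motion leaves no room for clusters).  At much larger caps
  these jams eventually resolve (tau ~ 3–5e5 moves), so "stuck" is defined,
  operationally, by exceeding a computation-time cap.

Passing these desk-scale checks shows the implementation reproduces the
model's structural behaviour at reduced size; it does not certify
quantitative agreement with any physical system, nor the absolute time
scales of the full-size study.

## Known limitations

* 2D lattice only; no hydrodynamics, electrostatics, or chemical detail —
  the pore and membrane are rigid and interact with the chain only through
  excluded volume.
* Bonds are constraints on segment *positions*; for membranes thinner than
  `delta_max + 1` a bond can geometrically span the slab outside the pore.
* The capture process is simplistic (head placed at the inlet, fresh run
  per capture attempt), so `q` should be read as a relative, not absolute,
  capture efficiency.
* The bias implementation (multiplicative forward up-weight, additive
  initiator weight) is one concrete reading of a "weak in-pore drag";
  alternatives would change absolute tau scales.
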