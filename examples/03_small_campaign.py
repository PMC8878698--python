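"""A small Monte Carlo campaign over a grid of pore geometries.

Each cell collects M successful translocations (retractions/stuck runs are
tallied separately); the summary holds per-cell mean and sd of tau plus the
capture fraction q with its Wilson 95% interval.
"""

from poretrans import GridSpec, MoveConfig, run_grid, summarize

spec = GridSpec(
    phi_cis_values=(4, 8),
    phi_trans_values=(4, 8),
    lengths=(10, 20),
    sample_size=30,
    move_config=MoveConfig(n_segments=30, max_moves=2_000_000),
    base_seed=7,
)
table = run_grid(spec, progress=True)
summary = summarize(table)
print()
print(summary.to_string(index=False))

# tau_mean falls as the openings widen and rises with membrane thickness L;
# q (the capture fraction) grows with the inlet width phi_cis.
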