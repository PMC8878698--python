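"""Build a conical pore region and look at its discretization.

The membrane is a slab of L lattice columns; the pore narrows linearly from
phi_cis free nodes at the inlet to phi_trans at the outlet.
"""

from poretrans import PoreGeometry, build_pore_region, pore_mask_lines

geometry = PoreGeometry(phi_cis=8, phi_trans=3, length=12)
region = build_pore_region(geometry)

print(f"pore {geometry.phi_cis} -> {geometry.phi_trans} nodes over L = {geometry.length}")
print("column widths:", region.column_widths)
print("free pore nodes:", len(region.allowed_pore_nodes))
print()
for line in pore_mask_lines(region):
    print(line)

# The width profile interpolates 8 -> 3 monotonically; '#' marks rigid wall
# nodes, '.' the free channel a chain segment may occupy.
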