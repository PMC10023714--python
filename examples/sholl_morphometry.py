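"""Sholl analysis and morphometrics of a synthetic M1-like neuron.

Grows a small dendritic tree (4 primary dendrites, ~162 um radial extent),
writes and re-reads it as SWC, and reports the Sholl crossing profile,
branch counts and diameters, plus the coverage factor those cells would
have at a given mosaic density.
"""

import io

import retinamosaic as rm

tree = rm.gen_morphology(n_primary=4, field_radius=162.0, seed=11)

buffer = io.StringIO()
rm.write_swc(tree, buffer)
buffer.seek(0)
tree = rm.read_swc(buffer)  # SWC round trip preserves the tree

result = rm.sholl_crossings(tree, r_max=200.0, step=25.0)
print("radius (um) :", " ".join(f"{r:5.0f}" for r in result.radii))
print("crossings   :", " ".join(f"{c:5d}" for c in result.crossings))
print(f"{result.n_branches} branches, {result.n_junctions} junctions, "
      f"{result.n_endpoints} endpoints")
print(f"soma diameter {result.soma_diameter:.0f} um, "
      f"dendritic field diameter {result.field_diameter:.0f} um")

cf = rm.coverage_factor(26.75, result.field_diameter)
print(f"coverage factor at 26.75 cells/mm^2: {cf.coverage_factor:.2f}")

# Crossings start at the 4 primary dendrites, rise through the branching
# zone and fall to zero past the field radius; a coverage factor near 2
# means about two dendritic fields overlap every retinal point.
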