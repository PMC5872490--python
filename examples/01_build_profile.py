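"""Build a cell-line profile database from cell-by-cell measurements.

Simulates single-cell attribute tables for three cell lines (as an imaging
assay would produce), estimates each line's attribute means and SDs, and
round-trips the profile through its CSV database format.
"""

import numpy as np

from cellmix import (
    cyclic_mean_matrix,
    estimate_profile,
    generate_cell_by_cell,
    load_profile,
    save_profile,
)

# true per-cell attribute means: 3 lines x 3 attributes, 20% CV
mu = cyclic_mean_matrix([200.0, 600.0, 1000.0])
cbc = generate_cell_by_cell(
    mu, cv=0.2, p=1000, seed=0,
    cell_line_names=["HCT116", "A2058", "SW480"],
    attribute_names=["red", "green", "blue"],
)

profile = estimate_profile(cbc)
print(profile.to_frame().to_string(index=False))

save_profile(profile, "profile.csv")
assert load_profile("profile.csv") == profile
print("\nround-trip through profile.csv preserved every entry exactly")
# mu should match the true means to ~ cv/sqrt(p) ~ 0.6% relative error:
# the one-time profiling cost buys a reusable database for any mixture.
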