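"""Simulate a ground-truthed dataset and quantify exon inclusion (psi).

Builds a synthetic islet-like experiment (3 cell types, ND/T2D conditions,
200 cassette exons), writes it to disk in the package's text formats, then
computes the psi matrix with the coverage filter and the event-level
quantifiability filter.
"""

import numpy as np

from isletsplice import (SimConfig, simulate_dataset, write_dataset,
                         quantify_matrix, filter_exons)

cfg = SimConfig(seed=42)
ds = simulate_dataset(cfg)
write_dataset(ds, "example_output/simulated")

psi = quantify_matrix(ds.junctions)            # coverage >= 20 per entry
kept = filter_exons(psi)                       # quantifiable in >= 10% cells

print(f"cells: {len(ds.cells)}   events simulated: {len(ds.events)}")
print(f"entries passing the >=20-read coverage filter: "
      f"{psi.observed.mean():.1%}")
print(f"events quantifiable in >=10% of cells: {len(kept.events)}")
obs_err = np.nanmean(np.abs(psi.psi - np.nanmean(psi.psi, axis=0)))
print(f"mean within-event spread of observed psi: {obs_err:.3f}")
print()
print("The coverage-pass rate reflects the zero-inflated junction depth")
print("(30 mean reads, 30% dropout); the retained events feed clustering")
print("and differential testing downstream.  Files are under")
print("example_output/simulated/ with the truth tables beside the data.")
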