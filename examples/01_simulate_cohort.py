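"""Generate a barcoded two-batch synthetic tumor-infiltrate cohort.

Builds the default two-group design (8 chow vs 8 HFD samples across two
batches, ~5% live CD45+ target fraction, planted G-MDSC/CD8/PD-L1+ DC
effect), writes one FCS 3.1 file per batch plus the per-event ground
truth, and prints the realized event composition.
"""

from pathlib import Path

from cytofpipe import default_design, simulate_cohort, write_cohort_fcs
from cytofpipe.synthetic import write_truth_csv

out = Path("scratch/example_cohort")
design = default_design(seed=0, events_per_sample=5000)
tables, truth = simulate_cohort(design)
paths = write_cohort_fcs(tables, out)
write_truth_csv(truth, out / "truth.csv")

print(f"wrote {len(paths)} batches under {out}")
print("event classes:", truth.events["class"].value_counts().to_dict())
print("viability among cells:",
      truth.events.loc[truth.events["class"] == "cell", "viability"]
      .value_counts().to_dict())
live = truth.live_cd45_mask().mean()
print(f"live CD45+ target fraction: {live:.3f} (designed {design.frac_cd45})")
# The target fraction is the share of acquired events that are live
# CD45+ leukocytes; everything else is tumor cells, dead/apoptotic
# events, beads and debris that the gating stage must remove.
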