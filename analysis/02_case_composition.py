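#!/usr/bin/env python
"""Case-composition measures: case-mix weights, adjusted volume, UrS, UrD.

Reads the simulated population from results/data/ and writes the
per-hospital-year measures table to results/measures.csv.
"""

import argparse
from pathlib import Path

from hospeff import HospitalPanel, UrgencyCatalogue, casemix_weights, urgency_measures
from hospeff.measures import write_measures_csv

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--datadir", type=Path, default=Path("results/data"))
ap.add_argument("--out", type=Path, default=Path("results/measures.csv"))
args = ap.parse_args()

catalogue = UrgencyCatalogue.from_csv(args.datadir / "catalogue.csv")
panel = HospitalPanel.from_csv(args.datadir / "panel.csv", catalogue)

weights = casemix_weights(catalogue)
measures = urgency_measures(panel)
args.out.parent.mkdir(parents=True, exist_ok=True)
write_measures_csv(measures, args.out)

print(f"case-mix weights: G = {weights.G} groups, "
      f"mean weight = {weights.weights.mean():.12f}")
print(f"UrS: mean {measures['urs'].mean():.3f} "
      f"(SD {measures['urs'].std():.3f}); "
      f"{100 * (measures['urs'] < 0.5).mean():.1f}% elective-dominated")
print(f"UrD: mean {measures['urd'].mean():.3f} "
      f"(SD {measures['urd'].std():.3f})")
print(f"adjusted inpatient volume: mean {measures['adjusted_inpatients'].mean():,.0f}")
print(f"written to {args.out}")
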