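"""Generate the study cohort: morphometry tables, retest sessions, covariates.

Writes the cohort (per-subject TSV feature tables, covariates CSV, config) to
results/cohort/ so later steps can run from disk as well as in memory.
"""

import argparse
from pathlib import Path

from msnkit import CohortConfig, generate_cohort, generate_retest, write_cohort

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-subjects", type=int, default=100)
parser.add_argument("--rho", type=float, default=0.85, help="test-retest reliability")
parser.add_argument("--out", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

cohort = generate_cohort(CohortConfig(n_subjects=args.n_subjects, seed=args.seed))
generate_retest(cohort, args.rho, seed=args.seed + 1)
out = write_cohort(cohort, args.out)

print(f"wrote {cohort.n_subjects} subjects (test + retest sessions) to {out}")
print(f"regions: {len(cohort.region_labels)}, features: {len(cohort.feature_labels)}")
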