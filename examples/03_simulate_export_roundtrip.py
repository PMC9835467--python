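"""Generate a synthetic collection, export it to CSV, read it back.

The on-disk dialect is one delimited file per study: first column sample
IDs, header row gene IDs, optional `outcome` column.  Round trips are
lossless, so exported collections can feed external tools and return.
"""

import tempfile
from pathlib import Path

import numpy as np

from pairimpute import eq2_config, generate_collection, read_study, write_study

config = eq2_config(missing_proportion=0.3, n_training=3, n_per_study=50, seed=7)
training, validation, truth = generate_collection(config)

print("per-study panels (note the study-specific missing genes):")
for s in [*training, validation]:
    missing = sorted(set(truth.full[s.study_id].columns) - s.gene_set)
    print(f"  {s.study_id}: {s.n_genes} genes observed, masked: {missing or '-'}")

with tempfile.TemporaryDirectory() as tmp:
    for s in [*training, validation]:
        write_study(s, Path(tmp) / f"{s.study_id}.csv")
    back = read_study(Path(tmp) / "T1.csv")
    same_matrix = back.expression.equals(training[0].expression)
    same_outcome = np.array_equal(back.outcome, training[0].outcome)
    print(f"\nround trip exact: matrix={same_matrix}, outcome={same_outcome}")
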