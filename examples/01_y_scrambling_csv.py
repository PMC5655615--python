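"""Generate y-scrambled copies of a descriptor table.

Builds a small 21-compound table with one planted descriptor signal, writes
it to CSV, and produces five y-scrambled copies: the activity column is
permuted across compounds while every descriptor value stays put.  Each
scrambled set preserves the activity column's multiset of values exactly —
only the assignment to compounds changes — which is what makes refitting on
these sets a fair estimate of chance performance.
"""

import pathlib
import tempfile

import numpy as np

import qsarchance as qc

workdir = pathlib.Path(tempfile.mkdtemp())
table = qc.make_regression_fixture(
    qc.FixtureSpec(n=21, p=8, signal_descriptors=(0,), beta=(2.0,), noise_sd=1.0, seed=4)
)
qc.write_csv(table, workdir / "training.csv")

plan = qc.RandomizationPlan(
    mode="y_scramble", target_fields=("activity",), n_sets=5, master_seed=42
)
for i, scrambled in enumerate(qc.generate_sets(table, plan), start=1):
    qc.write_csv(scrambled, workdir / f"training_set{i:03d}.csv")
    same_values = sorted(scrambled.activity_column("activity")) == sorted(
        table.activity_column("activity")
    )
    moved = int(np.sum(scrambled.activities != table.activities))
    print(f"set {i}: multiset preserved={same_values}, {moved}/21 activities moved")

print(f"\noriginal + 5 scrambled tables written under {workdir}")
print("descriptors are bit-identical across all sets; only 'activity' was permuted")
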