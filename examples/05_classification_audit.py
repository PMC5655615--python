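"""Chance audit for a classification tree on an imbalanced screening deck.

Builds a 1:36 actives:decoys deck (100 actives, 3600 decoys — the
prevalence typical of virtual-screening benchmarks), trains a depth-3 CART
tree, and compares its confusion-matrix metrics against trees trained on
25 x-scrambled decks and against the three no-model baselines (all-binders,
all-non-binders, coin toss).  With 97% decoys, accuracy alone is useless —
predicting "non-binder" for everything scores 0.97 — so precision and F1
carry the comparison.
"""

import numpy as np

import qsarchance as qc

deck = qc.make_classification_fixture(
    qc.FixtureSpec(n=1, p=20, signal_descriptors=(0, 1), beta=(2.0, 1.5),
                   class_ratio=(100, 3600), seed=13)
)
y = deck.activity_column("active").astype(int)
tree = qc.fit_tree(deck.values, y, max_depth=3,
                   feature_names=tuple(deck.descriptor_names))
pred = qc.predict(tree, deck.values)
real = qc.classification_metrics(qc.confusion(y, pred))
print("real-data depth-3 tree:", real.rounded())

for name, guess in [("all binders", np.ones_like(y)),
                    ("all non-binders", np.zeros_like(y))]:
    m = qc.classification_metrics(qc.confusion(y, guess))
    print(f"no-model ({name}):", m.rounded())

plan = qc.RandomizationPlan(mode="pseudo", family="original",
                            target_fields=tuple(deck.descriptor_names),
                            n_sets=25, master_seed=3)
summary = qc.run_chance_test(deck, plan, qc.EngineConfig(kind="tree", max_depth=3))
print("\nchance trees (25 x-scrambled decks), mean/SD/+k·SD per metric:")
print(summary.table().round(2).to_string())

v = qc.compare_to_chance(real.f1, summary, stat="f1", k=2.3)
print(f"\nreal F1 {v.real_value:.2f} vs chance +2.3SD {v.threshold:.2f} "
      f"-> better than chance: {v.better_than_chance}")
print("high accuracy is shared by chance models (majority class); F1 and "
      "precision separate the real tree from noise")
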