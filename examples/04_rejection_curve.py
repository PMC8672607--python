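"""Classification with rejection: the FDR / RRS trade-off.

Samples whose confidence score falls inside (-eps, eps) are rejected
("I don't know"). Raising eps removes the doubtful calls first, so the
misclassification load FDR = (errors among accepted) / (all samples)
falls while the rejection rate RRS rises.
"""

import numpy as np

import pdcr
from pdcr.preprocess import FeatureTable, LabelData

table, truth = pdcr.generate(pdcr.SyntheticSpec(m=200, seed=3))
idx = np.random.default_rng(3).permutation(200)
tr, te = idx[:100], idx[100:]
sub = lambda i: FeatureTable(  # noqa: E731
    sample_ids=[table.sample_ids[j] for j in i],
    feature_ids=list(table.feature_ids), values=table.values[i],
)
labels_tr = LabelData(class_names=list(truth.labels.class_names),
                      assignment=truth.labels.assignment[tr])

model = pdcr.fit(sub(tr), labels_tr, pdcr.SolverConfig(eta=5.0, max_iter=3000),
                 pseudocount=pdcr.suggest_pseudocount(sub(tr)))
results = pdcr.predict(model, sub(te))
truth_te = [truth.labels.labels[j] for j in te]

curve = pdcr.rejection_curve(results, truth_te, epsilons=np.linspace(0, 0.9, 10))
print(f"{'eps':>5s} {'FDR':>6s} {'RRS':>6s}")
for e, f, r in zip(curve.epsilons, curve.fdr, curve.rrs):
    print(f"{e:5.2f} {f:6.3f} {r:6.3f}")
print("FDR counts errors among accepted samples over ALL samples;")
print("RRS is the fraction rejected. Abstaining trades coverage for purity.")
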