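"""Permutation importance of the average-pooled logistic regression.

The LW window is pooled into four sub-domains; each feature's importance
is the ROC-AUC drop after shuffling that feature column (30 shuffles).
The sub-domain containing the injected band should dominate.
"""

import numpy as np

from ramanclass import preprocess, select_region, two_class_config
from ramanclass.linear import (
    PoolingLogisticClassifier,
    default_pooling_scheme,
    permutation_importance,
)
from ramanclass.synthetic import generate_dataset

ds = generate_dataset(two_class_config("lw", delta=1.5, n_per_class=150, seed=3))
ds, _ = preprocess(ds)
lw = select_region(ds, "LW")

half = np.arange(lw.n_spectra) % 2 == 0
train, test = lw.subset_rows(half), lw.subset_rows(~half)
scheme = default_pooling_scheme("LW")
clf = PoolingLogisticClassifier(scheme).fit(train)
imp = permutation_importance(
    clf.feature_scores, clf.featurize(test), test.labels, n_perm=30, seed=0
)
print(f"baseline test AUC: {imp.baseline_auc:.3f}")
b = scheme.boundaries
for i, score in enumerate(imp.scores):
    print(f"  sub-domain [{b[i]:7.2f}, {b[i+1]:7.2f}] cm^-1: importance {score:+.3f}")
# The injected effect sits on the Si band (514 cm^-1) inside the last
# sub-domain [480, 549.27], which therefore carries the largest AUC drop.
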