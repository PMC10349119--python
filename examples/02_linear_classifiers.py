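"""Cross-validate the four non-neural classifiers on one spectral window.

LRA regresses the label on the window's mean intensity; L2D is the
tau-weighted nearest-mean rule on squared l2 distances; LRP pools the
window into a few sub-domain means; PCA uses the leading principal
components. Each is scored by ten-fold stratified ROC-AUC.
"""

from ramanclass import preprocess, select_region, two_class_config
from ramanclass.linear import (
    L2DClassifier,
    LRAClassifier,
    PCALogisticClassifier,
    PoolingLogisticClassifier,
    cross_validate,
    default_pooling_scheme,
)
from ramanclass.synthetic import generate_dataset

ds = generate_dataset(two_class_config("hw", delta=1.5, n_per_class=100, seed=1))
ds, _ = preprocess(ds)
hw = select_region(ds, "HW")

factories = {
    "LRA": lambda: LRAClassifier(),
    "L2D": lambda: L2DClassifier(seed=0),
    "LRP": lambda: PoolingLogisticClassifier(default_pooling_scheme("HW")),
    "PCA": lambda: PCALogisticClassifier(),
}
for name, factory in factories.items():
    cv = cross_validate(factory, hw, k=10, seed=0)
    print(f"{name}: mean AUC {cv.mean_auc:.3f} +/- {cv.sem:.3f} (SEM over 10 folds)")
# With a 1.5x CH-band effect the HW window separates the classes almost
# perfectly, so all four AUCs sit near 1.0.
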