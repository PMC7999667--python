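"""Stratified 5-fold cross-validation of all four classifier families.

Prints per-family mean metrics with 95% confidence half-widths on the
synthetic benchmark. Accuracy/sensitivity/specificity/precision use the
fixed 0.5 probability threshold; AUC is threshold-free.
"""

import warnings

warnings.filterwarnings("ignore", category=FutureWarning)

from acescreen import SynthConfig, cross_validate, generate_synthetic, make_config
from acescreen.models import FAMILIES

ds = generate_synthetic(SynthConfig(n_pos=400, seed=0))
print(f"{'family':>24} {'Acc':>7} {'Sens':>7} {'Spec':>7} {'AUC':>7} {'±AUC':>6}")
for family in FAMILIES:
    rep = cross_validate(ds, make_config(family), n_folds=5, seed=0)
    m = rep.mean
    print(f"{family:>24} {m.acc:7.4f} {m.sens:7.4f} {m.spec:7.4f} "
          f"{m.auc:7.4f} {rep.ci95['auc']:6.4f}")

print("\nAll families beat chance on the compositional signal; the tree "
      "ensembles and the calibrated SVM land within a few AUC points of "
      "each other.")
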