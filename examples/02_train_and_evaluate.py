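"""Kennard-Stone split + the three classifiers on one pretreatment.

Pretreats the spectra (first-derivative vector normalization), splits
4/5 calibration / 1/5 validation with the Kennard-Stone algorithm, fits
RF, SVM-RBF and PLS-DA, and prints the four evaluation parameters
(sensitivity, specificity, accuracy, Matthews correlation) plus AUC on
the validation set.  Values near 1 mean the two classes are cleanly
separated by their discriminating bands.
"""

import numpy as np

import ftirclass as fc

train, _ = fc.make_fixture("easy", seed=7)
t = fc.apply_recipe("vector_first", train)
split = fc.kennard_stone(t, fraction=0.8, stratified=True)
lab = t.label_array().astype(str)
Xc, yc = t.values[split.calibration_idx], lab[split.calibration_idx]
Xv, yv = t.values[split.validation_idx], lab[split.validation_idx]
print(f"calibration {len(yc)} / validation {len(yv)} samples")

fits = {
    "rf": lambda: fc.fit_rf(Xc, yc, n_tree=300, seed=7),
    "svm": lambda: fc.fit_svm_rbf(Xc, yc, seed=7),
    "plsda": lambda: fc.fit_plsda(Xc, yc, seed=7),
}
for kind, fit in fits.items():
    model = fit()
    labels, scores = fc.predict(model, Xv)
    em = fc.evaluate_predictions(yv, labels.astype(str), scores, "A")
    print(f"{kind:>6}: SENS={em.sens:.4f} SPEC={em.spec:.4f} "
          f"ACC={em.acc:.4f} MCC={em.mcc:.4f} AUC={em.auc:.4f}")
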