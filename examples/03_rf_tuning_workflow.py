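"""The random-forest tuning workflow: OOB-driven n_tree / m_try selection
and importance-based variable (VIP) selection.

Prints the OOB error along each tuning grid and shows how many wavenumber
variables survive each importance cutoff.  Lower OOB error means better
expected generalization; the selected variables cluster around the
class-discriminating bands (1545/1400/930 vs 1528/781 cm^-1).
"""

import numpy as np

import ftirclass as fc

train, _ = fc.make_fixture("easy", seed=3)
t = fc.apply_recipe("none", train)  # absorbance scale
split = fc.kennard_stone(t, fraction=0.8, stratified=True)
lab = t.label_array().astype(str)
Xc, yc = t.values[split.calibration_idx], lab[split.calibration_idx]

best_nt, nt_table = fc.tune_ntree(Xc, yc, fc.RFConfig(seed=3))
print(nt_table[["n_tree", "oob_error", "ACC"]].to_string(index=False))
print(f"-> best n_tree = {best_nt}\n")

best_mt, mt_table = fc.tune_mtry(Xc, yc, best_nt, seed=3)
print(mt_table[["m_try", "oob_error", "cal_acc"]].to_string(index=False))
print(f"-> best m_try = {best_mt} (floor(sqrt(851)) = 29)\n")

model = fc.fit_rf(Xc, yc, n_tree=best_nt, m_try=best_mt, seed=3)
imp = fc.rf_importance(model, Xc, yc)
for cutoff in (0.05, 0.01, 0.015, 0.020):
    keep = fc.select_by_vip(imp, cutoff)
    print(f"VIP cutoff {cutoff:0.3f}: {keep.size:4d} variables survive")
top = t.wavenumbers[np.argsort(-imp)[:8]]
print("top-importance wavenumbers (cm^-1):", np.sort(top)[::-1])
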