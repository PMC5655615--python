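"""Regression validation metrics for a train/test split.

Fits a 3-variable model on 21 training compounds, predicts 10 held-out
compounds, and computes the full validation panel: training r², q² by
leave-one-out and exhaustive leave-three-out, external R², regression
through the origin (R0², slope k), the Golbraikh–Tropsha criteria, cRp²
against a chance baseline, rm(test)², and the Wold permutation intercepts.
"""

import numpy as np

import qsarchance as qc

spec = qc.FixtureSpec(n=31, p=3, signal_descriptors=(0, 1, 2),
                      beta=(2.0, 1.5, 1.0), noise_sd=0.8, seed=3)
full = qc.make_regression_fixture(spec)
Xtr, ytr = full.values[:21], full.activities[:21, 0]
Xte, yte = full.values[21:], full.activities[21:, 0]

fit = qc.fit_ols(Xtr, ytr, full.descriptor_names)
print("model:", fit.equation())

r2 = fit.r2_train
q2_loo = qc.q_squared_cv(Xtr, ytr, m=1)
q2_l3o = qc.q_squared_cv(Xtr, ytr, m=3)   # all C(21,3) = 1330 triples
pred_te = qc.predict(fit, Xte)
# external R² in the Golbraikh–Tropsha / rm² convention: the squared
# correlation of observed vs predicted (free regression), which always
# upper-bounds the origin-forced R0²
R2 = float(np.corrcoef(yte, pred_te)[0, 1] ** 2)
k, R0 = qc.origin_regression(yte, pred_te)
gt = qc.golbraikh_tropsha(q2_loo, R2, R0, k)
rm2 = qc.rm2_test(R2, max(0.0, R0))
crp2 = qc.c_rp2(r2, 0.35)  # chance baseline: e.g. mhr2 from a prior audit
r_int, q_int = qc.wold_intercept_experiment(Xtr, ytr, n_perm=25, seed=9)

print(f"training r^2 = {r2:.3f}, q^2(LOO) = {q2_loo:.3f}, q^2(L3O) = {q2_l3o:.3f}")
print(f"external R^2 = {R2:.3f}, R0^2 = {R0:.3f}, slope k = {k:.3f}")
print(f"Golbraikh-Tropsha: q2>{0.5}:{gt.q2_ok} R2>{0.6}:{gt.r2_ok} "
      f"ratio<0.1:{gt.ratio_ok} 0.85<=k<=1.15:{gt.slope_ok} -> overall {gt.overall}")
print(f"cRp^2 = {crp2:.3f} (vs chance mean 0.35), rm(test)^2 = {rm2:.3f}")
print(f"permutation intercepts: R2int = {r_int:.3f} (<0.4 ok), "
      f"Q2int = {q_int:.3f} (<0.05 ok)")
print("\nq^2 < r^2 (cross-validation penalizes overfit); rm^2 and cRp^2 > 0.5 "
      "support real predictive power")
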