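"""The method-agreement battery on a pair of measurement series.

Computes Lin's concordance correlation coefficient, Bland-Altman bias
and limits of agreement with the proportional-bias test, the group-level
absolute and percent error, the linearity null (slope 1, intercept 0),
and a paired t-test — the standard report for validating a candidate
body-composition method against a reference.
"""
import numpy as np

from silhofm import full_report, reproducibility

rng = np.random.default_rng(0)
ref = rng.uniform(8, 50, 80)              # reference fat mass, kg
pred = ref + rng.normal(0.2, 2.3, 80)     # candidate with 2.3 kg error

rep = full_report(pred, ref)
print(f"n={rep.n}  mean pred {rep.mean_pred:.1f} vs ref {rep.mean_ref:.1f} kg")
print(f"R^2 = {rep.r2:.3f}   CCC = {rep.ccc:.3f}   SEE = {rep.see:.2f} kg")
print(f"APE = {rep.ape:.3f} kg ({rep.percent_error:.2f}%)")
print(f"slope {rep.slope:.3f} (p vs 1: {rep.slope_eq1_p:.2f})   "
      f"intercept {rep.intercept:.2f} (p vs 0: {rep.intercept_eq0_p:.2f})")
print(f"bias {rep.bias:.2f} kg, LOA [{rep.loa_low:.2f}, {rep.loa_high:.2f}] kg, "
      f"proportional bias p = {rep.proportional_bias_p:.2f}")

test2 = pred + rng.normal(0, 0.05, 80)    # near-identical replicate
rr = reproducibility(pred, test2)
print(f"\nreplicates: TEM = {rr.tem:.3f} kg, CV = {rr.cv_percent:.2f}%, "
      f"CCC = {rr.ccc:.4f}")
print("\nCCC rewards agreement with the identity line, not just correlation;")
print("TEM is the within-pair error of repeated measurements.")
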