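"""Correlation indices of a weakly correlated closed-shell system.

Builds a 10-electron set of spatial natural orbital occupations (five
strongly occupied orbitals slightly depleted below 2, four weakly populated
virtuals), computes every occupancy index and classifies the system against
the MP2 thresholds.
"""

import noodiag as nd

occ = [1.9952, 1.9881, 1.9811, 1.9702, 1.9419, 0.0562, 0.0331, 0.0212, 0.0130]
system = nd.ClosedShellOccupancySet(occ, n_electrons=10, label="demo")
report = nd.correlation_report(system, method="mp2")

print(f"I_ND      = {report.i_nd:.6f}   (average deviation from idempotency)")
print(f"I_D       = {report.i_d:.6f}   (dynamic correlation)")
print(f"I_T       = {report.i_t:.6f}   (= I_ND + I_D)")
print(f"Î_ND      = {report.i_nd_hat:.6f}   (size-intensive, in [0, 1])")
print(f"  occupied part {report.i_nd_hat_occ:.6f} / virtual part "
      f"{report.i_nd_hat_vir:.6f}  (particle-hole asymmetry "
      f"{report.ph_asymmetry:.3f})")
print(f"I_ND^max  = {report.i_nd_max:.6f}   (maximal single-orbital deviation)")
print(f"MP2 verdict: {report.classification}  "
      "(thresholds 0.030 / 0.037: below = safe, above = multireference)")
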