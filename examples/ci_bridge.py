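"""From a CI vector to occupancy measures without a density matrix.

Takes the exact CI expansion of a 4-site Hubbard chain, aggregates it into
c0 and excitation weights, splits the 1-RDM trace over the HF-occupied and
HF-virtual blocks (checking it against the exact density), and evaluates the
size-intensive c0 measure and the Î_ND estimate 4(1 - c0²)/N.
"""

import numpy as np

import noodiag as nd

sol = nd.exact_diagonalize(nd.ModelSpec(kind="hubbard-chain", n_sites=4, u=2.0))
exp = sol.ci_expansion()
n = sol.occupancies.n_electrons

print(f"ground-state energy      E0  = {sol.energy:.6f}")
print(f"reference weight         c0² = {exp.c0 ** 2:.6f}")
print(f"singles / doubles / higher weights: {exp.singles_weight:.6f} / "
      f"{exp.doubles_weight:.6f} / {exp.higher_weight:.6f}")

td = nd.cisd_trace_decomposition(exp)
exact_vir = float(np.trace(sol.one_rdm_alpha[2:, 2:]) +
                  np.trace(sol.one_rdm_beta[2:, 2:]))
print(f"electrons promoted to virtuals: {td.trace_vir:.6f} "
      f"(exact from the 1-RDM: {exact_vir:.6f})")

i_nd_hat, _ = nd.size_intensive(sol.occupancies)
print(f"Î_ND (exact occupancies)     = {i_nd_hat:.6f}")
print(f"Î_ND estimate 4(1-c0²)/N     = {nd.predict_ind_hat_from_c0(exp.c0, n):.6f}")
print(f"size-intensive c0, 1-c0^(2/N) = {nd.size_intensive_c0(exp.c0, n):.6f}")
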