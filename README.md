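# noodiag

Electron-correlation measures and multireference diagnostics from natural
orbital occupancies.

## The problem

Single-reference electronic-structure methods (MP2, CCSD, most density
functionals) assume one Slater determinant dominates the wave function.
When several determinants carry comparable weight — a *multireference* (MR)
system — their results degrade silently, so large-scale screening pipelines
need a cheap, method-agnostic flag. Established diagnostics have drawbacks:
`1 − c0²` requires a CI expansion and is not size-intensive, and the
Nielsen–Janssen D₂ requires doubles amplitudes, so in practice it is limited
to MP2/CC wave functions.

The eigenvalues of the one-particle reduced density matrix — the natural
orbital occupancies (NOOs) `n_iσ ∈ [0, 1]` — are available for essentially
any method, and their deviation from integer filling measures correlation
directly. `noodiag` implements the NOO indices

- `I_ND = ½ Σ_iσ n_iσ(1 − n_iσ)` — nondynamic (static) correlation, the
  deviation from idempotency of the 1-RDM, in `[0, N/2]`;
- `I_T = ½ Σ_iσ √(n_iσ(1 − n_iσ))`, `I_D = I_T − I_ND` — total and dynamic
  correlation;
- `Î_ND = 2 I_ND / N ∈ [0, 1]`, `Î_D = 2 I_D / N` — size-intensive versions,
  with the pseudo-occupied/pseudo-virtual split of `Î_ND`;
- `I_ND^max = ½ max_iσ n_iσ(1 − n_iσ) ∈ [0, ⅛]` — the maximal single-orbital
  deviation, the recommended MR **diagnostic** (a diagnostic must flag the
  most correlated corner of a system, however small, which an averaged
  measure dilutes);

their two analytic bridges,

- CI: `Î_ND ≈ 4(1 − c0²)/N` for a dominant reference determinant, consistent
  with the size-intensive leading-coefficient measure `1 − c0^{2/N}`;
- amplitudes: through the unrelaxed MP2 density blocks, whose extreme
  eigenvalues `n_H`/`n_L` connect `I_ND^max = ⅛ max(n_H(2−n_H), n_L(2−n_L))`
  to D₂ via `ñ_L ≈ 4 D₂²`;

and the equivalent `I_ND^max` classification thresholds: MP2 0.030/0.037,
CCSD 0.024/0.034 (below the first value: safe/non-MR; at or above the
second: MR; in between: caution), mirroring the D₂ thresholds 0.15/0.17–0.18.

Exactly solvable Hubbard models (dimer and open chains, full CI over the
mean-field orbital determinants) ship as in-repo oracles whose `U/t` ratio
dials the correlation strength continuously.

## Worked example

```python
import noodiag as nd

occ = [1.9952, 1.9881, 1.9811, 1.9702, 1.9419,
       0.0562, 0.0331, 0.0212, 0.0130]          # spatial NOOs, 10 electrons
system = nd.ClosedShellOccupancySet(occ, n_electrons=10)
report = nd.correlation_report(system, method="mp2")
print(report.i_nd_hat, report.i_nd_max, report.classification)
```

prints

```
0.0242171 0.01410304875000001 non-MR
```

`Î_ND ≈ 0.024` says this system carries ~2% of the maximal per-electron
nondynamic correlation; `I_ND^max ≈ 0.0141` is well below the MP2 lower
threshold 0.030, so a single-reference treatment is safe. The same numbers
come from the CLI:

```bash
noodiag compute --occ occupancies.txt --method mp2
noodiag d2 --amplitudes t2.h5                    # D2 from a doubles tensor
noodiag classify --ind-max 0.031 --method mp2    # -> caution
noodiag simulate sweep --grid 0,1,2,4,8          # Hubbard-dimer scan
noodiag fixtures generate --dir fixtures/        # sample input files
```

The `examples/` directory contains one narrative script per capability
(occupancy indices, the Hubbard-dimer correlation dial, the CI bridge, the
D₂ bridge); each prints the quantities it computes with a line on what they
mean.

Occupancies are read from Molden files (`Occup=` fields), wfx files
(`<Molecular Orbital Occupation Numbers>`), plain text (one number per
line) or JSON; amplitude tensors from HDF5 (`t2` dataset with `n_occ`/
`n_vir` attributes).

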