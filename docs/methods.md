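# Methods

## Occupancy indices

All indices are functionals of the natural orbital occupancies (NOOs), the
eigenvalues of the one-particle reduced density matrix (1-RDM). Working with
spin occupations `n_iσ ∈ [0, 1]` (a closed-shell spatial occupation
`n_i ∈ [0, 2]` contributes `n_i/2` to each spin channel — the two code paths
are verified to agree to 1e-12):

| quantity | definition | range | meaning |
|---|---|---|---|
| `I_ND` | `½ Σ_iσ n(1−n)` | `[0, N/2]` | nondynamic correlation; 1-RDM idempotency deviation |
| `I_T` | `½ Σ_iσ √(n(1−n))` | `≥ I_ND` | total correlation |
| `I_D` | `I_T − I_ND` | `≥ 0`, unbounded | dynamic correlation |
| `Î_ND`, `Î_D` | `2 I / N` | `Î_ND ∈ [0,1]` | size-intensive (per-electron) versions |
| `I_ND^max` | `½ max_iσ n(1−n)` | `[0, ⅛]` | maximal single-orbital deviation; the MR diagnostic |

The per-term function `n(1−n)` vanishes only at integer filling and peaks at
`n = ½`, so `I_T = 0` iff the state is idempotent (mean-field-like) and
`I_ND^max = ⅛` iff some natural orbital is exactly half filled. `I_D` grows
without bound when a fixed number of electrons is spread over ever more
weakly occupied orbitals (each term contributes `√(n(1−n)) ≫ n(1−n)` for
small `n`), which is why only `Î_ND` and `I_ND^max` are used diagnostically;
`Î_D = 2 I_D/N` is reported for convenience even though `I_D`'s supremum
regime would call for a different normalization (the raw `I_D` is always
available alongside).

Every prefactor (the `½` of the sums, the `2/N` scaling, the bridge factors
below) lives in `noodiag/constants.py`, so an alternative normalization
convention is a one-line change.

The pseudo-occupied/pseudo-virtual split of `Î_ND` sums the `N^α` (resp.
`N^β`) highest-occupied spin natural orbitals versus the rest, both with the
same `2/N` scaling, so the two parts add to `Î_ND` exactly. Their near
equality (particle–hole symmetry of molecular 1-RDMs) is reported as
`ph_asymmetry = |Î_ND^o − Î_ND^v| / max(Î_ND, 1e-12)`; the suite asserts
`ph_asymmetry ≤ 0.2` on correlated model ground states — a deliberately
conservative bound for ensembles of CI-like solutions, not a claim about
arbitrary densities (fractional-occupancy densities of non-wave-function
origin can be more asymmetric).

## Classification

`I_ND^max` thresholds equivalent to the Nielsen–Janssen D₂ ones
(D₂ = 0.15 safe boundary; D₂ ≥ 0.17 MP2 / ≥ 0.18 CCSD multireference):

| method | lower (non-MR below) | upper (MR at/above) |
|---|---|---|
| `mp2` (default, 5090-molecule fit) | 0.030 | 0.037 |
| `mp2-small-set` (34-molecule fit) | 0.029 | 0.037 |
| `ccsd` (14- and 311-molecule fits agree) | 0.024 | 0.034 |

Values in between classify as `caution`. The table is a plain data object;
user-defined methods are added programmatically or via a JSON file (the
calibration workflow for new methods is a threshold-table entry, not a
refitting routine — fitting data are not shipped).

## CI bridge

For a normalized CI vector with a dominant reference determinant, tracing
the 1-RDM over the HF-virtual orbitals counts promoted electrons exactly:
`Tr ¹D^vir = Σ_k k·w_k` (the virtual-space number operator is diagonal in
the determinant basis), reducing to `c_S² + 2 c_D²` for CISD. With a
dominant block-diagonal 1-RDM, the weakly occupied NOOs are small, so
`Σ_vir n(1−n) ≈ Σ_vir n = Tr ¹D^vir ≈ 2(1−c0²)` (neglecting the singles,
whose weight is far below twice the total excitation weight), and with the
particle–hole symmetry `Î_ND ≈ 2 Î_ND^v` this gives

    Î_ND ≈ 4 (1 − c0²) / N.

The implementation keeps `c0`'s sign but uses only `c0²`. The suite asserts
agreement within 25% relative while `c0² > 0.9` on Hubbard-dimer solutions
and checks that the residual grows monotonically with `U/t`; 25% is a suite
choice for a relation validated in the literature by scatter plots, not
error bars. The size-intensive leading-coefficient measure `1 − c0^{2/N}`
approaches `(1 − c0²)/N` as `c0² → 1` (verified within 1% at `c0² = 0.999`
for N ∈ {2, 10, 100}).

## Amplitude diagnostics

**D₂.** For closed-shell doubles amplitudes `t_ij^ab` (`t_ij^ab = t_ji^ba`;
tensors violating this are symmetrized on load), the default matricization
takes, per occupied orbital `i`, the `n_vir × (n_occ·n_vir)` slice
`T^(i)_{a,(jb)} = t_ij^ab` and returns `max_i ‖T^(i)‖₂`. Because the
original definition cannot be disambiguated from a printed placeholder, the
full `(ij)×(ab)` compound spectral norm is also implemented behind
`matricization="compound"`. Spectral norms use a dense SVD up to dimension
500 and a Lanczos solver (tolerance 1e-10) above.

**Unrelaxed MP2 density blocks.** The standard spin-adapted second-order
contractions, written once and tested against a pure-python index-loop
oracle at 1e-12:

    ¹D^occ_ij = 2δ_ij − 2 Σ_kab (2 t_ik^ab − t_ik^ba) t_jk^ab
    ¹D^vir_ab = + 2 Σ_ijc (2 t_ij^ac − t_ji^ac) t_ij^bc

Both corrections contract the same scalar products, so their traces cancel
term by term and `Tr ¹D^occ + Tr ¹D^vir = 2 n_occ` holds to machine
precision (particle conservation of the unrelaxed density; there is no
occupied–virtual block at this order without orbital relaxation).

**Approximate blocks.** Dropping the exchange-like `−t^swap` part
(`2t − t^swap → 2t`) gives `2I − 4Σtt` and `4Σtt`. In the singlet/triplet
pair decomposition `t = t⁺ + t⁻` (components symmetric/antisymmetric under
`a↔b`), the neglected contraction is `Gram(t⁺) − Gram(t⁻)`: positive
semidefinite whenever singlet-coupled pair amplitudes dominate, which is
the generic closed-shell ground-state situation. Then, by the eigenvalue
shift inequality, the approximate extremes overestimate correlation:
`ñ_H ≤ n_H` (lowest occupied-block eigenvalue) and `ñ_L ≥ n_L` (highest
virtual-block eigenvalue), with the gap growing with amplitude scale — both
asserted on seeded ensembles.

**D₂ → I_ND^max map.** The approximate virtual block is
`4 Σ_i T^(i) T^(i)ᵀ`; when one occupied slice dominates, its largest
eigenvalue is `ñ_L ≈ 4 D₂²` (a lower bound on `ñ_L` in general — the named
constant `D2_SQ_TO_NL = 4`). Substituting into the single-orbital index:

    I_ND^max ≈ ⅛ ñ_L (2 − ñ_L),  ñ_L = min(4 D₂², 1),

zero at D₂ = 0, increasing up to saturation (⅛) at D₂ = ½. The map is
quantitative only for small D₂; the suite asserts the monotone association
instead (Spearman ≥ 0.9 between D₂ and the `I_ND^max` computed from the
full blocks on ensembles restricted to D₂ ≤ 0.4, the regime where the
correspondence is documented to be strong).

## Model systems

`exact_diagonalize` builds full CI for a Hubbard dimer/open chain (≤ 6
sites, Hilbert dimension guarded at 10⁴) in the determinant basis of its
mean-field (U = 0 tight-binding) orbitals: the on-site interaction is
transformed into that basis, the Hamiltonian assembled from single-spin
excitation-operator matrices (alpha-major determinant ordering, ascending
creation-operator convention fixes all signs), and the spin-resolved 1-RDMs
obtained as ground-state expectations of those operators. The reference
determinant for `c0` is the aufbau filling; the global phase is fixed so
`c0 ≥ 0`; near-degenerate ground states (gap < 1e-10) are flagged in the
metadata with the lowest-index eigenvector selected. Open-boundary chains
keep the mean-field spectrum nondegenerate.

`hubbard_dimer` solves the half-filled singlet analytically: site-inversion
symmetry decouples the open-shell singlet, leaving the 2×2 block over
|g²⟩/|u²⟩ with `E = U/2 − √(4t² + U²/4)` and per-spin occupations
`(c0², c2²)`. The cross-check against the generic path holds to 1e-10. The
dimer's single-pair CI vector also yields an effective doubles amplitude
`c2/c0`, giving a D₂ value along sweeps.

`sample_amplitudes` draws seeded Gaussian tensors with the exact
permutational symmetry and a dominant `a↔b`-symmetric component
(`triplet_fraction = 0.3` of antisymmetric admixture) — emulating the
singlet-pair dominance of real closed-shell amplitudes that underpins the
overestimation direction above. What these ensembles do **not** emulate:
the energy-denominator decay of real amplitudes, basis-set structure, or
any specific molecule; passing ensemble tests therefore validates the
algebraic machinery and the direction/association claims, not chemical
accuracy on real systems (for which occupancies/amplitudes are ingested
from external engines).

## Numerical policies

- Occupations within 1e-6 outside their physical range are clipped with a
  warning (relaxed-density artifacts); larger violations raise, naming the
  index. Trace/electron-count mismatches beyond 1e-4 warn, never raise.
- Sorting is stable descending, so degenerate occupations keep input order;
  a degenerate pseudo-occupied boundary (gap < 1e-10) warns.
- `I_T = I_ND + I_D` and `Î_ND = Î_ND^o + Î_ND^v` are re-summed so the
  identities hold exactly in every report.
- CSV reports print floats at 6 significant digits; JSON keeps full
  precision so reparsing reproduces the report bit-for-bit.
- Zero electrons make size-intensive quantities undefined (error, not NaN).

## Problem sizes

The suite and the acceptance script run entirely on desk-scale problems:
10⁴ random occupancy sets for the bounds sweep, 3×3×4×4 amplitude tensors
(100 against the loop oracle, 10³ for eigenvalue directions, 200-member
ensembles for the rank correlation), and model spaces of at most 400
determinants — sizes at which every oracle is exact and the whole suite
completes in well under a minute of compute.

## Known limitations

- The benchmark screening of real molecule sets behind the shipped
  thresholds is not reproduced here; the thresholds enter as configuration
  with provenance notes, and the library ingests occupancies from any
  engine instead.
- Only the unrelaxed (orbital-response-free) MP2 density is implemented;
  relaxed densities can produce small negative occupancies, which the
  clipping policy tolerates but whose physics is out of scope.
- No T₁/D₁ diagnostics: single-excitation-based measures are sensitive to
  orbital rotations and deliberately excluded.
- `predict_indmax_from_d2` saturates at D₂ = ½; it is a regime estimate,
  not an invertible map.
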