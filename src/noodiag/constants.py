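"""Normalization constants and numerical tolerances.

Every prefactor entering the occupancy indices is defined exactly once here,
so an alternative normalization convention is a one-line change.

Conventions (spin natural occupations ``n`` in [0, 1]):

* ``I_ND = IND_PREFACTOR * sum n (1 - n)``, bounded by [0, N/2];
* ``I_T  = IND_PREFACTOR * sum sqrt(n (1 - n))``, ``I_D = I_T - I_ND``;
* ``Î    = SIZE_INTENSIVE_SCALE * I / N`` (per-electron scaling, Î_ND in [0, 1]);
* ``I_ND^max = NDMAX_PREFACTOR * max n (1 - n)``, bounded by [0, 1/8];
* CI bridge: ``Î_ND ≈ C0_BRIDGE_FACTOR * (1 - c0²) / N``;
* amplitude bridge: ``ñ_L ≈ D2_SQ_TO_NL * D2²`` (approximate MP2 virtual
  block is ``4 Σ_i T(i) T(i)ᵀ``; a single dominant occupied slice gives 4).
"""

#: prefactor of the nondynamic/total index sums over spin orbitals
IND_PREFACTOR = 0.5

#: Î = SIZE_INTENSIVE_SCALE * I / N
SIZE_INTENSIVE_SCALE = 2.0

#: prefactor of the maximal single-orbital nondynamic contribution
NDMAX_PREFACTOR = 0.5

#: Î_ND estimate from the CI leading coefficient: C0_BRIDGE_FACTOR*(1-c0²)/N
C0_BRIDGE_FACTOR = 4.0

#: proportionality between D2² and the approximate extreme virtual occupation
D2_SQ_TO_NL = 4.0

#: occupations in [-OCC_CLIP_TOL, 1+OCC_CLIP_TOL] are clipped into [0, 1];
#: anything beyond is an error (relaxed-density artifacts are this small)
OCC_CLIP_TOL = 1e-6

#: |sum(occ) - n_electrons| above this emits a warning (never an error)
TRACE_TOL = 1e-4

#: occupation gaps below this at the pseudo-occupied boundary trigger a
#: degenerate-boundary warning for the occupied/virtual split
DEGENERACY_TOL = 1e-10

#: matricizations smaller than this use a dense SVD; larger use an iterative
#: (Lanczos) spectral-norm solver
SPECTRAL_DENSE_CUTOFF = 500

#: convergence tolerance of the iterative spectral-norm solver
SPECTRAL_ITER_TOL = 1e-10
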