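"""D2 diagnostic, unrelaxed MP2 density blocks, and the D2 ↔ I_ND^max bridge.

Closed-shell doubles amplitudes ``t_ij^ab`` (``i, j`` doubly occupied,
``a, b`` virtual spatial orbitals, ``t_ij^ab = t_ji^ba``) determine

* the Nielsen–Janssen **D2 diagnostic**: the largest spectral norm over a
  matricization of the amplitude tensor (see :func:`d2_diagnostic`);
* the diagonal blocks of the **unrelaxed MP2 one-particle density** through
  second order,

  .. math::

      ¹D^{occ}_{ij} = 2δ_{ij} − 2 Σ_{kab} (2 t_{ik}^{ab} − t_{ik}^{ba}) t_{jk}^{ab},
      \qquad
      ¹D^{vir}_{ab} = 2 Σ_{ijc} (2 t_{ij}^{ac} − t_{ji}^{ac}) t_{ij}^{bc},

  whose traces cancel exactly (particle conservation).  The extreme
  eigenvalues ``n_H`` (lowest occupied-block) and ``n_L`` (highest
  virtual-block) are the most strongly depleted and populated natural
  occupations.

Dropping the exchange-like ``−t^{swap}`` part of each contraction gives the
approximate blocks ``2δ − 4 Σ t t`` and ``4 Σ t t``; the neglected
contraction ``Σ t t^{swap}`` is positive semidefinite whenever singlet-coupled
pair amplitudes dominate (the generic closed-shell situation), so the
approximate extremes satisfy ``ñ_H ≤ n_H`` and ``ñ_L ≥ n_L`` — they
overestimate electron correlation, increasingly so as the amplitudes grow.

Since the approximate virtual block is ``4 Σ_i T^{(i)} T^{(i)ᵀ}`` in terms of
the per-occupied-orbital amplitude slices whose largest spectral norm defines
D2, a single dominant slice gives ``ñ_L ≈ 4 D2²``, and inserting the extreme
occupation into the single-orbital index yields the analytic D2 → I_ND^max
map of :func:`predict_indmax_from_d2`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse.linalg

from . import constants as C
from .errors import DimensionError, InvalidOccupancyError, SymmetryError

__all__ = [
    "AmplitudeSet",
    "DensityBlocks",
    "ExtremeOccupations",
    "D2Result",
    "d2_diagnostic",
    "mp2_density_blocks",
    "approx_density_blocks",
    "extreme_occupations",
    "indmax_from_blocks",
    "predict_indmax_from_d2",
]


@dataclass
class AmplitudeSet:
    """Closed-shell doubles amplitudes ``t2[i, j, a, b]``.

    The tensor must satisfy ``t_ij^ab = t_ji^ba``; deviations up to 1e-10 are
    symmetrized silently, larger ones with a warning.
    """

    t2: np.ndarray

    def __post_init__(self) -> None:
        t2 = np.asarray(self.t2, dtype=float)
        if t2.ndim != 4 or t2.shape[0] != t2.shape[1] or t2.shape[2] != t2.shape[3]:
            raise DimensionError(
                f"t2 must have shape (n_occ, n_occ, n_vir, n_vir), got {t2.shape}"
            )
        if min(t2.shape) == 0:
            raise DimensionError("empty amplitude tensor")
        if not np.all(np.isfinite(t2)):
            raise DimensionError("amplitude tensor contains non-finite entries")
        swapped = t2.transpose(1, 0, 3, 2)
        dev = float(np.max(np.abs(t2 - swapped)))
        if dev > 1e-10:
            warnings.warn(
                f"t_ij^ab = t_ji^ba violated by {dev:.3g}; symmetrizing",
                stacklevel=2,
            )
        if dev > 0.0:
            t2 = 0.5 * (t2 + swapped)
        self.t2 = t2

    @property
    def n_occ(self) -> int:
        return self.t2.shape[0]

    @property
    def n_vir(self) -> int:
        return self.t2.shape[2]


@dataclass
class DensityBlocks:
    """Occupied and virtual diagonal blocks of an (approximate) MP2 1-RDM."""

    occ_block: np.ndarray
    vir_block: np.ndarray
    approximate: bool

    def __post_init__(self) -> None:
        for name, block in (("occ_block", self.occ_block), ("vir_block", self.vir_block)):
            block = np.asarray(block, dtype=float)
            if block.ndim != 2 or block.shape[0] != block.shape[1]:
                raise DimensionError(f"{name} must be square, got {block.shape}")
            if float(np.max(np.abs(block - block.T), initial=0.0)) > 1e-12:
                raise SymmetryError(f"{name} is not symmetric to 1e-12")
            setattr(self, name, block)


@dataclass(frozen=True)
class ExtremeOccupations:
    """Extreme natural occupations ``n_H`` (occupied) and ``n_L`` (virtual)."""

    n_H: float
    n_L: float
    approximate: bool


@dataclass(frozen=True)
class D2Result:
    """D2 diagnostic value and the matricization convention that produced it."""

    value: float
    matricization: str
    singular_values: Optional[np.ndarray] = None


def _spectral_norm(mat: np.ndarray, keep_spectrum: bool) -> tuple[float, Optional[np.ndarray]]:
    """Largest singular value; dense SVD below the cutoff, Lanczos above."""
    if min(mat.shape) == 0:
        return 0.0, (np.zeros(0) if keep_spectrum else None)
    if max(mat.shape) <= C.SPECTRAL_DENSE_CUTOFF or keep_spectrum:
        s = np.linalg.svd(mat, compute_uv=False)
        return float(s[0]), (s if keep_spectrum else None)
    if not np.any(mat):
        return 0.0, None
    s = scipy.sparse.linalg.svds(
        mat, k=1, return_singular_vectors=False, tol=C.SPECTRAL_ITER_TOL
    )
    return float(s[0]), None


def d2_diagnostic(
    t: AmplitudeSet,
    matricization: str = "ref20",
    keep_spectrum: bool = False,
) -> D2Result:
    """D2 diagnostic: largest spectral norm of a doubles-amplitude matricization.

    ``matricization="ref20"`` (default, the original convention) takes, for
    each occupied orbital *i*, the ``n_vir × (n_occ·n_vir)`` slice
    ``T^{(i)}_{a,(jb)} = t_ij^ab`` and returns ``max_i ‖T^{(i)}‖₂``;
    ``"compound"`` returns the spectral norm of the single
    ``(ij) × (ab)`` compound matrix.  Both are |c|-homogeneous in the
    amplitudes and invariant under separate relabelings of the occupied and
    virtual orbitals.
    """
    t2 = t.t2
    no, nv = t.n_occ, t.n_vir
    if matricization == "ref20":
        best = 0.0
        spectrum = None
        for i in range(no):
            mat = t2[i].transpose(1, 0, 2).reshape(nv, no * nv)
            val, s = _spectral_norm(mat, keep_spectrum)
            if val >= best:
                best, spectrum = val, s
        return D2Result(value=best, matricization="ref20", singular_values=spectrum)
    if matricization == "compound":
        mat = t2.reshape(no * no, nv * nv)
        val, s = _spectral_norm(mat, keep_spectrum)
        return D2Result(value=val, matricization="compound", singular_values=s)
    raise ValueError(f"unknown matricization {matricization!r}")


def _contractions(t2: np.ndarray, exchange: bool) -> tuple[np.ndarray, np.ndarray]:
    """Occ/vir second-order density corrections from the doubles amplitudes.

    With ``exchange=True`` the spin-adapted combination ``t̃ = 2t − t^{swap}``
    is contracted against ``t`` (the full unrelaxed result); with False the
    exchange-like part is dropped (``t̃ → 2t``).
    """
    if exchange:
        tbar = 2.0 * t2 - t2.transpose(0, 1, 3, 2)
    else:
        tbar = 2.0 * t2
    occ_corr = -2.0 * np.einsum("ikab,jkab->ij", tbar, t2, optimize=True)
    vir_corr = 2.0 * np.einsum("ijac,ijbc->ab", tbar, t2, optimize=True)
    # both contractions are symmetric analytically; remove float asymmetry
    occ_corr = 0.5 * (occ_corr + occ_corr.T)
    vir_corr = 0.5 * (vir_corr + vir_corr.T)
    return occ_corr, vir_corr


def mp2_density_blocks(t: AmplitudeSet) -> DensityBlocks:
    """Unrelaxed MP2 1-RDM diagonal blocks through second order.

    ``occ_block = 2·I + correction``, ``vir_block = correction``; the two
    correction traces cancel, so ``Tr occ + Tr vir = 2 n_occ`` (particle
    conservation of the unrelaxed density).
    """
    occ_corr, vir_corr = _contractions(t.t2, exchange=True)
    occ_block = 2.0 * np.eye(t.n_occ) + occ_corr
    return DensityBlocks(occ_block=occ_block, vir_block=vir_corr, approximate=False)


def approx_density_blocks(t: AmplitudeSet) -> DensityBlocks:
    """Approximate blocks with the exchange-like contraction omitted.

    ``occ_block = 2·I − 4 Σ t t``, ``vir_block = 4 Σ t t``.  Relative to the
    full blocks this shifts the spectrum by the (generically PSD) neglected
    contraction, so the extreme occupations overestimate correlation:
    ``ñ_H ≤ n_H`` and ``ñ_L ≥ n_L``.
    """
    occ_corr, vir_corr = _contractions(t.t2, exchange=False)
    occ_block = 2.0 * np.eye(t.n_occ) + occ_corr
    return DensityBlocks(occ_block=occ_block, vir_block=vir_corr, approximate=True)


def extreme_occupations(blocks: DensityBlocks) -> ExtremeOccupations:
    """Extreme eigenvalues: lowest of the occupied block, highest of the virtual.

    For physically sensible (small) amplitudes ``0 ≤ n_L ≤ n_H ≤ 2``; strong
    amplitudes may push the approximate blocks outside that window, which is
    reported as-is.
    """
    occ_eigs = np.linalg.eigvalsh(blocks.occ_block)
    vir_eigs = np.linalg.eigvalsh(blocks.vir_block)
    return ExtremeOccupations(
        n_H=float(occ_eigs[0]),
        n_L=float(vir_eigs[-1]),
        approximate=blocks.approximate,
    )


def indmax_from_blocks(x: ExtremeOccupations) -> float:
    """``I_ND^max`` from the extreme occupation pair.

    ``I_ND^max = ⅛ max(n_H (2 − n_H), n_L (2 − n_L))`` — the single-orbital
    index evaluated at whichever extreme occupation deviates more from
    integer filling.
    """
    for name, val in (("n_H", x.n_H), ("n_L", x.n_L)):
        if not (-1e-10 <= val <= 2.0 + 1e-10):
            raise InvalidOccupancyError(f"{name} = {val:.6g} outside [0, 2]")
    n_h = min(max(x.n_H, 0.0), 2.0)
    n_l = min(max(x.n_L, 0.0), 2.0)
    return (C.NDMAX_PREFACTOR / 4.0) * max(n_h * (2.0 - n_h), n_l * (2.0 - n_l))


def predict_indmax_from_d2(d2: float) -> float:
    """Analytic ``I_ND^max`` estimate from the D2 diagnostic.

    Propagates ``ñ_L ≈ 4 D2²`` through the single-orbital index:
    ``I_ND^max ≈ ⅛ ñ_L (2 − ñ_L)`` with ``ñ_L`` capped at 1, so the map is
    zero at ``D2 = 0``, increases monotonically up to the saturation value
    1/8 at ``D2 = 1/2``, and stays there beyond.  Like the underlying
    approximation it is quantitative only for small D2 (the diagnostic
    regime, D2 ≲ 0.4).
    """
    n_l = min(C.D2_SQ_TO_NL * float(d2) ** 2, 1.0)
    return (C.NDMAX_PREFACTOR / 4.0) * n_l * (2.0 - n_l)
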