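"""CI-coefficient correlation measures and the bridge to the occupancy indices.

For a normalized CI expansion ``Ψ = c0 Φ0 + Σ c_i^a Φ_i^a + Σ c_ij^ab Φ_ij^ab
+ …`` built on Hartree–Fock orbitals, the weight lost by the reference
determinant, ``1 − c0²``, is itself a correlation measure (though not a
size-intensive one).  Tracing the 1-RDM of such a wave function over the
HF-virtual orbitals counts the electrons promoted out of the reference:
exactly one per single excitation, two per double, ``k`` per rank-``k``
determinant.  For a dominant block-diagonal 1-RDM this links the leading
coefficient to the size-intensive nondynamic index,

    Î_ND ≈ 4 (1 − c0²) / N,

and the size-intensive variant ``1 − c0^{2/N}`` shares the same leading term
``(1 − c0²)/N`` as ``c0² → 1``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Tuple, Union

import numpy as np

from . import constants as C
from .errors import DegenerateInputError, NormalizationError

__all__ = [
    "CIExpansion",
    "TraceDecomposition",
    "leading_weight",
    "size_intensive_c0",
    "cisd_trace_decomposition",
    "predict_ind_hat_from_c0",
]

#: a CI coefficient as (excitation rank, coefficient) or {"rank":, "coefficient":}
CoefficientRecord = Union[Tuple[int, float], Mapping[str, float]]


@dataclass
class CIExpansion:
    """Leading coefficient and per-rank excitation weights of a CI vector.

    ``rank_weights[k]`` is the total squared weight of rank-``k`` excited
    determinants; ``c0`` keeps its sign (only ``c0²`` enters any formula).
    """

    c0: float
    rank_weights: dict[int, float]
    n_electrons: int
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.normalized:
            total = self.c0**2 + sum(self.rank_weights.values())
            if abs(total - 1.0) > 1e-10:
                raise NormalizationError(
                    f"normalized CI expansion sums to {total:.12g}, not 1"
                )
        if self.c0**2 < 0.5:
            warnings.warn(
                f"c0² = {self.c0**2:.4g} < 0.5: the reference determinant is "
                "not dominant; CI-based measures are unreliable",
                stacklevel=2,
            )

    @property
    def singles_weight(self) -> float:
        return self.rank_weights.get(1, 0.0)

    @property
    def doubles_weight(self) -> float:
        return self.rank_weights.get(2, 0.0)

    @property
    def higher_weight(self) -> float:
        return sum(w for k, w in self.rank_weights.items() if k >= 3)


@dataclass(frozen=True)
class TraceDecomposition:
    """1-RDM trace split over HF-occupied and HF-virtual orbital blocks."""

    trace_occ: float
    trace_vir: float


def leading_weight(
    coefficients: Iterable[CoefficientRecord],
    n_electrons: int,
) -> CIExpansion:
    """Aggregate a CI coefficient vector into c0 and per-rank weights.

    *coefficients* is an iterable of ``(rank, coefficient)`` pairs (or dicts
    with ``"rank"``/``"coefficient"`` keys); exactly one record must carry
    rank 0, the reference determinant.  The vector is normalized internally,
    preserving the sign of ``c0``.
    """
    ranks: list[int] = []
    coeffs: list[float] = []
    for rec in coefficients:
        if isinstance(rec, Mapping):
            ranks.append(int(rec["rank"]))
            coeffs.append(float(rec["coefficient"]))
        else:
            ranks.append(int(rec[0]))
            coeffs.append(float(rec[1]))
    if not coeffs:
        raise DegenerateInputError("empty CI coefficient vector")
    vec = np.asarray(coeffs, dtype=float)
    norm2 = float(vec @ vec)
    if norm2 <= 0.0:
        raise DegenerateInputError("all-zero CI coefficient vector")
    vec = vec / math.sqrt(norm2)
    ref = [i for i, r in enumerate(ranks) if r == 0]
    if len(ref) != 1:
        raise DegenerateInputError(
            f"expected exactly one rank-0 (reference) coefficient, got {len(ref)}"
        )
    c0 = float(vec[ref[0]])
    rank_weights: dict[int, float] = {}
    for r, c in zip(ranks, vec):
        if r == 0:
            continue
        if r < 0:
            raise DegenerateInputError(f"negative excitation rank {r}")
        rank_weights[r] = rank_weights.get(r, 0.0) + float(c) ** 2
    return CIExpansion(
        c0=c0,
        rank_weights=rank_weights,
        n_electrons=int(n_electrons),
        normalized=True,
    )


def size_intensive_c0(c0: float, n_electrons: int) -> float:
    """Size-intensive reference weight ``1 − (c0²)^{1/N}``.

    Behaves as ``(1 − c0²)/N`` to first order as ``c0² → 1``, which makes it
    comparable across system sizes.
    """
    if n_electrons < 1:
        raise NormalizationError("n_electrons must be >= 1")
    c0sq = c0 * c0
    if c0sq == 0.0:
        raise NormalizationError("size-intensive c0 measure undefined for c0 = 0")
    if c0sq > 1.0 + 1e-12:
        raise NormalizationError(f"c0² = {c0sq:.6g} exceeds 1")
    return 1.0 - min(c0sq, 1.0) ** (1.0 / n_electrons)


def cisd_trace_decomposition(exp: CIExpansion) -> TraceDecomposition:
    """Split the 1-RDM trace over HF-occupied and HF-virtual blocks.

    The occupation-number operator of the HF-virtual space is diagonal in the
    determinant basis, so ``Tr ¹D^vir = Σ_k k · w_k`` exactly: each single
    excitation moves one electron into the virtuals, each double two (the
    singles' contribution is typically far smaller than the doubles').  For a
    CISD vector this is ``c_S² + 2 c_D²``; ``Tr ¹D^occ = N − Tr ¹D^vir``.
    """
    n = exp.n_electrons
    trace_vir = float(sum(k * w for k, w in exp.rank_weights.items()))
    return TraceDecomposition(trace_occ=n - trace_vir, trace_vir=trace_vir)


def predict_ind_hat_from_c0(c0: float, n_electrons: int) -> float:
    """Estimate ``Î_ND ≈ 4 (1 − c0²) / N`` from the CI leading coefficient.

    Valid in the weakly correlated regime (dominant block-diagonal 1-RDM,
    ``c0² ≳ 0.9``); the residual grows with correlation strength.
    """
    if n_electrons < 1:
        raise NormalizationError("n_electrons must be >= 1")
    c0sq = c0 * c0
    if c0sq > 1.0 + 1e-12:
        raise NormalizationError(f"c0² = {c0sq:.6g} exceeds 1")
    return C.C0_BRIDGE_FACTOR * (1.0 - min(c0sq, 1.0)) / n_electrons
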