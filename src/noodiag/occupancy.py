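"""Occupancy-based electron-correlation indices and multireference classification.

The eigenvalues of the one-particle reduced density matrix (the natural
orbital occupations, NOOs) are integers, 0 or 1 per spin orbital, exactly at
the mean-field limit; electron correlation makes them fractional.  The indices
computed here quantify that deviation:

* ``I_ND`` — nondynamic (static) correlation, the deviation from idempotency
  of the 1-RDM: ``½ Σ_{iσ} n_{iσ}(1 − n_{iσ})``, in ``[0, N/2]``;
* ``I_T``  — total correlation, ``½ Σ_{iσ} √(n_{iσ}(1 − n_{iσ}))``;
* ``I_D = I_T − I_ND`` — dynamic correlation, unbounded above as the number
  of weakly occupied orbitals grows;
* ``Î_ND = 2 I_ND / N`` — the size-intensive (per-electron) version, in
  ``[0, 1]``; ``Î_D`` analogously;
* ``I_ND^max = ½ max_{iσ} n_{iσ}(1 − n_{iσ})`` — the maximal single-orbital
  contribution, in ``[0, 1/8]``, recommended as a multireference diagnostic.

``Î_ND`` also splits into pseudo-occupied (the ``N^α``/``N^β`` highest
occupied spin natural orbitals) and pseudo-virtual parts, whose near equality
reflects the particle–hole symmetry of molecular 1-RDMs.

For closed-shell systems the spatial occupations ``n_i ∈ [0, 2]`` give the
equivalent forms ``I_ND = ¼ Σ n_i(2 − n_i)`` and
``I_ND^max = ⅛ max n_i(2 − n_i)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import constants as C
from .errors import (
    DimensionError,
    InvalidOccupancyError,
    MissingThresholdError,
    NormalizationError,
)

__all__ = [
    "SpinOccupancySet",
    "ClosedShellOccupancySet",
    "CorrelationReport",
    "ThresholdEntry",
    "ThresholdTable",
    "default_thresholds",
    "nondynamic_index",
    "dynamic_total_indices",
    "size_intensive",
    "split_occ_vir",
    "nd_max",
    "classify_mr",
    "correlation_report",
]


def _validate_channel(occ: np.ndarray, name: str, upper: float) -> np.ndarray:
    """Validate occupations against [0, upper], clip small artifacts.

    Values within ``OCC_CLIP_TOL`` outside the range (as produced by relaxed
    densities or finite-precision diagonalization) are clipped with a warning;
    anything beyond raises naming the offending index.
    """
    occ = np.asarray(occ, dtype=float)
    if occ.ndim != 1:
        raise DimensionError(f"{name} must be a 1-D vector, got shape {occ.shape}")
    if not np.all(np.isfinite(occ)):
        bad = int(np.flatnonzero(~np.isfinite(occ))[0])
        raise InvalidOccupancyError(f"{name}[{bad}] is not finite")
    low = occ < -C.OCC_CLIP_TOL
    high = occ > upper + C.OCC_CLIP_TOL
    if low.any() or high.any():
        bad = int(np.flatnonzero(low | high)[0])
        raise InvalidOccupancyError(
            f"{name}[{bad}] = {occ[bad]:.8g} outside [0, {upper}] "
            f"beyond tolerance {C.OCC_CLIP_TOL}"
        )
    if (occ < 0).any() or (occ > upper).any():
        warnings.warn(
            f"{name}: occupations within {C.OCC_CLIP_TOL} outside [0, {upper}] "
            "clipped",
            stacklevel=3,
        )
        occ = np.clip(occ, 0.0, upper)
    # descending, stable so equal occupations keep their input order
    order = np.argsort(-occ, kind="stable")
    return occ[order]


def _check_trace(occ: np.ndarray, n: int, name: str) -> None:
    if abs(float(occ.sum()) - n) > C.TRACE_TOL:
        warnings.warn(
            f"{name}: sum of occupations {occ.sum():.6g} deviates from the "
            f"electron count {n} by more than {C.TRACE_TOL}",
            stacklevel=3,
        )


@dataclass
class SpinOccupancySet:
    """Spin-resolved natural orbital occupations with electron counts.

    Occupations are stored in descending order within each spin channel (the
    sort is stable, so degenerate entries keep their input order).  Entries
    within ``OCC_CLIP_TOL`` outside [0, 1] are clipped with a warning; a trace
    deviating from the electron count by more than ``TRACE_TOL`` warns too.
    """

    occ_alpha: np.ndarray
    occ_beta: np.ndarray
    n_alpha: int
    n_beta: int
    label: str = ""

    def __post_init__(self) -> None:
        self.occ_alpha = _validate_channel(self.occ_alpha, "occ_alpha", 1.0)
        self.occ_beta = _validate_channel(self.occ_beta, "occ_beta", 1.0)
        self.n_alpha = int(self.n_alpha)
        self.n_beta = int(self.n_beta)
        if self.n_alpha < 0 or self.n_beta < 0:
            raise DimensionError("electron counts must be nonnegative")
        _check_trace(self.occ_alpha, self.n_alpha, "occ_alpha")
        _check_trace(self.occ_beta, self.n_beta, "occ_beta")

    @property
    def n_electrons(self) -> int:
        return self.n_alpha + self.n_beta

    def spin_orbitals(self) -> np.ndarray:
        """All spin-orbital occupations as one vector (alpha then beta)."""
        return np.concatenate([self.occ_alpha, self.occ_beta])


@dataclass
class ClosedShellOccupancySet:
    """Spatial natural orbital occupations ``n_i ∈ [0, 2]`` of a closed shell.

    Converts losslessly to a :class:`SpinOccupancySet` by halving each entry
    into both spin channels.
    """

    occ: np.ndarray
    n_electrons: int
    label: str = ""

    def __post_init__(self) -> None:
        self.occ = _validate_channel(self.occ, "occ", 2.0)
        self.n_electrons = int(self.n_electrons)
        if self.n_electrons % 2 != 0:
            raise DimensionError(
                f"closed-shell electron count must be even, got {self.n_electrons}"
            )
        _check_trace(self.occ, self.n_electrons, "occ")

    def to_spin(self) -> SpinOccupancySet:
        half = self.occ / 2.0
        return SpinOccupancySet(
            occ_alpha=half.copy(),
            occ_beta=half.copy(),
            n_alpha=self.n_electrons // 2,
            n_beta=self.n_electrons // 2,
            label=self.label,
        )


OccupancyLike = Union[SpinOccupancySet, ClosedShellOccupancySet]


def _as_spin(occ: OccupancyLike) -> SpinOccupancySet:
    if isinstance(occ, ClosedShellOccupancySet):
        return occ.to_spin()
    return occ


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------


def nondynamic_index(occ: OccupancyLike) -> float:
    """Nondynamic correlation index I_ND, the 1-RDM idempotency deviation.

    ``I_ND = ½ Σ_{iσ} n_{iσ}(1 − n_{iσ})`` (spin) or equivalently
    ``¼ Σ_i n_i(2 − n_i)`` (closed-shell spatial occupations).
    Returns a value in ``[0, N/2]``; zero iff the occupations are idempotent.
    """
    if isinstance(occ, ClosedShellOccupancySet):
        n = occ.occ
        return float((C.IND_PREFACTOR / 2.0) * np.sum(n * (2.0 - n)))
    n = occ.spin_orbitals()
    return float(C.IND_PREFACTOR * np.sum(n * (1.0 - n)))


def dynamic_total_indices(occ: OccupancyLike) -> tuple[float, float]:
    """Dynamic and total correlation indices ``(I_D, I_T)``.

    ``I_T = ½ Σ_{iσ} √(n_{iσ}(1 − n_{iσ}))`` and ``I_D = I_T − I_ND``.
    Unlike ``I_ND``, ``I_D`` is not bounded above: spreading a fixed number of
    electrons over ever more weakly occupied orbitals grows it without limit.
    """
    if isinstance(occ, ClosedShellOccupancySet):
        n = occ.occ
        i_t = float(C.IND_PREFACTOR * np.sum(np.sqrt(np.maximum(n * (2.0 - n), 0.0))))
    else:
        n = occ.spin_orbitals()
        i_t = float(C.IND_PREFACTOR * np.sum(np.sqrt(np.maximum(n * (1.0 - n), 0.0))))
    i_nd = nondynamic_index(occ)
    i_d = max(i_t - i_nd, 0.0)
    return i_d, i_nd + i_d  # re-sum so I_T = I_ND + I_D holds exactly


def size_intensive(occ: OccupancyLike) -> tuple[float, float]:
    """Size-intensive indices ``(Î_ND, Î_D) = (2 I_ND / N, 2 I_D / N)``.

    ``Î_ND ∈ [0, 1]``; ``Î_D ≥ 0`` uses the same per-electron scaling for
    practical purposes even though ``I_D`` itself is unbounded.
    """
    spin = _as_spin(occ)
    n_el = spin.n_electrons
    if n_el == 0:
        raise NormalizationError("size-intensive indices undefined for 0 electrons")
    i_nd = nondynamic_index(occ)
    i_d, _ = dynamic_total_indices(occ)
    scale = C.SIZE_INTENSIVE_SCALE / n_el
    return float(scale * i_nd), float(scale * i_d)


def split_occ_vir(occ: OccupancyLike) -> tuple[float, float]:
    """Pseudo-occupied / pseudo-virtual split of ``Î_ND``.

    The ``N^α`` (resp. ``N^β``) highest-occupied spin natural orbitals form
    the pseudo-occupied space, the rest the pseudo-virtual one; each partial
    sum carries the same ``2/N`` scaling, so the two parts add up to ``Î_ND``
    exactly.  Ties at the boundary are resolved by the stable descending sort
    (input order among equals) and warned about when degenerate within
    ``DEGENERACY_TOL``.
    """
    spin = _as_spin(occ)
    n_el = spin.n_electrons
    if n_el == 0:
        raise NormalizationError("occupied/virtual split undefined for 0 electrons")
    part_occ = 0.0
    part_vir = 0.0
    for channel, n_spin, name in (
        (spin.occ_alpha, spin.n_alpha, "alpha"),
        (spin.occ_beta, spin.n_beta, "beta"),
    ):
        if channel.size < n_spin:
            raise DimensionError(
                f"{name} channel has {channel.size} orbitals for {n_spin} electrons"
            )
        if 0 < n_spin < channel.size and (
            channel[n_spin - 1] - channel[n_spin] < C.DEGENERACY_TOL
        ):
            warnings.warn(
                f"{name} channel: degenerate occupations at the pseudo-occupied "
                "boundary; split resolved by input order",
                stacklevel=2,
            )
        terms = channel * (1.0 - channel)
        part_occ += float(np.sum(terms[:n_spin]))
        part_vir += float(np.sum(terms[n_spin:]))
    scale = C.SIZE_INTENSIVE_SCALE * C.IND_PREFACTOR / n_el
    return scale * part_occ, scale * part_vir


def nd_max(occ: OccupancyLike) -> float:
    """Maximal single-orbital nondynamic contribution ``I_ND^max``.

    ``I_ND^max = ½ max_{iσ} n_{iσ}(1 − n_{iσ}) = ⅛ max_i n_i(2 − n_i)``,
    in ``[0, 1/8]``; the maximum 1/8 is reached exactly when some spin
    occupation is 1/2, i.e. one natural orbital midway between occupied and
    empty.  This is the recommended multireference diagnostic.
    """
    if isinstance(occ, ClosedShellOccupancySet):
        n = occ.occ
        if n.size == 0:
            return 0.0
        return float((C.NDMAX_PREFACTOR / 4.0) * np.max(n * (2.0 - n)))
    n = occ.spin_orbitals()
    if n.size == 0:
        return 0.0
    return float(C.NDMAX_PREFACTOR * np.max(n * (1.0 - n)))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdEntry:
    """Lower/upper ``I_ND^max`` thresholds of one electronic-structure method."""

    lower: float
    upper: float
    note: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"lower ({self.lower}) must be < upper ({self.upper})")


@dataclass
class ThresholdTable:
    """Per-method ``I_ND^max`` classification thresholds.

    Below ``lower`` a molecule is safe for the single-reference method
    (non-MR); at or above ``upper`` it is multireference (MR); in between it
    should be treated with caution.
    """

    entries: dict[str, ThresholdEntry] = field(default_factory=dict)

    def add(self, method: str, lower: float, upper: float, note: str = "") -> None:
        self.entries[method.lower()] = ThresholdEntry(lower, upper, note)

    def get(self, method: str) -> ThresholdEntry:
        key = method.lower()
        if key not in self.entries:
            raise MissingThresholdError(
                f"no thresholds registered for method {method!r}; add a "
                "user-defined entry with ThresholdTable.add()"
            )
        return self.entries[key]

    @classmethod
    def from_json(cls, path) -> "ThresholdTable":
        with open(path) as fh:
            raw = json.load(fh)
        table = cls()
        for method, entry in raw.items():
            table.add(
                method,
                float(entry["lower"]),
                float(entry["upper"]),
                str(entry.get("note", "")),
            )
        return table

    def to_json(self, path) -> None:
        raw = {
            m: {"lower": e.lower, "upper": e.upper, "note": e.note}
            for m, e in self.entries.items()
        }
        with open(path, "w") as fh:
            json.dump(raw, fh, indent=2)


def default_thresholds() -> ThresholdTable:
    """Default ``I_ND^max`` thresholds equivalent to the D2 0.15/0.17–0.18 ones.

    The MP2 entry uses the large-set fit (5090 molecules, 0.030/0.037); the
    small-set MP2 fit (34 molecules, 0.029/0.037) is available as
    ``"mp2-small-set"``.  CCSD thresholds (0.024/0.034) agree between the
    14- and 311-molecule fits.
    """
    table = ThresholdTable()
    table.add("mp2", 0.030, 0.037, "fit on a 5090-molecule MP2 set (D2 0.15/0.17)")
    table.add(
        "mp2-small-set", 0.029, 0.037, "fit on a 34-molecule MP2 set (D2 0.15/0.17)"
    )
    table.add("ccsd", 0.024, 0.034, "fit on 14- and 311-molecule CCSD sets (D2 0.15/0.18)")
    return table


def classify_mr(
    i_nd_max: float,
    method: str,
    table: Optional[ThresholdTable] = None,
) -> str:
    """Classify a system as ``non-MR``, ``caution`` or ``MR`` from ``I_ND^max``."""
    if not (0.0 <= i_nd_max <= 0.125 + 1e-12):
        raise InvalidOccupancyError(
            f"i_nd_max = {i_nd_max:.6g} outside its range [0, 1/8]"
        )
    entry = (table or default_thresholds()).get(method)
    if i_nd_max < entry.lower:
        return "non-MR"
    if i_nd_max >= entry.upper:
        return "MR"
    return "caution"


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

#: order of the floating-point columns in serialized reports
REPORT_FIELDS = (
    "i_nd",
    "i_d",
    "i_t",
    "i_nd_hat",
    "i_d_hat",
    "i_nd_hat_occ",
    "i_nd_hat_vir",
    "i_nd_max",
    "ph_asymmetry",
)


@dataclass
class CorrelationReport:
    """All occupancy indices of one system plus its MR classification."""

    i_nd: float
    i_d: float
    i_t: float
    i_nd_hat: float
    i_d_hat: float
    i_nd_hat_occ: float
    i_nd_hat_vir: float
    i_nd_max: float
    ph_asymmetry: float
    classification: str = "not-classified"
    label: str = ""

    def to_dict(self) -> dict:
        out = {"label": self.label}
        out.update({f: getattr(self, f) for f in REPORT_FIELDS})
        out["classification"] = self.classification
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "CorrelationReport":
        kwargs = {f: float(raw[f]) for f in REPORT_FIELDS}
        return cls(
            label=str(raw.get("label", "")),
            classification=str(raw.get("classification", "not-classified")),
            **kwargs,
        )


def correlation_report(
    occ: OccupancyLike,
    method: Optional[str] = None,
    table: Optional[ThresholdTable] = None,
) -> CorrelationReport:
    """Compute every occupancy index and (optionally) classify the system.

    ``I_T = I_ND + I_D`` and ``Î_ND = Î_ND^o + Î_ND^v`` hold exactly by
    construction.  ``ph_asymmetry = |Î_ND^o − Î_ND^v| / max(Î_ND, 1e-12)``
    quantifies the particle–hole asymmetry of the 1-RDM.  When *method* is
    None the classification is ``"not-classified"``.
    """
    spin = _as_spin(occ)
    i_nd = nondynamic_index(occ)
    i_d, _ = dynamic_total_indices(occ)
    i_t = i_nd + i_d
    _, i_d_hat = size_intensive(occ)
    part_occ, part_vir = split_occ_vir(occ)
    i_nd_hat = part_occ + part_vir
    i_nd_max = nd_max(occ)
    ph = abs(part_occ - part_vir) / max(i_nd_hat, 1e-12)
    label = spin.label
    if method is None:
        classification = "not-classified"
    else:
        classification = classify_mr(i_nd_max, method, table)
    return CorrelationReport(
        i_nd=i_nd,
        i_d=i_d,
        i_t=i_t,
        i_nd_hat=i_nd_hat,
        i_d_hat=i_d_hat,
        i_nd_hat_occ=part_occ,
        i_nd_hat_vir=part_vir,
        i_nd_max=i_nd_max,
        ph_asymmetry=ph,
        classification=classification,
        label=label,
    )
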