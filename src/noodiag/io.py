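"""Readers and writers for occupancies, amplitudes, CI vectors and reports.

Supported occupancy sources:

* **molden** — ``Occup=`` fields of the ``[MO]`` section (``Spin= Alpha`` /
  ``Beta`` decides the channel; a file without beta entries is taken in the
  spatial [0, 2] convention);
* **wfx** — the ``<Molecular Orbital Occupation Numbers>`` block;
* **plain** — one number per line, ``#`` comments, spatial convention unless
  the caller says spin-resolved;
* **json** — ``{"occ": [...]}`` (spatial) or ``{"occ_alpha": [...],
  "occ_beta": [...]}`` with optional ``n_electrons``/``n_alpha``/``n_beta``/
  ``label`` keys;
* **auto** — sniffed by content.

Number parsing accepts Fortran ``D`` exponents and decimal commas.
Amplitude tensors travel in HDF5 containers with a 4-D C-order dataset
``t2`` (indices ``i, j, a, b``) and integer attributes ``n_occ``, ``n_vir``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import h5py
import numpy as np

from .amplitude_diagnostics import AmplitudeSet
from .errors import FormatError
from .occupancy import (
    REPORT_FIELDS,
    ClosedShellOccupancySet,
    CorrelationReport,
    SpinOccupancySet,
)

__all__ = [
    "OccupancyFileRecord",
    "read_occupancies",
    "write_report",
    "read_report",
    "read_amplitudes",
    "write_amplitudes",
    "read_ci_json",
    "write_fixtures",
]

_FLOAT_RE = re.compile(r"[-+]?\d*[.,]?\d+(?:[eEdD][-+]?\d+)?")


def _parse_float(token: str, path, line_no: int) -> float:
    """Locale/Fortran-tolerant float parsing (D exponents, decimal commas)."""
    try:
        return float(token.replace("d", "e").replace("D", "E").replace(",", "."))
    except ValueError:
        raise FormatError(f"{path}:{line_no}: cannot parse number {token!r}") from None


@dataclass
class OccupancyFileRecord:
    """Parsed occupancies plus whatever metadata the source file carried."""

    occ_alpha: Optional[np.ndarray] = None
    occ_beta: Optional[np.ndarray] = None
    occ_spatial: Optional[np.ndarray] = None
    n_alpha: Optional[int] = None
    n_beta: Optional[int] = None
    n_electrons: Optional[int] = None
    source_format: str = ""
    source_path: str = ""
    label: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def spin_resolved(self) -> bool:
        return self.occ_alpha is not None

    def to_occupancy_set(
        self, n_electrons: Optional[int] = None
    ) -> Union[SpinOccupancySet, ClosedShellOccupancySet]:
        """Build the domain object, inferring electron counts from the trace.

        An explicit *n_electrons* (or counts stored in the file) overrides the
        rounded occupation sum.
        """
        label = self.label or Path(self.source_path).name
        if self.spin_resolved:
            occ_a = np.asarray(self.occ_alpha, dtype=float)
            occ_b = np.asarray(
                self.occ_beta if self.occ_beta is not None else [], dtype=float
            )
            na = self.n_alpha if self.n_alpha is not None else int(round(occ_a.sum()))
            nb = self.n_beta if self.n_beta is not None else int(round(occ_b.sum()))
            if n_electrons is not None and n_electrons != na + nb:
                raise FormatError(
                    f"{self.source_path}: n_electrons={n_electrons} contradicts "
                    "the spin-resolved channel sums"
                )
            return SpinOccupancySet(occ_a, occ_b, na, nb, label=label)
        occ = np.asarray(self.occ_spatial, dtype=float)
        n = n_electrons if n_electrons is not None else self.n_electrons
        if n is None:
            n = int(round(occ.sum()))
            if n % 2 != 0:
                raise FormatError(
                    f"{self.source_path}: inferred electron count {n} is odd; "
                    "pass n_electrons explicitly or use spin-resolved input"
                )
        return ClosedShellOccupancySet(occ, n, label=label)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _sniff(text: str) -> str:
    lower = text.lower()
    if "[molden format]" in lower or "[mo]" in lower:
        return "molden"
    if "<molecular orbital occupation numbers>" in lower:
        return "wfx"
    if text.lstrip().startswith("{"):
        return "json"
    return "plain"


def _read_molden(text: str, path) -> OccupancyFileRecord:
    lines = text.splitlines()
    in_mo = False
    current_spin = "alpha"
    occ = {"alpha": [], "beta": []}
    for line_no, line in enumerate(lines, 1):
        stripped = line.strip()
        if stripped.lower().startswith("["):
            in_mo = stripped.lower().startswith("[mo]")
            continue
        if not in_mo:
            continue
        if "=" not in stripped:
            continue
        key, _, value = stripped.partition("=")
        key = key.strip().lower()
        if key == "spin":
            current_spin = value.strip().lower()
            if current_spin not in ("alpha", "beta"):
                raise FormatError(f"{path}:{line_no}: unknown spin {value.strip()!r}")
        elif key == "occup":
            occ[current_spin].append(_parse_float(value.strip(), path, line_no))
    if not occ["alpha"] and not occ["beta"]:
        raise FormatError(f"{path}: no Occup= entries found in the [MO] section")
    rec = OccupancyFileRecord(source_format="molden", source_path=str(path))
    if occ["beta"]:
        rec.occ_alpha = np.asarray(occ["alpha"])
        rec.occ_beta = np.asarray(occ["beta"])
    else:
        rec.occ_spatial = np.asarray(occ["alpha"])
    return rec


def _read_wfx(text: str, path) -> OccupancyFileRecord:
    def block(tag: str) -> Optional[str]:
        m = re.search(rf"<{tag}>(.*?)</{tag}>", text, re.S | re.I)
        return m.group(1) if m else None

    body = block("Molecular Orbital Occupation Numbers")
    if body is None:
        raise FormatError(
            f"{path}: missing <Molecular Orbital Occupation Numbers> block"
        )
    tokens = body.split()
    if not tokens:
        raise FormatError(f"{path}: empty occupation-number block")
    occ = np.asarray([_parse_float(tok, path, 0) for tok in tokens])
    rec = OccupancyFileRecord(
        occ_spatial=occ, source_format="wfx", source_path=str(path)
    )
    for tag, attr in (
        ("Number of Alpha Electrons", "n_alpha"),
        ("Number of Beta Electrons", "n_beta"),
        ("Number of Electrons", "n_electrons"),
    ):
        body = block(tag)
        if body is not None and body.split():
            setattr(rec, attr, int(body.split()[0]))
    return rec


def _read_plain(text: str, path, spin_resolved: bool) -> OccupancyFileRecord:
    values = []
    for line_no, line in enumerate(text.splitlines(), 1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        for token in stripped.split():
            values.append(_parse_float(token, path, line_no))
    if not values:
        raise FormatError(f"{path}: no occupation numbers found")
    rec = OccupancyFileRecord(source_format="plain", source_path=str(path))
    if spin_resolved:
        # two channels separated at the midpoint unless a blank-line split exists
        half = len(values) // 2
        rec.occ_alpha = np.asarray(values[:half])
        rec.occ_beta = np.asarray(values[half:])
    else:
        rec.occ_spatial = np.asarray(values)
    return rec


def _read_json(text: str, path) -> OccupancyFileRecord:
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}:{exc.lineno}: invalid JSON ({exc.msg})") from None
    rec = OccupancyFileRecord(source_format="json", source_path=str(path))
    if "occ_alpha" in raw:
        rec.occ_alpha = np.asarray(raw["occ_alpha"], dtype=float)
        rec.occ_beta = np.asarray(raw.get("occ_beta", []), dtype=float)
    elif "occ" in raw:
        rec.occ_spatial = np.asarray(raw["occ"], dtype=float)
    else:
        raise FormatError(f"{path}: JSON needs an 'occ' or 'occ_alpha' key")
    for key in ("n_alpha", "n_beta", "n_electrons"):
        if key in raw:
            setattr(rec, key, int(raw[key]))
    rec.label = str(raw.get("label", ""))
    return rec


def read_occupancies(
    path,
    format: str = "auto",
    spin_resolved: bool = False,
) -> OccupancyFileRecord:
    """Parse natural orbital occupancies from a file.

    *format* is one of ``molden``, ``wfx``, ``plain``, ``json`` or ``auto``
    (content sniffing, recorded in the result's warnings).  *spin_resolved*
    only affects the plain format, whose bare numbers are otherwise taken as
    spatial [0, 2] occupations.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"{path}: {exc}") from None
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    sniffed = None
    if format == "auto":
        sniffed = _sniff(text)
        format = sniffed
    if format == "molden":
        rec = _read_molden(text, path)
    elif format == "wfx":
        rec = _read_wfx(text, path)
    elif format == "plain":
        rec = _read_plain(text, path, spin_resolved)
    elif format == "json":
        rec = _read_json(text, path)
    else:
        raise FormatError(f"unknown occupancy format {format!r}")
    if sniffed is not None:
        rec.warnings.append(f"format auto-detected as {sniffed!r}")
    total = sum(
        float(np.sum(x))
        for x in (rec.occ_alpha, rec.occ_beta, rec.occ_spatial)
        if x is not None
    )
    if abs(total - round(total)) > 1e-2:
        rec.warnings.append(
            f"occupations sum to {total:.6g}, far from an integer electron count"
        )
    return rec


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

#: fixed column order of serialized reports
REPORT_COLUMNS = ("label", *REPORT_FIELDS, "classification")


def write_report(
    reports: Sequence[CorrelationReport],
    path,
    format: str = "csv",
) -> None:
    """Write correlation reports, one row/object per system, in input order.

    CSV uses the fixed column order :data:`REPORT_COLUMNS` with floats at six
    significant digits; JSON keeps full precision so a reparse reproduces the
    reports exactly.  Output is deterministic for identical input.
    """
    if not reports:
        raise ValueError("empty report list")
    if format == "csv":
        lines = [",".join(REPORT_COLUMNS)]
        for rep in reports:
            row = rep.to_dict()
            cells = []
            for col in REPORT_COLUMNS:
                val = row[col]
                cells.append(f"{val:.6g}" if isinstance(val, float) else str(val))
            lines.append(",".join(cells))
        Path(path).write_text("\n".join(lines) + "\n")
    elif format == "json":
        with open(path, "w") as fh:
            json.dump([rep.to_dict() for rep in reports], fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> list[CorrelationReport]:
    """Reparse a JSON report file written by :func:`write_report`."""
    with open(path) as fh:
        raw = json.load(fh)
    return [CorrelationReport.from_dict(entry) for entry in raw]


# ---------------------------------------------------------------------------
# amplitudes and CI vectors
# ---------------------------------------------------------------------------


def write_amplitudes(t: AmplitudeSet, path) -> None:
    """Store doubles amplitudes as HDF5: dataset ``t2``, attrs ``n_occ``/``n_vir``."""
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset("t2", data=np.ascontiguousarray(t.t2))
        dset.attrs["index_order"] = "i,j,a,b (occupied, occupied, virtual, virtual)"
        fh.attrs["n_occ"] = t.n_occ
        fh.attrs["n_vir"] = t.n_vir


def read_amplitudes(path) -> AmplitudeSet:
    """Load an :class:`AmplitudeSet` from an HDF5 container."""
    try:
        with h5py.File(path, "r") as fh:
            if "t2" not in fh:
                raise FormatError(f"{path}: missing 't2' dataset")
            t2 = np.asarray(fh["t2"][...], dtype=float)
            n_occ = int(fh.attrs.get("n_occ", t2.shape[0]))
            n_vir = int(fh.attrs.get("n_vir", t2.shape[2] if t2.ndim == 4 else 0))
    except OSError as exc:
        raise FormatError(f"{path}: {exc}") from None
    amp = AmplitudeSet(t2=t2)
    if (amp.n_occ, amp.n_vir) != (n_occ, n_vir):
        raise FormatError(
            f"{path}: attrs (n_occ={n_occ}, n_vir={n_vir}) contradict the "
            f"t2 shape {t2.shape}"
        )
    return amp


def read_ci_json(path) -> tuple[list[dict], int]:
    """Read a CI vector: ``{"n_electrons": N, "coefficients": [{rank, coefficient}]}``."""
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}:{exc.lineno}: invalid JSON ({exc.msg})") from None
    if "coefficients" not in raw or "n_electrons" not in raw:
        raise FormatError(f"{path}: needs 'coefficients' and 'n_electrons' keys")
    return list(raw["coefficients"]), int(raw["n_electrons"])


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def write_fixtures(directory, seed: int = 7) -> dict[str, Path]:
    """Write one small test fixture per supported format into *directory*.

    The occupancy fixtures all encode the same weakly correlated 10-electron
    closed-shell system, so readers can be cross-checked against each other;
    the HDF5 fixture holds a seeded random amplitude tensor.  Returns
    ``{format: path}``.
    """
    from .model_systems import sample_amplitudes

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    occ = [1.9952, 1.9881, 1.9811, 1.9702, 1.9419, 0.0562, 0.0331, 0.0212, 0.013]
    paths: dict[str, Path] = {}

    molden = directory / "fixture.molden"
    lines = ["[Molden Format]", "[Title]", "noodiag occupancy fixture", "[MO]"]
    for k, n in enumerate(occ, 1):
        lines += [f" Sym= a{k}", f" Ene= {0.1 * k - 1.0:.4f}", " Spin= Alpha",
                  f" Occup= {n!r}"]
    molden.write_text("\n".join(lines) + "\n")
    paths["molden"] = molden

    wfx = directory / "fixture.wfx"
    wfx.write_text(
        "<Number of Electrons>\n 10\n</Number of Electrons>\n"
        "<Molecular Orbital Occupation Numbers>\n"
        + "\n".join(f" {n!r}" for n in occ)
        + "\n</Molecular Orbital Occupation Numbers>\n"
    )
    paths["wfx"] = wfx

    plain = directory / "fixture_occ.txt"
    plain.write_text(
        "# spatial natural orbital occupations, one per line\n"
        + "\n".join(repr(n) for n in occ)
        + "\n"
    )
    paths["plain"] = plain

    occ_json = directory / "fixture_occ.json"
    occ_json.write_text(
        json.dumps(
            {"occ": occ, "n_electrons": 10, "label": "fixture"}, indent=2
        )
        + "\n"
    )
    paths["json"] = occ_json

    h5 = directory / "fixture_t2.h5"
    write_amplitudes(sample_amplitudes(3, 4, scale=0.05, seed=seed), h5)
    paths["hdf5"] = h5
    return paths
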