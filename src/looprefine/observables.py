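"""Experimental measurements: parsing, validation and atom binding.

A :class:`Measurement` is one experimental datum (an NOE-derived distance,
a three-bond scalar coupling, or a residual dipolar coupling) with its
uncertainty, atom selectors and dataset label.  Tables are TSV/CSV with a
required header and ``#`` comments::

    id  class  resid1  atom1  resid2  atom2  [resid3 atom3 resid4 atom4 |
    torsion_name]  value  sigma  sense  dataset  coupling_type  [quality]

NMR restraint tables and PDB files disagree on primed-hydrogen naming
(H5'1 vs H5', O1P vs OP1, ...); selectors are resolved through a documented
alias table so either dialect binds to the same atom.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble_io import Ensemble
from .errors import ValidationError

OBSERVABLE_CLASSES = ("noe_distance", "scalar_coupling", "rdc")
SENSES = ("equality", "upper_bound", "lower_bound")

#: Atom-name dialect aliases, applied when binding selectors to a topology.
ATOM_NAME_ALIASES = {
    "H5'1": "H5'",
    "H5'2": "H5''",
    'H5"': "H5''",
    "H2'1": "H2'",
    "H2'2": "H2''",
    'H2"': "H2''",
    "O1P": "OP1",
    "O2P": "OP2",
    "H5T": "HO5'",
    "H3T": "HO3'",
}

#: Default relative sigma per eNOE quality sub-class (configurable); applied
#: only when a table row carries a quality label but sigma is missing.
DEFAULT_QUALITY_RELATIVE_SIGMA = {
    "bidirectional": 0.02,
    "unidirectional": 0.05,
    "gn": 0.10,
}

TABLE_COLUMNS = [
    "id", "class", "resid1", "atom1", "resid2", "atom2", "resid3", "atom3",
    "resid4", "atom4", "torsion_name", "value", "sigma", "sense", "dataset",
    "coupling_type", "quality",
]


@dataclass
class Measurement:
    """One experimental datum ``F_exp`` with uncertainty ``sigma``.

    ``selectors`` are (residue index, atom name) pairs: two atoms for
    ``noe_distance`` and ``rdc``; four atoms *or* a named torsion
    (``torsion_name`` + ``resid1``) for ``scalar_coupling``.
    Units: Å for ``noe_distance``, Hz for ``scalar_coupling`` and ``rdc``.
    """

    id: str
    observable_class: str
    selectors: tuple
    value: float
    sigma: float
    sense: str = "equality"
    dataset: str = ""
    coupling_type: str | None = None
    torsion_name: str | None = None
    quality: str | None = None

    def __post_init__(self) -> None:
        self.value = float(self.value)
        self.sigma = float(self.sigma)
        if self.observable_class not in OBSERVABLE_CLASSES:
            raise ValidationError(
                f"measurement {self.id!r}: unknown observable class "
                f"{self.observable_class!r}"
            )
        if self.sense not in SENSES:
            raise ValidationError(f"measurement {self.id!r}: bad sense {self.sense!r}")
        if not np.isfinite(self.value):
            raise ValidationError(f"measurement {self.id!r}: non-finite value")
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValidationError(f"measurement {self.id!r}: sigma must be > 0")
        self.selectors = tuple((int(r), str(a)) for r, a in self.selectors)
        n_sel = len(self.selectors)
        if self.observable_class in ("noe_distance", "rdc"):
            if n_sel != 2:
                raise ValidationError(
                    f"measurement {self.id!r}: {self.observable_class} needs "
                    f"exactly 2 atom selectors"
                )
            if self.selectors[0] == self.selectors[1]:
                raise ValidationError(
                    f"measurement {self.id!r}: selectors must be distinct atoms"
                )
        elif self.observable_class == "scalar_coupling":
            if self.torsion_name is None and n_sel != 4:
                raise ValidationError(
                    f"measurement {self.id!r}: scalar_coupling needs 4 atom "
                    f"selectors or a torsion_name"
                )
            if n_sel == 4 and len(set(self.selectors)) != 4:
                raise ValidationError(
                    f"measurement {self.id!r}: selectors must be distinct atoms"
                )
        if self.observable_class == "noe_distance" and self.value <= 0:
            raise ValidationError(
                f"measurement {self.id!r}: NOE distance must be positive"
            )


@dataclass
class ObservableMatrix:
    """Per-frame back-calculated values ``F_i(x_j)`` for ``m`` measurements.

    ``transform`` records the space in which linear weight-averaging of the
    rows is exact: ``linear`` (couplings, RDCs) or ``r_minus_6`` (NOE rows
    stored as r^-6 so that ``matrix @ w`` is the physical ensemble average).
    """

    ids: list
    values: np.ndarray
    transform: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.transform not in ("linear", "r_minus_6"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if len(self.ids) != self.values.shape[0]:
            raise ValidationError("row count must equal number of measurements")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite observable values")

    @property
    def n_measurements(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def averages(self, weights: np.ndarray) -> np.ndarray:
        """Linear-space weighted averages of each row."""
        return self.values @ np.asarray(weights, dtype=float)


def _opt(row, key):
    v = row.get(key)
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return v


def _row_to_measurement(row: dict, line: int) -> Measurement:
    cls = str(row.get("class", "")).strip()
    torsion = _opt(row, "torsion_name")
    selectors = []
    if torsion is None:
        for k in (1, 2, 3, 4):
            rid, aname = _opt(row, f"resid{k}"), _opt(row, f"atom{k}")
            if rid is None or aname is None:
                break
            selectors.append((int(rid), str(aname)))
    else:
        # named-torsion couplings key off resid1; bind via the anchor atom
        selectors = [(int(row["resid1"]), "C1'")]
    try:
        sigma = float(row["sigma"])
    except (KeyError, TypeError, ValueError):
        quality = _opt(row, "quality")
        rel = DEFAULT_QUALITY_RELATIVE_SIGMA.get(str(quality), None)
        if rel is None:
            raise ValidationError(f"line {line}: missing or malformed sigma")
        sigma = rel * abs(float(row["value"]))
    return Measurement(
        id=str(row["id"]),
        observable_class=cls,
        selectors=tuple(selectors),
        value=float(row["value"]),
        sigma=sigma,
        sense=str(_opt(row, "sense") or "equality"),
        dataset=str(_opt(row, "dataset") or ""),
        coupling_type=_opt(row, "coupling_type"),
        torsion_name=str(torsion) if torsion is not None else None,
        quality=_opt(row, "quality"),
    )


def parse_measurements(table: str | Path, dialect: str | None = None) -> list:
    """Parse a measurement TSV/CSV into a validated list of Measurements.

    ``dialect`` may be ``"tsv"`` or ``"csv"``; by default it is inferred
    from the file extension (``.csv`` -> comma, otherwise tab).  Malformed
    rows are reported with their line number; duplicate ids are rejected.
    """
    path = Path(table)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = "," if (dialect == "csv" or (dialect is None and path.suffix == ".csv")) else "\t"
    try:
        df = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True,
                         float_precision="round_trip")
    except Exception as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    required = {"id", "class", "value", "sigma"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    measurements: list[Measurement] = []
    seen: set[str] = set()
    for pos, (_, row) in enumerate(df.iterrows()):
        line = pos + 2  # header is line 1 (comments aside)
        try:
            m = _row_to_measurement(row.to_dict(), line)
        except ValidationError:
            raise
        except Exception as exc:
            raise ValidationError(f"{path} line {line}: malformed row ({exc})") from exc
        if m.sigma <= 0:
            raise ValidationError(f"{path} line {line}: sigma must be > 0")
        if m.id in seen:
            raise ValidationError(f"{path} line {line}: duplicate id {m.id!r}")
        seen.add(m.id)
        measurements.append(m)
    return measurements


def write_measurements(measurements: list, path: str | Path) -> None:
    """Write measurements in the same TSV dialect :func:`parse_measurements` reads."""
    rows = []
    for m in measurements:
        row = {c: "" for c in TABLE_COLUMNS}
        row.update(id=m.id, **{"class": m.observable_class}, value=repr(m.value),
                   sigma=repr(m.sigma), sense=m.sense, dataset=m.dataset)
        if m.coupling_type:
            row["coupling_type"] = m.coupling_type
        if m.quality:
            row["quality"] = m.quality
        if m.torsion_name:
            row["torsion_name"] = m.torsion_name
            row["resid1"] = m.selectors[0][0] if m.selectors else ""
        else:
            for k, (rid, aname) in enumerate(m.selectors, start=1):
                row[f"resid{k}"] = rid
                row[f"atom{k}"] = aname
        rows.append(row)
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def class_counts(measurements: list) -> dict:
    counts: dict[str, int] = {}
    for m in measurements:
        counts[m.observable_class] = counts.get(m.observable_class, 0) + 1
    return counts


def bind_selectors(measurements: list, ensemble: Ensemble) -> dict:
    """Resolve every selector to an atom index in the ensemble topology.

    Returns a ``{(resid, atom_name): atom_index}`` map covering all
    selectors (alias-resolved).  Unresolved selectors are collected and
    reported together in a single error.
    """
    index = ensemble.atom_index
    resolved: dict[tuple[int, str], int] = {}
    misses: list[str] = []
    for m in measurements:
        for rid, aname in m.selectors:
            key = (rid, aname)
            if key in resolved:
                continue
            hit = index.get(key)
            if hit is None:
                alias = ATOM_NAME_ALIASES.get(aname)
                if alias is not None:
                    hit = index.get((rid, alias))
            if hit is None:
                misses.append(f"{m.id}: ({rid}, {aname!r})")
            else:
                resolved[key] = hit
    if misses:
        raise ValidationError(
            "unresolved atom selectors:\n  " + "\n  ".join(sorted(set(misses)))
        )
    return resolved


def transform_noe_to_rminus6(value: float | np.ndarray,
                             sigma: float | np.ndarray):
    """Map NOE distances (Å) to r^-6 space, propagating sigma to first order.

    BME requires observables linear in the weights; NOE averaging is linear
    in r^-6.  ``F' = F^-6`` and ``sigma' = 6 sigma F^-7``.
    """
    value = np.asarray(value, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(value <= 0):
        raise ValidationError("NOE distances must be positive")
    return value ** -6.0, 6.0 * sigma * value ** -7.0
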