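"""Back-calculation of NMR observables from conformational ensembles.

Three observable classes are supported:

* NOE effective distances -- ensemble r^-6 averages,
  ``r_eff = (sum_j w_j r_j^-6)^(-1/6)``.  Per-frame rows are stored as
  r^-6 so that linear weight-averaging of the observable matrix is exact.
* Three-bond scalar couplings -- Karplus equations,
  ``J = A cos^2(theta + phi) + B cos(theta + phi) + C``; coefficients are
  configuration (an editable table keyed by coupling type), not code.
* Residual dipolar couplings -- ``D_i = D_max,i * u^T S u`` with a single
  global alignment (Saupe) tensor ``S``; the tensor is obtained by a
  five-parameter linear least-squares fit on the weighted prior ensemble
  and held fixed during reweighting (linearization keeps each BME solve
  convex), with an optional refit-to-convergence mode at a higher level.

Angles are degrees in I/O and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ensemble_io import Ensemble, WeightSet
from .errors import StructureError, ValidationError
from .observables import (Measurement, ObservableMatrix, bind_selectors,
                          transform_noe_to_rminus6)
from . import structure_metrics as sm


@dataclass(frozen=True)
class KarplusCoefficients:
    """Karplus coefficients in Hz plus a phase offset in degrees."""

    A: float
    B: float
    C: float
    phase_deg: float = 0.0
    coupling_type: str = ""

    def __post_init__(self) -> None:
        for v in (self.A, self.B, self.C, self.phase_deg):
            if not np.isfinite(v):
                raise ValidationError("non-finite Karplus coefficient")


#: Default Karplus table.  Representative literature-style parametrizations
#: for sugar H-C-C-H, backbone H-C-O-P and C-C-O-P couplings; values are
#: deliberately configuration (see load_karplus_table) rather than pinned
#: physics, since published parametrizations vary.
DEFAULT_KARPLUS = {
    "sugar_HH": KarplusCoefficients(9.67, -2.03, 0.0, 0.0, "sugar_HH"),
    "backbone_HCOP": KarplusCoefficients(15.3, -6.1, 1.6, 0.0, "backbone_HCOP"),
    "backbone_CCOP": KarplusCoefficients(6.9, -3.4, 0.7, 0.0, "backbone_CCOP"),
}

#: RDC normalization constants D_max (Hz) per bond type; "default" applies
#: when a measurement's coupling_type is absent from the table.
DEFAULT_DMAX = {"default": 1.0}


def load_karplus_table(path: str | Path) -> dict:
    """Load a Karplus table (TSV: coupling_type, A, B, C, phase_deg)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"coupling_type", "A", "B", "C", "phase_deg"}
    if not required <= set(df.columns):
        raise ValidationError(f"Karplus table needs columns {sorted(required)}")
    table = {}
    for _, row in df.iterrows():
        key = str(row["coupling_type"])
        if key in table:
            raise ValidationError(f"duplicate coupling_type {key!r}")
        table[key] = KarplusCoefficients(float(row["A"]), float(row["B"]),
                                         float(row["C"]),
                                         float(row["phase_deg"]), key)
    return table


def load_dmax_table(path: str | Path) -> dict:
    """Load RDC normalization constants (TSV: bond_type, D_max_Hz)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"bond_type", "D_max_Hz"} <= set(df.columns):
        raise ValidationError("D_max table needs columns bond_type, D_max_Hz")
    return {str(r["bond_type"]): float(r["D_max_Hz"]) for _, r in df.iterrows()}


# ---------------------------------------------------------------------------
# NOE
# ---------------------------------------------------------------------------

def noe_effective_distance(per_frame_distances, weights: WeightSet) -> float:
    """r^-6-weighted effective distance ``(sum_j w_j r_j^-6)^(-1/6)`` in Å.

    Lies within [min r, max r] and never exceeds the linear weighted mean.
    """
    r = np.asarray(per_frame_distances, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("distances must be positive")
    if len(r) != len(weights):
        raise ValidationError("distance/weight length mismatch")
    return float((weights.weights @ r ** -6.0) ** (-1.0 / 6.0))


def _pair_distances(ensemble: Ensemble, measurements, index_map) -> np.ndarray:
    """(m, n) per-frame distances for two-atom measurements."""
    rows = np.empty((len(measurements), ensemble.n_frames))
    for k, m in enumerate(measurements):
        i = index_map[m.selectors[0]]
        j = index_map[m.selectors[1]]
        d = np.linalg.norm(ensemble.coords[:, i, :] - ensemble.coords[:, j, :],
                           axis=1)
        if np.any(d < 1e-6):
            raise StructureError(
                f"measurement {m.id!r}: zero-length atom pair in some frame"
            )
        rows[k] = d
    return rows


def noe_observable_rows(ensemble: Ensemble, measurements,
                        index_map=None) -> ObservableMatrix:
    """Per-frame r^-6 rows (Å^-6) for NOE distance measurements."""
    measurements = [m for m in measurements
                    if m.observable_class == "noe_distance"]
    if index_map is None:
        index_map = bind_selectors(measurements, ensemble)
    if not measurements:
        return ObservableMatrix([], np.empty((0, ensemble.n_frames)),
                                transform="r_minus_6")
    dist = _pair_distances(ensemble, measurements, index_map)
    return ObservableMatrix([m.id for m in measurements], dist ** -6.0,
                            transform="r_minus_6")


# ---------------------------------------------------------------------------
# Scalar couplings
# ---------------------------------------------------------------------------

def karplus_coupling(torsion_deg, coeff: KarplusCoefficients):
    """Karplus relation ``J = A cos^2(theta+phi) + B cos(theta+phi) + C`` (Hz)."""
    theta = np.radians(np.asarray(torsion_deg, dtype=float) + coeff.phase_deg)
    c = np.cos(theta)
    out = coeff.A * c ** 2 + coeff.B * c + coeff.C
    return float(out) if out.ndim == 0 else out


def coupling_observable_rows(ensemble: Ensemble, measurements,
                             index_map=None,
                             karplus_table=None) -> ObservableMatrix:
    """Per-frame scalar-coupling rows (Hz), linear averaging space."""
    if karplus_table is None:
        karplus_table = DEFAULT_KARPLUS
    measurements = [m for m in measurements
                    if m.observable_class == "scalar_coupling"]
    if not measurements:
        return ObservableMatrix([], np.empty((0, ensemble.n_frames)))
    if index_map is None:
        index_map = bind_selectors(measurements, ensemble)
    frame0 = ensemble.frame(0)
    rows = np.empty((len(measurements), ensemble.n_frames))
    for k, m in enumerate(measurements):
        if m.coupling_type not in karplus_table:
            raise ValidationError(
                f"measurement {m.id!r}: unknown coupling type "
                f"{m.coupling_type!r}"
            )
        coeff = karplus_table[m.coupling_type]
        if m.torsion_name is not None:
            resid = m.selectors[0][0]
            quad = sm.torsion_quadruplet_atoms(frame0, resid, m.torsion_name)
            if quad is None:
                raise ValidationError(
                    f"measurement {m.id!r}: torsion {m.torsion_name!r} "
                    f"undefined for residue {resid}"
                )
            idx = [ensemble.atom_index[sel] for sel in quad]
        else:
            idx = [index_map[sel] for sel in m.selectors]
        pts = ensemble.coords[:, idx, :]
        theta = sm.dihedral(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        rows[k] = karplus_coupling(theta, coeff)
    return ObservableMatrix([m.id for m in measurements], rows)


# ---------------------------------------------------------------------------
# RDCs
# ---------------------------------------------------------------------------

@dataclass
class AlignmentTensor:
    """3x3 symmetric traceless order (Saupe) matrix."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValidationError("alignment tensor must be 3x3")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValidationError("alignment tensor must be symmetric")
        if abs(np.trace(self.matrix)) > 1e-12:
            raise ValidationError("alignment tensor must be traceless")

    @classmethod
    def from_params(cls, s: np.ndarray) -> "AlignmentTensor":
        """Build from the 5 independent components (Sxx, Syy, Sxy, Sxz, Syz)."""
        sxx, syy, sxy, sxz, syz = np.asarray(s, dtype=float)
        return cls(np.array([
            [sxx, sxy, sxz],
            [sxy, syy, syz],
            [sxz, syz, -sxx - syy],
        ]))

    @property
    def params(self) -> np.ndarray:
        m = self.matrix
        return np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]])


def _unit_bond_vectors(ensemble: Ensemble, measurements, index_map) -> np.ndarray:
    """(m, n, 3) unit bond vectors for two-atom RDC measurements."""
    u = np.empty((len(measurements), ensemble.n_frames, 3))
    for k, m in enumerate(measurements):
        i = index_map[m.selectors[0]]
        j = index_map[m.selectors[1]]
        v = ensemble.coords[:, j, :] - ensemble.coords[:, i, :]
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        if np.any(norms < 1e-6):
            raise StructureError(f"measurement {m.id!r}: zero-length bond vector")
        u[k] = v / norms
    return u


def _orientation_products(u: np.ndarray) -> np.ndarray:
    """Map unit vectors (..., 3) to the 5 products multiplying the tensor params."""
    ux, uy, uz = u[..., 0], u[..., 1], u[..., 2]
    return np.stack([
        ux ** 2 - uz ** 2,
        uy ** 2 - uz ** 2,
        2.0 * ux * uy,
        2.0 * ux * uz,
        2.0 * uy * uz,
    ], axis=-1)


def _dmax_for(m: Measurement, dmax_table) -> float:
    table = DEFAULT_DMAX if dmax_table is None else dmax_table
    key = m.coupling_type if m.coupling_type in table else "default"
    if key not in table:
        raise ValidationError(
            f"measurement {m.id!r}: no D_max for bond type {m.coupling_type!r}"
        )
    return float(table[key])


def fit_alignment_tensor(ensemble: Ensemble, weights: WeightSet,
                         rdc_measurements, index_map=None,
                         dmax_table=None) -> AlignmentTensor:
    """Least-squares alignment tensor from >= 5 RDCs.

    Minimizes ``sum_i (D_calc,i - D_exp,i)^2 / sigma_i^2`` over the five
    independent tensor components, with ``D_calc`` the weighted ensemble
    average of ``D_max u^T S u``.
    """
    rdcs = [m for m in rdc_measurements if m.observable_class == "rdc"]
    if len(rdcs) < 5:
        raise ValidationError(
            f"underdetermined: tensor fit needs >= 5 RDCs, got {len(rdcs)}"
        )
    if index_map is None:
        index_map = bind_selectors(rdcs, ensemble)
    u = _unit_bond_vectors(ensemble, rdcs, index_map)     # (m, n, 3)
    q = _orientation_products(u)                          # (m, n, 5)
    q_avg = np.einsum("mnp,n->mp", q, weights.weights)    # (m, 5)
    dmax = np.array([_dmax_for(m, dmax_table) for m in rdcs])
    design = dmax[:, None] * q_avg
    sigma = np.array([m.sigma for m in rdcs])
    y = np.array([m.value for m in rdcs])
    a = design / sigma[:, None]
    b = y / sigma
    params, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 5:
        raise ValidationError(
            "unidentifiable tensor: rank-deficient design (degenerate bond "
            "orientations)"
        )
    return AlignmentTensor.from_params(params)


def rdc_observable_rows(ensemble: Ensemble, tensor: AlignmentTensor,
                        rdc_measurements, index_map=None,
                        dmax_table=None) -> ObservableMatrix:
    """Per-frame RDC rows ``D_i(x_j) = D_max,i u^T S u`` (Hz), linear space."""
    rdcs = [m for m in rdc_measurements if m.observable_class == "rdc"]
    if not rdcs:
        return ObservableMatrix([], np.empty((0, ensemble.n_frames)))
    if index_map is None:
        index_map = bind_selectors(rdcs, ensemble)
    u = _unit_bond_vectors(ensemble, rdcs, index_map)
    q = _orientation_products(u)                          # (m, n, 5)
    dmax = np.array([_dmax_for(m, dmax_table) for m in rdcs])
    rows = dmax[:, None] * (q @ tensor.params)
    return ObservableMatrix([m.id for m in rdcs], rows)


# ---------------------------------------------------------------------------
# Assembly for reweighting
# ---------------------------------------------------------------------------

def assemble_bme_inputs(ensemble: Ensemble, measurements, prior: WeightSet,
                        karplus_table=None, dmax_table=None, tensor=None):
    """Stack all observable classes into one linear-averaging-space problem.

    NOE targets and uncertainties are transformed to r^-6 space; couplings
    and RDCs stay linear.  If RDCs are present and no tensor is supplied,
    the tensor is fit on the prior ensemble.  Returns a dict with ids,
    matrix, f_exp, sigma (all aligned), the tensor used (or None), and the
    row slice per observable class.
    """
    index_map = bind_selectors(measurements, ensemble)
    noe = [m for m in measurements if m.observable_class == "noe_distance"]
    coup = [m for m in measurements if m.observable_class == "scalar_coupling"]
    rdc = [m for m in measurements if m.observable_class == "rdc"]

    blocks, ids, f_exp, sigma, slices = [], [], [], [], {}
    row = 0

    if noe:
        mat = noe_observable_rows(ensemble, noe, index_map)
        fe, sg = transform_noe_to_rminus6(
            np.array([m.value for m in noe]), np.array([m.sigma for m in noe])
        )
        blocks.append(mat.values)
        ids += mat.ids
        f_exp.append(fe)
        sigma.append(sg)
        slices["noe_distance"] = slice(row, row + len(noe))
        row += len(noe)
    if coup:
        mat = coupling_observable_rows(ensemble, coup, index_map, karplus_table)
        blocks.append(mat.values)
        ids += mat.ids
        f_exp.append(np.array([m.value for m in coup]))
        sigma.append(np.array([m.sigma for m in coup]))
        slices["scalar_coupling"] = slice(row, row + len(coup))
        row += len(coup)
    if rdc:
        if tensor is None:
            tensor = fit_alignment_tensor(ensemble, prior, rdc, index_map,
                                          dmax_table)
        mat = rdc_observable_rows(ensemble, tensor, rdc, index_map, dmax_table)
        blocks.append(mat.values)
        ids += mat.ids
        f_exp.append(np.array([m.value for m in rdc]))
        sigma.append(np.array([m.sigma for m in rdc]))
        slices["rdc"] = slice(row, row + len(rdc))
        row += len(rdc)

    if not blocks:
        raise ValidationError("no measurements to assemble")
    return {
        "ids": ids,
        "matrix": np.vstack(blocks),
        "f_exp": np.concatenate(f_exp),
        "sigma": np.concatenate(sigma),
        "slices": slices,
        "tensor": tensor,
        "measurements": list(noe) + list(coup) + list(rdc),
    }


def reweight_with_tensor_refit(ensemble: Ensemble, measurements,
                               prior: WeightSet, theta: float,
                               karplus_table=None, dmax_table=None,
                               max_rounds: int = 10, tol: float = 1e-6):
    """BME solve with the alignment tensor refit to self-consistency.

    The RDC forward model is linearized around a fixed tensor; fitting the
    tensor on the prior can bias the RDC rows when the refined weights
    differ substantially from the prior.  This iterates: fit tensor on the
    current weights -> rebuild RDC rows -> BME solve, until the weights
    change by less than ``tol`` (max ``max_rounds`` rounds).  Returns
    ``(inputs, result)`` with the final linearized inputs and BME result.
    """
    from . import bme as _bme

    inputs = assemble_bme_inputs(ensemble, measurements, prior,
                                 karplus_table, dmax_table)
    weights = prior
    result = None
    for _ in range(max_rounds):
        result = _bme.solve(_bme.BMEProblem(
            inputs["matrix"], prior, inputs["f_exp"], inputs["sigma"], theta))
        delta = np.max(np.abs(result.weights.weights - weights.weights))
        weights = result.weights
        if inputs["tensor"] is None or delta < tol:
            break
        inputs = assemble_bme_inputs(ensemble, measurements, prior,
                                     karplus_table, dmax_table,
                                     tensor=fit_alignment_tensor(
                                         ensemble, weights, measurements,
                                         dmax_table=dmax_table))
    return inputs, result


def physical_averages(inputs: dict, weights: WeightSet) -> np.ndarray:
    """Ensemble averages back-transformed to physical space (Å or Hz).

    NOE rows are averaged in r^-6 space then mapped back to distances;
    couplings and RDCs average linearly.
    """
    avg = inputs["matrix"] @ weights.weights
    out = avg.copy()
    noe_slice = inputs["slices"].get("noe_distance")
    if noe_slice is not None:
        out[noe_slice] = avg[noe_slice] ** (-1.0 / 6.0)
    return out
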