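"""Conformational-ensemble, bias-energy and weight I/O.

This module defines the frame/atom data model consumed by the rest of the
package and the readers/writers for the standard formats around it:

* multi-model PDB files (read and write, via biotite),
* MD trajectories -- XTC/DCD/TRR/GRO plus a PDB/GRO topology (read, via
  mdtraj),
* per-frame bias energies and frame weights as two-column TSV.

Conventions
-----------
Coordinates are stored internally in ångström; trajectory formats that are
natively in nanometre (XTC, TRR, GRO) are converted on read.  Residue
indices are 1-based and sequential 5'->3'; frames are indexed 0-based.

Prior weights for enhanced-sampling ensembles are obtained from the final
metadynamics bias potential: ``w0_j \\propto exp(+V_j / kB T)`` where ``V_j``
is the deposited bias at frame ``j``.  Deposited files sometimes store the
negative of the bias, so the sign is exposed as a flag rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

import numpy as np

from .errors import StructureError, ValidationError

#: Boltzmann constant in kJ mol^-1 K^-1.
KB_KJ_MOL_K = 0.008314462618



def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _build_atom_index(res_ids: np.ndarray, atom_names: np.ndarray) -> dict:
    index: dict[tuple[int, str], int] = {}
    for i, (rid, aname) in enumerate(zip(res_ids.tolist(), atom_names.tolist())):
        key = (int(rid), str(aname))
        if key in index:
            raise StructureError(f"duplicate atom {aname!r} in residue {rid}")
        index[key] = i
    return index


@dataclass
class Conformation:
    """A single structure: shared topology annotations plus coordinates in Å."""

    atom_names: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError("coordinates must be an (n_atoms, 3) array")
        if self.coords.shape[0] != len(self.atom_names):
            raise StructureError("coordinate/atom count mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def atom_index(self) -> dict:
        # cached lazily; dataclass fields stay comparable
        idx = getattr(self, "_atom_index", None)
        if idx is None:
            idx = _build_atom_index(self.res_ids, self.atom_names)
            object.__setattr__(self, "_atom_index", idx)
        return idx

    def position(self, res_id: int, atom_name: str) -> np.ndarray:
        """Coordinates of one atom, identified by (residue index, atom name)."""
        try:
            return self.coords[self.atom_index[(int(res_id), atom_name)]]
        except KeyError:
            raise StructureError(
                f"atom {atom_name!r} not found in residue {res_id}"
            ) from None

    def residue_ids(self) -> np.ndarray:
        return np.unique(self.res_ids)

    def residue_name(self, res_id: int) -> str:
        mask = self.res_ids == res_id
        if not mask.any():
            raise StructureError(f"no residue with index {res_id}")
        return str(self.res_names[mask][0])


@dataclass
class Ensemble:
    """Shared topology plus an ordered list of ``n`` conformations.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` in Å; all frames share
    the topology atom count and ordering.
    """

    atom_names: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError("ensemble coordinates must be (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise StructureError("an ensemble needs at least one frame")
        if self.coords.shape[1] != len(self.atom_names):
            raise StructureError("coordinate/atom count mismatch")
        if self.coords.shape[1] == 0:
            raise StructureError("zero atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def atom_index(self) -> dict:
        idx = getattr(self, "_atom_index", None)
        if idx is None:
            idx = _build_atom_index(self.res_ids, self.atom_names)
            object.__setattr__(self, "_atom_index", idx)
        return idx

    def frame(self, j: int) -> Conformation:
        return Conformation(
            self.atom_names, self.res_names, self.res_ids, self.chain_ids,
            self.coords[j],
        )

    def frames(self) -> Iterator[Conformation]:
        for j in range(self.n_frames):
            yield self.frame(j)

    @classmethod
    def from_frames(cls, frames: list[Conformation]) -> "Ensemble":
        if not frames:
            raise StructureError("empty frame list")
        first = frames[0]
        for k, f in enumerate(frames[1:], start=1):
            if f.n_atoms != first.n_atoms or not np.array_equal(
                f.atom_names, first.atom_names
            ):
                raise StructureError(f"inconsistent models: frame {k} topology differs")
        coords = np.stack([f.coords for f in frames])
        return cls(first.atom_names, first.res_names, first.res_ids,
                   first.chain_ids, coords)


@dataclass
class WeightSet:
    """Normalized per-frame weights with provenance.

    ``tag`` distinguishes the prior (w0) from refined (w*) weights;
    ``provenance`` records how they were obtained
    (``uniform`` | ``metadynamics-bias`` | ``BME``).
    """

    weights: np.ndarray
    tag: Literal["prior", "refined"] = "prior"
    provenance: str = "uniform"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValidationError("weights must be a 1-D vector")
        if not np.all(np.isfinite(self.weights)):
            raise ValidationError("non-finite weights")
        if np.any(self.weights < 0):
            raise ValidationError("negative weights")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"weights must sum to 1 (got {total!r})")

    def __len__(self) -> int:
        return len(self.weights)

    @classmethod
    def uniform(cls, n: int) -> "WeightSet":
        if n < 1:
            raise ValidationError("need at least one frame")
        return cls(np.full(n, 1.0 / n), tag="prior", provenance="uniform")

    @classmethod
    def from_unnormalized(cls, raw: np.ndarray, tag: str = "prior",
                          provenance: str = "uniform") -> "WeightSet":
        raw = np.asarray(raw, dtype=float)
        total = raw.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValidationError("weights must have a positive finite sum")
        return cls(raw / total, tag=tag, provenance=provenance)


# ---------------------------------------------------------------------------
# PDB ensembles
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path: str | Path) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    One frame per MODEL record; a single-structure PDB yields ``n = 1``.
    Models whose atom count deviates from the first model are rejected.
    """
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        pdb = pdbio.PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise StructureError(f"inconsistent models in {path.name}: {exc}") from exc
    if stack.array_length() == 0:
        raise StructureError(f"zero atoms in {path.name}")
    return Ensemble(
        atom_names=np.asarray(stack.atom_name, dtype="U6"),
        res_names=np.asarray(stack.res_name, dtype="U4"),
        res_ids=np.asarray(stack.res_id, dtype=int),
        chain_ids=np.asarray(stack.chain_id, dtype="U2"),
        coords=np.asarray(stack.coord, dtype=float),
    )


def write_multimodel_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    stack = struc.AtomArrayStack(ensemble.n_frames, ensemble.n_atoms)
    stack.coord = ensemble.coords
    stack.atom_name = np.asarray(ensemble.atom_names, dtype="U6")
    stack.res_name = np.asarray(ensemble.res_names, dtype="U4")
    stack.res_id = np.asarray(ensemble.res_ids, dtype=int)
    stack.chain_id = np.asarray(ensemble.chain_ids, dtype="U2")
    stack.element = np.array(
        [_element_from_name(n) for n in ensemble.atom_names], dtype="U2"
    )
    stack.hetero = np.zeros(ensemble.n_atoms, dtype=bool)
    pdb = pdbio.PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_conformation_pdb(conformation: Conformation, path: str | Path) -> None:
    ens = Ensemble(conformation.atom_names, conformation.res_names,
                   conformation.res_ids, conformation.chain_ids,
                   conformation.coords[None, :, :])
    write_multimodel_pdb(ens, path)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(topology: str | Path, trajectory: str | Path) -> Ensemble:
    """Read a trajectory (XTC/DCD/TRR/GRO/PDB) with a PDB/GRO topology.

    Frame order is preserved and coordinates are converted to Å regardless
    of the source unit convention (mdtraj normalizes internally to nm).
    """
    import mdtraj as md

    topology, trajectory = Path(topology), Path(trajectory)
    for p in (topology, trajectory):
        if not p.exists():
            raise ValidationError(f"no such file: {p}")
    try:
        traj = md.load(str(trajectory), top=str(topology))
    except Exception as exc:
        raise StructureError(
            f"cannot read trajectory {trajectory.name} with topology "
            f"{topology.name}: {exc}"
        ) from exc
    if traj.n_frames == 0:
        raise StructureError(f"trajectory {trajectory.name} contains no frames")
    top = traj.topology
    atom_names = np.array([a.name for a in top.atoms], dtype="U6")
    res_names = np.array([a.residue.name for a in top.atoms], dtype="U4")
    res_ids = np.array([a.residue.resSeq for a in top.atoms], dtype=int)
    chain_ids = np.array(
        [chr(ord("A") + min(a.residue.chain.index, 25)) for a in top.atoms],
        dtype="U2",
    )
    coords = np.asarray(traj.xyz, dtype=float) * 10.0  # nm -> Å
    return Ensemble(atom_names, res_names, res_ids, chain_ids, coords)


def to_mdtraj(ensemble: Ensemble):
    """Convert to an :class:`mdtraj.Trajectory` (coordinates back to nm)."""
    import mdtraj as md

    top = md.Topology()
    chain_map: dict[str, object] = {}
    res_map: dict[tuple[str, int], object] = {}
    for aname, rname, rid, cid in zip(
        ensemble.atom_names, ensemble.res_names, ensemble.res_ids,
        ensemble.chain_ids,
    ):
        cid = str(cid)
        if cid not in chain_map:
            chain_map[cid] = top.add_chain()
        rkey = (cid, int(rid))
        if rkey not in res_map:
            res_map[rkey] = top.add_residue(str(rname), chain_map[cid],
                                            resSeq=int(rid))
        try:
            elem = md.element.get_by_symbol(_element_from_name(str(aname)))
        except KeyError:
            elem = md.element.carbon
        top.add_atom(str(aname), elem, res_map[rkey])
    return md.Trajectory(ensemble.coords / 10.0, top)


# ---------------------------------------------------------------------------
# Bias energies and weights
# ---------------------------------------------------------------------------

def bias_to_prior_weights(bias_energies: np.ndarray, temperature: float,
                          sign: int = +1) -> WeightSet:
    """Turn final-bias metadynamics energies into prior frame weights.

    ``w0_j \\propto exp(sign * V_j / kB T)`` with ``V_j`` in kJ/mol.  The
    result is invariant to adding any constant to all ``V_j``.  ``sign=-1``
    accommodates deposited files that store the negative of the bias.
    """
    v = np.asarray(bias_energies, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValidationError("bias energies must be a non-empty 1-D vector")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite bias energy")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    if sign not in (+1, -1):
        raise ValidationError("sign must be +1 or -1")
    x = sign * v / (KB_KJ_MOL_K * temperature)
    x = x - x.max()  # uniform-shift invariance + overflow safety
    raw = np.exp(x)
    return WeightSet.from_unnormalized(raw, tag="prior",
                                       provenance="metadynamics-bias")


def read_two_column_tsv(path: str | Path) -> np.ndarray:
    """Read a 2-column (frame-id, value) TSV with '#' comments; values only."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    data = np.atleast_2d(np.loadtxt(path, comments="#"))
    if data.size == 0:
        raise ValidationError(f"empty table: {path}")
    if data.shape[1] != 2:
        raise ValidationError(f"{path}: expected 2 columns, got {data.shape[1]}")
    order = np.argsort(data[:, 0], kind="stable")
    return data[order, 1]


read_bias_tsv = read_two_column_tsv


def read_weights_tsv(path: str | Path, tag: str = "prior",
                     provenance: str = "uniform") -> WeightSet:
    values = read_two_column_tsv(path)
    return WeightSet.from_unnormalized(values, tag=tag, provenance=provenance)


def write_weights_tsv(weights: WeightSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# frame-id\tweight  (tag={weights.tag}, "
                 f"provenance={weights.provenance})\n")
        for j, w in enumerate(weights.weights):
            fh.write(f"{j}\t{float(w)!r}\n")
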