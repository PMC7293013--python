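import numpy as np
import pytest

from looprefine.ensemble_io import Conformation, Ensemble, WeightSet
from looprefine.structure_metrics import assign_states, ermsd_trajectory
from looprefine.synthetic_data import (make_synthetic_measurements,
                                       make_two_state_ensemble)


def make_conformation(atoms, res_names=None):
    """Build a Conformation from [(resid, atom_name, xyz), ...]."""
    res_names = res_names or {}
    resids = np.array([a[0] for a in atoms], dtype=int)
    return Conformation(
        atom_names=np.array([a[1] for a in atoms], dtype="U6"),
        res_names=np.array([res_names.get(a[0], "U") for a in atoms],
                           dtype="U4"),
        res_ids=resids,
        chain_ids=np.full(len(atoms), "A", dtype="U2"),
        coords=np.array([a[2] for a in atoms], dtype=float),
    )


def hexagon_residue(resid, center, res_name="U", normal=(0.0, 0.0, 1.0),
                    radius=1.39):
    """One pyrimidine-like residue: a regular six-membered ring (+ C1'/O4'
    so chi-style operations have anchors when needed)."""
    center = np.asarray(center, dtype=float)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    names = ("N1", "C2", "N3", "C4", "C5", "C6")
    atoms = []
    for k, name in enumerate(names):
        ang = np.radians(60.0 * k)
        atoms.append((resid, name,
                      center + radius * (np.cos(ang) * e1 + np.sin(ang) * e2)))
    return atoms


@pytest.fixture(scope="session")
def default_bundle():
    """One shared two-state ensemble at the generator defaults."""
    ensemble, truth = make_two_state_ensemble(n_frames=200, population_a=0.7,
                                              seed=42)
    return ensemble, truth


@pytest.fixture(scope="session")
def default_labels(default_bundle):
    ensemble, truth = default_bundle
    erms = ermsd_trajectory(ensemble, truth.template_a)
    return assign_states(erms)


@pytest.fixture(scope="session")
def noisy_measurements(default_bundle):
    ensemble, truth = default_bundle
    return make_synthetic_measurements(ensemble, truth, noise_scale=0.1,
                                       seed=123)


@pytest.fixture()
def toy_pdb(tmp_path):
    """A hand-written 2-model, 2-atom PDB file."""
    text = (
        "MODEL        1\n"
        "ATOM      1  C1'   U A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  N1    U A   1       1.400   0.000   0.000  1.00  0.00           N\n"
        "ENDMDL\n"
        "MODEL        2\n"
        "ATOM      1  C1'   U A   1       0.000   0.000   1.000  1.00  0.00           C\n"
        "ATOM      2  N1    U A   1       1.400   0.000   1.000  1.00  0.00           N\n"
        "ENDMDL\n"
        "END\n"
    )
    path = tmp_path / "toy.pdb"
    path.write_text(text)
    return path
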