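"""Base-centric structural geometry and state assignment.

Implements the nucleic-acid dissimilarity metric eRMSD, backbone/glycosidic
torsions, ring-centre distances, threshold state assignment, weighted
populations, weighted free-energy surfaces, and block standard errors.

eRMSD convention
----------------
Each nucleobase carries a local frame built from its six-membered ring:

* origin: unweighted centroid of the six ring atoms (N1 C2 N3 C4 C5 C6);
* orientation: from the C2/C4/C6 triangle -- x towards C2, the in-plane
  second axis towards C4 (pyrimidines) or C6 (purines), z normal to the
  base plane.  The purine/pyrimidine atom swap keeps the positive z side
  on the same base face for both families.

For every ordered base pair (i, j) the position of base j in the frame of
base i is anisotropically scaled by (5, 5, 3) Å, mapped to a smooth
four-vector G with cutoff ``|r~| = 2.4`` and ``gamma = pi/2.4``, and

    eRMSD(a, b) = sqrt( (1/N) * sum_pairs |G_a - G_b|^2 )

with N the number of bases.  The constants are module-level and surfaced
in config so the metric is pinned for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import Conformation, Ensemble, WeightSet
from .errors import StructureError, ValidationError

# eRMSD constants (original metric definition)
ERMSD_SCALE = np.array([5.0, 5.0, 3.0])   # Å, anisotropic scaling (x, y, z)
ERMSD_CUTOFF = 2.4                        # dimensionless, on |r~|
ERMSD_GAMMA = np.pi / ERMSD_CUTOFF

RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINES = frozenset({"A", "G", "RA", "RG", "ADE", "GUA"})
PYRIMIDINES = frozenset({"C", "U", "RC", "RU", "CYT", "URA"})

#: Default eRMSD threshold separating the ordered state A from state B.
STATE_THRESHOLD = 0.7

#: Backbone torsion quadruplets; offsets are relative residue indices.
TORSION_ATOMS = {
    "alpha":   ((-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'")),
    "beta":    ((0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'")),
    "gamma":   ((0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'")),
    "delta":   ((0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'")),
    "epsilon": ((0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P")),
    "zeta":    ((0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'")),
}
TORSION_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi")


@dataclass
class StateLabels:
    """Per-frame (or per-sample) A/B labels plus the threshold that made them."""

    labels: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.threshold < 0:
            raise ValidationError("threshold must be non-negative")
        bad = set(self.labels.tolist()) - {"A", "B"}
        if bad:
            raise ValidationError(f"labels must be 'A' or 'B', got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class FreeEnergySurface:
    """2-D free-energy grid in kB*T units, anchored so min over filled bins = 0."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray
    mask: np.ndarray  # True where the bin is empty

    def __post_init__(self) -> None:
        expected = (len(self.x_edges) - 1, len(self.y_edges) - 1)
        if self.values.shape != expected or self.mask.shape != expected:
            raise ValidationError("FES grid shape must match bin edges")


# ---------------------------------------------------------------------------
# Ring geometry and base frames
# ---------------------------------------------------------------------------

def ring_center(conformation: Conformation, residue: int) -> np.ndarray:
    """Unweighted centroid of a residue's six-membered-ring atoms (Å)."""
    pts = []
    for name in RING_ATOMS:
        try:
            pts.append(conformation.position(residue, name))
        except StructureError:
            raise StructureError(
                f"residue {residue}: missing ring atom {name}"
            ) from None
    return np.mean(pts, axis=0)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise StructureError("degenerate (zero-length) vector in base frame")
    return v / n


def base_frame(conformation: Conformation, residue: int):
    """Local frame of one nucleobase: (origin, rotation rows = x, y, z axes)."""
    res_name = conformation.residue_name(residue)
    origin = ring_center(conformation, residue)
    c2 = conformation.position(residue, "C2")
    c4 = conformation.position(residue, "C4")
    c6 = conformation.position(residue, "C6")
    second = c6 if res_name in PURINES else c4
    tri_center = (c2 + c4 + c6) / 3.0
    a = c2 - tri_center
    b = second - tri_center
    z = _unit(np.cross(a, b))
    x = _unit(a)
    y = np.cross(z, x)
    return origin, np.vstack([x, y, z])


def _gvectors(conformation: Conformation):
    """All-pairs (N, N, 4) G-vectors; diagonal entries are zero."""
    res_ids = conformation.residue_ids()
    n = len(res_ids)
    origins = np.empty((n, 3))
    rots = np.empty((n, 3, 3))
    for k, rid in enumerate(res_ids):
        origins[k], rots[k] = base_frame(conformation, int(rid))
    # r_ij: position of base j in the frame of base i, anisotropically scaled
    rel = origins[None, :, :] - origins[:, None, :]           # (i, j, 3)
    local = np.einsum("iab,ijb->ija", rots, rel)              # frame of i
    scaled = local / ERMSD_SCALE
    rho = np.linalg.norm(scaled, axis=-1)                     # (i, j)
    g = np.zeros((n, n, 4))
    np.fill_diagonal(rho, np.inf)                             # exclude i == j
    inside = rho < ERMSD_CUTOFF
    r = rho[inside]
    gr = ERMSD_GAMMA * r
    g[inside, :3] = np.sin(gr)[:, None] * scaled[inside] / r[:, None]
    g[inside, 3] = 1.0 + np.cos(gr)
    g /= ERMSD_GAMMA
    return g


def ermsd(conformation: Conformation, reference: Conformation) -> float:
    """eRMSD between two structures with the same base count and order.

    Non-negative, symmetric, zero on rigid copies.
    """
    n_a = len(conformation.residue_ids())
    n_b = len(reference.residue_ids())
    if n_a != n_b:
        raise StructureError(f"base-count mismatch: {n_a} vs {n_b}")
    dg = _gvectors(conformation) - _gvectors(reference)
    return float(np.sqrt(np.sum(dg ** 2) / n_a))


def ermsd_trajectory(ensemble: Ensemble, reference: Conformation) -> np.ndarray:
    """eRMSD of every frame to a reference structure."""
    g_ref = _gvectors(reference)
    n_res = len(reference.residue_ids())
    out = np.empty(ensemble.n_frames)
    for j in range(ensemble.n_frames):
        frame = ensemble.frame(j)
        if len(frame.residue_ids()) != n_res:
            raise StructureError("base-count mismatch with reference")
        dg = _gvectors(frame) - g_ref
        out[j] = np.sqrt(np.sum(dg ** 2) / n_res)
    return out


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float | np.ndarray:
    """Dihedral angle in degrees, IUPAC sign convention, in (-180, 180].

    Accepts single points or stacked ``(..., 3)`` arrays.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(n1, b1u)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
    return float(ang) if ang.ndim == 0 else ang


def chi_quadruplet(res_name: str):
    """Glycosidic torsion atoms: O4'-C1'-N9-C4 (purines), O4'-C1'-N1-C2 (pyrimidines)."""
    if res_name in PURINES:
        return ((0, "O4'"), (0, "C1'"), (0, "N9"), (0, "C4"))
    return ((0, "O4'"), (0, "C1'"), (0, "N1"), (0, "C2"))


def torsion_quadruplet_atoms(conformation: Conformation, residue: int,
                             torsion: str):
    """Resolve a named torsion's four (resid, atom) selectors, or None if undefined."""
    if torsion == "chi":
        spec = chi_quadruplet(conformation.residue_name(residue))
    else:
        try:
            spec = TORSION_ATOMS[torsion]
        except KeyError:
            raise ValidationError(f"unknown torsion {torsion!r}") from None
    res_ids = set(int(r) for r in conformation.residue_ids())
    quad = []
    for offset, aname in spec:
        rid = residue + offset
        if rid not in res_ids or (rid, aname) not in conformation.atom_index:
            return None
        quad.append((rid, aname))
    return tuple(quad)


def torsion_value(conformation: Conformation, residue: int, torsion: str):
    """One named torsion in degrees, or NaN where atoms are missing."""
    quad = torsion_quadruplet_atoms(conformation, residue, torsion)
    if quad is None:
        return float("nan")
    pts = [conformation.position(r, a) for r, a in quad]
    return dihedral(*pts)


def backbone_torsions(conformation: Conformation):
    """Per-residue alpha..zeta and chi in degrees as a pandas DataFrame.

    Terminal residues yield NaN for torsions whose atoms fall off the chain;
    missing atoms give NaN entries, never an error.
    """
    import pandas as pd

    res_ids = [int(r) for r in conformation.residue_ids()]
    data = {
        name: [torsion_value(conformation, rid, name) for rid in res_ids]
        for name in TORSION_NAMES
    }
    return pd.DataFrame(data, index=pd.Index(res_ids, name="resid"))


def torsion_matrix(ensemble: Ensemble, torsions=None) -> tuple:
    """Vectorized per-frame torsions for a whole ensemble.

    Returns ``(names, values)`` where ``values`` is (n_frames, n_torsions)
    in degrees; torsions undefined anywhere are omitted.  ``torsions`` is an
    optional list of (residue, torsion_name) pairs; default: all defined.
    """
    frame0 = ensemble.frame(0)
    res_ids = [int(r) for r in frame0.residue_ids()]
    if torsions is None:
        torsions = [(rid, t) for rid in res_ids for t in TORSION_NAMES]
    names, quads = [], []
    for rid, tname in torsions:
        quad = torsion_quadruplet_atoms(frame0, rid, tname)
        if quad is None:
            continue
        names.append(f"{tname}_{rid}")
        quads.append([ensemble.atom_index[sel] for sel in quad])
    if not names:
        return [], np.empty((ensemble.n_frames, 0))
    qidx = np.asarray(quads)                                  # (q, 4)
    pts = ensemble.coords[:, qidx, :]                         # (f, q, 4, 3)
    values = dihedral(pts[..., 0, :], pts[..., 1, :], pts[..., 2, :],
                      pts[..., 3, :])
    return names, np.atleast_2d(values)


# ---------------------------------------------------------------------------
# States, populations, surfaces, errors
# ---------------------------------------------------------------------------

def assign_states(ermsd_values, threshold: float = STATE_THRESHOLD) -> StateLabels:
    """Label samples A where eRMSD-to-reference < threshold, else B."""
    values = np.asarray(ermsd_values, dtype=float)
    if np.any(values < 0):
        raise ValidationError("eRMSD values must be non-negative")
    labels = np.where(values < threshold, "A", "B")
    return StateLabels(labels, threshold)


def population(labels: StateLabels, weights: WeightSet, state: str = "A") -> float:
    """Total weight of frames carrying ``state``; pop(A) + pop(B) = 1."""
    if len(labels) != len(weights):
        raise ValidationError("label/weight length mismatch")
    return float(weights.weights[labels.labels == state].sum())


def weighted_fes_2d(x, y, weights: WeightSet, bins=30) -> FreeEnergySurface:
    """Weighted 2-D free-energy surface, ``F = -ln p`` in kB*T units.

    Empty bins are masked; the global minimum over filled bins is anchored
    at zero (absolute free energies are undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) != len(weights):
        raise ValidationError("x, y and weights must have equal length")
    hist, xe, ye = np.histogram2d(x, y, bins=bins, weights=weights.weights)
    if hist.sum() <= 0:
        raise ValidationError("all points fall outside the grid")
    mask = hist <= 0
    values = np.full_like(hist, np.nan)
    values[~mask] = -np.log(hist[~mask])
    values[~mask] -= np.nanmin(values[~mask])
    return FreeEnergySurface(xe, ye, values, mask)


def block_standard_error(per_frame_quantity, weights: WeightSet,
                         n_blocks: int = 4, statistic=None) -> float:
    """Block standard error of a weighted statistic over contiguous blocks.

    Frames are split into ``n_blocks`` contiguous (time-ordered) blocks of
    equal size, remainder to the last block.  The statistic (default:
    weighted mean) is recomputed per block with renormalized block weights;
    SE = sample std across blocks / sqrt(n_blocks).
    """
    q = np.asarray(per_frame_quantity, dtype=float)
    w = weights.weights
    if len(q) != len(w):
        raise ValidationError("quantity/weight length mismatch")
    if len(q) < n_blocks:
        raise ValidationError("need at least n_blocks frames")
    if statistic is None:
        statistic = lambda values, wts: float(values @ wts)
    base = len(q) // n_blocks
    stats = []
    for b in range(n_blocks):
        lo = b * base
        hi = (b + 1) * base if b < n_blocks - 1 else len(q)
        wb = w[lo:hi]
        total = wb.sum()
        if total <= 0:
            raise ValidationError(f"block {b} has zero total weight")
        stats.append(statistic(q[lo:hi], wb / total))
    return float(np.std(stats, ddof=1) / np.sqrt(n_blocks))
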