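"""Independent reference implementations used as test oracles.

These re-derive quantities step by step with plain Python floats and
explicit geometry, deliberately not sharing code paths with the package.
"""

import math

import numpy as np
from scipy.special import logsumexp


# ---------------------------------------------------------------------------
# dihedral angle via an explicit plane-projection construction
# ---------------------------------------------------------------------------

def dihedral_reference(p0, p1, p2, p3):
    """Signed dihedral in degrees: angle between p0 and p3 projected onto
    the plane perpendicular to the central bond, measured right-handedly."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    axis = p2 - p1
    axis = axis / np.linalg.norm(axis)
    v0 = p0 - p1
    v3 = p3 - p2
    # remove components along the axis
    v0p = v0 - (v0 @ axis) * axis
    v3p = v3 - (v3 @ axis) * axis
    cosang = (v0p @ v3p) / (np.linalg.norm(v0p) * np.linalg.norm(v3p))
    cosang = min(1.0, max(-1.0, float(cosang)))
    ang = math.degrees(math.acos(cosang))
    # sign: positive if v3p is counterclockwise from v0p looking down axis
    if float(np.cross(v0p, v3p) @ axis) < 0:
        ang = -ang
    # the IUPAC convention measures from the *front* atom: flip sign
    ang = -ang
    if ang <= -180.0:
        ang += 360.0
    return ang


# ---------------------------------------------------------------------------
# eRMSD re-derivation, scalar loops
# ---------------------------------------------------------------------------

_SCALE = (5.0, 5.0, 3.0)
_CUT = 2.4
_GAMMA = math.pi / _CUT
_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
_PURINES = {"A", "G"}


def _base_frame_reference(conf, resid):
    ring_pts = [conf.position(resid, name) for name in _RING]
    origin = [sum(p[k] for p in ring_pts) / 6.0 for k in range(3)]
    c2 = conf.position(resid, "C2")
    c4 = conf.position(resid, "C4")
    c6 = conf.position(resid, "C6")
    second = c6 if conf.residue_name(resid) in _PURINES else c4
    centroid = [(c2[k] + c4[k] + c6[k]) / 3.0 for k in range(3)]
    a = [c2[k] - centroid[k] for k in range(3)]
    b = [second[k] - centroid[k] for k in range(3)]
    z = [a[1] * b[2] - a[2] * b[1],
         a[2] * b[0] - a[0] * b[2],
         a[0] * b[1] - a[1] * b[0]]
    na = math.sqrt(sum(x * x for x in a))
    nz = math.sqrt(sum(x * x for x in z))
    x_ax = [x / na for x in a]
    z_ax = [x / nz for x in z]
    y_ax = [z_ax[1] * x_ax[2] - z_ax[2] * x_ax[1],
            z_ax[2] * x_ax[0] - z_ax[0] * x_ax[2],
            z_ax[0] * x_ax[1] - z_ax[1] * x_ax[0]]
    return origin, (x_ax, y_ax, z_ax)


def _gvec_reference(conf, i, j):
    oi, (xi, yi, zi) = _base_frame_reference(conf, i)
    oj, _ = _base_frame_reference(conf, j)
    rel = [oj[k] - oi[k] for k in range(3)]
    local = [sum(ax[k] * rel[k] for k in range(3)) for ax in (xi, yi, zi)]
    scaled = [local[k] / _SCALE[k] for k in range(3)]
    rho = math.sqrt(sum(x * x for x in scaled))
    if rho >= _CUT or rho == 0.0:
        return [0.0, 0.0, 0.0, 0.0]
    s = math.sin(_GAMMA * rho)
    return [s * scaled[0] / rho / _GAMMA,
            s * scaled[1] / rho / _GAMMA,
            s * scaled[2] / rho / _GAMMA,
            (1.0 + math.cos(_GAMMA * rho)) / _GAMMA]


def ermsd_reference(conf_a, conf_b):
    resids = [int(r) for r in conf_a.residue_ids()]
    total = 0.0
    for i in resids:
        for j in resids:
            if i == j:
                continue
            ga = _gvec_reference(conf_a, i, j)
            gb = _gvec_reference(conf_b, i, j)
            total += sum((ga[k] - gb[k]) ** 2 for k in range(4))
    return math.sqrt(total / len(resids))


# ---------------------------------------------------------------------------
# BME dual objective evaluated on a dense lambda grid
# ---------------------------------------------------------------------------

def gamma_on_grid(grid, matrix, w0, f_exp, sigma, theta):
    """Vectorized Gamma over a (G, m) grid of lambda vectors."""
    grid = np.atleast_2d(grid)
    expo = -grid @ matrix
    logz = logsumexp(expo, axis=1, b=w0)
    reg = 0.5 * theta * np.sum(grid ** 2 * sigma ** 2, axis=1)
    return logz + grid @ f_exp + reg


def brute_force_weights(matrix, w0, f_exp, sigma, theta, bound=15.0,
                        points_1d=12001, points_2d=601):
    """Grid-search the dual problem and return the implied weights."""
    m = matrix.shape[0]
    if m == 1:
        grid = np.linspace(-bound, bound, points_1d)[:, None]
    elif m == 2:
        g = np.linspace(-bound, bound, points_2d)
        grid = np.stack(np.meshgrid(g, g), -1).reshape(-1, 2)
    else:
        raise ValueError("oracle supports m <= 2")
    vals = gamma_on_grid(grid, matrix, w0, f_exp, sigma, theta)
    lam = grid[np.argmin(vals)]
    logw = np.log(w0) - lam @ matrix
    logw -= logsumexp(logw)
    return np.exp(logw), lam, float(vals.min())
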