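"""Internal-coordinate chain geometry.

Chains are parameterized purely by torsion angles: bond lengths and bond
angles are held constant, so Cartesian coordinates are a deterministic
function of the torsional state.  The builder uses the standard natural
extension reference frame (NeRF) construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from foldswitch.sequences import (
    AROMATIC_PIPI,
    SIDECHAIN_CENTROID_DIST,
    validate_sequence,
)

# Fixed backbone internal coordinates (Angstrom, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0


try:  # numba accelerates the inherently sequential NeRF loop ~100x
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a soft dependency
    def _njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@_njit(cache=True)
def _nerf(ax, ay, az, bx, by, bz, cx, cy, cz, bond, angle, torsion):
    bcx, bcy, bcz = cx - bx, cy - by, cz - bz
    nb = (bcx * bcx + bcy * bcy + bcz * bcz) ** 0.5
    bcx, bcy, bcz = bcx / nb, bcy / nb, bcz / nb
    abx, aby, abz = bx - ax, by - ay, bz - az
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = (nx * nx + ny * ny + nz * nz) ** 0.5
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * np.cos(angle)
    d1 = bond * np.sin(angle) * np.cos(torsion)
    d2 = bond * np.sin(angle) * np.sin(torsion)
    return (cx + d0 * bcx + d1 * mx + d2 * nx,
            cy + d0 * bcy + d1 * my + d2 * ny,
            cz + d0 * bcz + d1 * mz + d2 * nz)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position a new atom D given A-B-C, |CD|, angle(B,C,D) and torsion(A,B,C,D)."""
    ab = b - a
    bc = c - b
    if np.linalg.norm(np.cross(ab, bc)) < 1e-10:
        raise ValueError("collinear reference atoms in NeRF placement")
    x, y, z = _nerf(a[0], a[1], a[2], b[0], b[1], b[2], c[0], c[1], c[2],
                    bond, np.deg2rad(angle_deg), np.deg2rad(torsion_deg))
    return np.array([x, y, z])


@_njit(cache=True)
def _build_arrays(phi, psi, chi, is_gly, d_sc,
                  bond_n_ca, bond_ca_c, bond_c_n, bond_c_o, bond_ca_cb,
                  ang_n_ca_c, ang_ca_c_n, ang_c_n_ca, ang_ca_c_o, omega):
    L = phi.shape[0]
    n = np.empty((L, 3))
    ca = np.empty((L, 3))
    c = np.empty((L, 3))
    o = np.empty((L, 3))
    cb = np.empty((L, 3))
    sc = np.empty((L, 3))

    n[0, 0], n[0, 1], n[0, 2] = 0.0, 0.0, 0.0
    ca[0, 0], ca[0, 1], ca[0, 2] = bond_n_ca, 0.0, 0.0
    # virtual previous carbonyl so that phi[0] is well defined
    vx = np.cos(np.deg2rad(122.0)) * bond_c_n
    vy = -np.sin(np.deg2rad(122.0)) * bond_c_n
    c[0, 0], c[0, 1], c[0, 2] = _nerf(vx, vy, 0.0, 0.0, 0.0, 0.0,
                                      bond_n_ca, 0.0, 0.0,
                                      bond_ca_c, ang_n_ca_c, phi[0])
    for i in range(1, L):
        n[i, 0], n[i, 1], n[i, 2] = _nerf(
            n[i - 1, 0], n[i - 1, 1], n[i - 1, 2],
            ca[i - 1, 0], ca[i - 1, 1], ca[i - 1, 2],
            c[i - 1, 0], c[i - 1, 1], c[i - 1, 2],
            bond_c_n, ang_ca_c_n, psi[i - 1])
        ca[i, 0], ca[i, 1], ca[i, 2] = _nerf(
            ca[i - 1, 0], ca[i - 1, 1], ca[i - 1, 2],
            c[i - 1, 0], c[i - 1, 1], c[i - 1, 2],
            n[i, 0], n[i, 1], n[i, 2],
            bond_n_ca, ang_c_n_ca, omega)
        c[i, 0], c[i, 1], c[i, 2] = _nerf(
            c[i - 1, 0], c[i - 1, 1], c[i - 1, 2],
            n[i, 0], n[i, 1], n[i, 2],
            ca[i, 0], ca[i, 1], ca[i, 2],
            bond_ca_c, ang_n_ca_c, phi[i])
    for i in range(L):
        o[i, 0], o[i, 1], o[i, 2] = _nerf(
            n[i, 0], n[i, 1], n[i, 2],
            ca[i, 0], ca[i, 1], ca[i, 2],
            c[i, 0], c[i, 1], c[i, 2],
            bond_c_o, ang_ca_c_o, psi[i] - np.deg2rad(180.0))
        if is_gly[i]:
            cb[i] = ca[i]
            sc[i] = ca[i]
            continue
        cb[i, 0], cb[i, 1], cb[i, 2] = _nerf(
            n[i, 0], n[i, 1], n[i, 2],
            c[i, 0], c[i, 1], c[i, 2],
            ca[i, 0], ca[i, 1], ca[i, 2],
            bond_ca_cb, np.deg2rad(110.6), np.deg2rad(-122.6))
        if d_sc[i] <= 0.0:
            sc[i] = cb[i]
        else:
            sc[i, 0], sc[i, 1], sc[i, 2] = _nerf(
                n[i, 0], n[i, 1], n[i, 2],
                ca[i, 0], ca[i, 1], ca[i, 2],
                cb[i, 0], cb[i, 1], cb[i, 2],
                d_sc[i], np.deg2rad(114.0), chi[i])
    return n, ca, c, o, cb, sc


@dataclass
class ChainCoords:
    """Cartesian coordinates of the reduced chain representation.

    Arrays are (L, 3): backbone N, CA, C, carbonyl O, C-beta and a single
    sidechain heavy-atom centroid SC per residue.  For Gly CB and SC fall
    back to CA; for Ala SC falls back to CB.  ``ring_normal`` is a unit
    pseudo-normal for aromatic sidechains (NaN elsewhere), used by the
    orientation-dependent pi-pi hook.
    """

    sequence: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    cb: np.ndarray
    sc: np.ndarray
    ring_normal: np.ndarray

    def __len__(self) -> int:
        return len(self.sequence)


def build_chain(sequence: str, phi: np.ndarray, psi: np.ndarray,
                chi: np.ndarray | None = None) -> ChainCoords:
    """Build Cartesian coordinates from backbone (phi, psi) and sidechain chi.

    Angles in degrees.  phi[0] and psi[-1] affect only terminal placement
    conventions; the proline phi, if any, should already be frozen by the
    caller (the builder uses whatever values are passed).
    """
    seq = validate_sequence(sequence)
    L = len(seq)
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != (L,) or psi.shape != (L,):
        raise ValueError("phi/psi length mismatch with sequence")
    chi = np.zeros(L) if chi is None else np.asarray(chi, dtype=float)

    is_gly = np.array([aa == "G" for aa in seq])
    d_sc = np.array([SIDECHAIN_CENTROID_DIST[aa] for aa in seq])
    n, ca, c, o, cb, sc = _build_arrays(
        np.deg2rad(phi), np.deg2rad(psi), np.deg2rad(chi), is_gly, d_sc,
        BOND_N_CA, BOND_CA_C, BOND_C_N, BOND_C_O, BOND_CA_CB,
        np.deg2rad(ANGLE_N_CA_C), np.deg2rad(ANGLE_CA_C_N),
        np.deg2rad(ANGLE_C_N_CA), np.deg2rad(ANGLE_CA_C_O),
        np.deg2rad(OMEGA))

    ring_normal = np.full((L, 3), np.nan)
    aromatic = [i for i, aa in enumerate(seq) if aa in AROMATIC_PIPI]
    if aromatic:
        idx = np.array(aromatic)
        v1 = cb[idx] - ca[idx]
        v2 = sc[idx] - cb[idx]
        nrm = np.cross(v1, v2)
        norm = np.linalg.norm(nrm, axis=1, keepdims=True)
        # a chi aligning the frame degenerates the cross product; fall back
        bad = norm[:, 0] < 1e-9
        if bad.any():
            alt = np.cross(v1[bad], np.array([1.0, 0.0, 0.0]))
            nrm[bad] = alt
            norm[bad] = np.linalg.norm(alt, axis=1, keepdims=True)
        ring_normal[idx] = nrm / norm
    return ChainCoords(seq, n, ca, c, o, cb, sc, ring_normal)


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Torsion angle A-B-C-D in degrees, in (-180, 180]."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.degrees(np.arctan2(y, x)))


def _dihedral_rows(a, b, c, d) -> np.ndarray:
    """Row-wise torsion angles (degrees) for stacked (N, 3) quadruples."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def backbone_torsions(coords: "ChainCoords") -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) arrays recomputed from backbone Cartesian coordinates.

    Terminal phi[0] and psi[-1] use the builder's virtual-atom convention
    and are returned as NaN.
    """
    L = len(coords)
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    if L > 1:
        phi[1:] = _dihedral_rows(coords.c[:-1], coords.n[1:], coords.ca[1:], coords.c[1:])
        psi[:-1] = _dihedral_rows(coords.n[:-1], coords.ca[:-1], coords.c[:-1], coords.n[1:])
    return phi, psi


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares superposition of ``mobile`` onto ``target`` (Kabsch).

    Returns (rotation, translation, transformed_mobile) such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to target.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (N, 3)")
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (mobile - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    trans = mu_t - rot @ mu_m
    moved = mobile @ rot.T + trans
    return rot, trans, moved


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without superposition."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets over rigid motions."""
    _, _, moved = kabsch(a, b)
    return rmsd(moved, b)
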