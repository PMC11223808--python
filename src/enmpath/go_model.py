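"""CA-only structure-based (Go-like) potential for proteins.

The Tirion network knows nothing about stereochemistry, so large
transitions can deform virtual bonds and angles badly.  The Go-like
alternative anchors the chain geometry with bonded terms and replaces
generic springs by native-contact attraction:

    E = sum_bonds   K_b (r - r0)^2
      + sum_angles  K_a (theta - theta0)^2
      + sum_diheds  K_d1 [1 - cos(phi - phi0)] + K_d3 [1 - cos 3(phi - phi0)]
      + sum_contacts eps [5 (sigma/r)^12 - 6 (sigma/r)^10]

with the native structure as the exact minimum.  Constants follow the
classic CA Go parametrization (K_b = 100 eps/A^2, K_a = 20 eps/rad^2,
K_d1 = eps, K_d3 = eps/2, eps = 1 kcal/mol), so the model runs without
user parameters.  Only CA atoms of protein chains are supported.

At the native state every term's first derivative vanishes, so the
Hessian reduces to a sum of positively weighted outer products of the
internal-coordinate gradients (Gauss-Newton form), which is exactly
positive semidefinite with the rigid-body kernel — the same operator
contract the Tirion Hessian provides, so either plugs into the path
solver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .elastic_network import HessianOperator
from .errors import SingularGeometryError, SizeMismatchError, UnsupportedInputError
from .structure_io import Structure, residue_polymer_type

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 1.0          # kcal/mol
DEFAULT_K_BOND = 100.0         # eps / A^2
DEFAULT_K_ANGLE = 20.0         # eps / rad^2
DEFAULT_K_DIH1 = 1.0           # eps
DEFAULT_K_DIH3 = 0.5           # eps
DEFAULT_CONTACT_CUTOFF = 8.0   # A
MIN_CONTACT_SEPARATION = 4     # |i - j| within a chain


@dataclass
class GoTopology:
    """Native-structure topology: bonded terms plus native contacts."""

    ref_coords: np.ndarray                 # (N, 3)
    bonds: np.ndarray                      # (nb, 2) atom indices
    bond_r0: np.ndarray
    angles: np.ndarray                     # (na, 3)
    angle_theta0: np.ndarray
    dihedrals: np.ndarray                  # (nd, 4)
    dihedral_phi0: np.ndarray
    contacts: np.ndarray                   # (nc, 2)
    contact_sigma: np.ndarray
    epsilon: float = DEFAULT_EPSILON
    k_bond: float = field(default=DEFAULT_K_BOND)
    k_angle: float = field(default=DEFAULT_K_ANGLE)
    k_dih1: float = field(default=DEFAULT_K_DIH1)
    k_dih3: float = field(default=DEFAULT_K_DIH3)

    @property
    def n_atoms(self) -> int:
        return len(self.ref_coords)

    def dump(self) -> str:
        """TSV sections (bonds/angles/dihedrals/contacts) for inspection."""
        parts = ["[bonds]\ni\tj\tr0"]
        parts += [f"{i}\t{j}\t{r:.4f}" for (i, j), r in zip(self.bonds, self.bond_r0)]
        parts.append("[angles]\ni\tj\tk\ttheta0_deg")
        parts += [f"{i}\t{j}\t{k}\t{np.degrees(t):.3f}"
                  for (i, j, k), t in zip(self.angles, self.angle_theta0)]
        parts.append("[dihedrals]\ni\tj\tk\tl\tphi0_deg")
        parts += [f"{i}\t{j}\t{k}\t{l}\t{np.degrees(p):.3f}"
                  for (i, j, k, l), p in zip(self.dihedrals, self.dihedral_phi0)]
        parts.append("[contacts]\ni\tj\tsigma")
        parts += [f"{i}\t{j}\t{s:.4f}"
                  for (i, j), s in zip(self.contacts, self.contact_sigma)]
        return "\n".join(parts) + "\n"


# ---------------------------------------------------------------------------
# internal-coordinate values and gradients
# ---------------------------------------------------------------------------

def _angle(a, b, c):
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        raise SingularGeometryError("zero-length bond in angle term")
    cosv = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.arccos(cosv))


def _angle_grad(a, b, c):
    """Gradient of the a-b-c angle wrt the three atom positions."""
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    cosv = np.clip(np.dot(uh, vh), -1.0, 1.0)
    sinv = np.sqrt(max(1.0 - cosv * cosv, 1e-14))
    ga = (cosv * uh - vh) / (nu * sinv)
    gc = (cosv * vh - uh) / (nv * sinv)
    return ga, -(ga + gc), gc


def _dihedral(p0, p1, p2, p3):
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-10:
        raise SingularGeometryError("zero-length central bond in dihedral")
    return float(np.arctan2(np.dot(np.cross(n1, n2), b2 / nb2),
                            np.dot(n1, n2)))


def _dihedral_grad(p0, p1, p2, p3):
    """Gradient of the dihedral angle wrt the four atom positions."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    n1sq, n2sq = np.dot(n1, n1), np.dot(n2, n2)
    if n1sq < 1e-14 or n2sq < 1e-14 or nb2 < 1e-10:
        raise SingularGeometryError("collinear atoms in dihedral term")
    g0 = -nb2 / n1sq * n1
    g3 = nb2 / n2sq * n2
    c12 = np.dot(b1, b2) / (nb2 * nb2)
    c32 = np.dot(b3, b2) / (nb2 * nb2)
    g1 = -(1.0 + c12) * g0 + c32 * g3
    g2 = c12 * g0 - (1.0 + c32) * g3
    return g0, g1, g2, g3


# ---------------------------------------------------------------------------
# topology construction
# ---------------------------------------------------------------------------

def build_go_topology(ref: Structure,
                      contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
                      epsilon: float = DEFAULT_EPSILON) -> GoTopology:
    """Bonded terms from chain connectivity, contacts from the native fold.

    Requires a one-bead-per-residue protein structure (CA atoms only).
    Bonds link residues consecutive in numbering within one chain; no
    bonded term spans a chain break.  Native contacts are CA pairs within
    ``contact_cutoff`` separated by at least 4 residues along a chain
    (inter-chain pairs always qualify).
    """
    for atom in ref.atoms:
        if residue_polymer_type(atom.residue_name) != "protein":
            raise UnsupportedInputError(
                f"the Go model supports proteins only; found residue "
                f"{atom.residue_name} in chain {atom.chain_id}")
        if atom.atom_name != "CA":
            raise UnsupportedInputError(
                f"the Go model needs a CA-only structure; found atom "
                f"{atom.atom_name} (coarse-grain first)")
    xyz = ref.coords()
    chains = [a.chain_id for a in ref.atoms]
    seqs = [a.residue_seq for a in ref.atoms]

    bonds, angles, dihedrals = [], [], []

    def consecutive(i, j):
        return chains[i] == chains[j] and seqs[j] - seqs[i] == 1

    n = len(xyz)
    for i in range(n - 1):
        if consecutive(i, i + 1):
            bonds.append((i, i + 1))
    for i in range(n - 2):
        if consecutive(i, i + 1) and consecutive(i + 1, i + 2):
            angles.append((i, i + 1, i + 2))
    for i in range(n - 3):
        if (consecutive(i, i + 1) and consecutive(i + 1, i + 2)
                and consecutive(i + 2, i + 3)):
            dihedrals.append((i, i + 1, i + 2, i + 3))

    tree = cKDTree(xyz)
    contacts = []
    for i, j in tree.query_pairs(contact_cutoff, output_type="ndarray"):
        i, j = int(min(i, j)), int(max(i, j))
        if chains[i] == chains[j] and abs(seqs[j] - seqs[i]) < MIN_CONTACT_SEPARATION:
            continue
        contacts.append((i, j))
    contacts = np.array(sorted(contacts), dtype=int).reshape(-1, 2)

    bonds = np.array(bonds, dtype=int).reshape(-1, 2)
    angles = np.array(angles, dtype=int).reshape(-1, 3)
    dihedrals = np.array(dihedrals, dtype=int).reshape(-1, 4)

    bond_r0 = np.array([np.linalg.norm(xyz[i] - xyz[j]) for i, j in bonds])
    angle_theta0 = np.array([_angle(xyz[i], xyz[j], xyz[k])
                             for i, j, k in angles])
    dihedral_phi0 = np.array([_dihedral(xyz[i], xyz[j], xyz[k], xyz[l])
                              for i, j, k, l in dihedrals])
    contact_sigma = np.array([np.linalg.norm(xyz[i] - xyz[j])
                              for i, j in contacts])
    return GoTopology(ref_coords=xyz, bonds=bonds, bond_r0=bond_r0,
                      angles=angles, angle_theta0=angle_theta0,
                      dihedrals=dihedrals, dihedral_phi0=dihedral_phi0,
                      contacts=contacts, contact_sigma=contact_sigma,
                      epsilon=epsilon)


# ---------------------------------------------------------------------------
# energy / gradient / Hessian
# ---------------------------------------------------------------------------

def go_energy(top: GoTopology, X: np.ndarray) -> float:
    """Total Go energy at coordinates X (kcal/mol)."""
    xyz = np.asarray(X, dtype=float).reshape(-1, 3)
    if len(xyz) != top.n_atoms:
        raise SizeMismatchError(
            f"coordinates have {len(xyz)} atoms, topology has {top.n_atoms}")
    e = 0.0
    eps = top.epsilon
    for (i, j), r0 in zip(top.bonds, top.bond_r0):
        r = np.linalg.norm(xyz[i] - xyz[j])
        e += top.k_bond * eps * (r - r0) ** 2
    for (i, j, k), t0 in zip(top.angles, top.angle_theta0):
        e += top.k_angle * eps * (_angle(xyz[i], xyz[j], xyz[k]) - t0) ** 2
    for (i, j, k, l), p0 in zip(top.dihedrals, top.dihedral_phi0):
        dphi = _dihedral(xyz[i], xyz[j], xyz[k], xyz[l]) - p0
        e += top.k_dih1 * eps * (1.0 - np.cos(dphi))
        e += top.k_dih3 * eps * (1.0 - np.cos(3.0 * dphi))
    for (i, j), sig in zip(top.contacts, top.contact_sigma):
        r = np.linalg.norm(xyz[i] - xyz[j])
        if r < 1e-10:
            raise SingularGeometryError(f"atoms {i},{j} coincide in contact term")
        sr = sig / r
        e += eps * (5.0 * sr ** 12 - 6.0 * sr ** 10)
    return float(e)


def go_gradient(top: GoTopology, X: np.ndarray) -> np.ndarray:
    """Analytic gradient of the Go energy, flattened to 3N."""
    xyz = np.asarray(X, dtype=float).reshape(-1, 3)
    grad = np.zeros_like(xyz)
    eps = top.epsilon
    for (i, j), r0 in zip(top.bonds, top.bond_r0):
        d = xyz[i] - xyz[j]
        r = np.linalg.norm(d)
        c = 2.0 * top.k_bond * eps * (r - r0) / r
        grad[i] += c * d
        grad[j] -= c * d
    for (i, j, k), t0 in zip(top.angles, top.angle_theta0):
        th = _angle(xyz[i], xyz[j], xyz[k])
        gi, gj, gk = _angle_grad(xyz[i], xyz[j], xyz[k])
        c = 2.0 * top.k_angle * eps * (th - t0)
        grad[i] += c * gi
        grad[j] += c * gj
        grad[k] += c * gk
    for (i, j, k, l), p0 in zip(top.dihedrals, top.dihedral_phi0):
        dphi = _dihedral(xyz[i], xyz[j], xyz[k], xyz[l]) - p0
        c = (top.k_dih1 * eps * np.sin(dphi)
             + 3.0 * top.k_dih3 * eps * np.sin(3.0 * dphi))
        for idx, g in zip((i, j, k, l),
                          _dihedral_grad(xyz[i], xyz[j], xyz[k], xyz[l])):
            grad[idx] += c * g
    for (i, j), sig in zip(top.contacts, top.contact_sigma):
        d = xyz[i] - xyz[j]
        r = np.linalg.norm(d)
        sr = sig / r
        dV = eps * (-60.0 * sr ** 12 + 60.0 * sr ** 10) / r
        c = dV / r
        grad[i] += c * d
        grad[j] -= c * d
    return grad.ravel()


def go_hessian(top: GoTopology) -> HessianOperator:
    """Gauss-Newton Hessian of the Go energy at the native reference.

    Every term is at its minimum there, so second derivatives of the
    internal coordinates drop out and each term contributes
    coeff * g g^T with g the internal-coordinate gradient:
    2 K_b (bonds), 2 K_a (angles), K_d1 + 9 K_d3 (dihedrals) and
    120 eps / sigma^2 (native contacts at r = sigma).
    """
    xyz = top.ref_coords
    n3 = 3 * top.n_atoms
    rows, cols, vals = [], [], []

    def add_outer(atom_indices, grads, coeff):
        flat_idx = np.concatenate([[3 * a, 3 * a + 1, 3 * a + 2]
                                   for a in atom_indices])
        g = np.concatenate(grads)
        block = coeff * np.outer(g, g)
        for p, ip in enumerate(flat_idx):
            for q, iq in enumerate(flat_idx):
                rows.append(ip)
                cols.append(iq)
                vals.append(block[p, q])

    eps = top.epsilon
    for (i, j), r0 in zip(top.bonds, top.bond_r0):
        u = (xyz[i] - xyz[j]) / r0
        add_outer((i, j), (u, -u), 2.0 * top.k_bond * eps)
    for (i, j, k), _t0 in zip(top.angles, top.angle_theta0):
        add_outer((i, j, k), _angle_grad(xyz[i], xyz[j], xyz[k]),
                  2.0 * top.k_angle * eps)
    coeff_dih = (top.k_dih1 + 9.0 * top.k_dih3) * eps
    for (i, j, k, l), _p0 in zip(top.dihedrals, top.dihedral_phi0):
        add_outer((i, j, k, l),
                  _dihedral_grad(xyz[i], xyz[j], xyz[k], xyz[l]), coeff_dih)
    for (i, j), sig in zip(top.contacts, top.contact_sigma):
        u = (xyz[i] - xyz[j]) / sig
        add_outer((i, j), (u, -u), 120.0 * eps / sig ** 2)

    H = sp.coo_matrix((vals, (rows, cols)), shape=(n3, n3))
    return HessianOperator(H.tocsr())
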