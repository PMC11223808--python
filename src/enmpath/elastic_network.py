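"""Elastic-network construction and the Tirion energy/gradient/Hessian.

A network is a set of springs over a reference conformation.  Two
geometries are supported: a distance cutoff (every pair closer than
``R_c`` is bonded) and the parameter-free 1-skeleton of the 3-D Delaunay
tetrahedralization, which copes well with loosely connected or dangling
parts.  The energy is the isotropic Tirion form

    V(X) = 1/2 k sum_(i,j) (r_ij - r0_ij)^2

with a single force constant per network.  At the reference state every
spring is at rest, which collapses each edge's Hessian contribution to
the rank-1 block k * u u^T along the unit edge vector; the assembled
Hessian is therefore exactly positive semidefinite with the six
rigid-body motions in its kernel.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, cKDTree

from .errors import (DegenerateGeometryError, IsolatedAtomError,
                     SingularGeometryError, SizeMismatchError)

logger = logging.getLogger(__name__)

#: spring constant expected from the B-factor calibration, kcal/mol/A^2
K_EXPECTED_RANGE = (0.16 - 0.09, 0.16 + 0.09)

#: dense Hessian materialization allowed up to this many coordinates (3N)
DENSE_LIMIT = 3000


class ElasticNetwork:
    """Springs over a reference conformation with one force constant.

    Parameters
    ----------
    ref_coords:
        (N, 3) reference coordinates, Angstrom.
    edges:
        integer array (n_edges, 2) with i < j, no duplicates.
    k:
        isotropic spring constant, kcal/mol/A^2.
    geometry_mode:
        "cutoff" or "delaunay" (bookkeeping only).
    cutoff:
        the cutoff radius for cutoff mode, None otherwise.
    """

    def __init__(self, ref_coords: np.ndarray, edges: np.ndarray, k: float,
                 geometry_mode: str, cutoff: float | None = None):
        self.ref_coords = np.asarray(ref_coords, dtype=float).reshape(-1, 3)
        edges = np.asarray(edges, dtype=int).reshape(-1, 2)
        edges = np.sort(edges, axis=1)
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        self.edges = edges[order]
        self.k = float(k)
        self.geometry_mode = geometry_mode
        self.cutoff = cutoff
        d = self.ref_coords[self.edges[:, 0]] - self.ref_coords[self.edges[:, 1]]
        self.rest_lengths = np.linalg.norm(d, axis=1)
        if np.any(self.rest_lengths < 1e-8):
            bad = self.edges[self.rest_lengths < 1e-8][0]
            raise SingularGeometryError(
                f"atoms {bad[0]} and {bad[1]} are coincident in the reference")
        self._check_connected()

    @property
    def n_atoms(self) -> int:
        return len(self.ref_coords)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def _check_connected(self) -> None:
        n = self.n_atoms
        adj = sp.coo_matrix(
            (np.ones(self.n_edges), (self.edges[:, 0], self.edges[:, 1])),
            shape=(n, n))
        ncomp, labels = connected_components(adj, directed=False)
        if ncomp > 1:
            sizes = np.bincount(labels)
            logger.warning("elastic network has %d connected components "
                           "(sizes %s)", ncomp, sizes.tolist())

    def edge_table(self) -> str:
        """TSV dump (i, j, rest length, k) for inspection."""
        lines = ["i\tj\tr0\tk"]
        for (i, j), r0 in zip(self.edges, self.rest_lengths):
            lines.append(f"{i}\t{j}\t{r0:.6f}\t{self.k:g}")
        return "\n".join(lines) + "\n"


def build_cutoff_network(ref: np.ndarray, cutoff: float, k: float) -> ElasticNetwork:
    """All atom pairs within ``cutoff`` Angstrom become springs."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    xyz = np.asarray(ref, dtype=float).reshape(-1, 3)
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    degree = np.zeros(len(xyz), dtype=int)
    if len(pairs):
        np.add.at(degree, pairs.ravel(), 1)
    isolated = np.nonzero(degree == 0)[0]
    if len(isolated):
        raise IsolatedAtomError(
            f"atom {isolated[0]} has no neighbour within {cutoff} A "
            f"({len(isolated)} isolated atoms in total); increase the cutoff")
    return ElasticNetwork(xyz, pairs, k, "cutoff", cutoff=cutoff)


def build_delaunay_network(ref: np.ndarray, k: float,
                           max_edge: float | None = None,
                           jitter_seed: int = 0) -> ElasticNetwork:
    """Edges of the 3-D Delaunay tetrahedralization of the reference.

    Degenerate (coplanar/collinear) inputs are retried once with a
    uniform 1e-6 A jitter drawn from a fixed seed, then rejected.
    ``max_edge`` optionally drops tetrahedralization edges longer than
    the given length (off by default: the construction is parameter-free).
    """
    xyz = np.asarray(ref, dtype=float).reshape(-1, 3)
    if len(xyz) < 5:
        raise DegenerateGeometryError(
            f"Delaunay network needs >= 5 atoms, got {len(xyz)}")

    def attempt(points: np.ndarray) -> np.ndarray:
        tri = Delaunay(points)
        e = set()
        for simplex in tri.simplices:
            for a in range(4):
                for b in range(a + 1, 4):
                    i, j = int(simplex[a]), int(simplex[b])
                    e.add((min(i, j), max(i, j)))
        return np.array(sorted(e), dtype=int)

    try:
        edges = attempt(xyz)
        pts = xyz
    except Exception:
        rng = np.random.default_rng(jitter_seed)
        jittered = xyz + rng.uniform(-1e-6, 1e-6, size=xyz.shape)
        try:
            edges = attempt(jittered)
            pts = xyz  # rest lengths from the true coordinates
        except Exception as exc:
            raise DegenerateGeometryError(
                f"Delaunay tetrahedralization failed even after jitter: {exc}"
            ) from exc
    if max_edge is not None:
        d = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
        edges = edges[d <= max_edge]
    return ElasticNetwork(pts, edges, k, "delaunay")


# ---------------------------------------------------------------------------
# energy / gradient / Hessian
# ---------------------------------------------------------------------------

def _edge_geometry(net: ElasticNetwork, X: np.ndarray):
    xyz = np.asarray(X, dtype=float).reshape(-1, 3)
    if len(xyz) != net.n_atoms:
        raise SizeMismatchError(
            f"coordinates have {len(xyz)} atoms, network has {net.n_atoms}")
    d = xyz[net.edges[:, 0]] - xyz[net.edges[:, 1]]
    r = np.linalg.norm(d, axis=1)
    return xyz, d, r


def tirion_energy(net: ElasticNetwork, X: np.ndarray) -> float:
    """1/2 k sum (r_ij - r0_ij)^2 over the network's springs, kcal/mol."""
    _, _, r = _edge_geometry(net, X)
    return float(0.5 * net.k * np.sum((r - net.rest_lengths) ** 2))


def tirion_gradient(net: ElasticNetwork, X: np.ndarray) -> np.ndarray:
    """Analytic gradient of the Tirion energy, flattened to 3N."""
    xyz, d, r = _edge_geometry(net, X)
    if np.any(r < 1e-10):
        bad = net.edges[r < 1e-10][0]
        raise SingularGeometryError(
            f"atoms {bad[0]} and {bad[1]} coincide; gradient undefined")
    coef = net.k * (r - net.rest_lengths) / r
    force = coef[:, None] * d
    grad = np.zeros_like(xyz)
    np.add.at(grad, net.edges[:, 0], force)
    np.add.at(grad, net.edges[:, 1], -force)
    return grad.ravel()


class HessianOperator:
    """Symmetric PSD operator of dimension 3N with cached spectral data.

    Wraps a sparse matrix; exposes a matvec contract for Krylov use, a
    dense materialization for small systems, and a cached (clamped)
    eigendecomposition for the dense path-solver backend.
    """

    #: eigenvalues in [-NEG_TOL*scale, 0) are clamped to 0; below aborts
    NEG_TOL = 1e-8

    def __init__(self, matrix: sp.spmatrix):
        self._m = matrix.tocsr()
        self.dim = matrix.shape[0]
        self._eig: tuple[np.ndarray, np.ndarray] | None = None

    def matvec(self, v: np.ndarray) -> np.ndarray:
        return self._m @ v

    __call__ = matvec

    def dense(self) -> np.ndarray:
        if self.dim > DENSE_LIMIT:
            raise MemoryError(
                f"dense materialization refused for dimension {self.dim} > "
                f"{DENSE_LIMIT}; use the Krylov backend")
        return self._m.toarray()

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues (ascending, clamped at 0) and orthonormal vectors."""
        if self._eig is None:
            w, P = np.linalg.eigh(self.dense())
            scale = max(1.0, float(np.max(np.abs(w))))
            if w[0] < -self.NEG_TOL * scale:
                raise ValueError(
                    f"Hessian has a negative eigenvalue {w[0]:.3e}; the "
                    "reference state is not a minimum of this network")
            w = np.clip(w, 0.0, None)
            self._eig = (w, P)
        return self._eig

    def quadratic_energy(self, dx: np.ndarray) -> float:
        """1/2 dx^T H dx — the harmonic well energy at displacement dx."""
        return float(0.5 * np.dot(dx, self.matvec(dx)))


def assemble_hessian(net: ElasticNetwork) -> HessianOperator:
    """Tirion Hessian at the network's own reference conformation.

    With every spring at rest length the mixed distance-derivative terms
    vanish and each edge contributes the exact 3x3 block -k u u^T off the
    diagonal (u the unit edge vector), with diagonal blocks accumulating
    the negatives.
    """
    xyz = net.ref_coords
    n = net.n_atoms
    d = xyz[net.edges[:, 0]] - xyz[net.edges[:, 1]]
    u = d / net.rest_lengths[:, None]
    blocks = net.k * np.einsum("ea,eb->eab", u, u)  # (n_edges, 3, 3)

    rows, cols, vals = [], [], []
    for (i, j), blk in zip(net.edges, blocks):
        for a in range(3):
            for b in range(3):
                v = blk[a, b]
                rows.extend((3 * i + a, 3 * j + a, 3 * i + a, 3 * j + a))
                cols.extend((3 * j + b, 3 * i + b, 3 * i + b, 3 * j + b))
                vals.extend((-v, -v, v, v))
    H = sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n))
    return HessianOperator(H.tocsr())


def rigid_body_modes(ref: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N, 6) of global translations and rotations."""
    xyz = np.asarray(ref, dtype=float).reshape(-1, 3)
    n = len(xyz)
    centered = xyz - xyz.mean(axis=0)
    modes = np.zeros((3 * n, 6))
    for a in range(3):
        modes[a::3, a] = 1.0
    axes = np.eye(3)
    for a in range(3):
        modes[:, 3 + a] = np.cross(np.broadcast_to(axes[a], (n, 3)),
                                   centered).ravel()
    q, r = np.linalg.qr(modes)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def spring_constant_from_bfactor(A_factor: float, mean_B: float) -> float:
    """Calibrate k = A/<B> from the mean crystallographic B-factor.

    Warns when the result falls outside the empirically expected window
    0.16 +/- 0.09 kcal/mol/A^2.
    """
    if mean_B is None or mean_B <= 0:
        raise ValueError(f"mean B-factor must be positive, got {mean_B}")
    k = A_factor / mean_B
    lo, hi = K_EXPECTED_RANGE
    if not lo <= k <= hi:
        logger.warning("calibrated spring constant %.3g kcal/mol/A^2 lies "
                       "outside the expected range [%.2f, %.2f]", k, lo, hi)
    return k
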