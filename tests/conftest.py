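"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from enmpath import fixtures as fx
from enmpath import elastic_network as en


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def quaternion_rmsd(X, Y):
    """Optimal superposed RMSD via the quaternion (Horn) closed form.

    Independent of the SVD/Kabsch route used by the package.
    """
    X = np.asarray(X, float).reshape(-1, 3)
    Y = np.asarray(Y, float).reshape(-1, 3)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    M = Yc.T @ Xc
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K)[-1]
    n = len(X)
    msd = (np.sum(Xc * Xc) + np.sum(Yc * Yc) - 2.0 * lam) / n
    return float(np.sqrt(max(msd, 0.0)))


def brute_force_cutoff_edges(xyz, cutoff):
    """O(N^2) distance scan."""
    xyz = np.asarray(xyz, float)
    out = []
    for i in range(len(xyz)):
        for j in range(i + 1, len(xyz)):
            if np.linalg.norm(xyz[i] - xyz[j]) <= cutoff:
                out.append((i, j))
    return sorted(out)


def circumsphere(p):
    """Center and radius of the sphere through 4 points (or None)."""
    p = np.asarray(p, float)
    A = 2.0 * (p[1:] - p[0])
    b = np.sum(p[1:] ** 2 - p[0] ** 2, axis=1)
    try:
        c = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return None, None
    return c, float(np.linalg.norm(p[0] - c))


def finite_difference_gradient(f, x, h=1e-5):
    x = np.asarray(x, float)
    g = np.zeros_like(x)
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


def finite_difference_hessian(f, x, h=1e-4):
    x = np.asarray(x, float)
    n = len(x)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += h; xpp[j] += h
            xpm = x.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x.copy(); xmm[i] -= h; xmm[j] -= h
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h * h)
    return H


# ---------------------------------------------------------------------------
# reusable toy systems
# ---------------------------------------------------------------------------

def random_cloud(n, box=30.0, seed=0, min_sep=2.5):
    """Seeded random points with a minimum separation (rejection sampling)."""
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        cand = rng.uniform(0, box, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    return np.array(pts)


@pytest.fixture(scope="session")
def five_atom_pair():
    """Two conformations of a 5-atom toy, fully connected networks."""
    xyz_a = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.2, 2.0, 0],
                      [9.0, 5.0, 1.5], [6.0, 7.5, 3.0]])
    xyz_b = xyz_a + np.array([[0.0, 0, 0], [0.2, 0.5, 0], [0.8, 1.2, 0.3],
                              [1.5, 0.5, -0.5], [2.5, -0.5, 1.0]])
    return xyz_a, xyz_b


@pytest.fixture(scope="session")
def helix_pair():
    return fx.make_helix_pair(n=20, bend_angle=30.0, seed=7)


@pytest.fixture(scope="session")
def dumbbell_pair():
    return fx.make_dumbbell_pair(n_per_lobe=30, seed=3)


def dense_wells(xyz_a, xyz_b, k1=0.1, k2=0.1, cutoff=30.0):
    """Cutoff networks + Hessians on each endpoint's own geometry."""
    na = en.build_cutoff_network(xyz_a, cutoff, k1)
    nb = en.build_cutoff_network(xyz_b, cutoff, k2)
    return ((xyz_a.ravel(), en.assemble_hessian(na)),
            (xyz_b.ravel(), en.assemble_hessian(nb)), na, nb)
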