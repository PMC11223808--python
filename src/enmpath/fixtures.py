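"""Deterministic generators of small synthetic structure pairs.

Real conformational transitions (hinge bending, domain opening/closing)
are emulated with toy CA traces whose properties are known in closed
form, so the whole pipeline — parsing, matching, network building, path
solving, analysis — is testable offline.  Every generator is a pure
function of its arguments: a fixed seed regenerates identical bytes.
"""

from __future__ import annotations

import numpy as np

from .errors import EnmPathError
from .structure_io import (AMINO3_TO_1, Atom, Structure, to_mmcif_text,
                           to_pdb_text)

_AA1_TO_3 = {v: k for k, v in AMINO3_TO_1.items()}

# ideal CA-trace helix: 100 deg turn and 1.5 A rise per residue, 2.3 A radius
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN = np.deg2rad(100.0)


def _ca_structure(xyz: np.ndarray, chain_ids, residue_names=None,
                  residue_seqs=None, b_factors=None) -> Structure:
    """Assemble a CA-only Structure from coordinates and per-atom metadata."""
    n = len(xyz)
    if residue_names is None:
        residue_names = ["ALA"] * n
    if residue_seqs is None:
        seqs, counters = [], {}
        for cid in chain_ids:
            counters[cid] = counters.get(cid, 0) + 1
            seqs.append(counters[cid])
        residue_seqs = seqs
    if b_factors is None:
        b_factors = [25.0] * n
    atoms = [Atom(chain_id=chain_ids[i], residue_seq=int(residue_seqs[i]),
                  insertion_code="", residue_name=residue_names[i],
                  atom_name="CA", element="C",
                  position=np.asarray(xyz[i], dtype=float),
                  b_factor=float(b_factors[i]))
             for i in range(n)]
    return Structure(atoms)


def _helix_coords(n: int) -> np.ndarray:
    t = np.arange(n)
    return np.column_stack([
        _HELIX_RADIUS * np.cos(_HELIX_TURN * t),
        _HELIX_RADIUS * np.sin(_HELIX_TURN * t),
        _HELIX_RISE * t,
    ])


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    K = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def make_helix_pair(n: int = 20, bend_angle: float = 30.0,
                    seed: int = 0) -> tuple[Structure, Structure]:
    """An ideal CA helix and the same helix hinge-bent at its midpoint.

    The two structures share residue numbering and atom count, so they
    are usable both with full matching and with the matching bypass.
    B-factors get a small seeded spread around 25 A^2.
    """
    if n < 8:
        raise EnmPathError(f"helix fixture needs n >= 8 residues, got {n}")
    rng = np.random.default_rng(seed)
    xyz_a = _helix_coords(n)
    xyz_b = xyz_a.copy()
    hinge = n // 2
    rot = _rotation_about_axis(np.array([1.0, 0.0, 0.0]), np.deg2rad(bend_angle))
    pivot = xyz_a[hinge]
    xyz_b[hinge:] = (xyz_b[hinge:] - pivot) @ rot.T + pivot
    b = 25.0 + rng.normal(0.0, 2.0, size=n).round(2)
    chain = ["A"] * n
    return (_ca_structure(xyz_a, chain, b_factors=b),
            _ca_structure(xyz_b, chain, b_factors=b))


def _lobe_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    """A compact quasi-lattice blob with ~3.8 A spacing plus seeded jitter."""
    side = int(np.ceil(n ** (1 / 3)))
    grid = np.array([[i, j, k] for i in range(side)
                     for j in range(side) for k in range(side)][:n], dtype=float)
    grid *= 3.8
    grid += rng.uniform(-0.4, 0.4, size=grid.shape)
    return grid - grid.mean(axis=0)


def make_dumbbell_pair(n_per_lobe: int = 30, separation_open: float = 14.0,
                       separation_closed: float = 11.0, seed: int = 0,
                       twist_angle: float = 100.0,
                       two_chains: bool = False) -> tuple[Structure, Structure]:
    """Two rigid lobes joined by a 3-residue linker, open vs closed.

    Emulates a two-domain closure: the lobes keep their internal
    geometry in both endpoints while the second lobe approaches
    (separation change) and twists about the inter-lobe axis by
    ``twist_angle`` degrees.  The twist breaks interface contacts of the
    open form and creates closed-form-specific ones, so both native
    contact fractions (Q1, Q2) vary along a transition path.  With
    ``two_chains`` the lobes carry distinct chain IDs, which exercises
    cross-chain network edges.
    """
    rng = np.random.default_rng(seed)
    lobe1 = _lobe_coords(n_per_lobe, rng)
    lobe2 = _lobe_coords(n_per_lobe, rng)

    def assemble(separation: float, twist_deg: float) -> np.ndarray:
        left = lobe1 + np.array([-separation / 2, 0.0, 0.0])
        # 3-residue linker bridging the lobes along x
        link_x = np.linspace(-separation / 2 + 2.0, separation / 2 - 2.0, 3)
        linker = np.column_stack([link_x, np.full(3, 8.0), np.zeros(3)])
        right = lobe2
        if twist_deg:
            rot = _rotation_about_axis(np.array([1.0, 0.0, 0.0]),
                                       np.deg2rad(twist_deg))
            right = right @ rot.T
        right = right + np.array([separation / 2, 0.0, 0.0])
        return np.vstack([left, linker, right])

    n_total = 2 * n_per_lobe + 3
    if two_chains:
        chains = ["A"] * (n_per_lobe + 3) + ["B"] * n_per_lobe
    else:
        chains = ["A"] * n_total
    b = 25.0 + rng.normal(0.0, 2.0, size=n_total).round(2)
    return (_ca_structure(assemble(separation_open, 0.0), chains, b_factors=b),
            _ca_structure(assemble(separation_closed, twist_angle), chains,
                          b_factors=b))


def make_mutation_pair(sequence: str, mutations: dict[int, str] | None = None,
                       seed: int = 0) -> tuple[Structure, Structure]:
    """Same helical backbone, with residue identities mutated in B.

    ``mutations`` maps 0-based residue positions to 1-letter codes.  The
    expected matched/excluded residue sets follow from the amino-acid
    class table, making this fixture the closed-form test bed for the
    class-based matching rule.
    """
    mutations = mutations or {}
    for pos, code in mutations.items():
        if code not in _AA1_TO_3:
            raise EnmPathError(f"invalid residue code {code!r} at {pos}")
        if not 0 <= pos < len(sequence):
            raise EnmPathError(f"mutation position {pos} outside sequence")
    names_a = []
    for c in sequence:
        if c not in _AA1_TO_3:
            raise EnmPathError(f"invalid residue code {c!r} in sequence")
        names_a.append(_AA1_TO_3[c])
    names_b = list(names_a)
    for pos, code in mutations.items():
        names_b[pos] = _AA1_TO_3[code]
    rng = np.random.default_rng(seed)
    xyz = _helix_coords(len(sequence))
    b = 25.0 + rng.normal(0.0, 2.0, size=len(sequence)).round(2)
    chain = ["A"] * len(sequence)
    return (_ca_structure(xyz, chain, residue_names=names_a, b_factors=b),
            _ca_structure(xyz.copy(), chain, residue_names=names_b, b_factors=b))


def write_pair(pair: tuple[Structure, Structure], directory, stem: str = "pair",
               formats: tuple[str, ...] = ("pdb", "cif")) -> dict[str, str]:
    """Write both endpoints in the requested dialects; returns path map."""
    import os
    paths: dict[str, str] = {}
    for label, s in zip(("A", "B"), pair):
        for fmt in formats:
            p = os.path.join(str(directory), f"{stem}_{label}.{fmt}")
            text = to_pdb_text(s) if fmt == "pdb" else to_mmcif_text(s)
            with open(p, "w") as fh:
                fh.write(text)
            paths[f"{label}.{fmt}"] = p
    return paths
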