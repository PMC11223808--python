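"""Atom correspondence between the two endpoint conformations.

The two input files may differ in atom count and chain naming.  The
common-atom subset is recovered by global sequence alignment of every
chain of one endpoint against every chain of the other, followed by a
score-driven one-to-one chain assignment.  Aligned amino-acid pairs are
kept when both residues fall in the same physico-chemical class —
(P,A,G,S,T), (D,N,E,Q), (H,K,R), (F,Y,W), (V,L,I,C,M) — while aligned
nucleotides must be identical.  Within a retained residue pair, atoms
are paired by name.

Endpoint B is then rigidly superposed onto endpoint A over the common
atoms (proper-rotation least squares), so that the path solver works in
a shared frame free of spurious rigid-body motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .errors import (DegenerateGeometryError, MixedAlphabetError,
                     NoCorrespondenceError, SizeMismatchError,
                     TooFewAtomsError)
from .structure_io import Residue, Structure, residue_one_letter, residue_polymer_type

logger = logging.getLogger(__name__)

#: amino-acid physico-chemical classes for residue pairing
AA_CLASSES = [set("PAGST"), set("DNEQ"), set("HKR"), set("FYW"), set("VLICM")]
_AA_CLASS_OF = {aa: i for i, cls in enumerate(AA_CLASSES) for aa in cls}

#: minimum per-chain alignment score for a chain pair to count as matched
MIN_CHAIN_SCORE = 10.0

NUCLEOTIDE_LETTERS = set("ACGTU")


def same_class(res1: str, res2: str, moltype: str) -> bool:
    """True when two aligned 1-letter residues may be paired."""
    if moltype == "protein":
        c1, c2 = _AA_CLASS_OF.get(res1), _AA_CLASS_OF.get(res2)
        return c1 is not None and c1 == c2
    return res1 == res2  # nucleotides: identical base required


@dataclass
class ChainAlignment:
    chain_a: str
    chain_b: str
    score: float
    moltype: str
    # per-column residue indices into each chain's residue list; -1 = gap
    columns: np.ndarray = field(repr=False, default=None)
    seq_a: str = ""
    seq_b: str = ""


@dataclass
class AtomCorrespondence:
    """Paired common atoms of the two endpoints, in a fixed shared order."""

    pairs: list[tuple[int, int]]
    chain_map: list[ChainAlignment]

    @property
    def n_common(self) -> int:
        return len(self.pairs)

    def indices_a(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    def indices_b(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


def _possible_alphabets(seq: str) -> set[str]:
    """Alphabets a sequence is valid under (letters like ACGT fit both)."""
    letters = set(seq.upper())
    out = set()
    if letters <= NUCLEOTIDE_LETTERS:
        out.add("nucleotide")
    if letters <= set(_AA_CLASS_OF):
        out.add("protein")
    if not out:
        raise MixedAlphabetError(
            f"sequence contains non-residue letters: "
            f"{sorted(letters - set(_AA_CLASS_OF) - NUCLEOTIDE_LETTERS)}")
    return out


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = 0.0
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    return al


def align_sequences(seq1: str, seq2: str):
    """Global alignment of two residue strings.

    Scoring strongly prefers ungapped matches (match +1, mismatch 0, gap
    open -10, extend -0.5).  Returns ``(columns, score)`` where columns
    is a (2, L) array of residue indices with -1 marking gaps.
    """
    if not seq1 or not seq2:
        raise MixedAlphabetError("cannot align empty sequences")
    if not (_possible_alphabets(seq1) & _possible_alphabets(seq2)):
        raise MixedAlphabetError(
            "alphabet mismatch: a nucleotide and an amino-acid sequence "
            "cannot be aligned")
    alignment = _aligner().align(seq1, seq2)[0]
    return np.asarray(alignment.indices, dtype=int), float(alignment.score)


def _chain_sequence(residues: list[Residue]) -> tuple[str, str, list[int]]:
    """1-letter sequence of a chain plus molecule type and kept indices.

    Residues outside the standard alphabets (modified residues) are
    excluded from matching.
    """
    letters, kept, types = [], [], []
    for i, r in enumerate(residues):
        code = residue_one_letter(r.name)
        ptype = residue_polymer_type(r.name)
        if code is None or ptype is None:
            continue
        letters.append(code)
        kept.append(i)
        types.append(ptype)
    if not letters:
        return "", "", []
    moltype = "protein" if types.count("protein") >= len(types) / 2 else "nucleic"
    return "".join(letters), moltype, kept


def match_chains(A: Structure, B: Structure) -> list[ChainAlignment]:
    """Score-driven one-to-one assignment of chains of A to chains of B.

    All chains are aligned against all chains of the same molecule type;
    pairs are then accepted greedily by descending score (ties broken by
    chain-ID order), so crossed chain namings between the two files are
    resolved by sequence content, not by name.
    """
    res_a = {c: A.chain_residues(c) for c in A.chain_ids()}
    res_b = {c: B.chain_residues(c) for c in B.chain_ids()}
    seqs_a = {c: _chain_sequence(r) for c, r in res_a.items()}
    seqs_b = {c: _chain_sequence(r) for c, r in res_b.items()}

    candidates: list[ChainAlignment] = []
    for ca, (sa, ta, _) in seqs_a.items():
        for cb, (sb, tb, _) in seqs_b.items():
            if not sa or not sb or ta != tb:
                continue
            cols, score = align_sequences(sa, sb)
            if score < MIN_CHAIN_SCORE:
                continue
            candidates.append(ChainAlignment(ca, cb, score, ta, cols, sa, sb))
    candidates.sort(key=lambda c: (-c.score, c.chain_a, c.chain_b))
    used_a: set[str] = set()
    used_b: set[str] = set()
    chosen: list[ChainAlignment] = []
    for cand in candidates:
        if cand.chain_a in used_a or cand.chain_b in used_b:
            continue
        used_a.add(cand.chain_a)
        used_b.add(cand.chain_b)
        chosen.append(cand)
    if not chosen:
        raise NoCorrespondenceError(
            "no chain pair aligned with score >= %g; the two structures do "
            "not share a recognizable sequence" % MIN_CHAIN_SCORE)
    for c in set(res_a) - {c.chain_a for c in chosen}:
        logger.warning("chain %s of the start structure is unmatched; dropped", c)
    for c in set(res_b) - {c.chain_b for c in chosen}:
        logger.warning("chain %s of the target structure is unmatched; dropped", c)
    chosen.sort(key=lambda c: list(res_a).index(c.chain_a))
    return chosen


def extract_common_atoms(A: Structure, B: Structure,
                         chain_map: list[ChainAlignment]) -> AtomCorrespondence:
    """Pair atoms of aligned, class-compatible residues by atom name.

    Ordering is chain-map order, then A-side residue order, then A-side
    atom order.  Fewer than 7 common atoms cannot support a 3-D elastic
    problem beyond its rigid-body modes, so that is an error.
    """
    pairs: list[tuple[int, int]] = []
    for ca in chain_map:
        ares = A.chain_residues(ca.chain_a)
        bres = B.chain_residues(ca.chain_b)
        _, _, kept_a = _chain_sequence(ares)
        _, _, kept_b = _chain_sequence(bres)
        moltype = "protein" if ca.moltype == "protein" else "nucleic"
        for ia, ib in ca.columns.T:
            if ia < 0 or ib < 0:
                continue
            rA, rB = ares[kept_a[ia]], bres[kept_b[ib]]
            codes = (residue_one_letter(rA.name), residue_one_letter(rB.name))
            if not same_class(codes[0], codes[1],
                              "protein" if moltype == "protein" else "nucleic"):
                continue
            b_by_name = {B.atoms[j].atom_name: j for j in rB.atom_indices}
            for i in rA.atom_indices:
                j = b_by_name.get(A.atoms[i].atom_name)
                if j is not None:
                    pairs.append((i, j))
    if len(pairs) < 7:
        raise TooFewAtomsError(
            f"only {len(pairs)} common atoms; at least 7 are required")
    return AtomCorrespondence(pairs, chain_map)


def bypass_matching(A: Structure, B: Structure) -> AtomCorrespondence:
    """Identity correspondence in file order (equal atom counts required)."""
    if A.n_atoms != B.n_atoms:
        raise SizeMismatchError(
            f"matching bypass requires equal atom counts, got {A.n_atoms} vs "
            f"{B.n_atoms}; rerun with matching enabled")
    return AtomCorrespondence([(i, i) for i in range(A.n_atoms)], [])


def superpose(A_coords: np.ndarray, B_coords: np.ndarray):
    """Least-squares rigid superposition of B onto A (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``B @ rotation.T + translation`` best fits A.  Only proper rotations
    are allowed.
    """
    X = np.asarray(A_coords, dtype=float).reshape(-1, 3)
    Y = np.asarray(B_coords, dtype=float).reshape(-1, 3)
    if X.shape != Y.shape:
        raise SizeMismatchError("superposition requires paired coordinates")
    if len(X) < 3:
        raise DegenerateGeometryError("superposition needs >= 3 atoms")
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - cx, Y - cy
    # guard against collinear sets: rotation about the line is undetermined
    if np.linalg.matrix_rank(X0, tol=1e-8 * max(1.0, np.abs(X0).max())) < 2:
        raise DegenerateGeometryError("collinear point set; superposition "
                                      "is not unique")
    H = Y0.T @ X0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cx - R @ cy
    diff = X - (Y @ R.T + t)
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return R, t, rmsd


def match_report(A: Structure, B: Structure, corr: AtomCorrespondence,
                 rmsd: float | None = None) -> str:
    """Human-readable chain-matching report with per-chain alignments."""
    lines = ["Chain matching report", "====================="]
    if not corr.chain_map:
        lines.append("matching bypassed: identity correspondence in file order")
    for ca in corr.chain_map:
        lines.append(f"\nchain {ca.chain_a} (start) <-> chain {ca.chain_b} "
                     f"(target)  score={ca.score:.1f}  type={ca.moltype}")
        ga, gb = [], []
        for ia, ib in ca.columns.T:
            ga.append(ca.seq_a[ia] if ia >= 0 else "-")
            gb.append(ca.seq_b[ib] if ib >= 0 else "-")
        lines.append("  " + "".join(ga))
        lines.append("  " + "".join(gb))
    lines.append(f"\ncommon atoms: {corr.n_common}")
    if rmsd is not None:
        lines.append(f"superposition rmsd over common atoms: {rmsd:.3f} A")
    return "\n".join(lines) + "\n"
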