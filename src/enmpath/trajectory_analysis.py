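"""Per-frame analytics for generated paths: RMSD, energy, Q1/Q2, action.

Q1 (resp. Q2) is the fraction of the start (resp. target) structure's
native contacts that are present in a frame, where the contact sets are
the elastic-network edge lists of the two endpoints and a contact counts
as present when its length does not exceed lambda times its native
length (lambda = 1.2 by default).  RMSD versus both endpoints is
computed in the shared frame established at superposition time, without
per-frame refitting, so rigid drift along the path stays visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .chain_matching import superpose
from .elastic_network import ElasticNetwork
from .errors import SizeMismatchError
from .path_solver import Trajectory

logger = logging.getLogger(__name__)

#: contact-presence tolerance: r <= Q_LAMBDA * r0 counts as formed
Q_LAMBDA = 1.2


def rmsd(X: np.ndarray, Y: np.ndarray, superpose_first: bool = False) -> float:
    """Root-mean-square deviation between paired coordinate sets, Angstrom."""
    X = np.asarray(X, dtype=float).reshape(-1, 3)
    Y = np.asarray(Y, dtype=float).reshape(-1, 3)
    if X.shape != Y.shape:
        raise SizeMismatchError(f"rmsd over mismatched shapes {X.shape} vs {Y.shape}")
    if len(X) == 0:
        raise SizeMismatchError("rmsd of empty coordinate sets")
    if superpose_first:
        _, _, value = superpose(X, Y)
        return value
    diff = X - Y
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def q_fraction(frame: np.ndarray, contacts: np.ndarray,
               native_lengths: np.ndarray, lam: float = Q_LAMBDA) -> float:
    """Fraction of reference contacts still formed in a frame."""
    if len(contacts) == 0:
        raise SizeMismatchError("Q undefined for an empty contact list")
    xyz = np.asarray(frame, dtype=float).reshape(-1, 3)
    d = np.linalg.norm(xyz[contacts[:, 0]] - xyz[contacts[:, 1]], axis=1)
    return float(np.mean(d <= lam * native_lengths))


def q_fraction_net(frame: np.ndarray, net: ElasticNetwork,
                   lam: float = Q_LAMBDA) -> float:
    return q_fraction(frame, net.edges, net.rest_lengths, lam)


def action_value(traj: Trajectory, wellA, wellB, dE: float = 0.0) -> float:
    """Onsager-Machlup action S = 1/2 int (dX/dt + grad U)^2 dt (diagnostic).

    The time derivative uses central differences on the frame grid and
    grad U comes from whichever well is active under U = min(U_A+dE, U_B).
    The value is reported, never optimized.
    """
    X_A, HA = wellA
    X_B, HB = wellB
    X_A = np.asarray(X_A, dtype=float).ravel()
    X_B = np.asarray(X_B, dtype=float).ravel()
    t = traj.times
    Xs = traj.frames
    if len(t) < 3:
        raise ValueError("action quadrature needs at least 3 frames")
    dXdt = np.gradient(Xs, t, axis=0)
    integrand = np.empty(len(t))
    for i in range(len(t)):
        uA = HA.quadratic_energy(Xs[i] - X_A) + dE
        uB = HB.quadratic_energy(Xs[i] - X_B)
        if uA <= uB:
            grad = HA.matvec(Xs[i] - X_A)
        else:
            grad = HB.matvec(Xs[i] - X_B)
        resid = dXdt[i] + grad
        integrand[i] = np.dot(resid, resid)
    return float(0.5 * np.trapezoid(integrand, t))


@dataclass
class FrameStats:
    index: int
    time: float
    energy: float
    rmsd_to_A: float
    rmsd_to_B: float
    q1: float
    q2: float


def analyze_trajectory(traj: Trajectory, net_A: ElasticNetwork,
                       net_B: ElasticNetwork, lam: float = Q_LAMBDA,
                       fit_per_frame: bool = False) -> list[FrameStats]:
    """Per-frame RMSD to both endpoints, two-well energy and Q1/Q2."""
    X_A = net_A.ref_coords.ravel()
    X_B = net_B.ref_coords.ravel()
    out = []
    for i, (t, frame) in enumerate(zip(traj.times, traj.frames)):
        out.append(FrameStats(
            index=i, time=float(t), energy=float(traj.energies[i]),
            rmsd_to_A=rmsd(frame, X_A, superpose_first=fit_per_frame),
            rmsd_to_B=rmsd(frame, X_B, superpose_first=fit_per_frame),
            q1=q_fraction_net(frame, net_A, lam),
            q2=q_fraction_net(frame, net_B, lam),
        ))
    return out


TSV_HEADER = "frame\ttime\tU\trmsd_A\trmsd_B\tQ1\tQ2"


def stats_to_tsv(stats: list[FrameStats]) -> str:
    lines = [TSV_HEADER]
    for s in stats:
        lines.append(f"{s.index}\t{s.time:.6f}\t{s.energy:.6f}\t"
                     f"{s.rmsd_to_A:.6f}\t{s.rmsd_to_B:.6f}\t"
                     f"{s.q1:.6f}\t{s.q2:.6f}")
    return "\n".join(lines) + "\n"


def tsv_to_stats(text: str) -> list[FrameStats]:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if not lines or lines[0] != TSV_HEADER:
        raise ValueError("frame table header missing or unrecognized")
    out = []
    for ln in lines[1:]:
        f = ln.split("\t")
        out.append(FrameStats(int(f[0]), float(f[1]), float(f[2]),
                              float(f[3]), float(f[4]), float(f[5]),
                              float(f[6])))
    return out


def write_report(stats: list[FrameStats], meta: dict, tsv_path: str,
                 log_path: str) -> None:
    """Write the frame table (TSV) and a run log with the key quantities."""
    try:
        with open(tsv_path, "w") as fh:
            fh.write(stats_to_tsv(stats))
    except OSError as exc:
        raise OSError(f"cannot write frame table to {tsv_path!r}: {exc}") from exc

    def fmt(v):
        if v is None:
            return "unavailable"
        if isinstance(v, float):
            return f"{v:.6g}"
        return str(v)

    lines = ["run log", "======="]
    for key, val in meta.items():
        lines.append(f"{key}: {fmt(val)}")
    try:
        with open(log_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write log to {log_path!r}: {exc}") from exc
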