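"""Second-principal-axis (P2) orientation analysis.

For each molecule the tensor of the moments of inertia about its COM is
eigendecomposed.  The eigenvector with the *smallest* moment is the
long molecular axis P1 (mass far from an axis means a large moment, so
the long axis carries the least); P2, with the intermediate moment,
lies in the backbone zigzag plane perpendicular to P1 and reports the
rotational setting of the chain about its long axis.  A gyration-tensor
mode is also provided, in which the *largest* eigenvalue corresponds to
the long axis.

After rotating the crystallite so the molecular long axes align with z,
the in-plane direction of P2 quantifies the relative rotational order:
uniform in a crystal, alternating on two sublattices in a herringbone
packing, scattered in a rotator phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from quasicryst.model_io import ChainTopology, MoleculeTable, TrajectoryWindow, molecule_com
from quasicryst.pbc import align_long_axes_to_z
from quasicryst.model_io import SnapshotFrame

logger = logging.getLogger(__name__)


def inertia_tensor(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Inertia tensor about the molecular COM, amu nm^2.

    I = sum_i m_i ((r_i . r_i) E - r_i r_i^T) with r_i relative to the
    COM; symmetric by construction.
    """
    coords = np.asarray(coords, float)
    masses = np.asarray(masses, float)
    if len(coords) < 2:
        raise ValueError("need at least 2 atoms")
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    r = coords - com
    if np.allclose(r, 0.0):
        raise ValueError("all atoms coincident; inertia tensor is zero")
    r2 = (r ** 2).sum(axis=1)
    return (masses[:, None, None]
            * (r2[:, None, None] * np.eye(3) - r[:, :, None] * r[:, None, :])
            ).sum(axis=0)


def gyration_tensor(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weighted gyration tensor about the COM (largest axis = long axis)."""
    coords = np.asarray(coords, float)
    masses = np.asarray(masses, float)
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    r = coords - com
    return (masses[:, None, None] * r[:, :, None] * r[:, None, :]).sum(axis=0) / masses.sum()


_REF_AXES = np.eye(3)  # sign references: +x, tie-broken by +y then +z


def _fix_sign(v: np.ndarray) -> np.ndarray:
    for ref in _REF_AXES:
        d = float(v @ ref)
        if abs(d) > 1e-12:
            return v if d > 0 else -v
    return v


def principal_axes(tensor: np.ndarray, mode: str = "inertia",
                   degeneracy_rtol: float = 1e-9,
                   ) -> tuple[np.ndarray, bool]:
    """Principal axes (P1, P2, P3) ordered long axis first.

    For an inertia tensor the axes are ordered by ascending moment
    (P1 = long axis = smallest moment); for a gyration tensor by
    descending eigenvalue.  Each axis sign is fixed to a non-negative
    dot with +x (ties: +y, then +z).  Returns (axes rows, degenerate):
    ``degenerate`` is True when the two moments defining P2 and P3
    differ by less than ``degeneracy_rtol`` relative (axially symmetric
    molecule, P2 ill-defined).
    """
    T = np.asarray(tensor, float)
    if not np.allclose(T, T.T, atol=1e-10):
        raise ValueError("tensor must be symmetric")
    evals, evecs = np.linalg.eigh(T)  # ascending
    if mode == "inertia":
        order = [0, 1, 2]
        pair = (evals[1], evals[2])  # moments of P2, P3
    elif mode == "gyration":
        order = [2, 1, 0]
        pair = (evals[1], evals[0])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    scale = max(abs(evals[-1]), 1e-300)
    degenerate = abs(pair[0] - pair[1]) < degeneracy_rtol * scale
    if degenerate:
        logger.warning("P2/P3 moments degenerate; P2 direction ill-defined")
    axes = np.stack([_fix_sign(evecs[:, i]) for i in order])
    return axes, degenerate


def p2_inplane_angles(p2: np.ndarray,
                      alignment_rotation: np.ndarray | None = None,
                      ) -> tuple[float, float, bool]:
    """In-plane director angles of P2 after crystallite alignment.

    The P2 axis is rotated into the frame where the molecular long axes
    are parallel to z, projected onto the xy plane and renormalized.
    Since an eigenvector's sign is arbitrary, P2 is a director: angles
    are folded modulo 180 degrees.  ``angle_x`` is the director angle
    from +x in [0, 180); ``angle_y`` the same angle measured from +y.
    Returns (angle_x, angle_y, flagged); ``flagged`` marks a P2 nearly
    parallel to z after alignment (projection norm < 1e-6), whose
    in-plane direction is meaningless.
    """
    p2 = np.asarray(p2, float)
    if alignment_rotation is not None:
        p2 = np.asarray(alignment_rotation, float) @ p2
    x, y = float(p2[0]), float(p2[1])
    if np.hypot(x, y) < 1e-6:
        return np.nan, np.nan, True
    if y < 0 or (y == 0 and x < 0):  # canonical director fold: exact under v -> -v
        x, y = -x, -y
    theta = float(np.degrees(np.arctan2(y, x))) % 180.0
    angle_y = (theta - 90.0) % 180.0
    return theta, angle_y, False


def orientation_field(window: TrajectoryWindow, table: MoleculeTable,
                      member_ids: np.ndarray,
                      topology: ChainTopology | None = None,
                      every_n: int = 1,
                      tensor_mode: str = "inertia") -> list[pd.DataFrame]:
    """P2 vector-field frames for one crystallite.

    Every ``every_n``-th frame yields a table with one row per molecule:
    the anchor point (the molecule's COM in the LAST frame of the
    window, so consecutive plots overlay as a movie), the in-plane P2
    components and the folded angles.  The crystallite is aligned to z
    by the same rotation in every frame (fitted on the last frame).
    """
    if every_n < 1:
        raise ValueError("every_n must be >= 1")
    topology = topology or ChainTopology()
    member_ids = np.asarray(member_ids, int)
    sub = table.subset(member_ids)
    last = window.frames[-1]
    R, _ = align_long_axes_to_z(last, sub, topology)
    anchors = molecule_com(last, sub) @ R.T

    fields = []
    for f in window.frames[::every_n]:
        rows = []
        for m in range(sub.n_molecules):
            coords = f.coords[sub.atom_indices[m]]
            axes, degenerate = principal_axes(
                inertia_tensor(coords, sub.masses[m]) if tensor_mode == "inertia"
                else gyration_tensor(coords, sub.masses[m]),
                mode=tensor_mode)
            p2 = R @ axes[1]
            ax_deg, ay_deg, flagged = p2_inplane_angles(p2)
            proj = p2[:2]
            nrm = np.linalg.norm(proj)
            if nrm > 1e-12 and not flagged:
                # fold the drawn vector into the [0,180) half plane too
                proj = proj / nrm
                if proj[1] < 0 or (proj[1] == 0 and proj[0] < 0):
                    proj = -proj
            rows.append((int(member_ids[m]), anchors[m, 0], anchors[m, 1],
                         proj[0], proj[1], ax_deg, ay_deg,
                         bool(flagged or degenerate)))
        fields.append(pd.DataFrame(
            rows, columns=["molecule_id", "anchor_x", "anchor_y",
                           "p2x", "p2y", "angle_x_deg", "angle_y_deg",
                           "flagged"]).assign(frame_time=f.time))
    return fields
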