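"""Crystallite eigenplane fitting and molecular tilt angles.

The eigenplane of a crystallite is the least-squares plane through the
mid-chain atoms (C8 by default) of its molecules: coordinates are
mean-centered, the 3x3 second-moment matrix is eigendecomposed, and the
eigenvector of the smallest eigenvalue is the plane normal.  Note the
centering: the second-moment matrix of *raw* coordinates only yields
the plane normal for planes through the origin; mean-centering makes
the fit valid for any plane placement and is equivalent to using the
coordinate covariance.

The tilt angle of a molecule is the angle between its long-axis anchor
vector (C3 -> C13) and the plane normal, folded to [0, 90] degrees
since both the normal sign and the chain head-tail direction are
arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from quasicryst.model_io import ChainTopology, MoleculeTable, TrajectoryWindow, SnapshotFrame
from quasicryst.segmentation import chain_vectors


@dataclass(frozen=True)
class Eigenplane:
    """Plane a*x + b*y + c*z = d with unit normal (a, b, c)."""

    normal: np.ndarray
    d: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be a unit vector")
        object.__setattr__(self, "normal", n)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.normal - self.d


def _fix_normal_sign(n: np.ndarray) -> np.ndarray:
    """Deterministic sign: c >= 0; ties broken by b >= 0, then a >= 0."""
    for comp in (2, 1, 0):
        if abs(n[comp]) > 1e-12:
            return n if n[comp] > 0 else -n
    return n


def fit_eigenplane(points: np.ndarray) -> Eigenplane:
    """Least-squares plane through a point cloud via the smallest eigenvector.

    Points are mean-centered; the normal is the unit eigenvector of the
    smallest eigenvalue of the centered second-moment matrix, and
    d = normal . mean(points).  The smallest eigenvalue equals the sum
    of squared point-plane distances (least-squares optimality).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("need at least 3 points of shape (n, 3)")
    mean = pts.mean(axis=0)
    centered = pts - mean
    moment = centered.T @ centered
    evals, evecs = np.linalg.eigh(moment)
    if evals[1] <= max(evals[-1], 1.0) * 1e-12:
        raise ValueError("points are collinear; plane is underdetermined")
    normal = _fix_normal_sign(evecs[:, 0])
    return Eigenplane(normal=normal, d=float(normal @ mean))


def tilt_angle(tilt_vector: np.ndarray, plane: Eigenplane) -> np.ndarray:
    """Angle between molecule vector(s) and the plane normal, degrees [0, 90].

    theta = arccos(|n_hat . v_hat|); folding absorbs the arbitrary
    normal sign and chain head-tail direction, so theta(v) == theta(-v).
    """
    v = np.asarray(tilt_vector, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero tilt vector")
    cos = np.abs(v @ plane.normal) / norms
    theta = np.degrees(np.arccos(np.clip(cos, 0.0, 1.0)))
    return float(theta[0]) if single else theta


@dataclass
class TiltStatistics:
    """Temporal and spatial tilt statistics (degrees, population std)."""

    per_molecule: pd.DataFrame  # molecule_id, mean_deg, std_deg, n_frames
    per_frame: pd.DataFrame     # frame_time, mean_deg, std_deg, n_molecules
    grand_mean: float
    grand_std: float


def tilt_statistics(records: pd.DataFrame) -> TiltStatistics:
    """Aggregate tilt records (molecule_id, frame_time, theta_deg).

    Per-molecule statistics run over frames (temporal: ordering of the
    crystallite over time); per-frame statistics over molecules
    (spatial: mobility within a frame).  Standard deviations use the
    population (N) denominator.
    """
    if records.empty:
        raise ValueError("no tilt records")
    per_mol = (records.groupby("molecule_id")["theta_deg"]
               .agg(mean_deg="mean", std_deg=lambda s: s.std(ddof=0), n_frames="count")
               .reset_index())
    per_frame = (records.groupby("frame_time")["theta_deg"]
                 .agg(mean_deg="mean", std_deg=lambda s: s.std(ddof=0), n_molecules="count")
                 .reset_index())
    return TiltStatistics(
        per_molecule=per_mol, per_frame=per_frame,
        grand_mean=float(records["theta_deg"].mean()),
        grand_std=float(records["theta_deg"].std(ddof=0)),
    )


def crystallite_tilt(window: TrajectoryWindow, table: MoleculeTable,
                     member_ids: np.ndarray,
                     topology: ChainTopology | None = None,
                     per_frame_plane: bool = False,
                     ) -> tuple[pd.DataFrame, Eigenplane | list[Eigenplane]]:
    """Tilt-angle records for one crystallite over a window.

    By default a single static plane is fitted to the time-averaged
    mid-atom coordinates; with ``per_frame_plane=True`` the plane is
    refitted in every frame.  Assumes the crystallite has already been
    reconstructed in real space if it was split by the periodic box.
    """
    topology = topology or ChainTopology()
    member_ids = np.asarray(member_ids, int)
    sub = table.subset(member_ids)
    mid_idx = sub.position_indices(topology.mid_atom)

    rows = []
    if per_frame_plane:
        planes: list[Eigenplane] = []
        for f in window:
            plane = fit_eigenplane(f.coords[mid_idx])
            planes.append(plane)
            theta = tilt_angle(chain_vectors(f, sub, topology.anchor_tilt), plane)
            rows.append(pd.DataFrame({"molecule_id": member_ids,
                                      "frame_time": f.time,
                                      "theta_deg": theta}))
        return pd.concat(rows, ignore_index=True), planes
    mid_mean = np.mean([f.coords[mid_idx] for f in window], axis=0)
    plane = fit_eigenplane(mid_mean)
    for f in window:
        theta = tilt_angle(chain_vectors(f, sub, topology.anchor_tilt), plane)
        rows.append(pd.DataFrame({"molecule_id": member_ids,
                                  "frame_time": f.time,
                                  "theta_deg": theta}))
    return pd.concat(rows, ignore_index=True), plane
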