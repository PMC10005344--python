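"""Crystallite segmentation by chain-vector orientation.

Each quasilinear molecule is represented by the vector spanning two
backbone anchors (C3 -> C14 by default).  Its orientation is described
either by the three slopes of the vector's projections on the xy, yz
and zx coordinate planes (arctan of coordinate-difference ratios), or —
more robustly when the vector lies close to a coordinate plane — by the
three angles it closes with the coordinate axes.  Descriptors are
time-averaged over an analysis window and clustered with a density-based
method; molecules assigned to no cluster form the disordered pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from quasicryst.model_io import ChainTopology, MoleculeTable, TrajectoryWindow, SnapshotFrame

logger = logging.getLogger(__name__)

HALF_PI = np.pi / 2


def chain_vectors(frame: SnapshotFrame, table: MoleculeTable,
                  anchor_pair: tuple[int, int]) -> np.ndarray:
    """Displacement vectors from the first to the second anchor, (n_mol, 3) nm."""
    a, b = anchor_pair
    v = frame.coords[table.position_indices(b)] - frame.coords[table.position_indices(a)]
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        bad = int(np.flatnonzero(norms == 0)[0])
        raise ValueError(f"degenerate molecule {bad}: coincident anchor atoms")
    return v


def slopes(v: np.ndarray) -> np.ndarray:
    """Projection-plane slopes (Bxy, Byz, Bzx) in rad, each in (-pi/2, pi/2].

    Bxy = arctan(dy/dx), Byz = arctan(dz/dy), Bzx = arctan(dx/dz).
    A zero denominator with nonzero numerator maps to exactly pi/2; a
    0/0 component maps to 0 by convention (logged).  Slopes are
    invariant under v -> -v and under positive scaling.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    if np.any(np.linalg.norm(v, axis=1) == 0):
        raise ValueError("zero chain vector has no orientation")
    dx, dy, dz = v[:, 0], v[:, 1], v[:, 2]
    out = np.empty((len(v), 3))
    for k, (num, den) in enumerate(((dy, dx), (dz, dy), (dx, dz))):
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            s = np.arctan(num / den)
        both_zero = (num == 0) & (den == 0)
        s = np.where(den == 0, HALF_PI, s)
        s = np.where(both_zero, 0.0, s)
        if np.any(both_zero):
            logger.debug("0/0 slope component set to 0 for %d molecules",
                         int(both_zero.sum()))
        out[:, k] = s
    return out[0] if single else out


def axis_angles(v: np.ndarray) -> np.ndarray:
    """Angles (alpha_x, alpha_y, alpha_z) of v with the coordinate axes, rad.

    alpha_i = arccos(v_i / |v|), each in [0, pi].  The squared cosines
    sum to one.  Under v -> -v each angle maps to pi - alpha.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    v = np.atleast_2d(v)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero chain vector has no orientation")
    ang = np.arccos(np.clip(v / norms[:, None], -1.0, 1.0))
    return ang[0] if single else ang


def _sign_align(vectors: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip vectors with negative dot product against the reference."""
    s = np.sign(np.einsum("...i,...i->...", vectors, reference))
    s[s == 0] = 1.0
    return vectors * s[..., None]


def time_average_descriptors(window: TrajectoryWindow, table: MoleculeTable,
                             topology: ChainTopology | None = None,
                             mode: str = "slopes",
                             averaging: str = "mean_vector") -> pd.DataFrame:
    """Per-molecule orientation descriptors averaged over a window.

    ``averaging="mean_vector"`` (default) sign-aligns each molecule's
    per-frame chain vector to its first-frame vector, averages the
    vectors, and takes the descriptor of the mean — robust to the slope
    wrap at +-pi/2 and to head-tail flips.  ``averaging="literal"``
    arithmetically averages per-frame descriptor angles, which suffers
    a wrap artifact for orientations near the branch cut (e.g. slopes
    +89 deg and -89 deg average to 0 deg).

    Returns a DataFrame with molecule_id, the three descriptor angles
    in radians, and n_frames.
    """
    if len(window) == 0:
        raise ValueError("empty trajectory window")
    if mode not in ("slopes", "axis_angles"):
        raise ValueError(f"unknown descriptor mode {mode!r}")
    if averaging not in ("mean_vector", "literal"):
        raise ValueError(f"unknown averaging {averaging!r}")
    topology = topology or ChainTopology()
    per_frame = np.stack([
        chain_vectors(f, table, topology.anchor_orient) for f in window
    ])  # (n_frames, n_mol, 3)
    descriptor = slopes if mode == "slopes" else axis_angles
    if averaging == "mean_vector":
        aligned = _sign_align(per_frame, per_frame[0][None, :, :])
        mean_v = aligned.mean(axis=0)
        if np.any(np.linalg.norm(mean_v, axis=1) == 0):
            raise ValueError("mean chain vector vanished during averaging")
        values = descriptor(mean_v)
    else:
        values = np.stack([descriptor(v) for v in per_frame]).mean(axis=0)
    cols = (["Bxy", "Byz", "Bzx"] if mode == "slopes"
            else ["alpha_x", "alpha_y", "alpha_z"])
    df = pd.DataFrame(values, columns=cols)
    df.insert(0, "molecule_id", np.arange(table.n_molecules))
    df["n_frames"] = len(window)
    df.attrs["mode"] = mode
    return df


@dataclass
class Crystallite:
    """A labelled set of co-oriented molecules.

    ``crystallite_id`` is 1-based by descending size; the disordered
    pool carries id -1 and ``is_disordered_pool=True``.
    """

    crystallite_id: int
    member_molecule_ids: np.ndarray
    centroid_descriptor: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    is_disordered_pool: bool = False

    @property
    def size(self) -> int:
        return len(self.member_molecule_ids)


def _wrapped_distance_matrix(angles: np.ndarray, period: float) -> np.ndarray:
    """Pairwise Euclidean distance with each component periodic."""
    d = np.abs(angles[:, None, :] - angles[None, :, :])
    d = np.minimum(d, period - d)
    return np.sqrt((d ** 2).sum(axis=2))


def _circular_mean(angles: np.ndarray, period: float) -> np.ndarray:
    """Componentwise mean of angles living on a circle of given period."""
    scale = 2 * np.pi / period
    mean = np.arctan2(np.sin(angles * scale).mean(axis=0),
                      np.cos(angles * scale).mean(axis=0)) / scale
    # fold into (-period/2, period/2]
    mean = np.where(mean <= -period / 2, mean + period, mean)
    return mean


def cluster_orientations(descriptors: pd.DataFrame,
                         eps_deg: float = 5.0,
                         min_cluster_size: int = 5,
                         mode: str | None = None) -> list[Crystallite]:
    """Density-cluster orientation descriptors into crystallites.

    Uses DBSCAN on a wrap-aware metric: for slope descriptors each
    component distance is taken modulo pi (slopes identify v and -v, so
    they live on a half-turn circle); axis-angle descriptors are used
    as-is (they are computed from hemisphere-aligned vectors).  Points
    in no cluster form the disordered pool (id -1).  Clusters are
    sorted by size descending and labelled 1..K.
    """
    if eps_deg <= 0:
        raise ValueError("eps_deg must be positive")
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be at least 2")
    mode = mode or descriptors.attrs.get("mode", "slopes")
    cols = (["Bxy", "Byz", "Bzx"] if mode == "slopes"
            else ["alpha_x", "alpha_y", "alpha_z"])
    angles = descriptors[cols].to_numpy()
    mol_ids = descriptors["molecule_id"].to_numpy()
    if len(angles) < min_cluster_size:
        raise ValueError("fewer molecules than min_cluster_size")
    eps = np.deg2rad(eps_deg)
    if mode == "slopes":
        dist = _wrapped_distance_matrix(angles, np.pi)
    else:
        dist = _wrapped_distance_matrix(angles, 2 * np.pi)
    labels = DBSCAN(eps=eps, min_samples=min_cluster_size,
                    metric="precomputed").fit_predict(dist)

    crystallites: list[Crystallite] = []
    cluster_ids = sorted(set(labels) - {-1},
                         key=lambda c: (-(labels == c).sum(), c))
    for new_id, c in enumerate(cluster_ids, start=1):
        members = mol_ids[labels == c]
        centroid = _circular_mean(angles[labels == c],
                                  np.pi if mode == "slopes" else 2 * np.pi)
        crystallites.append(Crystallite(new_id, np.sort(members), centroid))
    pool = mol_ids[labels == -1]
    crystallites.append(Crystallite(-1, np.sort(pool), is_disordered_pool=True))
    logger.info("segmentation: %d crystallites, %d disordered of %d molecules",
                len(crystallites) - 1, len(pool), len(mol_ids))
    return crystallites


def segment(window: TrajectoryWindow, table: MoleculeTable,
            topology: ChainTopology | None = None,
            mode: str = "slopes", eps_deg: float = 5.0,
            min_cluster_size: int = 5,
            averaging: str = "mean_vector",
            ) -> tuple[list[Crystallite], pd.DataFrame]:
    """Full segmentation: descriptors, time average, clustering.

    In ``axis_angles`` mode the chain vectors are first sign-aligned to
    a global reference hemisphere (the dominant direction), since
    axis angles map v -> -v to pi - alpha.
    """
    topology = topology or ChainTopology()
    if mode == "axis_angles":
        per_frame = np.stack([
            chain_vectors(f, table, topology.anchor_orient) for f in window])
        aligned = _sign_align(per_frame, per_frame[0][None, :, :])
        mean_v = aligned.mean(axis=0)
        # global hemisphere: align every molecule's mean vector to the
        # dominant direction (largest-|component| axis of the mean of means)
        ref = mean_v.sum(axis=0)
        if np.linalg.norm(ref) == 0:
            ref = np.array([0.0, 0.0, 1.0])
        mean_v = _sign_align(mean_v, ref[None, :])
        values = axis_angles(mean_v)
        desc = pd.DataFrame(values, columns=["alpha_x", "alpha_y", "alpha_z"])
        desc.insert(0, "molecule_id", np.arange(table.n_molecules))
        desc["n_frames"] = len(window)
        desc.attrs["mode"] = "axis_angles"
    else:
        desc = time_average_descriptors(window, table, topology,
                                        mode=mode, averaging=averaging)
    return cluster_orientations(desc, eps_deg, min_cluster_size, mode=mode), desc
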