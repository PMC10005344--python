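"""Synthetic crystallites with known ground truth.

The generator plants all-trans zigzag chains on a 2D lattice (area per
molecule 0.195 nm^2 by default, the initial packing of rotator-phase
alkane lattices), tilts them by a prescribed angle about a chosen
azimuth, rotates each chain about its long axis by a setting-angle
pattern (uniform, herringbone or random), adds noise, and finally
applies an arbitrary rigid rotation + translation.  Three independent
noise channels emulate distinct kinds of disorder: ``noise_sigma``
displaces whole molecules rigidly from their lattice sites (positional
disorder, orientations untouched), ``angular_noise_deg`` wobbles each
chain axis (orientational disorder), and ``atom_noise_sigma`` jitters
individual atoms (thermal conformational motion).
Every generated quantity (eigenplane, tilts, lattice spacings, setting
angles, crystallite labels, periodic image shifts) is recorded as
ground truth, so each analysis stage can be verified by round trip.

What the generator does *not* emulate: thermal chain conformations
(gauche defects), realistic dynamics, surfactant heads or water.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from quasicryst.model_io import (MoleculeTable, SimulationBox, SnapshotFrame,
                                 TrajectoryWindow, ANGSTROM_PER_NM)

CARBON_MASS = 12.011
#: standard all-trans alkane backbone geometry: rise per carbon along the
#: chain axis and half-amplitude of the planar zigzag (nm)
DEFAULT_RISE = 0.127
DEFAULT_ZIG_OFFSET = 0.044


@dataclass(frozen=True)
class CrystalliteSpec:
    """Construction parameters of one synthetic crystallite."""

    lattice: str = "hexagonal"  # hexagonal | distorted_hexagonal | rectangular
    area_per_molecule: float = 0.195  # nm^2
    n_a: int = 10
    n_b: int = 10
    chain_length: int = 16
    rise: float = DEFAULT_RISE
    zig_offset: float = DEFAULT_ZIG_OFFSET
    tilt_deg: float = 0.0
    tilt_azimuth_deg: float = 0.0
    setting_pattern: tuple = ("uniform", 0.0)
    noise_sigma: float = 0.0  # nm, rigid per-molecule site displacement
    angular_noise_deg: float = 0.0  # per-molecule chain-axis wobble
    atom_noise_sigma: float = 0.0  # nm, independent per-atom jitter
    rotation: tuple[float, float, float] | None = None  # intrinsic zyx Euler, deg
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    distortion: float = 1.08  # lattice-vector scaling for distorted_hexagonal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_per_molecule <= 0:
            raise ValueError("area_per_molecule must be positive")
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("lattice counts must be at least 2")
        if not (0 <= self.tilt_deg < 90):
            raise ValueError("tilt_deg must lie in [0, 90)")
        if min(self.noise_sigma, self.angular_noise_deg,
               self.atom_noise_sigma) < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.lattice not in ("hexagonal", "distorted_hexagonal", "rectangular"):
            raise ValueError(f"unknown lattice {self.lattice!r}")


@dataclass
class GroundTruth:
    """Exact construction values recorded before noise."""

    plane_normal: np.ndarray
    plane_d: float
    tilt_deg: np.ndarray
    spacings: tuple[float, ...]
    setting_angles_deg: np.ndarray
    labels: np.ndarray
    image_shifts: np.ndarray | None = None  # integer box multiples (n_mol, 3)
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))


def hexagonal_spacing(area: float) -> float:
    """Lattice constant of a hexagonal lattice with the given cell area."""
    return float(np.sqrt(2.0 * area / np.sqrt(3.0)))


def _euler_matrix(angles_deg: Sequence[float]) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("zyx", angles_deg, degrees=True).as_matrix()


def _rot_z(angle_deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _tilt_matrix(tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    """Rotation tilting the z axis by tilt_deg toward the azimuth direction."""
    phi = np.deg2rad(azimuth_deg)
    axis = np.array([-np.sin(phi), np.cos(phi), 0.0])
    t = np.deg2rad(tilt_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def _chain_template(n: int, rise: float, zig: float) -> np.ndarray:
    """All-trans zigzag extended along z, zigzag in the xz plane, centered."""
    i = np.arange(n)
    x = np.where(i % 2 == 0, zig / 2.0, -zig / 2.0)
    z = (i - (n - 1) / 2.0) * rise
    return np.column_stack([x, np.zeros(n), z])


def _lattice_sites(spec: CrystalliteSpec) -> tuple[np.ndarray, np.ndarray, tuple[float, ...]]:
    """Lattice sites (centered), (i+j) parity per site, neighbor spacings."""
    A = spec.area_per_molecule
    if spec.lattice == "rectangular":
        a = float(np.sqrt(A))
        a1, a2 = np.array([a, 0.0, 0.0]), np.array([0.0, a, 0.0])
        spacings: tuple[float, ...] = (a,)
    else:
        a = hexagonal_spacing(A)
        a1 = np.array([a, 0.0, 0.0])
        a2 = np.array([a / 2.0, a * np.sqrt(3.0) / 2.0, 0.0])
        if spec.lattice == "distorted_hexagonal":
            a2 = a2 * np.array([1.0, spec.distortion, 1.0])
            spacings = (a, float(np.linalg.norm(a2)))
        else:
            spacings = (a,)
    if min(np.linalg.norm(a1), np.linalg.norm(a2)) < 0.1:
        raise ValueError("lattice spacing below 0.1 nm: chains would overlap")
    ii, jj = np.meshgrid(np.arange(spec.n_a), np.arange(spec.n_b), indexing="ij")
    sites = ii[..., None] * a1 + jj[..., None] * a2
    sites = sites.reshape(-1, 3)
    parity = ((ii + jj) % 2).reshape(-1)
    return sites - sites.mean(axis=0), parity, spacings


def _setting_angles(spec: CrystalliteSpec, parity: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    kind = spec.setting_pattern[0]
    n = len(parity)
    if kind == "uniform":
        return np.full(n, float(spec.setting_pattern[1]))
    if kind == "herringbone":
        a1, a2 = float(spec.setting_pattern[1]), float(spec.setting_pattern[2])
        return np.where(parity == 0, a1, a2)
    if kind == "random":
        return rng.uniform(0.0, 180.0, n)
    raise ValueError(f"unknown setting pattern {kind!r}")


def _default_box(coords: np.ndarray, margin: float = 2.0) -> SimulationBox:
    span = np.ptp(coords, axis=0) + 2 * margin
    return SimulationBox(*np.maximum(span, 1.0))


def generate_crystallite(spec: CrystalliteSpec,
                         box: SimulationBox | None = None,
                         ) -> tuple[SnapshotFrame, MoleculeTable, GroundTruth]:
    """Build one crystallite frame with its molecule table and ground truth."""
    rng = np.random.default_rng(spec.seed)
    sites, parity, spacings = _lattice_sites(spec)
    n_mol = len(sites)
    template = _chain_template(spec.chain_length, spec.rise, spec.zig_offset)
    setting = _setting_angles(spec, parity, rng)
    T = _tilt_matrix(spec.tilt_deg, spec.tilt_azimuth_deg)
    Rg = _euler_matrix(spec.rotation) if spec.rotation is not None else np.eye(3)
    tr = np.asarray(spec.translation, float)

    coords = np.empty((n_mol * spec.chain_length, 3))
    mid_ideal = np.empty((n_mol, 3))
    site_noise = (rng.normal(0.0, spec.noise_sigma, (n_mol, 3))
                  if spec.noise_sigma > 0 else np.zeros((n_mol, 3)))
    for m in range(n_mol):
        local = (T @ _rot_z(setting[m]) @ template.T).T
        chain_global = (local + sites[m]) @ Rg.T + tr
        mid_ideal[m] = chain_global[7] if spec.chain_length >= 8 else chain_global[-1]
        if spec.angular_noise_deg > 0:
            # chain-axis wobble: small rotation about a random in-plane
            # axis, pivoting about the lattice site
            phi = rng.uniform(0.0, 360.0)
            delta = rng.normal(0.0, spec.angular_noise_deg)
            W = _tilt_matrix(delta, phi)
            local = (W @ local.T).T
            chain_global = (local + sites[m]) @ Rg.T + tr
        coords[m * spec.chain_length:(m + 1) * spec.chain_length] = (
            chain_global + site_noise[m] @ Rg.T)
    normal = Rg @ np.array([0.0, 0.0, 1.0])
    truth = GroundTruth(
        plane_normal=normal,
        plane_d=float(normal @ mid_ideal.mean(axis=0)),
        tilt_deg=np.full(n_mol, spec.tilt_deg),
        spacings=spacings,
        setting_angles_deg=setting % 180.0,
        labels=np.zeros(n_mol, dtype=int),
        rotation=Rg,
    )
    if spec.atom_noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.atom_noise_sigma, coords.shape)

    atom_indices = np.arange(n_mol * spec.chain_length).reshape(n_mol, spec.chain_length)
    table = MoleculeTable(atom_indices,
                          np.full((n_mol, spec.chain_length), CARBON_MASS),
                          [f"HEX{m + 1}" for m in range(n_mol)])
    frame = SnapshotFrame(time=0.0, coords=coords,
                          box=box or _default_box(coords))
    return frame, table, truth


def generate_disordered(n_molecules: int, box: SimulationBox, seed: int = 0,
                        chain_length: int = 16, rise: float = DEFAULT_RISE,
                        zig_offset: float = DEFAULT_ZIG_OFFSET,
                        ) -> tuple[SnapshotFrame, MoleculeTable]:
    """Chains with uniformly random orientations and positions in the box.

    Emulates the molecules of the melt remainder that belong to no
    ordered domain.
    """
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    template = _chain_template(chain_length, rise, zig_offset)
    coords = np.empty((n_molecules * chain_length, 3))
    for m in range(n_molecules):
        R = Rotation.random(random_state=rng).as_matrix()
        pos = rng.uniform(0.0, 1.0, 3) * box.lengths
        coords[m * chain_length:(m + 1) * chain_length] = template @ R.T + pos
    atom_indices = np.arange(n_molecules * chain_length).reshape(
        n_molecules, chain_length)
    table = MoleculeTable(atom_indices,
                          np.full((n_molecules, chain_length), CARBON_MASS),
                          [f"DIS{m + 1}" for m in range(n_molecules)])
    return SnapshotFrame(time=0.0, coords=coords, box=box), table


def generate_polycrystal_frame(specs: Sequence[CrystalliteSpec],
                               box: SimulationBox,
                               wrap: bool = False,
                               n_disordered: int = 0,
                               disordered_seed: int = 1234,
                               ) -> tuple[SnapshotFrame, MoleculeTable, GroundTruth]:
    """Assemble several crystallites in one box, optionally PBC-wrapped.

    Crystallites keep their own rigid rotations/translations (which
    must place them inside the box if ``wrap`` is requested).  With
    ``wrap=True`` whole molecules whose COM falls outside [0, L) are
    shifted by integer box multiples, and the true shifts are recorded
    per molecule for reconstruction round-trip tests.
    ``n_disordered`` randomly oriented chains are appended with label
    -1 in the ground truth.
    """
    frames, tables, truths = zip(*(generate_crystallite(s, box=box) for s in specs))
    frames, tables, truths = list(frames), list(tables), list(truths)
    if n_disordered > 0:
        dframe, dtable = generate_disordered(n_disordered, box,
                                             seed=disordered_seed)
        frames.append(dframe)
        tables.append(dtable)
    offsets = np.cumsum([0] + [t.atom_indices.size for t in tables[:-1]])
    coords = np.concatenate([f.coords for f in frames])
    atom_indices = np.concatenate(
        [t.atom_indices + off for t, off in zip(tables, offsets)])
    masses = np.concatenate([t.masses for t in tables])
    labels = []
    for c, t in enumerate(tables):
        labels.extend(f"HEX{c}:{lab}" for lab in t.labels)
    table = MoleculeTable(atom_indices, masses, labels)
    n_mol = table.n_molecules
    crystallite_of = np.concatenate(
        [np.full(t.n_molecules, c if c < len(specs) else -1)
         for c, t in enumerate(tables)])

    span = np.ptp(coords, axis=0)
    if np.any(span > box.lengths) and wrap:
        raise ValueError("crystallites do not fit in the box for wrapping")

    shifts = np.zeros((n_mol, 3), dtype=int)
    if wrap:
        masses_sum = table.masses.sum(axis=1)
        com = (coords[table.atom_indices] * table.masses[..., None]
               ).sum(axis=1) / masses_sum[:, None]
        shifts = -np.floor(com / box.lengths).astype(int)
        for m in range(n_mol):
            coords[table.atom_indices[m]] += shifts[m] * box.lengths
    n_dis = n_mol - sum(t.tilt_deg.size for t in truths)
    truth = GroundTruth(
        plane_normal=truths[0].plane_normal, plane_d=truths[0].plane_d,
        tilt_deg=np.concatenate([t.tilt_deg for t in truths]
                                + [np.full(n_dis, np.nan)]),
        spacings=truths[0].spacings,
        setting_angles_deg=np.concatenate(
            [t.setting_angles_deg for t in truths] + [np.full(n_dis, np.nan)]),
        labels=crystallite_of,
        image_shifts=shifts,
        rotation=truths[0].rotation,
    )
    return SnapshotFrame(time=0.0, coords=coords, box=box), table, truth


def generate_trajectory(spec: CrystalliteSpec, n_frames: int,
                        frame_noise_sigma: float = 0.0,
                        noise_kind: str = "site",
                        seed: int | None = None,
                        dt: float = 1.0,
                        ) -> tuple[TrajectoryWindow, MoleculeTable, GroundTruth]:
    """Trajectory of independently noised frames about one ground truth.

    Each frame draws fresh Gaussian noise of width ``frame_noise_sigma``
    (nm): ``noise_kind="site"`` displaces whole molecules rigidly
    (lattice positional disorder, leaves orientations exact) while
    ``"atom"`` jitters every atom independently (thermal conformational
    motion).  Timestamps are 0, dt, 2*dt, ... ps.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be at least 1")
    if noise_kind not in ("site", "atom"):
        raise ValueError(f"unknown noise_kind {noise_kind!r}")
    base_spec = replace(spec, noise_sigma=0.0, atom_noise_sigma=0.0)
    frame0, table, truth = generate_crystallite(base_spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    for t in range(n_frames):
        coords = frame0.coords.copy()
        if frame_noise_sigma > 0:
            if noise_kind == "atom":
                coords += rng.normal(0.0, frame_noise_sigma, coords.shape)
            else:
                disp = rng.normal(0.0, frame_noise_sigma,
                                  (table.n_molecules, 3))
                for m in range(table.n_molecules):
                    coords[table.atom_indices[m]] += disp[m]
        frames.append(SnapshotFrame(time=t * dt, coords=coords,
                                    box=frame0.box))
    window = TrajectoryWindow(frames=frames, t_start=0.0,
                              t_end=(n_frames - 1) * dt)
    return window, table, truth


# ---------------------------------------------------------------------------
# structure / trajectory export (via MDAnalysis)

def _as_universe(frame: SnapshotFrame, table: MoleculeTable):
    import MDAnalysis as mda

    n_atoms = frame.coords.shape[0]
    n_res = table.n_molecules
    resindex = np.zeros(n_atoms, dtype=int)
    names = np.array(["X"] * n_atoms, dtype=object)
    for m in range(n_res):
        resindex[table.atom_indices[m]] = m
        for p, idx in enumerate(table.atom_indices[m], start=1):
            names[idx] = f"C{p}"
    u = mda.Universe.empty(n_atoms, n_residues=n_res, atom_resindex=resindex,
                           trajectory=True)
    u.add_TopologyAttr("names", names.tolist())
    u.add_TopologyAttr("resnames", ["HEX"] * n_res)
    u.add_TopologyAttr("resids", list(range(1, n_res + 1)))
    u.atoms.positions = frame.coords * ANGSTROM_PER_NM
    u.dimensions = [frame.box.lx * ANGSTROM_PER_NM,
                    frame.box.ly * ANGSTROM_PER_NM,
                    frame.box.lz * ANGSTROM_PER_NM, 90.0, 90.0, 90.0]
    return u


def write_gro(frame: SnapshotFrame, table: MoleculeTable, path: str | Path) -> None:
    """Write one frame as a GRO structure (nm, box on the last line)."""
    _as_universe(frame, table).atoms.write(str(path))


def write_xyz_trajectory(window: TrajectoryWindow, table: MoleculeTable,
                         path: str | Path,
                         box_sidecar: str | Path | None = None) -> None:
    """Write a multi-frame XYZ trajectory plus an optional box sidecar.

    XYZ carries no box; the sidecar is a text file with the three box
    edges in nm, accepted by :func:`quasicryst.model_io.load_trajectory`.
    """
    import MDAnalysis as mda

    u = _as_universe(window.frames[0], table)
    with mda.Writer(str(path), u.atoms.n_atoms) as w:
        for f in window.frames:
            u.atoms.positions = f.coords * ANGSTROM_PER_NM
            u.trajectory.ts.time = f.time
            w.write(u.atoms)
    if box_sidecar is not None:
        box = window.frames[0].box
        Path(box_sidecar).write_text(f"{box.lx} {box.ly} {box.lz}\n")
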