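"""Structure/trajectory input, chain-anchor resolution and centers of mass.

All coordinates are handled in nanometers and times in picoseconds
internally, regardless of the units of the input format (MDAnalysis
reads in angstroms; converted on load).  Chain positions are 1-based to
match the conventional C1...C16 numbering of alkane backbones; molecule
ids are 0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

ANGSTROM_PER_NM = 10.0

#: fallback atomic masses (amu) when the topology carries none
_ELEMENT_MASSES = {
    "C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "S": 32.06,
    "P": 30.974,
}


@dataclass(frozen=True)
class ChainTopology:
    """Which atoms anchor each quasilinear molecule's analysis vectors.

    Parameters
    ----------
    residue_selector:
        MDAnalysis selection string identifying the quasilinear
        molecules (e.g. ``"resname HEX"``).  Residues matching the
        selection must each contain all ``backbone_atoms``.
    backbone_atoms:
        Ordered atom names along the chain; position in this list is
        the 1-based chain position.
    anchor_orient:
        Pair of chain positions spanning the orientation vector used
        for crystallite segmentation (default C3 -> C14).
    anchor_tilt:
        Pair of chain positions spanning the long-axis vector used for
        tilt angles and plane intersections (default C3 -> C13; for an
        all-trans chain this vector is parallel to the long axis).
    mid_atom:
        Chain position of the mid-chain atom used for eigenplane
        fitting (default C8).
    """

    residue_selector: str = "resname HEX"
    backbone_atoms: tuple[str, ...] = tuple(f"C{i}" for i in range(1, 17))
    anchor_orient: tuple[int, int] = (3, 14)
    anchor_tilt: tuple[int, int] = (3, 13)
    mid_atom: int = 8

    def __post_init__(self) -> None:
        if not self.backbone_atoms:
            raise ValueError("backbone_atoms must be non-empty")
        n = len(self.backbone_atoms)
        for name, pair in (("anchor_orient", self.anchor_orient),
                           ("anchor_tilt", self.anchor_tilt)):
            a, b = pair
            if not (1 <= a <= n and 1 <= b <= n):
                raise ValueError(f"{name} positions {pair} outside chain of length {n}")
            if a >= b:
                raise ValueError(f"{name} positions must be distinct and ascending: {pair}")
        if not (1 <= self.mid_atom <= n):
            raise ValueError(f"mid_atom {self.mid_atom} outside chain of length {n}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ChainTopology":
        """Load a topology config from YAML.

        Recognized keys: ``residue_selector``, ``backbone_atoms``,
        ``anchor_orient``, ``anchor_tilt``, ``mid_atom``.
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        kwargs = {}
        if "residue_selector" in cfg:
            kwargs["residue_selector"] = str(cfg["residue_selector"])
        if "backbone_atoms" in cfg:
            kwargs["backbone_atoms"] = tuple(cfg["backbone_atoms"])
        for key in ("anchor_orient", "anchor_tilt"):
            if key in cfg:
                kwargs[key] = tuple(int(x) for x in cfg[key])
        if "mid_atom" in cfg:
            kwargs["mid_atom"] = int(cfg["mid_atom"])
        return cls(**kwargs)


@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic periodic box, edge lengths in nm."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.lz) <= 0:
            raise ValueError(f"box edges must be positive, got {self}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])

    def length(self, direction: str) -> float:
        return float(self.lengths["xyz".index(direction)])


@dataclass
class SnapshotFrame:
    """One trajectory frame: time (ps), per-atom coordinates (nm), box."""

    time: float
    coords: np.ndarray
    box: SimulationBox

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if self.time < 0:
            raise ValueError("frame time must be non-negative")


@dataclass
class TrajectoryWindow:
    """Time-ordered sequence of frames inside [t_start, t_end]."""

    frames: list[SnapshotFrame]
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        if self.t_start > self.t_end:
            raise ValueError("t_start must not exceed t_end")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class MoleculeTable:
    """Resolved mapping from molecules to atoms.

    Attributes
    ----------
    atom_indices:
        integer array of shape (n_molecules, chain_length); entry
        ``[m, p-1]`` is the global atom index of chain position ``p``
        of molecule ``m``.  Molecule ids are the row numbers.
    masses:
        array (n_molecules, chain_length) of atomic masses in amu.
    labels:
        free-form per-molecule label (e.g. resname/resid), for reports.
    """

    atom_indices: np.ndarray
    masses: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.atom_indices.shape != self.masses.shape:
            raise ValueError("atom_indices and masses must have the same shape")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if not self.labels:
            self.labels = [f"mol{m}" for m in range(self.n_molecules)]

    @property
    def n_molecules(self) -> int:
        return self.atom_indices.shape[0]

    @property
    def chain_length(self) -> int:
        return self.atom_indices.shape[1]

    def position_indices(self, chain_position: int) -> np.ndarray:
        """Global atom indices of a 1-based chain position, per molecule."""
        return self.atom_indices[:, chain_position - 1]

    def subset(self, molecule_ids: Sequence[int]) -> "MoleculeTable":
        ids = np.asarray(molecule_ids, dtype=int)
        return MoleculeTable(
            self.atom_indices[ids], self.masses[ids],
            [self.labels[i] for i in ids],
        )


def _universe(structure_path: str | Path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(structure_path))


def _guess_masses(atoms) -> np.ndarray:
    masses = np.asarray(getattr(atoms, "masses", np.zeros(len(atoms))), dtype=float)
    if np.all(masses > 0):
        return masses
    out = masses.copy()
    for i, name in enumerate(atoms.names):
        if out[i] <= 0:
            el = name.strip()[0].upper()
            out[i] = _ELEMENT_MASSES.get(el, 12.011)
    return out


def resolve_molecules(universe, topology: ChainTopology) -> MoleculeTable:
    """Resolve chain positions to atom indices for every selected residue."""
    sel = universe.select_atoms(topology.residue_selector)
    residues = sel.residues
    if len(residues) == 0:
        raise ValueError(
            f"selector {topology.residue_selector!r} matched zero molecules")
    rows, mass_rows, labels = [], [], []
    for res in residues:
        names = list(res.atoms.names)
        row = []
        for atom_name in topology.backbone_atoms:
            hits = [i for i, n in enumerate(names) if n == atom_name]
            if len(hits) != 1:
                raise ValueError(
                    f"residue {res.resname}{res.resid}: expected exactly one "
                    f"atom named {atom_name!r}, found {len(hits)}")
            row.append(res.atoms.indices[hits[0]])
        rows.append(row)
        mass_rows.append(_guess_masses(res.atoms)[[names.index(a) for a in topology.backbone_atoms]])
        labels.append(f"{res.resname}{res.resid}")
    return MoleculeTable(np.array(rows), np.array(mass_rows), labels)


def load_structure(structure_path: str | Path,
                   topology: ChainTopology | None = None) -> MoleculeTable:
    """Read a GRO/PDB structure and resolve the chain topology.

    Returns a :class:`MoleculeTable` with stable 0-based molecule ids in
    residue order.
    """
    topology = topology or ChainTopology()
    return resolve_molecules(_universe(structure_path), topology)


def _box_from_dimensions(dimensions) -> SimulationBox:
    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        raise ValueError("trajectory frame carries no box information")
    lx, ly, lz = np.asarray(dimensions[:3], dtype=float) / ANGSTROM_PER_NM
    angles = np.asarray(dimensions[3:6], dtype=float)
    if angles.size and not np.allclose(angles, 90.0, atol=1e-3):
        logger.warning(
            "triclinic box (angles %s) reduced to its orthorhombic diagonal",
            angles)
    return SimulationBox(lx, ly, lz)


def make_molecules_whole(coords: np.ndarray, table: MoleculeTable,
                         box: SimulationBox) -> np.ndarray:
    """Unwrap each molecule to the periodic image nearest its first atom.

    The analyses assume whole molecules; trajectory writers often wrap
    atoms independently into the primary box.
    """
    out = coords.copy()
    L = box.lengths
    for m in range(table.n_molecules):
        idx = table.atom_indices[m]
        ref = out[idx[0]]
        delta = out[idx] - ref
        out[idx] -= np.round(delta / L) * L
    return out


def _read_box_sidecar(path: Path) -> SimulationBox:
    vals = [float(x) for x in path.read_text().split()]
    if len(vals) != 3:
        raise ValueError(f"box sidecar {path} must contain exactly 3 floats (nm)")
    return SimulationBox(*vals)


def load_trajectory(traj_path: str | Path,
                    structure_path: str | Path,
                    topology: ChainTopology | None = None,
                    t_start: float = 0.0,
                    t_end: float = np.inf,
                    stride: int = 1,
                    box_sidecar: str | Path | None = None,
                    make_whole: bool = True,
                    ) -> tuple[TrajectoryWindow, MoleculeTable]:
    """Read a trajectory window (XTC/TRR/DCD/multi-frame XYZ).

    Frames with time in ``[t_start, t_end]`` are retained at the given
    stride (stride counts retained frames).  XYZ trajectories carry no
    box; supply ``box_sidecar``, a text file with three floats (nm).
    Molecules are made whole on load unless ``make_whole=False``.
    """
    import MDAnalysis as mda

    topology = topology or ChainTopology()
    if stride < 1:
        raise ValueError("stride must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        uni = mda.Universe(str(structure_path), str(traj_path))
    table = resolve_molecules(uni, topology)
    sidecar_box = _read_box_sidecar(Path(box_sidecar)) if box_sidecar else None

    frames: list[SnapshotFrame] = []
    kept = 0
    for ts in uni.trajectory:
        t = float(ts.time)
        if t < t_start or t > t_end:
            continue
        if kept % stride == 0:
            if sidecar_box is not None:
                box = sidecar_box
            else:
                box = _box_from_dimensions(ts.dimensions)
            coords = np.asarray(ts.positions, dtype=float) / ANGSTROM_PER_NM
            if make_whole:
                coords = make_molecules_whole(coords, table, box)
            frames.append(SnapshotFrame(time=t, coords=coords, box=box))
        kept += 1
    if not frames:
        raise ValueError(
            f"no frames in window [{t_start}, {t_end}] ps of {traj_path}")
    window = TrajectoryWindow(frames=frames, t_start=t_start,
                              t_end=min(t_end, frames[-1].time))
    return window, table


def molecule_com(frame: SnapshotFrame, table: MoleculeTable,
                 molecule_ids: Sequence[int] | None = None) -> np.ndarray:
    """Mass-weighted centers of mass, shape (n_molecules, 3), in nm.

    No periodic re-wrapping is applied inside a molecule; molecules are
    assumed whole (see :func:`make_molecules_whole`).
    """
    idx = table.atom_indices
    masses = table.masses
    if molecule_ids is not None:
        ids = np.asarray(molecule_ids, dtype=int)
        idx, masses = idx[ids], masses[ids]
    total = masses.sum(axis=1)
    if np.any(total <= 0):
        raise ValueError("molecule with non-positive total mass")
    pos = frame.coords[idx]  # (n_mol, chain_len, 3)
    return (pos * masses[:, :, None]).sum(axis=1) / total[:, None]


def write_csv(df, path: str | Path) -> None:
    """Write a DataFrame as UTF-8 CSV with a header row."""
    df.to_csv(path, index=False, encoding="utf-8")
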