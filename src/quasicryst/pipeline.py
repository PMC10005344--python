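"""End-to-end orchestration: segment -> reconstruct -> tilt -> packing -> P2.

One YAML config drives the whole chain; every stage writes plain CSV /
JSON artifacts per crystallite, and a manifest records a checksum of
every output so a rerun with the same config and seed can be verified
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from quasicryst import __version__
from quasicryst.eigenplane import crystallite_tilt, tilt_statistics
from quasicryst.model_io import (ChainTopology, MoleculeTable, SnapshotFrame,
                                 TrajectoryWindow, load_trajectory,
                                 molecule_com, write_csv)
from quasicryst.orientation import orientation_field
from quasicryst.packing import (com_rdf, neighbor_distance_histogram,
                                plane_line_intersection, to_plane_2d,
                                voronoi_tessellate)
from quasicryst.pbc import reconstruct_crystallite
from quasicryst.segmentation import chain_vectors, segment

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    structure: str
    trajectory: str
    outdir: str
    topology: ChainTopology = field(default_factory=ChainTopology)
    t_start: float = 0.0
    t_end: float = float("inf")
    stride: int = 1
    box_sidecar: str | None = None
    mode: str = "slopes"
    eps_deg: float = 5.0
    min_size: int = 5
    averaging: str = "mean_vector"
    direction: str = "auto"
    void_threshold: float | None = None
    per_frame_plane: bool = False
    rdf_bin_width: float = 0.01
    hist_bin_width: float = 0.005
    p2_every: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        topo_cfg = cfg.pop("topology", None)
        if isinstance(topo_cfg, str):
            topology = ChainTopology.from_yaml(topo_cfg)
        elif isinstance(topo_cfg, dict):
            tmp = Path(path).parent / "__inline_topology__"
            topology = ChainTopology(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in topo_cfg.items()})
        else:
            topology = ChainTopology()
        window = cfg.pop("window", {})
        seg = cfg.pop("segmentation", {})
        rec = cfg.pop("reconstruction", {})
        ana = cfg.pop("analysis", {})
        return cls(
            structure=cfg["structure"], trajectory=cfg["trajectory"],
            outdir=cfg.get("outdir", "quasicryst_out"),
            topology=topology,
            t_start=float(window.get("t_start", 0.0)),
            t_end=float(window.get("t_end", np.inf)),
            stride=int(window.get("stride", 1)),
            box_sidecar=cfg.get("box_sidecar"),
            mode=seg.get("mode", "slopes"),
            eps_deg=float(seg.get("eps_deg", 5.0)),
            min_size=int(seg.get("min_size", 5)),
            averaging=seg.get("averaging", "mean_vector"),
            direction=rec.get("direction", "auto"),
            void_threshold=rec.get("void_threshold"),
            per_frame_plane=bool(ana.get("per_frame_plane", False)),
            rdf_bin_width=float(ana.get("rdf_bin_width", 0.01)),
            hist_bin_width=float(ana.get("hist_bin_width", 0.005)),
            p2_every=int(ana.get("p2_every", 1)),
            seed=int(cfg.get("seed", 0)),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _reconstructed_window(window: TrajectoryWindow, table: MoleculeTable,
                          members: np.ndarray, cfg: RunConfig,
                          ) -> tuple[TrajectoryWindow, pd.DataFrame]:
    frames, log_rows = [], []
    for f in window:
        coords, report = reconstruct_crystallite(
            f, table, members, cfg.topology, direction=cfg.direction,
            void_threshold=cfg.void_threshold)
        frames.append(SnapshotFrame(time=f.time, coords=coords, box=f.box))
        for slab_index, k in enumerate(np.atleast_1d(report.shifts)):
            log_rows.append((f.time, slab_index, int(k), report.direction))
    log = pd.DataFrame(log_rows,
                       columns=["frame_time", "slab_index", "k", "direction"])
    return TrajectoryWindow(frames=frames, t_start=window.t_start,
                            t_end=window.t_end), log


def analyze_crystallite(window: TrajectoryWindow, table: MoleculeTable,
                        members: np.ndarray, cfg: RunConfig,
                        outdir: Path) -> None:
    """Run reconstruction + all per-crystallite analyses into ``outdir``."""
    outdir.mkdir(parents=True, exist_ok=True)
    members = np.asarray(members, int)
    rec_window, shift_log = _reconstructed_window(window, table, members, cfg)
    write_csv(shift_log, outdir / "image_shifts.csv")

    # eigenplane + tilt
    records, plane = crystallite_tilt(rec_window, table, members,
                                      cfg.topology,
                                      per_frame_plane=cfg.per_frame_plane)
    static_plane = plane[-1] if isinstance(plane, list) else plane
    (outdir / "plane.json").write_text(json.dumps({
        "a": static_plane.normal[0], "b": static_plane.normal[1],
        "c": static_plane.normal[2], "d": static_plane.d}, indent=1))
    write_csv(records, outdir / "tilt.csv")
    stats = tilt_statistics(records)
    write_csv(stats.per_molecule, outdir / "tilt_per_molecule.csv")
    write_csv(stats.per_frame, outdir / "tilt_per_frame.csv")

    # Voronoi packing on plane intersections
    sub = table.subset(members)
    a, b = cfg.topology.anchor_tilt
    cells_per_frame = []
    for f in rec_window:
        pts3, _ = plane_line_intersection(
            f.coords[sub.position_indices(a)],
            f.coords[sub.position_indices(b)], static_plane)
        pts2 = to_plane_2d(pts3, static_plane)
        cells_per_frame.append(voronoi_tessellate(pts2, members))
    last_cells = cells_per_frame[-1]
    last_pts = to_plane_2d(plane_line_intersection(
        rec_window.frames[-1].coords[sub.position_indices(a)],
        rec_window.frames[-1].coords[sub.position_indices(b)],
        static_plane)[0], static_plane)
    write_csv(pd.DataFrame({
        "molecule_id": [c.molecule_id for c in last_cells],
        "x2d": last_pts[:, 0], "y2d": last_pts[:, 1],
        "area_nm2": [c.area for c in last_cells],
        "n_neighbors": [len(c.neighbor_ids) for c in last_cells],
        "is_boundary": [c.is_boundary for c in last_cells],
    }), outdir / "cells.csv")
    centers, weights = neighbor_distance_histogram(cells_per_frame,
                                                   cfg.hist_bin_width)
    write_csv(pd.DataFrame({"r_nm": centers, "weight": weights}),
              outdir / "hist.csv")

    # COM RDF
    com_frames = [molecule_com(f, table, members) for f in rec_window]
    try:
        rdf = com_rdf(com_frames, rec_window.frames[0].box,
                      bin_width=cfg.rdf_bin_width)
        write_csv(pd.DataFrame({"r_nm": rdf.bin_centers, "g": rdf.g}),
                  outdir / "rdf.csv")
    except ValueError as exc:
        logger.warning("RDF skipped: %s", exc)

    # P2 orientation fields
    p2_dir = outdir / "p2_frames"
    p2_dir.mkdir(exist_ok=True)
    for i, frame_df in enumerate(orientation_field(
            rec_window, table, members, cfg.topology, every_n=cfg.p2_every)):
        write_csv(frame_df, p2_dir / f"frame_{i:05d}.csv")


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Artifacts per crystallite: image_shifts.csv, plane.json, tilt.csv
    (+ per-molecule/per-frame stats), cells.csv, hist.csv, rdf.csv and
    p2_frames/; plus a top-level crystallites.csv and manifest.json.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        window, table = load_trajectory(
            cfg.trajectory, cfg.structure, cfg.topology,
            t_start=cfg.t_start, t_end=cfg.t_end, stride=cfg.stride,
            box_sidecar=cfg.box_sidecar)
        logger.info("loaded %d frames, %d molecules", len(window),
                    table.n_molecules)

        stage = "segment"
        crystallites, desc = segment(window, table, cfg.topology,
                                     mode=cfg.mode, eps_deg=cfg.eps_deg,
                                     min_cluster_size=cfg.min_size,
                                     averaging=cfg.averaging)
        label = np.full(table.n_molecules, -1)
        for c in crystallites:
            if not c.is_disordered_pool:
                label[c.member_molecule_ids] = c.crystallite_id
        seg_df = desc.copy()
        angle_cols = [c for c in seg_df.columns
                      if c not in ("molecule_id", "n_frames")]
        seg_df[[f"{c}_deg" for c in angle_cols]] = np.degrees(seg_df[angle_cols])
        seg_df = seg_df.drop(columns=angle_cols)
        seg_df.insert(1, "crystallite_id", label)
        write_csv(seg_df, outdir / "crystallites.csv")
        ordered = [c for c in crystallites if not c.is_disordered_pool]
        if not ordered:
            logger.warning("no crystallites found; all molecules disordered")

        for c in ordered:
            stage = f"crystallite {c.crystallite_id}"
            analyze_crystallite(window, table, c.member_molecule_ids, cfg,
                                outdir / f"crystallite_{c.crystallite_id}")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "quasicryst_version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps({k: str(v) for k, v in vars(cfg).items()},
                       sort_keys=True).encode()).hexdigest(),
        "n_crystallites": len(ordered),
        "files": {},
    }
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(outdir))] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
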