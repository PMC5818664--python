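"""Readers and writers: the columnar trajectory contract format, geometry
configs (YAML/JSON), PDB structures, and ground-truth sidecars.

Columnar trajectory format (plain text, whitespace separated)::

    #permeon-trajectory 1
    #box <bx> <by> <bz>
    #particle <id> <species> <charge> <subunit> <residue_number> <atom_name> <channel>
    ...                                  (one line per particle; '-' = empty)
    #frames <n_frames> <n_particles>
    <frame_index> <time_ps> <id> <species> <x> <y> <z>
    ...                                  (one row per particle per frame)

The format round-trips losslessly at the written precision (coordinates
%.6f, times %.4f).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .channel import ChannelGeometry, build_geometry
from .synthetic import GroundTruth
from .trajectory import Trajectory, make_particles

__all__ = [
    "TrajectoryParseError",
    "write_trajectory",
    "read_trajectory",
    "load_geometry",
    "default_geometry_path",
    "write_structure",
    "read_structure",
    "write_ground_truth",
    "read_ground_truth",
]

FORMAT_VERSION = 1


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


def _fmt_opt(value) -> str:
    s = str(value)
    return s if s else "-"


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the columnar contract format."""
    path = Path(path)
    p = trajectory.particles
    with path.open("w") as fh:
        fh.write(f"#permeon-trajectory {FORMAT_VERSION}\n")
        fh.write("#box {:.6f} {:.6f} {:.6f}\n".format(*trajectory.box))
        for row in p.itertuples(index=False):
            fh.write(
                "#particle {} {} {:.6f} {} {} {} {}\n".format(
                    row.id,
                    row.species,
                    row.charge,
                    _fmt_opt(row.subunit),
                    row.residue_number,
                    _fmt_opt(row.atom_name),
                    _fmt_opt(row.channel),
                )
            )
        fh.write(f"#frames {trajectory.n_frames} {trajectory.n_particles}\n")
        ids = p["id"].to_numpy()
        species = p["species"].to_numpy()
        for f in range(trajectory.n_frames):
            t = trajectory.times[f]
            for j in range(trajectory.n_particles):
                x, y, z = trajectory.positions[f, j]
                fh.write(
                    f"{f} {t:.4f} {ids[j]} {species[j]} {x:.6f} {y:.6f} {z:.6f}\n"
                )


def read_trajectory(path: str | Path) -> Trajectory:
    """Read the columnar contract format back into a Trajectory."""
    path = Path(path)
    box = None
    particle_rows = []
    n_frames = n_particles = None
    header_lines = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            header_lines = lineno
            fields = line[1:].split()
            if not fields:
                raise TrajectoryParseError("empty header line", lineno)
            tag = fields[0]
            try:
                if tag == "permeon-trajectory":
                    if int(fields[1]) != FORMAT_VERSION:
                        raise TrajectoryParseError(
                            f"unsupported format version {fields[1]}", lineno
                        )
                elif tag == "box":
                    box = np.array([float(v) for v in fields[1:4]])
                elif tag == "particle":
                    particle_rows.append(
                        dict(
                            id=int(fields[1]),
                            species=fields[2],
                            charge=float(fields[3]),
                            subunit="" if fields[4] == "-" else fields[4],
                            residue_number=int(fields[5]),
                            atom_name="" if fields[6] == "-" else fields[6],
                            channel="" if fields[7] == "-" else fields[7],
                        )
                    )
                elif tag == "frames":
                    n_frames, n_particles = int(fields[1]), int(fields[2])
                else:
                    raise TrajectoryParseError(f"unknown header tag {tag!r}", lineno)
            except (IndexError, ValueError) as exc:
                if isinstance(exc, TrajectoryParseError):
                    raise
                raise TrajectoryParseError(f"malformed header: {exc}", lineno) from exc
    if box is None or n_frames is None or not particle_rows:
        raise TrajectoryParseError(
            "incomplete header (need #box, #particle rows and #frames)", header_lines
        )
    particles = make_particles(particle_rows)
    if len(particles) != n_particles:
        raise TrajectoryParseError(
            f"#frames declares {n_particles} particles, header lists {len(particles)}"
        )
    try:
        data = pd.read_csv(
            path,
            sep=r"\s+",
            comment="#",
            header=None,
            names=["frame", "time", "id", "species", "x", "y", "z"],
            dtype={"frame": int, "time": float, "id": int, "species": str,
                   "x": float, "y": float, "z": float},
        )
    except Exception as exc:  # pandas raises various parse errors
        raise TrajectoryParseError(f"malformed data row: {exc}") from exc
    if len(data) != n_frames * n_particles:
        raise TrajectoryParseError(
            f"expected {n_frames * n_particles} data rows, found {len(data)}"
        )
    order = np.lexsort((data["id"].to_numpy(), data["frame"].to_numpy()))
    data = data.iloc[order]
    positions = data[["x", "y", "z"]].to_numpy().reshape(n_frames, n_particles, 3)
    times = data["time"].to_numpy().reshape(n_frames, n_particles)[:, 0]
    id_order = np.sort(particles["id"].to_numpy())
    particles = (
        particles.set_index("id").loc[id_order].reset_index()[particles.columns]
    )
    return Trajectory(particles=particles, times=times, box=box, positions=positions)


# ---------------------------------------------------------------------------
# geometry config


def default_geometry_path() -> Path:
    return Path(str(resources.files("permeon") / "data" / "default_geometry.yaml"))


def load_geometry(path: str | Path) -> ChannelGeometry:
    """Load and validate a geometry config (YAML or JSON)."""
    text = Path(path).read_text()
    mapping = (
        json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    )
    return build_geometry(mapping)


# ---------------------------------------------------------------------------
# structures and sidecars


def write_structure(structure: struc.AtomArray, path: str | Path) -> None:
    f = pdb.PDBFile()
    f.set_structure(structure)
    f.write(str(path))


def read_structure(path: str | Path) -> struc.AtomArray:
    return pdb.PDBFile.read(str(path)).get_structure(model=1)


def write_ground_truth(truth: GroundTruth, events_path: str | Path,
                       flips_path: str | Path | None = None) -> None:
    truth.events.to_csv(events_path, index=False)
    if flips_path is not None:
        truth.flips.to_csv(flips_path, index=False)


def read_ground_truth(events_path: str | Path,
                      flips_path: str | Path | None = None,
                      seed: int = -1) -> GroundTruth:
    events = pd.read_csv(events_path, keep_default_na=False)
    flips = (
        pd.read_csv(flips_path)
        if flips_path is not None
        else pd.DataFrame(columns=["subunit", "start_ps", "end_ps"])
    )
    return GroundTruth(events=events, flips=flips, seed=seed)
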