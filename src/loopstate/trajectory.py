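"""Trajectory frames with a shared topology.

Two on-disk forms are supported:

* standard binary trajectories (DCD/XTC) read through MDAnalysis with a PDB
  topology;
* a plain-text frame dialect used for portable fixtures: one line per atom,
  ``LABEL x y z`` with ``LABEL = RESNAME_RESID_ATOMNAME`` (e.g.
  ``GLU_17_CA``), frames separated by a line containing only ``END``.
  Whitespace-delimited, coordinates in Å.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import StructureModel

__all__ = ["Frames", "read_text_frames", "write_text_frames", "read_binary_traj"]


@dataclass
class Frames:
    """Stacked coordinates (n_frames, n_atoms, 3) over a fixed topology."""

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    coords: np.ndarray
    elements: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1:] != (len(self.names), 3):
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.elements is None:
            self.elements = np.array(
                [str(n).strip()[:1] for n in self.names], dtype=object
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, k: int) -> StructureModel:
        """Materialize frame ``k`` as a StructureModel."""
        n = self.n_atoms
        return StructureModel(
            self.names, self.elements, self.resnames, self.resids,
            np.array(["A"] * n, dtype=object), self.coords[k],
        )

    def topology(self) -> StructureModel:
        """Topology-only view (coordinates of the first frame)."""
        return self.frame(0)

    def matches_topology(self, other: "Frames | StructureModel") -> bool:
        return (
            len(self.names) == len(other.names)
            and (self.names == other.names).all()
            and (self.resids == other.resids).all()
        )


def _parse_label(label: str) -> tuple[str, int, str]:
    parts = label.split("_")
    if len(parts) != 3:
        raise ValueError(
            f"bad atom label {label!r}; expected RESNAME_RESID_ATOMNAME"
        )
    return parts[0], int(parts[1]), parts[2]


def read_text_frames(path: str) -> Frames:
    """Read the plain-text frame dialect into :class:`Frames`.

    All frames must carry the same atoms in the same order; a mismatch is a
    topology error.
    """
    frames: list[list[tuple[float, float, float]]] = []
    labels_ref: list[str] | None = None
    cur_labels: list[str] = []
    cur_xyz: list[tuple[float, float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line == "END":
                if labels_ref is None:
                    labels_ref = cur_labels
                elif cur_labels != labels_ref:
                    raise ValueError("frame topology mismatch in text trajectory")
                frames.append(cur_xyz)
                cur_labels, cur_xyz = [], []
                continue
            tok = line.split()
            if len(tok) != 4:
                raise ValueError(f"bad frame line: {line!r}")
            cur_labels.append(tok[0])
            cur_xyz.append((float(tok[1]), float(tok[2]), float(tok[3])))
    if cur_labels:  # trailing frame without END terminator
        if labels_ref is None:
            labels_ref = cur_labels
        elif cur_labels != labels_ref:
            raise ValueError("frame topology mismatch in text trajectory")
        frames.append(cur_xyz)
    if labels_ref is None:
        raise ValueError(f"no frames found in {path}")
    parsed = [_parse_label(lab) for lab in labels_ref]
    resnames = [p[0] for p in parsed]
    resids = [p[1] for p in parsed]
    names = [p[2] for p in parsed]
    return Frames(names, resnames, resids, np.array(frames, dtype=float))


def write_text_frames(frames: Frames, path: str) -> None:
    """Write :class:`Frames` in the plain-text dialect (round-trips exactly
    to the printed precision of %.6f Å)."""
    labels = [
        f"{frames.resnames[k]}_{frames.resids[k]}_{frames.names[k]}"
        for k in range(frames.n_atoms)
    ]
    with open(path, "w") as fh:
        for f in range(frames.n_frames):
            for k, lab in enumerate(labels):
                x, y, z = frames.coords[f, k]
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")
            fh.write("END\n")


def read_binary_traj(traj_path: str, top_path: str, stride: int = 1) -> Frames:
    """Read a DCD/XTC trajectory (MDAnalysis backend) with a PDB topology."""
    import MDAnalysis as mda

    u = mda.Universe(top_path, traj_path)
    atoms = u.atoms
    coords = np.array([atoms.positions.copy() for _ in u.trajectory[::stride]])
    return Frames(
        np.array(atoms.names, dtype=object),
        np.array(atoms.resnames, dtype=object),
        np.array(atoms.resids, dtype=int),
        coords,
        elements=np.array([n[:1] for n in atoms.names], dtype=object),
    )
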