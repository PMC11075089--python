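"""M20-loop geometry: anchor points, the conformational coordinate R_c,
the reaction plane, and conformer classification.

The M20 loop of E. coli dihydrofolate reductase (residues 9-24) adopts
*occluded*, *open*, or *closed* conformations depending on whether the loop
"nose" (E17/N18) points toward the substrate-binding site, away from both
sites, or toward the coenzyme-binding site. A single scalar coordinate R_c
captures this. Two anchor points are built from Cα centroids:

* ``P1`` — coenzyme side: mean Cα of R44, H45 (helix C) and G97, R98
  (helix F);
* ``P2`` — substrate side: mean Cα of L28, A29, W30, F31 (helix B);
* ``j``  — the loop turn: mean Cα of E17 and N18;
* ``i``  — for each tracked loop residue (E17, N18, M20, P21), the
  geometric center of its side-chain heavy atoms.

R_c is the mean, over the tracked residues, of the displacement of the
side-chain center toward P1 and away from P2, measured relative to the
backbone turn point j:

    R_c = (1/4) Σ_i [ (d_{P1→j} − d_{P1→i}) + (d_{P2→i} − d_{P2→j}) ]

R_c is large and positive (≈ 5.8-7.4 Å) for closed loops whose side chains
pack against the coenzyme site, intermediate (≈ 4.6-5.7 Å) for open loops,
and small or negative (< 2 Å) for occluded loops pointing at the substrate
site. Being a combination of interatomic distances it is invariant under
rigid-body motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StructureModel",
    "AnchorSet",
    "AnchorPoints",
    "LoopDescriptor",
    "ReactionPlane",
    "CONFORMER_CLASSES",
    "DEFAULT_BOUNDARIES",
    "load_structure",
    "anchor_points",
    "compute_rc",
    "classify_conformer",
    "reaction_plane",
    "rc_timeseries",
    "write_pdb",
]

#: Backbone atom names excluded from side-chain heavy-atom selections.
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: Default class boundaries on R_c (Å): occluded < 2.0 <= intermediate
#: < 4.0 <= open < 5.75 <= closed.
DEFAULT_BOUNDARIES = (2.0, 4.0, 5.75)

CONFORMER_CLASSES = ("occluded", "intermediate", "open", "closed")


@dataclass
class StructureModel:
    """Flat atom-table model of a structure (one frame).

    Parallel arrays, one entry per atom: atom ``names``, ``elements``,
    residue ``resnames``, ``resids`` (author numbering), ``chains``,
    ``coords`` (N, 3) in Å.
    """

    names: np.ndarray
    elements: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.chains = np.asarray(self.chains, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.names), 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def is_hydrogen(self) -> np.ndarray:
        return np.array([e.upper() == "H" for e in self.elements], dtype=bool)

    def heavy_coords(self) -> np.ndarray:
        """Coordinates of non-hydrogen atoms."""
        return self.coords[~self.is_hydrogen()]

    def ca_index(self, resid: int) -> int:
        """Index of the Cα atom of residue ``resid`` (first match)."""
        hits = np.nonzero((self.resids == resid) & (self.names == "CA"))[0]
        if len(hits) == 0:
            raise KeyError(f"residue {resid} has no CA atom")
        return int(hits[0])

    def ca(self, resid: int) -> np.ndarray:
        return self.coords[self.ca_index(resid)]

    def sidechain_indices(self, resid: int) -> np.ndarray:
        """Indices of side-chain heavy atoms of ``resid``.

        All non-hydrogen atoms excluding backbone N, CA, C, O and OXT; for
        proline the ring atoms CB/CG/CD count as side chain.
        """
        sel = (
            (self.resids == resid)
            & ~self.is_hydrogen()
            & ~np.isin(self.names.astype(str), list(BACKBONE_ATOMS))
        )
        return np.nonzero(sel)[0]

    def translated(self, shift: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.names, self.elements, self.resnames, self.resids, self.chains,
            self.coords + np.asarray(shift, dtype=float),
        )

    def rotated(self, rotation: np.ndarray) -> "StructureModel":
        return StructureModel(
            self.names, self.elements, self.resnames, self.resids, self.chains,
            self.coords @ np.asarray(rotation, dtype=float).T,
        )


@dataclass(frozen=True)
class AnchorSet:
    """Residue numbers defining the anchor centroids and tracked residues."""

    p1_residues: tuple[int, ...] = (44, 45, 97, 98)
    p2_residues: tuple[int, ...] = (28, 29, 30, 31)
    turn_residues: tuple[int, ...] = (17, 18)
    tracked_residues: tuple[int, ...] = (17, 18, 20, 21)


@dataclass
class AnchorPoints:
    """Resolved anchor geometry for one frame."""

    p1: np.ndarray
    p2: np.ndarray
    j: np.ndarray
    i_centers: dict[int, np.ndarray]
    dropped: tuple[int, ...] = ()


@dataclass
class LoopDescriptor:
    """R_c with the distances it is built from, plus marker distances."""

    rc: float
    d_p1_j: float
    d_p2_j: float
    d_p1_i: dict[int, float]
    d_p2_i: dict[int, float]
    d_n18_h45: float | None = None
    d_e17_l28: float | None = None
    frame: int = 0
    label: str = field(default="")


@dataclass
class ReactionPlane:
    """Plane through three Cα-group centroids near the hydride-transfer site."""

    centroids: np.ndarray  # (3, 3): helix-B, helix-C, helix-F groups
    point: np.ndarray
    normal: np.ndarray

    def signed_distance(self, x: np.ndarray) -> float:
        return float(np.dot(np.asarray(x, dtype=float) - self.point, self.normal))


def load_structure(
    path: str,
    chain: str | None = None,
    altloc_policy: str = "A",
    model: int = 0,
) -> StructureModel:
    """Read one model/chain of a PDB file into a :class:`StructureModel`.

    ``chain=None`` selects the first chain containing amino-acid residues.
    Atoms with blank altloc or altloc equal to ``altloc_policy`` are kept.
    Hydrogens are retained (heavy-atom selections ignore them downstream).
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", path)
    models = list(structure)
    if model >= len(models):
        raise ValueError(f"model {model} not present ({len(models)} models)")
    mdl = models[model]
    chains = {c.id: c for c in mdl}
    if chain is None:
        for c in mdl:
            if any(is_aa(r) for r in c):
                chain = c.id
                break
        else:
            chain = next(iter(chains))
    if chain not in chains:
        raise KeyError(f"chain {chain!r} not found; available: {sorted(chains)}")

    names, elements, resnames, resids, chain_ids, coords = [], [], [], [], [], []
    for res in chains[chain]:
        for atom in res:
            alt = atom.get_altloc()
            if alt not in (" ", "", altloc_policy):
                continue
            names.append(atom.get_name())
            elem = (atom.element or atom.get_name()[0]).strip()
            elements.append(elem if elem else atom.get_name()[0])
            resnames.append(res.get_resname())
            resids.append(res.get_id()[1])
            chain_ids.append(chain)
            coords.append(atom.get_coord())
    if not names:
        raise ValueError(f"no atoms read from {path} chain {chain!r}")
    return StructureModel(names, elements, resnames, resids, chain_ids, np.array(coords))


def anchor_points(structure: StructureModel, anchors: AnchorSet | None = None) -> AnchorPoints:
    """Resolve P1, P2, the turn point j, and tracked side-chain centers.

    Missing Cα atoms in the anchor or turn groups are an error. A tracked
    residue with no side-chain heavy atoms (disordered side chain) is
    dropped from the R_c average with a warning.
    """
    anchors = anchors or AnchorSet()
    p1 = np.mean([structure.ca(r) for r in anchors.p1_residues], axis=0)
    p2 = np.mean([structure.ca(r) for r in anchors.p2_residues], axis=0)
    j = np.mean([structure.ca(r) for r in anchors.turn_residues], axis=0)
    centers: dict[int, np.ndarray] = {}
    dropped: list[int] = []
    for r in anchors.tracked_residues:
        idx = structure.sidechain_indices(r)
        if len(idx) == 0:
            dropped.append(r)
            warnings.warn(
                f"residue {r} has no side-chain heavy atoms; dropped from R_c",
                stacklevel=2,
            )
            continue
        centers[r] = structure.coords[idx].mean(axis=0)
    if not centers:
        raise ValueError("no tracked residue has side-chain heavy atoms")
    return AnchorPoints(p1, p2, j, centers, tuple(dropped))


def _descriptor_from_points(
    pts: AnchorPoints,
    d_n18_h45: float | None = None,
    d_e17_l28: float | None = None,
    frame: int = 0,
) -> LoopDescriptor:
    d_p1_j = float(np.linalg.norm(pts.j - pts.p1))
    d_p2_j = float(np.linalg.norm(pts.j - pts.p2))
    d_p1_i = {r: float(np.linalg.norm(c - pts.p1)) for r, c in pts.i_centers.items()}
    d_p2_i = {r: float(np.linalg.norm(c - pts.p2)) for r, c in pts.i_centers.items()}
    terms = [
        (d_p1_j - d_p1_i[r]) + (d_p2_i[r] - d_p2_j) for r in pts.i_centers
    ]
    rc = float(np.mean(terms))
    return LoopDescriptor(
        rc=rc, d_p1_j=d_p1_j, d_p2_j=d_p2_j, d_p1_i=d_p1_i, d_p2_i=d_p2_i,
        d_n18_h45=d_n18_h45, d_e17_l28=d_e17_l28, frame=frame,
    )


def compute_rc(structure: StructureModel, anchors: AnchorSet | None = None) -> LoopDescriptor:
    """Compute R_c and its constituent distances for one structure.

    Marker distances Cα(N18)-Cα(H45) (closed ≈ 7 Å, open ≈ 11-13 Å) and
    Cα(E17)-Cα(L28) (short in occluded loops) are attached when the marker
    residues are present.
    """
    pts = anchor_points(structure, anchors)

    def _marker(r1: int, r2: int) -> float | None:
        try:
            return float(np.linalg.norm(structure.ca(r1) - structure.ca(r2)))
        except KeyError:
            return None

    return _descriptor_from_points(pts, _marker(18, 45), _marker(17, 28))


def classify_conformer(
    rc: float | LoopDescriptor,
    boundaries: tuple[float, float, float] = DEFAULT_BOUNDARIES,
) -> str:
    """Map R_c to occluded / intermediate / open / closed.

    Half-open bands: occluded R_c < b0; intermediate b0 <= R_c < b1; open
    b1 <= R_c < b2; closed R_c >= b2, with defaults (2.0, 4.0, 5.75) Å.
    Every finite R_c maps to exactly one class.
    """
    x = rc.rc if isinstance(rc, LoopDescriptor) else float(rc)
    if not np.isfinite(x):
        raise ValueError("R_c must be finite")
    b0, b1, b2 = boundaries
    if x < b0:
        return "occluded"
    if x < b1:
        return "intermediate"
    if x < b2:
        return "open"
    return "closed"


def reaction_plane(structure: StructureModel) -> ReactionPlane:
    """Plane through the helix-B (L28-F31), helix-C (R44, H45) and helix-F
    (G97, R98) Cα centroids, oriented toward the M20-loop turn when that
    turn (E17/N18 Cα) is resolvable."""
    g_b = np.mean([structure.ca(r) for r in (28, 29, 30, 31)], axis=0)
    g_c = np.mean([structure.ca(r) for r in (44, 45)], axis=0)
    g_f = np.mean([structure.ca(r) for r in (97, 98)], axis=0)
    n = np.cross(g_c - g_b, g_f - g_b)
    norm = np.linalg.norm(n)
    if norm < 1e-9:
        raise ValueError("reaction-plane centroids are collinear")
    n = n / norm
    point = (g_b + g_c + g_f) / 3.0
    try:
        j = np.mean([structure.ca(r) for r in (17, 18)], axis=0)
        if np.dot(j - point, n) < 0:
            n = -n
    except KeyError:
        pass
    return ReactionPlane(np.vstack([g_b, g_c, g_f]), point, n)


def rc_timeseries(
    frames,
    anchors: AnchorSet | None = None,
    stride: int = 1,
    boundaries: tuple[float, float, float] = DEFAULT_BOUNDARIES,
) -> pd.DataFrame:
    """Per-frame loop descriptors for a trajectory, as a tidy table.

    ``frames`` is a :class:`loopstate.trajectory.Frames` (shared topology,
    stacked coordinates). Columns: ``frame, Rc, dP1j, dP2j, dP1_<res>,
    dP2_<res> ..., dN18_H45, dE17_L28, conformer``. Fully vectorized over
    frames, so million-frame synthetic trajectories are cheap.
    """
    anchors = anchors or AnchorSet()
    top = frames.topology()
    coords = np.asarray(frames.coords, dtype=float)[::stride]
    fidx = np.arange(frames.n_frames)[::stride]

    def _ca_idx(resid: int) -> int:
        return top.ca_index(resid)

    p1 = coords[:, [_ca_idx(r) for r in anchors.p1_residues], :].mean(axis=1)
    p2 = coords[:, [_ca_idx(r) for r in anchors.p2_residues], :].mean(axis=1)
    j = coords[:, [_ca_idx(r) for r in anchors.turn_residues], :].mean(axis=1)

    d_p1_j = np.linalg.norm(j - p1, axis=1)
    d_p2_j = np.linalg.norm(j - p2, axis=1)

    cols: dict[str, np.ndarray] = {"frame": fidx}
    terms = []
    per_res: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for r in anchors.tracked_residues:
        idx = top.sidechain_indices(r)
        if len(idx) == 0:
            warnings.warn(f"residue {r} has no side-chain heavy atoms; dropped")
            continue
        ic = coords[:, idx, :].mean(axis=1)
        d1 = np.linalg.norm(ic - p1, axis=1)
        d2 = np.linalg.norm(ic - p2, axis=1)
        per_res[r] = (d1, d2)
        terms.append((d_p1_j - d1) + (d2 - d_p2_j))
    if not terms:
        raise ValueError("no tracked residue has side-chain heavy atoms")
    rc = np.mean(terms, axis=0)

    cols["Rc"] = rc
    cols["dP1j"] = d_p1_j
    cols["dP2j"] = d_p2_j
    for r, (d1, d2) in per_res.items():
        cols[f"dP1_{r}"] = d1
        cols[f"dP2_{r}"] = d2
    try:
        cols["dN18_H45"] = np.linalg.norm(
            coords[:, _ca_idx(18), :] - coords[:, _ca_idx(45), :], axis=1
        )
        cols["dE17_L28"] = np.linalg.norm(
            coords[:, _ca_idx(17), :] - coords[:, _ca_idx(28), :], axis=1
        )
    except KeyError:
        pass
    df = pd.DataFrame(cols)
    b0, b1, b2 = boundaries
    df["conformer"] = pd.cut(
        df["Rc"], [-np.inf, b0, b1, b2, np.inf],
        labels=CONFORMER_CLASSES, right=False,
    ).astype(str)
    return df


def write_pdb(structure: StructureModel, path: str, hetatm: bool = False) -> None:
    """Write a StructureModel as fixed-width PDB ATOM/HETATM records."""
    rec = "HETATM" if hetatm else "ATOM  "
    with open(path, "w") as fh:
        for k in range(len(structure)):
            name = str(structure.names[k])
            # PDB name column convention: 1-char elements start in col 14
            name_f = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = structure.coords[k]
            fh.write(
                f"{rec}{k + 1:>5d} {name_f:<4s} {str(structure.resnames[k]):<3s} "
                f"{str(structure.chains[k])[:1]}{int(structure.resids[k]):>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{str(structure.elements[k]):>2s}\n"
            )
        fh.write("END\n")
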