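"""Shared fixtures: small synthetic structures and trajectories."""

import numpy as np
import pytest

from loopstate.geometry import StructureModel
from loopstate.synthetic import ToyAnchorLayout


@pytest.fixture(scope="session")
def layout() -> ToyAnchorLayout:
    return ToyAnchorLayout()


def toy_structure_from_points(p1, p2, j, i_centers) -> StructureModel:
    """Hand-buildable structure realizing given anchor points.

    Anchor Cα pseudo-atoms coincide at their group centroid; each tracked
    residue gets a single CB side-chain pseudo-atom at its center.
    """
    roster = []
    coords = []
    for resname, resid in (("ARG", 44), ("HIS", 45), ("GLY", 97), ("ARG", 98)):
        roster.append((resname, resid, "CA"))
        coords.append(p1)
    for resname, resid in (("LEU", 28), ("ALA", 29), ("TRP", 30), ("PHE", 31)):
        roster.append((resname, resid, "CA"))
        coords.append(p2)
    for resname, resid in (("GLU", 17), ("ASN", 18)):
        roster.append((resname, resid, "CA"))
        coords.append(j)
    for (resname, resid), c in zip(
        (("GLU", 17), ("ASN", 18), ("MET", 20), ("PRO", 21)), i_centers
    ):
        roster.append((resname, resid, "CB"))
        coords.append(c)
    names = [r[2] for r in roster]
    resnames = [r[0] for r in roster]
    resids = [r[1] for r in roster]
    return StructureModel(
        names, ["C"] * len(names), resnames, resids, ["A"] * len(names),
        np.array(coords, dtype=float),
    )


@pytest.fixture()
def collinear_structure() -> StructureModel:
    """All anchor points on the x axis; R_c evaluable by hand.

    P1 = (0,0,0), P2 = (10,0,0), j = (5,0,0), all four side-chain centers
    at (4,0,0):
      d_P1j = 5, d_P2j = 5, d_P1i = 4, d_P2i = 6
      R_c   = mean[(5-4) + (6-5)] = 2.0
    """
    p1 = np.zeros(3)
    p2 = np.array([10.0, 0.0, 0.0])
    j = np.array([5.0, 0.0, 0.0])
    centers = [np.array([4.0, 0.0, 0.0])] * 4
    return toy_structure_from_points(p1, p2, j, centers)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
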