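"""Ionic-strength arithmetic and solvated-box composition utilities.

The molar ionic strength of a solution of ionic species with charges
``Z_i`` (in units of e) and molar concentrations ``c_i`` is

    I^M = 1/2 * sum_i c_i * Z_i**2        [mol/L]

so a 2:1 salt such as CaCl2 at concentration ``c`` contributes ``3c``.
This module also provides the box-composition helpers used to set up
ionic-solution boxes around a protein: integer ion counts for a cubic
periodic box, counterion adjustment to neutralize a charged solute,
sequential random ion placement with a minimum mutual spacing, and removal
of water molecules overlapping protein heavy atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import MOLAR_TO_PER_A3

__all__ = [
    "IonSpecies",
    "SolutionSpec",
    "IonCounts",
    "SALTS",
    "salt_species",
    "ionic_strength",
    "ionic_strength_from_counts",
    "ion_counts_for_box",
    "neutralize_counts",
    "place_ions",
    "trim_waters",
]


@dataclass(frozen=True)
class IonSpecies:
    """One dissolved ionic species.

    Parameters
    ----------
    label : str
        Species name, e.g. ``"Ca2+"``.
    charge : int
        Ionic charge in units of the elementary charge; must be nonzero.
    concentration : float
        Molar concentration, mol/L; must be nonnegative.
    """

    label: str
    charge: int
    concentration: float

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError(f"ion species {self.label!r} must carry a nonzero charge")
        if not math.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError(
                f"ion species {self.label!r} has invalid concentration "
                f"{self.concentration!r} (must be finite and >= 0)"
            )


@dataclass(frozen=True)
class SolutionSpec:
    """Ionic species in a cubic periodic box of edge ``box_edge`` Å."""

    species: tuple[IonSpecies, ...]
    box_edge: float

    def __post_init__(self) -> None:
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        object.__setattr__(self, "species", tuple(self.species))

    @property
    def volume(self) -> float:
        """Box volume in Å^3."""
        return self.box_edge**3


@dataclass
class IonCounts:
    """Integer particle counts per species label, with their charges."""

    counts: dict[str, int] = field(default_factory=dict)
    charges: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for species {label!r}")
            if label not in self.charges:
                raise ValueError(f"no charge recorded for species {label!r}")

    def total_charge(self) -> int:
        """Net charge of all counted ions, in e (exact integer arithmetic)."""
        return sum(self.charges[s] * n for s, n in self.counts.items())

    def copy(self) -> "IonCounts":
        return IonCounts(dict(self.counts), dict(self.charges))


#: Supported crystallization salts: label -> (cation label, cation charge,
#: anion label, anion charge, cations per formula unit, anions per formula unit).
SALTS: dict[str, tuple[str, int, str, int, int, int]] = {
    "NaCl": ("Na+", 1, "Cl-", -1, 1, 1),
    "KCl": ("K+", 1, "Cl-", -1, 1, 1),
    "CaCl2": ("Ca2+", 2, "Cl-", -1, 1, 2),
    "MgCl2": ("Mg2+", 2, "Cl-", -1, 1, 2),
    "MnCl2": ("Mn2+", 2, "Cl-", -1, 1, 2),
}


def salt_species(salt: str, concentration: float) -> list[IonSpecies]:
    """Fully dissociated species list for a named salt at molar concentration.

    Only the fixed vocabulary in :data:`SALTS` is supported (the 1:1 and 2:1
    chlorides that appear in ecDHFR crystallization buffers).
    """
    if salt not in SALTS:
        raise ValueError(f"unsupported salt {salt!r}; supported: {sorted(SALTS)}")
    cat, zc, an, za, nc, na = SALTS[salt]
    return [
        IonSpecies(cat, zc, nc * concentration),
        IonSpecies(an, za, na * concentration),
    ]


def ionic_strength(species: list[IonSpecies] | tuple[IonSpecies, ...]) -> float:
    """Molar ionic strength I^M = 1/2 Σ c_i Z_i², in mol/L.

    An empty species list gives 0. Species invariants (nonzero charge,
    nonnegative concentration) are enforced at construction.
    """
    return 0.5 * sum(s.concentration * s.charge**2 for s in species)


def ionic_strength_from_counts(counts: IonCounts, volume: float) -> float:
    """I^M realized by integer ion counts in a box of ``volume`` Å^3."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    total = 0.0
    for label, n in counts.counts.items():
        c = n / (MOLAR_TO_PER_A3 * volume)
        total += c * counts.charges[label] ** 2
    return 0.5 * total


def ion_counts_for_box(spec: SolutionSpec, target_concentration: float) -> IonCounts:
    """Integer ion counts realizing a salt concentration in a cubic box.

    The cation count is ``round(c · N_A · V)`` (round-half-to-even); anion
    counts restore the exact formula-unit stoichiometry inferred from the
    species concentration ratio. The realized concentration is within one
    particle per box of the target.
    """
    if target_concentration < 0:
        raise ValueError("target concentration must be >= 0")
    cations = [s for s in spec.species if s.charge > 0]
    anions = [s for s in spec.species if s.charge < 0]
    if target_concentration == 0:
        return IonCounts(
            {s.label: 0 for s in spec.species},
            {s.label: s.charge for s in spec.species},
        )
    if not cations or not anions:
        raise ValueError("need at least one cation and one anion species")

    counts: dict[str, int] = {}
    charges: dict[str, int] = {}
    n_formula = round(target_concentration * MOLAR_TO_PER_A3 * spec.volume)
    for s in spec.species:
        # particles per formula unit, from the concentration ratio
        stoich = s.concentration / target_concentration
        if s.charge > 0:
            counts[s.label] = int(round(n_formula * stoich))
        else:
            counts[s.label] = int(round(n_formula * stoich))
        charges[s.label] = s.charge
    # restore electroneutral stoichiometry by adjusting the (first) anion
    net = sum(charges[k] * v for k, v in counts.items())
    an0 = anions[0].label
    if net % abs(charges[an0]) == 0:
        counts[an0] += net // abs(charges[an0])
    if counts[an0] < 0:
        raise ValueError("stoichiometry adjustment produced a negative count")
    return IonCounts(counts, charges)


def neutralize_counts(counts: IonCounts, solute_net_charge: int) -> IonCounts:
    """Adjust monovalent counterion counts so the full system is neutral.

    The total ionic charge plus ``solute_net_charge`` is driven to zero with
    the minimal number of added/removed monovalent counterions, adjusting
    anions before cations (tie-break). Raises if neutrality is unreachable
    with the available species charges (e.g. odd excess with only divalent
    ions present).
    """
    out = counts.copy()
    excess = out.total_charge() + int(solute_net_charge)
    if excess == 0:
        return out
    mono_anions = [s for s, z in out.charges.items() if z == -1]
    mono_cations = [s for s, z in out.charges.items() if z == 1]

    if excess > 0:
        # too much positive charge: add anions, or remove cations
        if mono_anions:
            out.counts[mono_anions[0]] = out.counts.get(mono_anions[0], 0) + excess
            return out
        if mono_cations and out.counts.get(mono_cations[0], 0) >= excess:
            out.counts[mono_cations[0]] -= excess
            return out
    else:
        need = -excess
        if mono_cations:
            out.counts[mono_cations[0]] = out.counts.get(mono_cations[0], 0) + need
            return out
        if mono_anions and out.counts.get(mono_anions[0], 0) >= need:
            out.counts[mono_anions[0]] -= need
            return out
    raise ValueError(
        f"cannot neutralize net charge {excess:+d} e with available species "
        f"{out.charges}"
    )


def _min_image_dist(a: np.ndarray, b: np.ndarray, box: float) -> np.ndarray:
    """Minimum-image distances between point a (3,) and points b (N, 3)."""
    d = b - a
    d -= box * np.round(d / box)
    return np.linalg.norm(d, axis=-1)


def place_ions(
    box_edge: float,
    counts: IonCounts,
    seed: int,
    spacing: float = 15.0,
    solvent_overlap: float = 2.8,
    solvent: np.ndarray | None = None,
    strict: bool = True,
    max_attempts: int = 10_000,
) -> tuple[list[str], np.ndarray]:
    """Sequentially place ions at random in a cubic periodic box.

    Each new ion must lie at least ``spacing`` Å (minimum image) from
    previously placed ions — from *all* of them in strict mode (default,
    which best avoids artificial ion clustering), or only from the most
    recently placed one when ``strict=False`` — and at least
    ``solvent_overlap`` Å from every provided solvent atom.

    Returns ``(labels, positions)`` with positions of shape (N, 3) in Å,
    deterministic for a given seed. Raises ``RuntimeError`` naming the
    offending ion if a position cannot be found within ``max_attempts``
    trials.
    """
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    for label in sorted(counts.counts):
        labels.extend([label] * counts.counts[label])
    placed = np.empty((0, 3))
    solv_tree = None
    if solvent is not None and len(solvent):
        solvent = np.asarray(solvent, dtype=float)

    for idx, label in enumerate(labels):
        for _ in range(max_attempts):
            pos = rng.uniform(0.0, box_edge, size=3)
            if len(placed):
                ref = placed if strict else placed[-1:]
                if _min_image_dist(pos, ref, box_edge).min() < spacing:
                    continue
            if solvent is not None and len(solvent):
                if _min_image_dist(pos, solvent, box_edge).min() < solvent_overlap:
                    continue
            placed = np.vstack([placed, pos])
            break
        else:
            raise RuntimeError(
                f"failed to place ion #{idx} ({label}) after {max_attempts} "
                f"attempts at spacing {spacing} Å in a {box_edge} Å box"
            )
    return labels, placed


def trim_waters(
    protein_heavy: np.ndarray,
    waters: np.ndarray,
    cutoff: float = 2.8,
) -> np.ndarray:
    """Indices of water molecules retained after the overlap trim.

    A water molecule is removed as a whole if *any* of its atoms lies within
    ``cutoff`` Å of *any* protein heavy atom.

    Parameters
    ----------
    protein_heavy : (N, 3) array or StructureModel
        Coordinates of protein heavy (non-hydrogen) atoms, Å (a structure
        is reduced to its heavy atoms automatically).
    waters : (M, A, 3) array
        Water coordinates, one row of A atoms per molecule (A=1 for
        oxygen-only representations, 3 for full TIP3P).

    Returns
    -------
    (K,) integer array of retained molecule indices.
    """
    if hasattr(protein_heavy, "heavy_coords"):
        protein_heavy = protein_heavy.heavy_coords()
    waters = np.asarray(waters, dtype=float)
    if waters.ndim == 2:
        waters = waters[:, None, :]
    if waters.size == 0:
        return np.arange(0)
    protein_heavy = np.asarray(protein_heavy, dtype=float)
    tree = cKDTree(protein_heavy)
    flat = waters.reshape(-1, 3)
    dmin = tree.query(flat, k=1)[0].reshape(waters.shape[0], waters.shape[1])
    keep = (dmin >= cutoff).all(axis=1)
    return np.nonzero(keep)[0]
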