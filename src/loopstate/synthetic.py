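"""Ground-truth generators for end-to-end testing without external data.

Every stage of the analysis can be exercised on synthetic inputs whose
truth is known exactly:

* Boltzmann samples of R_c drawn from a specified 1-D free-energy profile
  at 298.16 K (inverse-CDF on a fine grid);
* umbrella-biased samples per window (Metropolis chain on W + bias);
* 3-D pseudo-atom frames realizing any achievable R_c through a fixed
  anchor layout, so the geometric pipeline can be driven end to end;
* ideal (uniform-density) ionic/water configurations in a cubic periodic
  box, matching the uniform-fluid assumptions of the electrostatics
  oracles;
* minimal PDB-writable toy structures in a requested conformer class.

All generators are seed-deterministic and record provenance metadata
(generator settings, seed, n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .constants import MOLAR_TO_PER_A3  # noqa: F401  (re-exported for configs)
from .geometry import StructureModel
from .pmf import ThermoConstants, UmbrellaWindow, bias_energy
from .trajectory import Frames

__all__ = [
    "ToyPotentialSpec",
    "double_well",
    "ToyAnchorLayout",
    "sample_rc",
    "embed_frames",
    "gen_umbrella_samples",
    "gen_ionic_config",
    "gen_toy_structure",
]

#: Inverse-CDF grid resolution, Å.
CDF_GRID = 1.0e-3


@dataclass
class ToyPotentialSpec:
    """Tabulated free-energy profile W(x) on a uniform grid (kcal/mol)."""

    x: np.ndarray
    w: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not (np.isfinite(self.x).all() and np.isfinite(self.w).all()):
            raise ValueError("potential must be finite on its domain")
        if self.x.ndim != 1 or self.x.shape != self.w.shape or len(self.x) < 2:
            raise ValueError("need matching 1-D x and w arrays")

    def __call__(self, xq) -> np.ndarray:
        return np.interp(np.asarray(xq, dtype=float), self.x, self.w)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])


def double_well(
    x_a: float = -0.17,
    x_b: float = 6.0,
    barrier: float = 1.6,
    sigma: float = 1.1,
    domain: tuple[float, float] = (-3.0, 8.0),
    grid: float = CDF_GRID,
) -> ToyPotentialSpec:
    """Equal-depth double-Gaussian well with an exactly calibrated barrier.

    W(x) = A [2 - exp(-(x-x_a)^2 / 2 sigma^2) - exp(-(x-x_b)^2 / 2 sigma^2)],
    shifted to min 0, with the amplitude A solved (linearly, since W scales
    with A) so that the saddle between the wells sits exactly ``barrier``
    kcal/mol above the well floor. Outside the wells W plateaus near the
    barrier height, emulating the broad shallow landscape the loop explores;
    defaults put the wells at the occluded (-0.17 Å) and closed (6.0 Å)
    R_c minima with the low-salt barrier of 1.6 kcal/mol.
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    if x_a >= x_b:
        x_a, x_b = min(x_a, x_b), max(x_a, x_b)
    if x_b - x_a < 1e-9:
        raise ValueError("wells must be distinct")
    if not (domain[0] < x_a and x_b < domain[1]):
        raise ValueError("domain must contain both wells")
    x = np.arange(domain[0], domain[1] + grid / 2, grid)

    def shape(xq: np.ndarray) -> np.ndarray:
        return (
            2.0
            - np.exp(-((xq - x_a) ** 2) / (2.0 * sigma**2))
            - np.exp(-((xq - x_b) ** 2) / (2.0 * sigma**2))
        )

    s = shape(x)
    between = (x >= x_a) & (x <= x_b)
    unit_barrier = s[between].max() - s.min()
    amp = barrier / unit_barrier
    w = amp * (s - s.min())
    return ToyPotentialSpec(
        x, w,
        meta={"kind": "double_well", "x_a": x_a, "x_b": x_b,
              "barrier": barrier, "sigma": sigma},
    )


def sample_rc(
    spec: ToyPotentialSpec,
    thermo: ThermoConstants | None = None,
    n: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """I.i.d. Boltzmann samples from density ∝ exp(-W/RT).

    Inverse-CDF on the potential's grid (refined to 1e-3 Å if coarser);
    bit-deterministic for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    thermo = thermo or ThermoConstants()
    lo, hi = spec.domain
    m = max(int(np.ceil((hi - lo) / CDF_GRID)), len(spec.x) - 1)
    x = np.linspace(lo, hi, m + 1)
    p = np.exp(-(spec(x) - spec(x).min()) / thermo.rt)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (p[1:] + p[:-1]) * np.diff(x))])
    cdf /= cdf[-1]
    # strictly increasing knots only
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n)
    return np.interp(u, cdf[keep], x[keep])


@dataclass
class ToyAnchorLayout:
    """Fixed anchor geometry with a one-parameter loop path.

    P1 (coenzyme side) and P2 (substrate side) sit ``separation`` Å apart
    on the x axis; the turn point j sits above the midpoint. The four
    tracked side-chain centers ride a straight path from the P2 side
    (t = 0, occluded-like) to the P1 side (t = 1, closed-like), carrying
    small per-residue offsets. The induced map t -> R_c is precomputed on a
    dense grid, verified strictly monotone, and inverted with monotone
    (PCHIP) interpolation.
    """

    separation: float = 12.0
    j_height: float = 5.0
    path_height: float = 3.0
    path_span: float = 10.0
    n_grid: int = 2001

    def __post_init__(self) -> None:
        self.p1 = np.array([0.0, 0.0, 0.0])
        self.p2 = np.array([self.separation, 0.0, 0.0])
        self.j = np.array([self.separation / 2.0, self.j_height, 0.0])
        # per-residue offsets of the tracked side-chain centers (E17, N18,
        # M20, P21), Å; small so the t -> R_c map stays monotone
        self.offsets = np.array(
            [
                [0.0, 0.0, 0.6],
                [0.0, 0.4, -0.6],
                [0.0, -0.4, 0.3],
                [0.0, 0.0, -0.3],
            ]
        )
        t = np.linspace(0.0, 1.0, self.n_grid)
        rc = self._rc_of_t(t)
        if not (np.diff(rc) > 0).all():
            raise ValueError("layout map t -> R_c is not strictly monotone")
        self._t_grid = t
        self._rc_grid = rc
        self._t_of_rc = PchipInterpolator(rc, t)

    def _centers_of_t(self, t: np.ndarray) -> np.ndarray:
        """Tracked centers for parameters t: shape (len(t), 4, 3)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        x = self.separation / 2.0 + (0.5 - t) * self.path_span
        base = np.stack(
            [x, np.full_like(x, self.path_height), np.zeros_like(x)], axis=-1
        )
        return base[:, None, :] + self.offsets[None, :, :]

    def _rc_of_t(self, t: np.ndarray) -> np.ndarray:
        centers = self._centers_of_t(t)
        d1j = np.linalg.norm(self.j - self.p1)
        d2j = np.linalg.norm(self.j - self.p2)
        d1i = np.linalg.norm(centers - self.p1, axis=-1)
        d2i = np.linalg.norm(centers - self.p2, axis=-1)
        return ((d1j - d1i) + (d2i - d2j)).mean(axis=-1)

    @property
    def rc_range(self) -> tuple[float, float]:
        return float(self._rc_grid[0]), float(self._rc_grid[-1])

    def t_of_rc(self, rc) -> np.ndarray:
        rc = np.asarray(rc, dtype=float)
        lo, hi = self.rc_range
        bad = (rc < lo) | (rc > hi)
        if bad.any():
            k = int(np.argmax(bad))
            raise ValueError(
                f"sample {np.atleast_1d(rc)[k]:.3f} Å outside achievable "
                f"R_c range [{lo:.3f}, {hi:.3f}]"
            )
        return self._t_of_rc(rc)


#: Atom roster emitted per frame: (resname, resid, atom name, role).
#: Cα pseudo-atoms realize the anchor centroids exactly (all members of a
#: centroid coincide at it); one CB pseudo-atom per tracked residue carries
#: its side-chain center.
_TOY_ATOMS = (
    [("ARG", 44, "CA", "p1"), ("HIS", 45, "CA", "p1"),
     ("GLY", 97, "CA", "p1"), ("ARG", 98, "CA", "p1")]
    + [("LEU", 28, "CA", "p2"), ("ALA", 29, "CA", "p2"),
       ("TRP", 30, "CA", "p2"), ("PHE", 31, "CA", "p2")]
    + [("GLU", 17, "CA", "j"), ("ASN", 18, "CA", "j"),
       ("MET", 20, "CA", "near_j")]
    + [("GLU", 17, "CB", "i0"), ("ASN", 18, "CB", "i1"),
       ("MET", 20, "CB", "i2"), ("PRO", 21, "CB", "i3")]
)


def embed_frames(rc_samples, layout: ToyAnchorLayout | None = None) -> Frames:
    """Emit pseudo-atom frames whose R_c equals each requested sample.

    Only the points entering the coordinate are materialized: coincident Cα
    pseudo-atoms at P1/P2/j and one side-chain pseudo-atom per tracked
    residue. Round-trip through the geometric pipeline recovers the input
    samples to well within 0.01 Å. An empty sample list yields an empty
    (0-frame) trajectory.
    """
    layout = layout or ToyAnchorLayout()
    rc_samples = np.atleast_1d(np.asarray(rc_samples, dtype=float))
    names = [a[2] for a in _TOY_ATOMS]
    resnames = [a[0] for a in _TOY_ATOMS]
    resids = [a[1] for a in _TOY_ATOMS]
    n_atoms = len(_TOY_ATOMS)
    if rc_samples.size == 0:
        return Frames(names, resnames, resids, np.zeros((0, n_atoms, 3)))
    t = layout.t_of_rc(rc_samples)
    centers = layout._centers_of_t(t)  # (F, 4, 3)
    coords = np.empty((len(t), n_atoms, 3))
    coords[:, 0:4, :] = layout.p1
    coords[:, 4:8, :] = layout.p2
    coords[:, 8:11, :] = layout.j  # M20 Cα rides with the turn point
    coords[:, 11:15, :] = centers
    return Frames(names, resnames, resids, coords)


def gen_umbrella_samples(
    spec: ToyPotentialSpec,
    centers,
    k: float = 10.0,
    thermo: ThermoConstants | None = None,
    n_per_window: int = 5000,
    seed: int = 0,
    mcmc_steps: int | None = None,
    half_k_convention: bool = True,
) -> list[UmbrellaWindow]:
    """Metropolis samples of W + harmonic bias for each window center.

    One independent chain per window, seeded from ``seed`` and the window
    index; the first 10% of each chain is discarded as burn-in and the step
    size is tuned during burn-in toward 30-50% acceptance. Raises on zero
    acceptance after burn-in.
    """
    thermo = thermo or ThermoConstants()
    rt = thermo.rt
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    lo, hi = spec.domain
    if (centers < lo).any() or (centers > hi).any():
        raise ValueError("window centers must lie within the potential domain")
    windows: list[UmbrellaWindow] = []
    for wi, x0 in enumerate(centers):
        rng = np.random.default_rng((seed, wi))
        win = UmbrellaWindow(float(x0), k, np.empty(0), half_k_convention)
        n_total = mcmc_steps or int(np.ceil(n_per_window / 0.9))
        burn = n_total - n_per_window if mcmc_steps is None else max(n_total // 10, 1)
        step = 0.5 if k == 0 else max(0.05, min(0.5, np.sqrt(rt / max(k, 1e-9))))
        x = float(np.clip(x0, lo, hi))
        e = spec(x) + float(bias_energy(x, win))
        out = np.empty(n_total)
        accepted_burn = 0
        accepted_main = 0
        for s in range(n_total):
            xp = x + rng.normal(0.0, step)
            if lo <= xp <= hi:
                ep = spec(xp) + float(bias_energy(xp, win))
                if ep <= e or rng.uniform() < np.exp(-(ep - e) / rt):
                    x, e = xp, ep
                    if s < burn:
                        accepted_burn += 1
                    else:
                        accepted_main += 1
            out[s] = x
            # crude step tuning during burn-in toward ~40% acceptance
            if s + 1 == burn // 2 and burn:
                acc = accepted_burn / max(s + 1, 1)
                if acc < 0.3:
                    step *= 0.6
                elif acc > 0.5:
                    step *= 1.5
        if n_total - burn > 0 and accepted_main == 0:
            raise RuntimeError(f"window {wi} at {x0}: zero acceptance after burn-in")
        win.samples = out[burn:][:n_per_window] if mcmc_steps is None else out[burn:]
        windows.append(win)
    return windows


def gen_ionic_config(
    box_edge: float,
    densities: dict[str, float],
    charges: dict[str, float],
    n_frames: int = 1,
    seed: int = 0,
    exclusion: float = 0.0,
):
    """Ideal-solution frames: Poisson counts at each species' density,
    positions uniform in the cubic box (optional hard-core exclusion by
    rejection). Returns a ``ChargedParticleSet``; densities in Å^-3.
    """
    from .electro import ChargedParticleSet

    for lab, d in densities.items():
        if d < 0:
            raise ValueError(f"negative density for {lab}")
    rng = np.random.default_rng(seed)
    vol = box_edge**3
    positions, qs, sps = [], [], []
    for _ in range(n_frames):
        pos_f, q_f, sp_f = [], [], []
        for lab in sorted(densities):
            n = rng.poisson(densities[lab] * vol)
            placed = 0
            attempts = 0
            while placed < n:
                p = rng.uniform(0.0, box_edge, size=3)
                if exclusion > 0 and pos_f:
                    d = np.asarray(pos_f) - p
                    d -= box_edge * np.round(d / box_edge)
                    if (np.linalg.norm(d, axis=1) < exclusion).any():
                        attempts += 1
                        if attempts > 1000 * max(n, 1):
                            raise RuntimeError(
                                "cannot satisfy hard-core exclusion; box too dense"
                            )
                        continue
                pos_f.append(p)
                q_f.append(charges[lab])
                sp_f.append(lab)
                placed += 1
        positions.append(np.asarray(pos_f, dtype=float).reshape(-1, 3))
        qs.append(np.asarray(q_f, dtype=float))
        sps.append(np.asarray(sp_f, dtype=object))
    return ChargedParticleSet(positions, qs, sps, dict(densities), box_edge)


#: R_c used to realize each conformer class (band midpoints / representative
#: interior points of the default boundaries).
_CLASS_TARGETS = {
    "occluded": 1.0,
    "intermediate": 3.0,
    "open": 4.875,
    "closed": 6.6,
}


def gen_toy_structure(
    target_class: str,
    layout: ToyAnchorLayout | None = None,
) -> StructureModel:
    """Minimal PDB-writable synthetic structure in a requested conformer
    class (synthetic stand-in, not a deposited structure).

    The structure carries the pseudo-atoms of :func:`embed_frames` at the
    class band's representative R_c; recomputing R_c on it lands inside the
    class band by construction.
    """
    if target_class not in _CLASS_TARGETS:
        raise ValueError(
            f"unknown class {target_class!r}; choose from {sorted(_CLASS_TARGETS)}"
        )
    layout = layout or ToyAnchorLayout()
    rc = _CLASS_TARGETS[target_class]
    lo, hi = layout.rc_range
    if not (lo <= rc <= hi):
        raise ValueError(f"class {target_class!r} unachievable in this layout")
    frames = embed_frames([rc], layout)
    return frames.frame(0)
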