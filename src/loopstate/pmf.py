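"""Free-energy profiles along R_c: Boltzmann inversion, pooling, WHAM.

The potential of mean force at 298.16 K is obtained from the relative
probability density rho(R_c) of trajectory samples,

    W(R_c) = -R T ln rho(R_c),   R = 1.9872e-3 kcal/(mol K),

shifted so the sampled minimum is zero. Samples from several simulations of
identical composition are pooled by summing bin counts before
normalization. Umbrella-biased windows (harmonic bias U_w(x) =
1/2 k (x - x0)^2) and unbiased segments (k = 0) are merged with the
standard self-consistent WHAM iteration:

    rho(x_b) = sum_w n_w(b) / sum_w N_w exp[-(U_w(x_b) - f_w)/RT]
    f_w      = -RT ln sum_b rho(x_b) exp[-U_w(x_b)/RT] dx

iterated until the window constants f_w stabilize. Empty bins are masked,
never padded with pseudo-counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, GAS_CONSTANT_R

__all__ = [
    "ThermoConstants",
    "Histogram1D",
    "FreeEnergyProfile",
    "UmbrellaWindow",
    "histogram_rc",
    "pmf_from_density",
    "pool_pmf",
    "bias_energy",
    "wham_join",
    "barrier_height",
    "block_errors",
]

#: Default binning along R_c, Å. The bin width matches the umbrella-window
#: spacing; the range spans the region the loop explores.
DEFAULT_BIN_WIDTH = 0.2
DEFAULT_RANGE = (-4.0, 9.0)


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant and temperature; ``RT`` in kcal/mol."""

    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT_R

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass
class Histogram1D:
    """Uniform-bin histogram with a normalized density over all samples."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def density(self) -> np.ndarray:
        """Probability density per bin; integrates to 1 over the support."""
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty histogram")
        return self.counts / (total * self.width)


@dataclass
class FreeEnergyProfile:
    """W(R_c) on bin centers, min = 0 over sampled bins; unsampled masked."""

    centers: np.ndarray
    w: np.ndarray
    mask: np.ndarray  # True where sampled
    errors: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    def sampled(self) -> tuple[np.ndarray, np.ndarray]:
        return self.centers[self.mask], self.w[self.mask]

    def interp(self, x: np.ndarray) -> np.ndarray:
        c, w = self.sampled()
        return np.interp(np.asarray(x, dtype=float), c, w)


@dataclass
class UmbrellaWindow:
    """Harmonic umbrella window: bias 1/2 k (x - center)^2, plus samples.

    ``k`` in kcal/(mol Å^2); ``k = 0`` marks an unbiased segment.
    ``half_k_convention=False`` switches to the k (x - x0)^2 convention used
    by some WHAM front ends.
    """

    center: float
    k: float
    samples: np.ndarray
    half_k_convention: bool = True

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("force constant must be >= 0")
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size and not np.isfinite(self.samples).all():
            raise ValueError("window samples must be finite")


def bias_energy(x, window: UmbrellaWindow):
    """Umbrella bias energy at ``x`` (kcal/mol)."""
    x = np.asarray(x, dtype=float)
    pref = 0.5 if window.half_k_convention else 1.0
    return pref * window.k * (x - window.center) ** 2


def _make_edges(bin_width: float, rng: tuple[float, float]) -> np.ndarray:
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = rng
    n = int(np.ceil((hi - lo) / bin_width - 1e-9))
    return lo + bin_width * np.arange(n + 1)


def histogram_rc(
    samples,
    bin_width: float = DEFAULT_BIN_WIDTH,
    rc_range: tuple[float, float] | None = None,
) -> Histogram1D:
    """Bin R_c samples on a uniform grid.

    The default range is (-4, 9) Å, expanded if samples fall outside it.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("no samples to histogram")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if rc_range is None:
        lo = min(DEFAULT_RANGE[0], np.floor(samples.min() / bin_width) * bin_width)
        hi = max(DEFAULT_RANGE[1], np.ceil(samples.max() / bin_width) * bin_width)
        rc_range = (lo, hi)
    edges = _make_edges(bin_width, rc_range)
    counts, _ = np.histogram(samples, bins=edges)
    return Histogram1D(edges, counts)


def pmf_from_density(
    hist: Histogram1D, thermo: ThermoConstants | None = None
) -> FreeEnergyProfile:
    """Boltzmann inversion W = -RT ln rho, shifted so min(W) = 0."""
    thermo = thermo or ThermoConstants()
    dens = hist.density
    mask = dens > 0
    if not mask.any():
        raise ValueError("histogram has no occupied bins")
    w = np.full_like(dens, np.nan)
    w[mask] = -thermo.rt * np.log(dens[mask])
    w[mask] -= w[mask].min()
    return FreeEnergyProfile(
        hist.centers, w, mask,
        meta={"temperature": thermo.temperature, "bin_width": hist.width},
    )


def pool_pmf(
    sample_sets,
    thermo: ThermoConstants | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    rc_range: tuple[float, float] | None = None,
) -> FreeEnergyProfile:
    """PMF from several simulations of identical composition.

    Counts are summed across the sets before normalization, which is exactly
    equivalent to Boltzmann inversion of the concatenated samples.
    """
    arrays = [np.asarray(s, dtype=float).ravel() for s in sample_sets]
    pooled = np.concatenate(arrays) if arrays else np.array([])
    if pooled.size == 0:
        raise ValueError("no samples in any set")
    return pmf_from_density(histogram_rc(pooled, bin_width, rc_range), thermo)


def wham_join(
    windows: list[UmbrellaWindow],
    thermo: ThermoConstants | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    rc_range: tuple[float, float] | None = None,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> FreeEnergyProfile:
    """Merge (possibly biased) R_c populations into one free-energy curve.

    Standard binned WHAM self-consistency on the union support of all
    windows. With a single unbiased window this reduces exactly to
    :func:`pmf_from_density`; non-overlapping biased windows or failure to
    converge raise.
    """
    thermo = thermo or ThermoConstants()
    windows = [w for w in windows if w.samples.size]
    if not windows:
        raise ValueError("no non-empty windows")
    rt = thermo.rt
    allx = np.concatenate([w.samples for w in windows])
    if rc_range is None:
        lo = np.floor(allx.min() / bin_width) * bin_width
        hi = np.ceil(allx.max() / bin_width) * bin_width + 1e-12
        rc_range = (lo, hi)
    edges = _make_edges(bin_width, rc_range)
    centers = 0.5 * (edges[:-1] + edges[1:])

    n_wb = np.vstack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    n_w = n_wb.sum(axis=1).astype(float)  # samples per window inside range
    sum_counts = n_wb.sum(axis=0).astype(float)
    mask = sum_counts > 0

    # check pairwise overlap chain for biased windows (sorted by center)
    biased = sorted((w for w in windows if w.k > 0), key=lambda w: w.center)
    for a, b in zip(biased, biased[1:]):
        ia = np.histogram(a.samples, bins=edges)[0] > 0
        ib = np.histogram(b.samples, bins=edges)[0] > 0
        if not (ia & ib).any():
            raise ValueError(
                f"umbrella windows at {a.center} and {b.center} share no "
                "sampled bins; WHAM cannot join them"
            )

    # bias factors per window per bin
    bias = np.vstack([bias_energy(centers, w) for w in windows])
    boltz = np.exp(-bias / rt)  # (W, B)

    f = np.zeros(len(windows))
    for it in range(max_iter):
        # unnormalized unbiased density estimate
        denom = (n_w[:, None] * boltz * np.exp(f[:, None] / rt)).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.where(mask & (denom > 0), sum_counts / denom, 0.0)
        z_w = (rho[None, :] * boltz).sum(axis=1) * bin_width
        f_new = -rt * np.log(z_w)
        f_new -= f_new[0]
        resid = np.max(np.abs(f_new - f))
        f = f_new
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM failed to converge in {max_iter} iterations "
            f"(residual {resid:.3e} > tol {tol:.1e})"
        )

    denom = (n_w[:, None] * boltz * np.exp(f[:, None] / rt)).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(mask & (denom > 0), sum_counts / denom, np.nan)
    w_arr = np.full(len(centers), np.nan)
    w_arr[mask] = -rt * np.log(rho[mask])
    w_arr[mask] -= w_arr[mask].min()
    return FreeEnergyProfile(
        centers, w_arr, mask,
        meta={
            "temperature": thermo.temperature, "bin_width": bin_width,
            "iterations": it + 1, "residual": float(resid),
            "window_constants": f.tolist(),
        },
    )


def barrier_height(
    profile: FreeEnergyProfile,
    well_a: tuple[float, float],
    well_b: tuple[float, float],
) -> dict:
    """Barrier between two wells, measured from the shallower well.

    Each well range must contain sampled bins; the barrier is the maximum of
    W on the sampled span between the two well minima minus W at the higher
    (shallower) minimum — the crossing cost out of the less stable state.
    Returns well positions/depths, the barrier-top position, and the height.
    """
    if min(well_b) < max(well_a) and min(well_a) < max(well_b):
        raise ValueError("well ranges must be disjoint")
    c, w = profile.sampled()

    def _well(rng):
        sel = (c >= rng[0]) & (c <= rng[1])
        if not sel.any():
            raise ValueError(f"no sampled bins in well range {rng}")
        k = np.argmin(w[sel])
        return c[sel][k], w[sel][k]

    xa, wa = _well(well_a)
    xb, wb = _well(well_b)
    lo, hi = min(xa, xb), max(xa, xb)
    between = (c >= lo) & (c <= hi)
    if not between.any():
        raise ValueError("no sampled bins between the wells")
    ktop = np.argmax(w[between])
    w_top = w[between][ktop]
    shallower = max(wa, wb)
    return {
        "barrier": float(w_top - shallower),
        "top_position": float(c[between][ktop]),
        "wells": {"a": (float(xa), float(wa)), "b": (float(xb), float(wb))},
    }


def block_errors(
    samples,
    n_blocks: int = 3,
    thermo: ThermoConstants | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    rc_range: tuple[float, float] | None = None,
) -> FreeEnergyProfile:
    """Per-bin standard error of W from contiguous time blocks.

    The sample stream is split in time order into ``n_blocks`` equal blocks;
    each block yields its own W = -RT ln rho (un-shifted), and the per-bin
    standard error across blocks (ddof=1, /sqrt(n_blocks)) is attached to
    the pooled profile. Bins must be sampled in every block to receive an
    error bar.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if samples.size < n_blocks:
        raise ValueError("fewer samples than blocks")
    thermo = thermo or ThermoConstants()
    if rc_range is None:
        lo = np.floor(samples.min() / bin_width) * bin_width
        hi = np.ceil(samples.max() / bin_width) * bin_width + 1e-12
        rc_range = (lo, hi)
    profile = pmf_from_density(histogram_rc(samples, bin_width, rc_range), thermo)
    blocks = np.array_split(samples, n_blocks)
    ws = []
    for b in blocks:
        hist = histogram_rc(b, bin_width, rc_range)
        dens = hist.counts / (hist.counts.sum() * hist.width)
        with np.errstate(divide="ignore"):
            ws.append(np.where(dens > 0, -thermo.rt * np.log(dens), np.nan))
    ws = np.vstack(ws)
    with np.errstate(invalid="ignore"):
        err = np.nanstd(ws, axis=0, ddof=1) / np.sqrt(n_blocks)
    err[np.isnan(ws).any(axis=0)] = np.nan
    profile.errors = err
    profile.meta["n_blocks"] = n_blocks
    return profile
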