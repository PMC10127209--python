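"""Boost-potential reweighting of enhanced-sampling ensembles.

Accelerated MD adds a non-negative boost potential ``dV_i`` to each frame's
energy so that barriers are crossed more often; canonical statistics are
recovered afterwards by weighting frame ``i`` with ``exp(dV_i / kT)``.  The
weighted histogram over M bins of a collective-variable space,

    p_m = sum_i w_i * delta(frame i in bin m) / sum_i w_i,

yields the potential of mean force ``F_m = -kT ln p_m`` (shifted so the
global minimum is zero).  Because the exponential amplifies noise from
rare large-boost frames, the weights are usually approximated by a
truncated Maclaurin series of ``exp``; the exact exponential is kept as a
diagnostic oracle.

Units: energies in kcal/mol, temperature in K.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError, FormatError, InputError

#: Boltzmann constant in kcal/(mol K).
KB = 0.0019872041

#: Simulation temperature default (K); kT at 300 K is ~0.596 kcal/mol.
DEFAULT_TEMPERATURE = 300.0

DEFAULT_MACLAURIN_ORDER = 10
DEFAULT_BINS = 50
DEFAULT_MIN_COUNT = 10
#: Fractional padding applied to the observed CV range when auto-binning.
RANGE_PAD = 0.02


def kT_at(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in kcal/mol at the given temperature in K."""
    if temperature <= 0:
        raise ConfigError(f"temperature must be positive, got {temperature}")
    return KB * temperature


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class BoostedEnsemble:
    """Per-frame collective-variable values plus boost potentials.

    Parameters
    ----------
    cv : ndarray, shape (N,) or (N, d)
        Collective-variable value(s) per frame; d is 1 or 2.
    dv_total : ndarray, shape (N,)
        Total boost potential per frame in kcal/mol (the quantity entering
        the reweighting factor).  When a dual-boost scheme was used this is
        the sum of the dihedral and total-potential components.
    dv_dihedral : ndarray or None
        Dihedral component of the boost, if recorded separately.
    temperature : float
        Simulation temperature in K.
    truth : object or None
        Optional generator ground truth (an analytic surface) carried along
        for recovery tests; never consumed by the reweighting itself.
    """

    cv: np.ndarray
    dv_total: np.ndarray
    dv_dihedral: np.ndarray | None = None
    temperature: float = DEFAULT_TEMPERATURE
    truth: object | None = None

    def __post_init__(self) -> None:
        self.cv = np.atleast_1d(np.asarray(self.cv, dtype=float))
        if self.cv.ndim == 1:
            self.cv = self.cv[:, None]
        if self.cv.ndim != 2 or self.cv.shape[1] not in (1, 2):
            raise InputError("cv must have 1 or 2 components per frame")
        self.dv_total = np.asarray(self.dv_total, dtype=float)
        if self.dv_total.shape != (self.n_frames,):
            raise InputError(
                f"dv_total length {self.dv_total.shape} does not match "
                f"frame count {self.n_frames}"
            )
        if np.any(self.dv_total < 0):
            raise InputError("boost potential must be non-negative for every frame")
        if self.dv_dihedral is not None:
            self.dv_dihedral = np.asarray(self.dv_dihedral, dtype=float)
            if self.dv_dihedral.shape != (self.n_frames,):
                raise InputError("dv_dihedral length does not match frame count")
            if np.any(self.dv_dihedral < 0) or np.any(
                self.dv_dihedral > self.dv_total + 1e-9
            ):
                raise InputError("dihedral boost component must lie in [0, dv_total]")
        if self.n_frames < 1:
            raise InputError("ensemble needs at least one frame")

    @property
    def n_frames(self) -> int:
        return self.cv.shape[0]

    @property
    def ndim(self) -> int:
        return self.cv.shape[1]

    @property
    def kT(self) -> float:
        return kT_at(self.temperature)


@dataclass
class WeightedHistogram:
    """Boost-weighted probability histogram over a CV grid.

    ``p`` is normalised over the binning range (sums to 1 to machine
    precision); ``counts`` are raw frame counts; ``n_clipped`` frames fell
    outside the range and were excluded.
    """

    edges: tuple[np.ndarray, ...]
    counts: np.ndarray
    p: np.ndarray
    n_clipped: int = 0

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def n_bins(self) -> int:
        return int(self.p.size)

    def centers(self, axis: int) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])


@dataclass
class FreeEnergyLandscape:
    """Free-energy surface F = -kT ln p over a binned CV grid.

    Masked (under-populated) bins hold NaN; the minimum over unmasked bins
    is zero after shifting.
    """

    edges: tuple[np.ndarray, ...]
    free_energy: np.ndarray
    mask: np.ndarray  # True where the bin carries a finite free energy
    kT: float
    p: np.ndarray | None = field(default=None, repr=False)

    @property
    def ndim(self) -> int:
        return len(self.edges)

    def centers(self, axis: int) -> np.ndarray:
        e = self.edges[axis]
        return 0.5 * (e[:-1] + e[1:])


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------


def maclaurin_weights(
    dv: np.ndarray, kT: float, order: int = DEFAULT_MACLAURIN_ORDER
) -> np.ndarray:
    """Truncated-series reweighting factors ``sum_{j<=order} (dV/kT)^j / j!``.

    Order 0 gives unit weights (no reweighting); the order-to-infinity
    limit is the exact exponential ``exp(dV/kT)``.
    """
    if kT <= 0:
        raise ConfigError(f"kT must be positive, got {kT}")
    if order < 0 or int(order) != order:
        raise ConfigError(f"order must be a non-negative integer, got {order}")
    x = np.asarray(dv, dtype=float) / kT
    if np.any(x < 0):
        raise InputError("boost potential must be non-negative")
    # Horner evaluation of the partial sum for numerical stability.
    w = np.ones_like(x)
    for j in range(int(order), 0, -1):
        w = 1.0 + w * x / j
    return w


def exact_weights(dv: np.ndarray, kT: float) -> np.ndarray:
    """Exact exponential reweighting factors ``exp(dV/kT)``.

    Oracle for the Maclaurin approximation; intended for tests and
    diagnostics.  For very large ``dV/kT`` prefer subtracting a constant
    from ``dv`` first — the reweighted probabilities are invariant under a
    uniform shift because the weights are renormalised.
    """
    if kT <= 0:
        raise ConfigError(f"kT must be positive, got {kT}")
    x = np.asarray(dv, dtype=float) / kT
    if np.any(x < 0):
        raise InputError("boost potential must be non-negative")
    return np.exp(x)


# ---------------------------------------------------------------------------
# Histogramming and free energy
# ---------------------------------------------------------------------------


def _auto_edges(cv: np.ndarray, bins: int) -> list[np.ndarray]:
    edges = []
    for k in range(cv.shape[1]):
        lo, hi = float(cv[:, k].min()), float(cv[:, k].max())
        pad = (hi - lo) * RANGE_PAD
        if pad == 0.0:
            pad = max(abs(lo), 1.0) * 1e-6
        edges.append(np.linspace(lo - pad, hi + pad, bins + 1))
    return edges


def reweight_histogram(
    ensemble: BoostedEnsemble,
    bins: int | Sequence[np.ndarray] = DEFAULT_BINS,
    weights: np.ndarray | None = None,
) -> WeightedHistogram:
    """Weighted probability histogram of the ensemble's CV values.

    ``bins`` is either a bin count applied per axis over the observed range
    (padded 2%) or explicit edge arrays per axis.  ``weights`` defaults to
    Maclaurin weights of the ensemble's own boost at the default order.
    Frames outside the binning range are clipped and counted.
    """
    cv = ensemble.cv
    if weights is None:
        weights = maclaurin_weights(ensemble.dv_total, ensemble.kT)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (ensemble.n_frames,):
        raise InputError(
            f"weights length {weights.shape} does not match frame count "
            f"{ensemble.n_frames}"
        )
    if np.any(weights < 0):
        raise InputError("weights must be non-negative")
    if not np.any(weights > 0):
        raise DegenerateInputError("all reweighting weights are zero")

    if isinstance(bins, (int, np.integer)):
        edges = _auto_edges(cv, int(bins))
    else:
        edges = [np.asarray(e, dtype=float) for e in bins]
        if len(edges) != cv.shape[1]:
            raise ConfigError(
                f"{len(edges)} edge arrays given for {cv.shape[1]} CV axes"
            )

    counts, _ = np.histogramdd(cv, bins=edges)
    wsum, _ = np.histogramdd(cv, bins=edges, weights=weights)
    n_clipped = ensemble.n_frames - int(counts.sum())
    total = wsum.sum()
    if total <= 0:
        raise DegenerateInputError("no frames with positive weight fall in range")
    p = wsum / total
    # histogramdd division is already exact; renormalise defensively.
    p = p / p.sum()
    return WeightedHistogram(
        edges=tuple(edges), counts=counts, p=p, n_clipped=n_clipped
    )


def free_energy(
    hist: WeightedHistogram,
    kT: float,
    min_count: int = DEFAULT_MIN_COUNT,
) -> FreeEnergyLandscape:
    """Free-energy surface from a weighted histogram.

    Bins with fewer than ``min_count`` raw frames (or zero probability) are
    masked: -kT ln of a tiny noisy probability would otherwise dominate the
    surface.  The unmasked minimum is shifted to zero.
    """
    mask = (hist.counts >= min_count) & (hist.p > 0)
    if not mask.any():
        raise DegenerateInputError(
            f"no bin reaches the minimum occupancy of {min_count} frames"
        )
    F = np.full(hist.p.shape, np.nan)
    with np.errstate(divide="ignore"):
        F[mask] = -kT * np.log(hist.p[mask])
    F[mask] -= np.nanmin(F[mask])
    return FreeEnergyLandscape(
        edges=hist.edges, free_energy=F, mask=mask, kT=kT, p=hist.p
    )


def marginal_landscape(landscape: FreeEnergyLandscape, axis: int) -> FreeEnergyLandscape:
    """1D landscape along ``axis`` obtained by integrating probability.

    Marginalisation sums p over the other axes (never free energies) and
    re-derives F; a 1D bin is finite if any contributing 2D bin was.
    """
    if landscape.ndim == 1:
        if axis != 0:
            raise ConfigError("axis out of range for a 1D landscape")
        return landscape
    if landscape.p is None:
        raise InputError("landscape lacks stored probabilities; rebuild from histogram")
    other = 1 - axis
    p1 = np.where(landscape.mask, landscape.p, 0.0).sum(axis=other)
    mask1 = landscape.mask.any(axis=other) & (p1 > 0)
    F = np.full(p1.shape, np.nan)
    with np.errstate(divide="ignore"):
        F[mask1] = -landscape.kT * np.log(p1[mask1])
    F[mask1] -= np.nanmin(F[mask1])
    return FreeEnergyLandscape(
        edges=(landscape.edges[axis],), free_energy=F, mask=mask1,
        kT=landscape.kT, p=p1,
    )


@dataclass(frozen=True)
class Minimum:
    """A local free-energy minimum: grid coordinate and depth (kcal/mol)."""

    coords: tuple[float, ...]
    depth: float
    bin_index: tuple[int, ...]


def locate_minima(
    landscape: FreeEnergyLandscape,
    max_minima: int = 10,
    axis: int | None = None,
) -> tuple[list[Minimum], bool]:
    """Strict local minima of the landscape, sorted by depth.

    With ``axis`` given on a 2D landscape, the landscape is first
    marginalised onto that axis (integrating probability).  Returns the
    minima and a ``flat`` flag; a landscape whose finite bins are all equal
    has no strict minima and is flagged flat.
    """
    if axis is not None and landscape.ndim == 2:
        landscape = marginal_landscape(landscape, axis)
    F = landscape.free_energy
    mask = landscape.mask
    finite = F[mask]
    if finite.size == 0:
        return [], True
    flat = bool(np.ptp(finite) < 1e-12)
    if flat:
        return [], True

    minima: list[Minimum] = []
    it = np.ndindex(*F.shape)
    offsets = [
        off
        for off in np.ndindex(*([3] * F.ndim))
        if any(o != 1 for o in off)
    ]
    for idx in it:
        if not mask[idx]:
            continue
        val = F[idx]
        is_min = True
        has_neighbor = False
        for off in offsets:
            nb = tuple(i + o - 1 for i, o in zip(idx, off))
            if any(j < 0 or j >= F.shape[d] for d, j in enumerate(nb)):
                continue
            if not mask[nb]:
                continue
            has_neighbor = True
            if F[nb] <= val:
                is_min = False
                break
        if is_min and has_neighbor:
            coords = tuple(
                float(landscape.centers(d)[idx[d]]) for d in range(F.ndim)
            )
            minima.append(Minimum(coords=coords, depth=float(val), bin_index=idx))
    minima.sort(key=lambda m: m.depth)
    return minima[:max_minima], False


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

ENSEMBLE_COLUMNS_1D = ["frame", "cv1", "dV_total", "dV_dihedral"]
ENSEMBLE_COLUMNS_2D = ["frame", "cv1", "cv2", "dV_total", "dV_dihedral"]


def read_ensemble_csv(
    path: str | Path, temperature: float = DEFAULT_TEMPERATURE
) -> BoostedEnsemble:
    """Read a boosted-ensemble table (frame, cv1[, cv2], dV_total, dV_dihedral).

    ``dV_total`` is the full boost entering the reweighting factor;
    ``dV_dihedral`` (optional column) is its dihedral component.
    """
    df = pd.read_csv(path)
    if "cv1" not in df.columns or "dV_total" not in df.columns:
        raise FormatError(
            f"{path}: expected columns cv1 and dV_total, found {list(df.columns)}"
        )
    cv_cols = ["cv1", "cv2"] if "cv2" in df.columns else ["cv1"]
    dvd = df["dV_dihedral"].to_numpy() if "dV_dihedral" in df.columns else None
    return BoostedEnsemble(
        cv=df[cv_cols].to_numpy(),
        dv_total=df["dV_total"].to_numpy(),
        dv_dihedral=dvd,
        temperature=temperature,
    )


def write_landscape_csv(landscape: FreeEnergyLandscape, path: str | Path) -> None:
    """Write the landscape in long format: bin centers, F (kcal/mol), occupied."""
    if landscape.ndim == 1:
        df = pd.DataFrame(
            {
                "cv1": landscape.centers(0),
                "free_energy_kcal_mol": landscape.free_energy,
                "occupied": landscape.mask.astype(int),
            }
        )
    else:
        c0, c1 = landscape.centers(0), landscape.centers(1)
        g0, g1 = np.meshgrid(c0, c1, indexing="ij")
        df = pd.DataFrame(
            {
                "cv1": g0.ravel(),
                "cv2": g1.ravel(),
                "free_energy_kcal_mol": landscape.free_energy.ravel(),
                "occupied": landscape.mask.astype(int).ravel(),
            }
        )
    df.to_csv(path, index=False, float_format="%.6f")


def read_landscape_csv(path: str | Path, kT: float) -> FreeEnergyLandscape:
    """Reconstruct a landscape written by :func:`write_landscape_csv`.

    Bin edges are rebuilt from the regular center grid; probabilities are
    not stored and come back as None.
    """
    df = pd.read_csv(path)
    cols = [c for c in ("cv1", "cv2") if c in df.columns]

    def edges_from_centers(c: np.ndarray) -> np.ndarray:
        if len(c) == 1:
            return np.array([c[0] - 0.5, c[0] + 0.5])
        h = c[1] - c[0]
        return np.concatenate([[c[0] - h / 2], c + h / 2])

    centers = [np.unique(df[c].to_numpy()) for c in cols]
    shape = tuple(len(c) for c in centers)
    F = df["free_energy_kcal_mol"].to_numpy().reshape(shape)
    mask = df["occupied"].to_numpy().astype(bool).reshape(shape)
    return FreeEnergyLandscape(
        edges=tuple(edges_from_centers(c) for c in centers),
        free_energy=F,
        mask=mask,
        kT=kT,
    )


def plot_landscape(landscape: FreeEnergyLandscape, path: str | Path,
                   cv_labels: Sequence[str] | None = None) -> None:
    """Render the landscape to an image file (1D line or 2D filled contour)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = list(cv_labels) if cv_labels else [f"CV{i+1}" for i in range(2)]
    if landscape.ndim == 1:
        ax.plot(landscape.centers(0), landscape.free_energy, "-o", ms=2)
        ax.set_xlabel(labels[0])
        ax.set_ylabel("F (kcal/mol)")
    else:
        c0, c1 = landscape.centers(0), landscape.centers(1)
        im = ax.pcolormesh(c0, c1, landscape.free_energy.T, shading="auto",
                           cmap="viridis")
        fig.colorbar(im, ax=ax, label="F (kcal/mol)")
        ax.set_xlabel(labels[0])
        ax.set_ylabel(labels[1] if len(labels) > 1 else "CV2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
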