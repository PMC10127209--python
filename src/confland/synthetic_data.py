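"""Synthetic inputs with known ground truth for the analysis pipeline.

Three generators live here:

* boosted ensembles drawn from analytic free-energy surfaces under a
  harmonic boost potential, for validating the reweighting machinery;
* toy pseudo-atom trajectories with scheduled conformational states, for
  validating the collective-variable engine;
* peptide-level deuterium-uptake tables with exponential exchange
  kinetics, replicate noise and a global back-exchange loss, for
  validating the HDX pipeline.

Every generator takes an explicit seed and records its ground truth so
that recovery tests can compare against exact expected values.  Sampling
happens directly in collective-variable space: the reweighting equations
consume only (CV, boost) pairs, so Cartesian dynamics would add nothing
but cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InputError
from .gamd_reweight import (
    DEFAULT_TEMPERATURE,
    BoostedEnsemble,
    kT_at,
)
from .hdx_pipeline import Peptide, max_uptake

# ---------------------------------------------------------------------------
# Analytic surfaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyticSurface:
    """A known potential V over a rectangular CV domain, in kcal/mol.

    ``potential`` maps one array per axis to V; ``bounds`` is one (lo, hi)
    pair per axis.  Serves as the ground truth that reweighting should
    recover.
    """

    potential: Callable[..., np.ndarray]
    bounds: tuple[tuple[float, float], ...]
    temperature: float = DEFAULT_TEMPERATURE
    name: str = "surface"

    @property
    def ndim(self) -> int:
        return len(self.bounds)

    @property
    def kT(self) -> float:
        return kT_at(self.temperature)

    def grid(self, points_per_axis: int) -> tuple[list[np.ndarray], np.ndarray]:
        """Regular evaluation grid: per-axis coordinates and V on the mesh."""
        axes = [
            np.linspace(lo, hi, points_per_axis) for lo, hi in self.bounds
        ]
        if self.ndim == 1:
            V = np.asarray(self.potential(axes[0]), dtype=float)
        else:
            mesh = np.meshgrid(*axes, indexing="ij")
            V = np.asarray(self.potential(*mesh), dtype=float)
        if not np.all(np.isfinite(V)):
            raise InputError(
                f"surface '{self.name}' is non-finite somewhere on its domain"
            )
        return axes, V


def flat_surface(domain: tuple[float, float] = (0.0, 1.0),
                 temperature: float = DEFAULT_TEMPERATURE) -> AnalyticSurface:
    """V = 0 everywhere; sampling is uniform, any valid boost is zero-effect."""
    return AnalyticSurface(
        potential=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        bounds=(domain,), temperature=temperature, name="flat",
    )


def harmonic_surface(k: float = 2.0, x0: float = 3.0,
                     domain: tuple[float, float] = (0.0, 6.0),
                     temperature: float = DEFAULT_TEMPERATURE) -> AnalyticSurface:
    """Single harmonic well V = k (x - x0)^2."""
    return AnalyticSurface(
        potential=lambda x: k * (np.asarray(x, dtype=float) - x0) ** 2,
        bounds=(domain,), temperature=temperature, name="harmonic",
    )


def double_well_1d(domain: tuple[float, float] = (-2.0, 2.0),
                   temperature: float = DEFAULT_TEMPERATURE) -> AnalyticSurface:
    """Symmetric double well V = x^4 - 2 x^2 with minima at x = ±1."""
    return AnalyticSurface(
        potential=lambda x: np.asarray(x, dtype=float) ** 4
        - 2.0 * np.asarray(x, dtype=float) ** 2,
        bounds=(domain,), temperature=temperature, name="double_well",
    )


def basin_delta_f(surface: AnalyticSurface, split: float = 0.0,
                  grid_points: int = 4001) -> float:
    """Quadrature free-energy difference between the two basins of a 2D
    (or 1D) surface split at CV1 = ``split``: dF = -kT ln(p_right / p_left).
    """
    axes, V = surface.grid(grid_points)
    kT = surface.kT
    w = np.exp(-(V - V.min()) / kT)
    left = axes[0] < split
    if surface.ndim == 1:
        p_left, p_right = w[left].sum(), w[~left].sum()
    else:
        p_left, p_right = w[left, :].sum(), w[~left, :].sum()
    return float(-kT * np.log(p_right / p_left))


def two_basin_surface_2d(delta_f: float = 1.0,
                         temperature: float = DEFAULT_TEMPERATURE) -> AnalyticSurface:
    """2D surface with two basins (x ≈ ±1) separated by a known dF.

    V = a (x² − 1)² + c x + b y²; the tilt c is solved numerically so that
    the population free-energy difference between the x>0 and x<0 basins
    equals ``delta_f`` exactly (by quadrature).  The deeper basin is on the
    left, so dF(left→right) = +delta_f.
    """
    a, b = 2.0, 2.0

    def make(c: float) -> AnalyticSurface:
        return AnalyticSurface(
            potential=lambda x, y: a * (np.asarray(x) ** 2 - 1.0) ** 2
            + c * np.asarray(x) + b * np.asarray(y) ** 2,
            bounds=((-2.0, 2.0), (-1.5, 1.5)),
            temperature=temperature,
            name="two_basin",
        )

    kT = kT_at(temperature)

    def objective(c: float) -> float:
        return basin_delta_f(make(c), grid_points=801) - delta_f

    c_star = brentq(objective, 0.0, 10.0 * kT + delta_f, xtol=1e-10)
    return make(c_star)


# ---------------------------------------------------------------------------
# Boost model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoostComponent:
    """One harmonic boost: threshold energy E (kcal/mol) and force constant
    k0 (dimensionless, in (0, 1]).

    The boost applied at potential V is zero for V >= E and
    ``k0 / (2 (E - V_min)) * (E - V)^2`` below the threshold — the standard
    lower-bound harmonic form, which keeps the boost non-negative and its
    distribution near-Gaussian for small k0.
    """

    E: float
    k0: float

    def __post_init__(self) -> None:
        if not (0.0 < self.k0 <= 1.0):
            raise InputError(f"k0 must lie in (0, 1], got {self.k0}")

    def boost(self, V: np.ndarray, v_min: float) -> np.ndarray:
        V = np.asarray(V, dtype=float)
        if self.E <= v_min:
            return np.zeros_like(V)
        dv = np.where(
            V < self.E,
            self.k0 / (2.0 * (self.E - v_min)) * (self.E - V) ** 2,
            0.0,
        )
        return dv


@dataclass(frozen=True)
class GaussianEnvironment:
    """Gaussian bath-energy term added to the CV potential before boosting.

    In a solvated simulation the boost acts on the total potential energy,
    whose fluctuations are near-Gaussian because thousands of degrees of
    freedom contribute; the CV-space potential alone has too few degrees of
    freedom to show that.  Adding an independent Gaussian energy per frame
    (mean/sd in kcal/mol) restores the realistic near-Gaussian boost
    distribution while leaving the reweighting mathematics exact — each
    frame still carries its exact boost.
    """

    mean: float = 0.0
    sd: float = 3.0
    n_grid: int = 161
    span: float = 8.0  # grid half-width in units of sd

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise InputError("environment sd must be positive")

    def axis(self) -> tuple[np.ndarray, np.ndarray]:
        """(energy grid, unnormalised density) for quadrature sampling."""
        eps = np.linspace(
            self.mean - self.span * self.sd,
            self.mean + self.span * self.sd,
            self.n_grid,
        )
        logf = -0.5 * ((eps - self.mean) / self.sd) ** 2
        return eps, logf


@dataclass(frozen=True)
class BoostModel:
    """Dual-boost model: independent total-potential and dihedral components.

    Either component may be None (single-boost run).  The full per-frame
    boost is the sum of the two; both are recorded so downstream code can
    inspect them separately.
    """

    total: BoostComponent | None = None
    dihedral: BoostComponent | None = None

    def __post_init__(self) -> None:
        if self.total is None and self.dihedral is None:
            raise InputError("boost model needs at least one component")

    def components(self, V: np.ndarray, v_min: float) -> tuple[np.ndarray, np.ndarray]:
        """(total-potential component, dihedral component) boost arrays."""
        V = np.asarray(V, dtype=float)
        zero = np.zeros_like(V)
        dv_pot = self.total.boost(V, v_min) if self.total else zero
        dv_dih = self.dihedral.boost(V, v_min) if self.dihedral else zero
        return dv_pot, dv_dih

    @staticmethod
    def for_surface(surface: AnalyticSurface, k0_total: float = 0.2,
                    k0_dihedral: float | None = None,
                    grid_points: int = 2001,
                    environment: "GaussianEnvironment | None" = None) -> "BoostModel":
        """Lower-bound parameterisation: threshold E at the sampled V max
        (plus the top of the environment-energy grid when one is used)."""
        _, V = surface.grid(grid_points)
        e = float(V.max())
        if environment is not None:
            e += environment.mean + environment.span * environment.sd
        total = BoostComponent(E=e, k0=k0_total)
        dihedral = (
            BoostComponent(E=e, k0=k0_dihedral) if k0_dihedral else None
        )
        return BoostModel(total=total, dihedral=dihedral)


def gen_boosted_ensemble(
    surface: AnalyticSurface,
    boost: BoostModel,
    n_frames: int,
    seed: int,
    grid_points: int | None = None,
    environment: GaussianEnvironment | None = None,
) -> BoostedEnsemble:
    """Draw frames from the boosted Boltzmann density exp(-(V+dV)/kT).

    Sampling is exact on a fine regular grid (categorical draw over grid
    cells, uniform jitter within the cell), so there is no equilibration or
    correlation to worry about.  Each frame carries its CV value(s) and the
    exact boost components evaluated at its grid cell; the generating
    surface rides along as ground truth.

    With ``environment`` given, the boost is evaluated on the sum of the
    CV potential and an independent Gaussian bath energy, which makes the
    per-frame boost distribution near-Gaussian as in a full simulation;
    the CV marginal and the per-frame reweighting stay exact.
    """
    if n_frames < 1:
        raise InputError(f"n_frames must be >= 1, got {n_frames}")
    if grid_points is None:
        grid_points = 2001 if surface.ndim == 1 else 301
    axes, V = surface.grid(grid_points)
    kT = surface.kT

    if environment is None:
        v_min = float(V.min())
        dv_pot, dv_dih = boost.components(V, v_min)
        dv = dv_pot + dv_dih
        logp = -(V + dv - v_min) / kT
        cell_shape = V.shape
    else:
        eps, logf = environment.axis()
        v_tot = V[..., None] + eps  # bath energy as an extra quadrature axis
        v_min = float(V.min()) + float(eps.min())
        dv_pot, dv_dih = boost.components(v_tot, v_min)
        dv = dv_pot + dv_dih
        logp = logf - (V[..., None] - V.min()) / kT - dv / kT
        cell_shape = v_tot.shape

    p = np.exp(logp - logp.max())
    p /= p.sum()

    rng = np.random.default_rng(seed)
    flat_idx = rng.choice(p.size, size=n_frames, p=p.ravel())
    cell_idx = np.unravel_index(flat_idx, cell_shape)
    steps = [ax[1] - ax[0] if len(ax) > 1 else 1.0 for ax in axes]
    cv = np.column_stack(
        [
            axes[d][cell_idx[d]] + rng.uniform(-0.5, 0.5, n_frames) * steps[d]
            for d in range(surface.ndim)
        ]
    )
    dv_frames = dv.ravel()[flat_idx]
    dvd_frames = dv_dih.ravel()[flat_idx]
    return BoostedEnsemble(
        cv=cv,
        dv_total=dv_frames,
        dv_dihedral=dvd_frames,
        temperature=surface.temperature,
        truth=surface,
    )


def write_ensemble_csv(ensemble: BoostedEnsemble, path: str | Path) -> None:
    """Write the ensemble table (frame, cv1[, cv2], dV_total, dV_dihedral)."""
    data = {"frame": np.arange(ensemble.n_frames)}
    for k in range(ensemble.ndim):
        data[f"cv{k+1}"] = ensemble.cv[:, k]
    data["dV_total"] = ensemble.dv_total
    data["dV_dihedral"] = (
        ensemble.dv_dihedral
        if ensemble.dv_dihedral is not None
        else np.zeros(ensemble.n_frames)
    )
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Toy labeled trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyAtom:
    """A named pseudo-atom: residue number/name and atom name (PDB style)."""

    resid: int
    resname: str
    name: str

    @property
    def label(self) -> str:
        return f"{self.resid}:{self.name}"


@dataclass
class ToyGeometry:
    """Named pseudo-atom layout with one coordinate set per state (Å)."""

    atoms: list[ToyAtom]
    coords: dict[str, np.ndarray]  # state -> (n_atoms, 3)
    box: float = 200.0  # orthorhombic box edge, large enough to be inert

    def __post_init__(self) -> None:
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise InputError(f"duplicate atom labels: {dupes}")
        for state, xyz in self.coords.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (len(self.atoms), 3):
                raise InputError(
                    f"state '{state}' coordinates have shape {xyz.shape}, "
                    f"expected ({len(self.atoms)}, 3)"
                )
            self.coords[state] = xyz

    def index_of(self, label: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.label == label:
                return i
        raise InputError(f"no atom labelled '{label}'")


@dataclass
class ToyStructureSet:
    """Synthetic trajectory with per-frame state labels and exact geometry.

    ``frames`` are the (possibly noisy) emitted coordinates; ``ideal`` are
    the noiseless state-template coordinates per frame, which define the
    ground truth for every distance/angle.
    """

    geometry: ToyGeometry
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    ideal: np.ndarray
    schedule: list[str]
    noise_sd: float
    seed: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    # -- ground truth -----------------------------------------------------

    def truth_distance(self, a: str, b: str) -> np.ndarray:
        ia, ib = self.geometry.index_of(a), self.geometry.index_of(b)
        return np.linalg.norm(self.ideal[:, ia] - self.ideal[:, ib], axis=1)

    def truth_angle(self, a: str, b: str, c: str) -> np.ndarray:
        ia = self.geometry.index_of(a)
        ib = self.geometry.index_of(b)
        ic = self.geometry.index_of(c)
        u = self.ideal[:, ia] - self.ideal[:, ib]
        w = self.ideal[:, ic] - self.ideal[:, ib]
        cosang = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
        )
        return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    # -- output -----------------------------------------------------------

    def _universe(self):
        import MDAnalysis as mda

        n = len(self.geometry.atoms)
        u = mda.Universe.empty(
            n, n_residues=n, atom_resindex=np.arange(n), trajectory=True
        )
        u.add_TopologyAttr("names", [a.name for a in self.geometry.atoms])
        u.add_TopologyAttr("resnames", [a.resname for a in self.geometry.atoms])
        u.add_TopologyAttr("resids", [a.resid for a in self.geometry.atoms])
        u.add_TopologyAttr("tempfactors", np.zeros(n))
        u.load_new(self.frames.astype(np.float32))
        box = self.geometry.box
        for ts in u.trajectory:
            ts.dimensions = [box, box, box, 90.0, 90.0, 90.0]
        u.trajectory[0]
        return u

    def write_pdb(self, path: str | Path) -> None:
        """First-frame topology as PDB."""
        import warnings

        u = self._universe()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.write(str(path))

    def write_dcd(self, path: str | Path) -> None:
        import warnings

        import MDAnalysis as mda

        u = self._universe()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), n_atoms=u.atoms.n_atoms) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)

    def write_csv(self, path: str | Path) -> None:
        """Plain-text coordinates: frame, atom_index, x, y, z (Å)."""
        f, a, _ = self.frames.shape
        frame_idx = np.repeat(np.arange(f), a)
        atom_idx = np.tile(np.arange(a), f)
        xyz = self.frames.reshape(-1, 3)
        pd.DataFrame(
            {
                "frame": frame_idx,
                "atom_index": atom_idx,
                "x": xyz[:, 0],
                "y": xyz[:, 1],
                "z": xyz[:, 2],
            }
        ).to_csv(path, index=False)

    def write_truth_json(self, path: str | Path) -> None:
        payload = {
            "schedule": self.schedule,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "atoms": [a.label for a in self.geometry.atoms],
            "state_coords": {
                s: xyz.tolist() for s, xyz in self.geometry.coords.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def default_kinase_geometry() -> ToyGeometry:
    """Two-rigid-group layout mimicking the kinase N-lobe/C-lobe atoms.

    The closed state puts the lobe-separation distance (CA 1904 – CA 2060)
    at 28.5 Å and the compact distance (CA 2054 – CA 1791) at 20 Å; the
    open state moves the C-lobe group so those become 29.8 Å and 25 Å,
    and breaks the K1906–D2017 triad contact.
    """
    atoms = [
        ToyAtom(1904, "ALA", "CA"),
        ToyAtom(1906, "LYS", "NZ"),
        ToyAtom(1920, "GLU", "CD"),
        ToyAtom(2017, "ASP", "CG"),
        ToyAtom(2060, "ALA", "CA"),
        ToyAtom(2054, "ALA", "CA"),
        ToyAtom(1791, "TRP", "CA"),
    ]
    closed = np.array(
        [
            [0.0, 0.0, 0.0],    # 1904 CA
            [2.0, 1.0, 0.0],    # 1906 NZ
            [4.8, 1.0, 0.0],    # 1920 CD  (K-E 2.8 Å)
            [2.0, 4.5, 0.0],    # 2017 CG  (K-D 3.5 Å: triad formed)
            [28.5, 0.0, 0.0],   # 2060 CA  (lobe distance 28.5 Å)
            [26.0, 3.0, 0.0],   # 2054 CA
            [26.0, 23.0, 0.0],  # 1791 CA  (compact distance 20 Å)
        ]
    )
    open_ = np.array(
        [
            [0.0, 0.0, 0.0],
            [2.0, 1.0, 0.0],
            [4.8, 1.0, 0.0],
            [3.0, 6.0, 0.0],    # triad broken (K-D ~5.1 Å)
            [29.8, 0.0, 0.0],   # lobe distance 29.8 Å
            [27.3, 3.0, 0.0],
            [27.3, 28.0, 0.0],  # extended distance 25 Å
        ]
    )
    return ToyGeometry(atoms=atoms, coords={"closed": closed, "open": open_})


def gen_toy_trajectory(
    n_frames: int,
    geometry: ToyGeometry | None = None,
    state_schedule: Sequence[str] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ToyStructureSet:
    """Emit a labelled pseudo-atom trajectory following a state schedule.

    Each frame copies its state's template coordinates plus isotropic
    Gaussian noise of ``noise_sd`` Å; with zero noise the emitted
    coordinates reproduce the templates exactly.
    """
    if n_frames < 1:
        raise InputError(f"n_frames must be >= 1, got {n_frames}")
    if geometry is None:
        geometry = default_kinase_geometry()
    states = sorted(geometry.coords)
    if state_schedule is None:
        state_schedule = [states[i % len(states)] for i in range(n_frames)]
    schedule = list(state_schedule)
    if len(schedule) != n_frames:
        raise InputError(
            f"schedule length {len(schedule)} does not match n_frames {n_frames}"
        )
    unknown = sorted(set(schedule) - set(geometry.coords))
    if unknown:
        raise InputError(f"schedule names unknown states: {unknown}")

    ideal = np.stack([geometry.coords[s] for s in schedule])
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, noise_sd, ideal.shape) if noise_sd > 0 else np.zeros_like(ideal)
    )
    return ToyStructureSet(
        geometry=geometry,
        frames=ideal + noise,
        ideal=ideal,
        schedule=schedule,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Synthetic HDX uptake tables
# ---------------------------------------------------------------------------


@dataclass
class HDXGroundTruth:
    """Exchange kinetics underlying a synthetic uptake table.

    Per peptide: one intrinsic rate constant k_j (min^-1) and plateau
    contribution (Da) per exchangeable amide.  A global back-exchange
    fraction f scales everything the instrument would see; replicate noise
    is Gaussian with the stated sd.
    """

    rates: list[np.ndarray]
    plateaus: list[np.ndarray] | None = None
    back_exchange: float = 0.25
    noise_sd: float = 0.1
    exposures: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)

    def __post_init__(self) -> None:
        self.rates = [np.atleast_1d(np.asarray(r, dtype=float)) for r in self.rates]
        for r in self.rates:
            if np.any(r <= 0):
                raise InputError("all intrinsic rates k_j must be positive")
        if self.plateaus is None:
            self.plateaus = [np.ones_like(r) for r in self.rates]
        else:
            self.plateaus = [
                np.atleast_1d(np.asarray(p, dtype=float)) for p in self.plateaus
            ]
        for r, p in zip(self.rates, self.plateaus):
            if r.shape != p.shape:
                raise InputError("rates and plateaus must align per peptide")
        if not (0.0 <= self.back_exchange < 1.0):
            raise InputError(
                f"back-exchange fraction must lie in [0, 1), got {self.back_exchange}"
            )
        if 0.0 not in self.exposures:
            raise InputError("exposure set must include the 0 min control")

    def mean_uptake(self, peptide_index: int, t: float) -> float:
        """Noise-free observed uptake (Da) at exposure t (min)."""
        k = self.rates[peptide_index]
        a = self.plateaus[peptide_index]
        return float((1.0 - self.back_exchange) * np.sum(a * (1.0 - np.exp(-k * t))))


def gen_hdx_dataset(
    peptides: Sequence[Peptide],
    truth: HDXGroundTruth,
    n_replicates: int = 3,
    seed: int = 0,
    state: str = "apo",
) -> pd.DataFrame:
    """Synthetic replicate uptake table for one experimental state.

    Columns: peptide_start, peptide_end, sequence, charge, state,
    exposure_min, replicate, uptake_Da.  The noise-free value at exposure
    t is ``(1 - f) * sum_j plateau_j (1 - exp(-k_j t))``; Gaussian noise
    of sd ``truth.noise_sd`` is added independently per replicate
    (including at t = 0, whose mean is exactly zero).
    """
    if n_replicates < 1:
        raise InputError(f"n_replicates must be >= 1, got {n_replicates}")
    if len(truth.rates) != len(peptides):
        raise InputError(
            f"{len(truth.rates)} rate sets given for {len(peptides)} peptides"
        )
    for pep, plateau in zip(peptides, truth.plateaus):
        if plateau.sum() > max_uptake(pep) + 1e-9:
            raise InputError(
                f"peptide {pep.start}-{pep.end}: plateau {plateau.sum():.2f} Da "
                f"exceeds theoretical maximum {max_uptake(pep)} Da"
            )

    rng = np.random.default_rng(seed)
    rows = []
    for i, pep in enumerate(peptides):
        for t in truth.exposures:
            mean = truth.mean_uptake(i, t)
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
                rows.append(
                    {
                        "peptide_start": pep.start,
                        "peptide_end": pep.end,
                        "sequence": pep.sequence,
                        "charge": pep.charge,
                        "state": state,
                        "exposure_min": t,
                        "replicate": rep,
                        "uptake_Da": mean + noise,
                    }
                )
    return pd.DataFrame(rows)


def write_hdx_truth_json(truth: HDXGroundTruth, peptides: Sequence[Peptide],
                         path: str | Path) -> None:
    payload = {
        "back_exchange": truth.back_exchange,
        "noise_sd": truth.noise_sd,
        "exposures": list(truth.exposures),
        "peptides": [
            {
                "start": p.start,
                "end": p.end,
                "sequence": p.sequence,
                "rates_per_min": truth.rates[i].tolist(),
                "plateaus_Da": truth.plateaus[i].tolist(),
            }
            for i, p in enumerate(peptides)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
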