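"""Collective-variable extraction from topology/trajectory files.

Reads a PDB topology with DCD/XTC coordinates (via MDAnalysis) or a plain
CSV coordinate table, and computes the conformational coordinates used to
characterise kinase states: atom-pair distances (e.g. the N-lobe to
C-lobe CA 1904 – CA 2060 separation), three-point angles (N-lobe
orientation, ROC alpha-C tilt), contact / hydrogen-bond occupancies, and
least-squares-fitted RMSD series.

Selections use full-length LRRK2 residue numbering as carried in the PDB
— no internal renumbering — so a selection like ``1906:NZ`` means residue
1906, atom NZ.  A selection that does not resolve to exactly one atom is
a hard error: silent nearest-atom substitution is how selection bugs
hide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import FormatError, InputError, SelectionError

logger = logging.getLogger(__name__)

#: Heavy-atom contact cutoff (Å).
DEFAULT_CONTACT_CUTOFF = 4.0
#: Donor-acceptor heavy-atom distance proxy for a hydrogen bond (Å).
HBOND_CUTOFF = 3.5


@dataclass(frozen=True)
class AtomSelection:
    """One atom: residue number (1-based), optional residue name, atom name."""

    resid: int
    name: str
    resname: str | None = None

    @classmethod
    def parse(cls, text: str) -> "AtomSelection":
        """Parse ``RESID:NAME`` (e.g. ``1904:CA``) or ``RESID:RESNAME:NAME``."""
        parts = text.strip().split(":")
        if len(parts) == 2:
            return cls(resid=int(parts[0]), name=parts[1].upper())
        if len(parts) == 3:
            return cls(resid=int(parts[0]), resname=parts[1].upper(),
                       name=parts[2].upper())
        raise SelectionError(f"cannot parse atom selection '{text}'")

    def __str__(self) -> str:
        if self.resname:
            return f"{self.resid}:{self.resname}:{self.name}"
        return f"{self.resid}:{self.name}"


@dataclass
class CVSeries:
    """A named per-frame scalar series with units (Å or degrees)."""

    name: str
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.units not in ("angstrom", "degrees"):
            raise InputError(f"unsupported units '{self.units}'")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)


class Trajectory:
    """In-memory trajectory handle: atom metadata plus frame coordinates (Å)."""

    def __init__(
        self,
        resids: np.ndarray,
        resnames: np.ndarray,
        names: np.ndarray,
        coords: np.ndarray,
        box: np.ndarray | None = None,
        source: str = "<memory>",
    ) -> None:
        self.resids = np.asarray(resids)
        self.resnames = np.asarray(resnames)
        self.names = np.asarray(names)
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coordinates must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.resids.size:
            raise FormatError(
                f"coordinate atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.resids.size}"
            )
        self.box = None if box is None else np.asarray(box, dtype=float)
        self.source = source

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def resolve(self, sel: AtomSelection) -> int:
        """Index of the unique atom matching the selection."""
        match = (self.resids == sel.resid) & (
            np.char.upper(self.names.astype(str)) == sel.name.upper()
        )
        if sel.resname is not None:
            match &= np.char.upper(self.resnames.astype(str)) == sel.resname.upper()
        idx = np.flatnonzero(match)
        if idx.size == 0:
            raise SelectionError(
                f"selection {sel} matches no atom in {self.source}"
            )
        if idx.size > 1:
            raise SelectionError(
                f"selection {sel} is ambiguous ({idx.size} atoms) in {self.source}"
            )
        return int(idx[0])


def load_trajectory(topology_path: str | Path,
                    coordinates_path: str | Path) -> Trajectory:
    """Load a PDB topology with DCD/XTC or CSV coordinates into memory.

    The CSV alternative carries columns frame, atom_index, x, y, z in Å and
    must cover every topology atom in every frame.  Any atom-count mismatch
    between topology and coordinates fails closed, naming both counts.
    """
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    coordinates_path = Path(coordinates_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        top = mda.Universe(str(topology_path))
    n_atoms = top.atoms.n_atoms
    resids = top.atoms.resids.copy()
    resnames = top.atoms.resnames.copy()
    names = top.atoms.names.copy()

    if coordinates_path.suffix.lower() == ".csv":
        df = pd.read_csv(coordinates_path)
        need = ["frame", "atom_index", "x", "y", "z"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise FormatError(f"{coordinates_path}: missing columns {missing}")
        frames = np.sort(df["frame"].unique())
        per_frame = df.groupby("frame").size()
        if not (per_frame == n_atoms).all():
            raise FormatError(
                f"{coordinates_path}: frame atom count "
                f"{int(per_frame.iloc[0])} does not match topology atom count "
                f"{n_atoms}"
            )
        df = df.sort_values(["frame", "atom_index"])
        coords = df[["x", "y", "z"]].to_numpy().reshape(len(frames), n_atoms, 3)
        box = None
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(str(topology_path), str(coordinates_path))
                coords = np.stack(
                    [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
                )
                dims = u.trajectory[0].dimensions
        except Exception as exc:  # MDAnalysis raises a zoo of types here
            raise FormatError(
                f"cannot read {coordinates_path} against {topology_path} "
                f"({n_atoms} topology atoms): {exc}"
            ) from exc
        box = dims[:3].copy() if dims is not None and np.all(dims[:3] > 0) else None

    traj = Trajectory(resids, resnames, names, coords, box=box,
                      source=str(coordinates_path))
    logger.info(
        "loaded %s: %d atoms, %d frames", coordinates_path, traj.n_atoms,
        traj.n_frames,
    )
    return traj


# ---------------------------------------------------------------------------
# Scalar coordinates
# ---------------------------------------------------------------------------


def _pair_vectors(traj: Trajectory, a: AtomSelection, b: AtomSelection) -> np.ndarray:
    ia, ib = traj.resolve(a), traj.resolve(b)
    d = traj.coords[:, ia] - traj.coords[:, ib]
    if traj.box is not None:
        # minimum-image for an orthorhombic box
        d -= traj.box * np.rint(d / traj.box)
    return d


def distance_series(traj: Trajectory, a: AtomSelection, b: AtomSelection) -> CVSeries:
    """Per-frame Euclidean distance in Å (minimum image when a box exists)."""
    d = np.linalg.norm(_pair_vectors(traj, a, b), axis=1)
    return CVSeries(name=f"d_{a}_{b}", values=d, units="angstrom")


def angle_series(traj: Trajectory, a: AtomSelection, b: AtomSelection,
                 c: AtomSelection) -> CVSeries:
    """Per-frame angle a-b-c (vertex b) in degrees, clamped into [0, 180].

    A zero-length arm at the vertex yields NaN for that frame rather than
    a crash.
    """
    if len({str(a), str(b), str(c)}) != 3:
        raise SelectionError("angle needs three distinct atom selections")
    u = _pair_vectors(traj, a, b)
    w = _pair_vectors(traj, c, b)
    nu = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, w) / (nu * nw)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[(nu == 0) | (nw == 0)] = np.nan
    return CVSeries(name=f"ang_{a}_{b}_{c}", values=ang, units="degrees")


def contact_occupancy(traj: Trajectory, a: AtomSelection, b: AtomSelection,
                      cutoff: float = DEFAULT_CONTACT_CUTOFF) -> float:
    """Fraction of frames with the pair distance <= cutoff (Å)."""
    if cutoff <= 0:
        raise InputError(f"cutoff must be positive, got {cutoff}")
    d = distance_series(traj, a, b).values
    return float(np.mean(d <= cutoff))


def hbond_occupancy(traj: Trajectory, donor: AtomSelection,
                    acceptor: AtomSelection) -> float:
    """Hydrogen-bond proxy: donor-acceptor heavy-atom distance <= 3.5 Å."""
    return contact_occupancy(traj, donor, acceptor, cutoff=HBOND_CUTOFF)


# ---------------------------------------------------------------------------
# RMSD with least-squares superposition
# ---------------------------------------------------------------------------


def _resolve_many(traj: Trajectory, sels: Sequence[AtomSelection]) -> np.ndarray:
    return np.array([traj.resolve(s) for s in sels], dtype=int)


def rmsd_series(
    traj: Trajectory,
    fit_selection: Sequence[AtomSelection],
    measure_selection: Sequence[AtomSelection],
    reference_frame: int = 0,
) -> CVSeries:
    """Per-frame RMSD (Å) of ``measure_selection`` after optimally
    superposing each frame onto the reference frame over ``fit_selection``.

    Superposition removes the fit-group centroid and applies the Kabsch
    least-squares rotation; at least three fit atoms are required or the
    rotation is underdetermined.
    """
    if len(fit_selection) < 3:
        raise InputError(
            f"need >= 3 fit atoms for superposition, got {len(fit_selection)}"
        )
    if len(measure_selection) < 1:
        raise InputError("measure selection is empty")
    if not (0 <= reference_frame < traj.n_frames):
        raise InputError(
            f"reference frame {reference_frame} outside 0..{traj.n_frames - 1}"
        )
    fit_idx = _resolve_many(traj, fit_selection)
    meas_idx = _resolve_many(traj, measure_selection)

    ref_fit = traj.coords[reference_frame, fit_idx]
    ref_meas = traj.coords[reference_frame, meas_idx]
    ref_fit_c = ref_fit.mean(axis=0)
    ref_fit0 = ref_fit - ref_fit_c
    ref_meas0 = ref_meas - ref_fit_c

    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        fit = traj.coords[i, fit_idx]
        c = fit.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_fit0, fit - c)
        moved = rot.apply(traj.coords[i, meas_idx] - c)
        out[i] = np.sqrt(np.mean(np.sum((moved - ref_meas0) ** 2, axis=1)))
    return CVSeries(name="rmsd", values=out, units="angstrom")


def windowed_rmsd(
    traj: Trajectory,
    fit_selection: Sequence[AtomSelection],
    residue_windows: Sequence[tuple[int, int]],
    atom_name: str = "CA",
    reference_frame: int = 0,
) -> pd.DataFrame:
    """Mean RMSD per residue window (inclusive ranges), fit on a common set.

    Emulates per-region flexibility profiles: a window whose residues have
    no ``atom_name`` atoms is an error.
    """
    rows = []
    for lo, hi in residue_windows:
        sels = [
            AtomSelection(int(r), atom_name)
            for r in np.unique(traj.resids)
            if lo <= r <= hi
        ]
        if not sels:
            raise SelectionError(f"window {lo}-{hi} selects no {atom_name} atoms")
        series = rmsd_series(traj, fit_selection, sels, reference_frame)
        rows.append({"start": lo, "end": hi,
                     "mean_rmsd": float(np.nanmean(series.values))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_cv_csv(series_list: Sequence[CVSeries], path: str | Path) -> None:
    """Write one column per CV (plus a frame column) with a units header row."""
    if not series_list:
        raise InputError("no CV series to write")
    n = series_list[0].n_frames
    for s in series_list:
        if s.n_frames != n:
            raise InputError("all CV series must have the same frame count")
    df = pd.DataFrame({"frame": np.arange(n)})
    for s in series_list:
        df[f"{s.name} ({s.units})"] = s.values
    df.to_csv(path, index=False, float_format="%.4f")
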