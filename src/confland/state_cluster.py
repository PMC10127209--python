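"""Conformational-state assignment, occupancies, and QT clustering.

States (DYG-in/out, open/closed kinase lobes, compact/extended global
arrangement) are defined as threshold rules on a collective variable,
with an optional dead band labelled ``unassigned``.  Occupancies may be
weighted by reweighting factors so that populations refer to the
canonical ensemble; free-energy differences between states follow from
the population ratio, dF(A→B) = -kT ln(p_B / p_A).

Clustering uses the quality-threshold (QT) scheme: repeatedly emit the
frame with the largest neighbourhood within a distance cutoff as a
cluster representative, remove that neighbourhood, and continue until a
maximum number of clusters (default 20) is reached; leftover frames form
an explicit overflow class, never a silently merged one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.spatial.transform import Rotation

from .cv_engine import CVSeries, Trajectory
from .errors import ConfigError, DegenerateInputError, InputError

UNASSIGNED = "unassigned"
OVERFLOW_CLUSTER = -1
DEFAULT_MAX_CLUSTERS = 20


@dataclass(frozen=True)
class StateDefinition:
    """Two-sided threshold rule on one CV, with an optional dead band.

    Values strictly inside ``threshold ± dead_band/2`` are ``unassigned``;
    at or below the lower edge the frame takes ``below_label``, at or
    above the upper edge ``above_label``.
    """

    name: str
    cv_name: str
    threshold: float
    below_label: str
    above_label: str
    units: str = "angstrom"
    dead_band: float = 0.0

    def __post_init__(self) -> None:
        if self.dead_band < 0:
            raise ConfigError("dead_band must be >= 0")
        if self.below_label == self.above_label:
            raise ConfigError("state labels must differ")

    @property
    def labels(self) -> tuple[str, str]:
        return (self.below_label, self.above_label)


# Documented stand-in defaults for the kinase states.  The open/closed
# threshold (29.0 Å on the CA 1904 - CA 2060 lobe distance) sits midway
# between the closed and open basin minima at 28.5 and 29.8 Å; the
# compact/extended threshold (24.0 Å on CA 2054 - CA 1791) between the
# 20-23 Å compact and 25 Å extended minima.  The DYG-in criterion is a
# configurable proxy: the K1906 NZ - D2017 CG triad distance <= 12 Å.
OPEN_CLOSED = StateDefinition(
    name="kinase_lobes",
    cv_name="d_1904:CA_2060:CA",
    threshold=29.0,
    below_label="closed",
    above_label="open",
)
COMPACT_EXTENDED = StateDefinition(
    name="global_arrangement",
    cv_name="d_2054:CA_1791:CA",
    threshold=24.0,
    below_label="compact",
    above_label="extended",
)
DYG_IN_OUT = StateDefinition(
    name="dyg",
    cv_name="d_1906:NZ_2017:CG",
    threshold=12.0,
    below_label="DYG-in",
    above_label="DYG-out",
)


@dataclass
class StateTrajectory:
    """Per-frame categorical labels with optional reweighting weights."""

    labels: np.ndarray
    definition: StateDefinition
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.labels.shape:
                raise InputError("weights length must equal frame count")

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)


def assign_states(cv: CVSeries, definition: StateDefinition) -> StateTrajectory:
    """Deterministic labelling of every frame by the threshold rule."""
    if cv.units != definition.units:
        raise ConfigError(
            f"CV '{cv.name}' has units {cv.units} but state '{definition.name}' "
            f"expects {definition.units}"
        )
    half = definition.dead_band / 2.0
    lo_edge = definition.threshold - half
    hi_edge = definition.threshold + half
    labels = np.full(cv.n_frames, UNASSIGNED, dtype=object)
    labels[cv.values <= lo_edge] = definition.below_label
    labels[cv.values >= hi_edge] = definition.above_label
    # a zero dead band leaves exactly-at-threshold frames on the low side
    if definition.dead_band == 0:
        labels[cv.values <= definition.threshold] = definition.below_label
    labels[~np.isfinite(cv.values)] = UNASSIGNED
    return StateTrajectory(labels=labels, definition=definition)


def state_occupancy(
    st: StateTrajectory, weights: np.ndarray | None = None
) -> dict[str, float]:
    """Fraction of (weighted) frames per label; fractions sum to 1."""
    if weights is None:
        weights = st.weights
    if weights is None:
        weights = np.ones(st.n_frames)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (st.n_frames,):
        raise InputError("weights length must equal frame count")
    if np.any(weights < 0):
        raise InputError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise DegenerateInputError("all occupancy weights are zero")
    out: dict[str, float] = {}
    for lab in (*st.definition.labels, UNASSIGNED):
        mask = st.labels == lab
        if lab == UNASSIGNED and not mask.any():
            continue
        out[lab] = float(weights[mask].sum() / total)
    return out


def state_free_energy_difference(
    st: StateTrajectory,
    label_a: str,
    label_b: str,
    kT: float,
    weights: np.ndarray | None = None,
) -> float:
    """dF(A→B) = -kT ln(p_B / p_A) from weighted populations (kcal/mol).

    NaN (with a warning) when either state is unpopulated — the difference
    is undefined, not zero.
    """
    occ = state_occupancy(st, weights)
    pa, pb = occ.get(label_a, 0.0), occ.get(label_b, 0.0)
    if pa <= 0 or pb <= 0:
        warnings.warn(
            f"free-energy difference {label_a}→{label_b} undefined: "
            f"occupancies {pa:.3g}, {pb:.3g}",
            stacklevel=2,
        )
        return float("nan")
    return float(-kT * np.log(pb / pa))


# ---------------------------------------------------------------------------
# Quality-threshold clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """QT clustering outcome.

    ``labels`` holds a 0-based cluster id per frame (ids ordered by size,
    largest first) or -1 for overflow frames that no emitted cluster
    absorbed.  Each representative frame belongs to its own cluster.
    """

    labels: np.ndarray
    representatives: list[int]
    sizes: list[int]
    cutoff: float
    n_clusters: int

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def _pairwise_fitted_rmsd(coords: np.ndarray) -> np.ndarray:
    """All-pairs RMSD after Kabsch superposition; coords (N, A, 3)."""
    n = coords.shape[0]
    centered = coords - coords.mean(axis=1, keepdims=True)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rot, rssd = Rotation.align_vectors(centered[i], centered[j])
            d[i, j] = d[j, i] = rssd / np.sqrt(coords.shape[1])
    return d


def qt_cluster(
    frames: np.ndarray,
    cutoff: float,
    metric: str = "euclidean",
    max_clusters: int = DEFAULT_MAX_CLUSTERS,
) -> ClusterResult:
    """Quality-threshold clustering of frames.

    ``frames`` is (N, d) feature vectors for the euclidean metric or
    (N, A, 3) coordinates for the fitted-RMSD metric.  Deterministic for a
    given input order: ties in neighbourhood size break toward the lowest
    frame index.  Emitted ids are re-ranked by cluster size (descending,
    stable), and frames left after ``max_clusters`` rounds go to the
    overflow class (-1).
    """
    frames = np.asarray(frames, dtype=float)
    if not np.all(np.isfinite(frames)):
        raise InputError("frames contain non-finite coordinates")
    if cutoff <= 0:
        raise InputError(f"cutoff must be positive, got {cutoff}")
    if max_clusters < 1:
        raise ConfigError("max_clusters must be >= 1")

    if metric == "euclidean":
        if frames.ndim == 1:
            frames = frames[:, None]
        if frames.ndim != 2:
            raise InputError("euclidean metric expects (N, d) feature vectors")
        dist = squareform(pdist(frames))
    elif metric == "rmsd":
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise InputError("rmsd metric expects (N, atoms, 3) coordinates")
        dist = _pairwise_fitted_rmsd(frames)
    else:
        raise ConfigError(f"unknown metric '{metric}'")

    n = dist.shape[0]
    labels = np.full(n, OVERFLOW_CLUSTER, dtype=int)
    remaining = np.ones(n, dtype=bool)
    neighbors = dist <= cutoff

    reps: list[int] = []
    sizes: list[int] = []
    for _ in range(max_clusters):
        if not remaining.any():
            break
        counts = (neighbors & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest tied index
        members = np.flatnonzero(neighbors[center] & remaining)
        labels[members] = len(reps)
        reps.append(center)
        sizes.append(int(members.size))
        remaining[members] = False

    # re-rank by size descending (stable: emission order already non-increasing)
    order = sorted(range(len(reps)), key=lambda i: (-sizes[i], i))
    relabel = {old: new for new, old in enumerate(order)}
    new_labels = labels.copy()
    for old, new in relabel.items():
        new_labels[labels == old] = new
    return ClusterResult(
        labels=new_labels,
        representatives=[reps[i] for i in order],
        sizes=[sizes[i] for i in order],
        cutoff=cutoff,
        n_clusters=len(reps),
    )


def qt_cluster_bruteforce(
    frames: np.ndarray, cutoff: float, max_clusters: int = DEFAULT_MAX_CLUSTERS
) -> ClusterResult:
    """Reference QT implementation by explicit enumeration (tests only).

    Recomputes every candidate neighbourhood from scratch each round
    instead of masking a precomputed matrix; O(rounds · N²) distance
    evaluations on purpose, as an independent oracle for small N.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 1:
        frames = frames[:, None]
    n = frames.shape[0]
    labels = np.full(n, OVERFLOW_CLUSTER, dtype=int)
    remaining = list(range(n))
    reps, sizes = [], []
    for _ in range(max_clusters):
        if not remaining:
            break
        best_center, best_members = None, None
        for c in remaining:
            members = [
                j for j in remaining
                if float(np.linalg.norm(frames[c] - frames[j])) <= cutoff
            ]
            if best_members is None or len(members) > len(best_members):
                best_center, best_members = c, members
        labels[best_members] = len(reps)
        reps.append(best_center)
        sizes.append(len(best_members))
        remaining = [j for j in remaining if j not in set(best_members)]
    order = sorted(range(len(reps)), key=lambda i: (-sizes[i], i))
    new_labels = labels.copy()
    for new, old in enumerate(order):
        new_labels[labels == old] = new
    return ClusterResult(
        labels=new_labels,
        representatives=[reps[i] for i in order],
        sizes=[sizes[i] for i in order],
        cutoff=cutoff,
        n_clusters=len(reps),
    )


def representative_structures(
    cluster: ClusterResult,
    traj: Trajectory,
    out_dir: str | Path,
    ranks: Sequence[int] | None = None,
) -> list[Path]:
    """Write one PDB per requested cluster rank (1-based, 1 = largest).

    A rank beyond the available clusters is an error that lists what
    exists.
    """
    import MDAnalysis as mda

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if ranks is None:
        ranks = [1]
    paths = []
    for rank in ranks:
        if not (1 <= rank <= cluster.n_clusters):
            raise InputError(
                f"cluster rank {rank} unavailable; "
                f"available ranks: 1..{cluster.n_clusters}"
            )
        frame = cluster.representatives[rank - 1]
        if not (0 <= frame < traj.n_frames):
            raise InputError(
                f"representative frame {frame} outside trajectory "
                f"(0..{traj.n_frames - 1})"
            )
        n = traj.n_atoms
        u = mda.Universe.empty(
            n, n_residues=n, atom_resindex=np.arange(n), trajectory=True
        )
        u.add_TopologyAttr("names", traj.names.astype(str))
        u.add_TopologyAttr("resnames", traj.resnames.astype(str))
        u.add_TopologyAttr("resids", traj.resids)
        u.atoms.positions = traj.coords[frame].astype(np.float32)
        path = out_dir / f"cluster_{rank:02d}_frame_{frame}.pdb"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.write(str(path))
        paths.append(path)
    return paths


def cluster_report(cluster: ClusterResult) -> pd.DataFrame:
    """Cluster summary table: cluster id, size, representative frame."""
    rows = [
        {"cluster": i, "size": cluster.sizes[i],
         "representative_frame": cluster.representatives[i]}
        for i in range(cluster.n_clusters)
    ]
    n_overflow = int((cluster.labels == OVERFLOW_CLUSTER).sum())
    if n_overflow:
        rows.append(
            {"cluster": OVERFLOW_CLUSTER, "size": n_overflow,
             "representative_frame": -1}
        )
    return pd.DataFrame(rows)
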