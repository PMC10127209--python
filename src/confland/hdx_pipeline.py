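"""Peptide-level deuterium-uptake quantification for HDX-MS.

Centroid-based uptake, theoretical maxima, percent-of-maximum, global
back-exchange correction, replicate statistics (mean ± SEM), exponential
uptake-curve fits, differential (state vs reference) comparison, and
mapping of per-peptide values onto a structure's B-factor column.

Conventions:

* Theoretical maximum uptake counts exchangeable backbone amides:
  peptide length minus the first residue minus internal prolines (the
  N-terminal amide back-exchanges too fast to measure; proline has no
  amide hydrogen).  An 11-residue proline-free peptide thus has a 10 Da
  maximum.
* Percent-of-maximum is computed on uncorrected uptake; the
  back-exchange-corrected value is carried as a separate column.
* SEM uses the sample standard deviation (n-1 denominator) over
  replicates; a single replicate reports SEM as missing, never 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InputError, SchemaError

DEFAULT_BACK_EXCHANGE = 0.25
#: Differential-significance rule: |delta| must exceed both this floor (Da)
#: and 2x the propagated SEM.  A repo convention, configurable per call.
DEFAULT_MIN_DELTA = 0.5

#: B-factor sentinel for residues not covered by any peptide.
UNCOVERED_SENTINEL = -99.99


@dataclass(frozen=True)
class Peptide:
    """A pepsin peptide: inclusive residue range, sequence, charge state."""

    start: int
    end: int
    sequence: str
    charge: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError("peptide sequence is empty")
        if self.end - self.start + 1 != len(self.sequence):
            raise InputError(
                f"peptide {self.start}-{self.end} spans "
                f"{self.end - self.start + 1} residues but sequence has "
                f"{len(self.sequence)}"
            )
        if self.charge < 1:
            raise InputError(f"charge must be >= 1, got {self.charge}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UptakeMeasurement:
    """One replicate observation for a peptide/state/exposure.

    Either ``uptake_da`` directly, or a deuterated/undeuterated centroid
    m/z pair from which uptake is derived.
    """

    peptide: Peptide
    state: str
    exposure_min: float
    replicate: int
    uptake_da: float | None = None
    centroid_deuterated: float | None = None
    centroid_undeuterated: float | None = None

    def __post_init__(self) -> None:
        if self.exposure_min < 0:
            raise InputError("exposure must be >= 0 min")


@dataclass(frozen=True)
class UptakeSummary:
    """Replicate summary for one peptide/state/exposure."""

    peptide: Peptide
    state: str
    exposure_min: float
    mean_da: float
    sem_da: float | None  # None when n == 1
    n: int
    percent_of_max: float | None
    corrected_da: float
    flagged_over_max: bool = False


def max_uptake(p: Peptide) -> int:
    """Theoretical maximum uptake in Da: exchangeable backbone amides.

    Length minus the first residue minus prolines at positions 2..length.
    """
    return p.length - 1 - p.sequence[1:].count("P")


def uptake_from_centroids(m: UptakeMeasurement) -> float:
    """Uptake (Da) from centroid m/z: (deuterated - undeuterated) * charge.

    Slightly negative values (to -0.2 Da) are tolerated as centroid noise;
    anything more negative is kept but flagged, since a swapped pair is the
    usual culprit.
    """
    if m.centroid_deuterated is None or m.centroid_undeuterated is None:
        raise InputError("both deuterated and undeuterated centroids are required")
    uptake = (m.centroid_deuterated - m.centroid_undeuterated) * m.peptide.charge
    if uptake < -0.2:
        warnings.warn(
            f"peptide {m.peptide.start}-{m.peptide.end} state {m.state} "
            f"t={m.exposure_min}: uptake {uptake:.2f} Da is strongly negative "
            "(swapped centroids suspected)",
            stacklevel=2,
        )
    return uptake


def percent_of_max(uptake_da: float, p: Peptide) -> float:
    """Uptake as a percentage of the peptide's theoretical maximum."""
    mx = max_uptake(p)
    if mx <= 0:
        raise InputError(
            f"peptide {p.start}-{p.end} has no exchangeable amides; "
            "percent-of-maximum is undefined"
        )
    return 100.0 * uptake_da / mx


def back_exchange_correct(uptake_da: float, f: float = DEFAULT_BACK_EXCHANGE) -> float:
    """Correct observed uptake for a global back-exchange loss fraction f."""
    if not (0.0 <= f < 1.0):
        raise InputError(f"back-exchange fraction must lie in [0, 1), got {f}")
    return uptake_da / (1.0 - f)


def summarize_replicates(
    peptide: Peptide,
    state: str,
    exposure_min: float,
    uptakes: Sequence[float],
    back_exchange: float = DEFAULT_BACK_EXCHANGE,
) -> UptakeSummary:
    """Mean ± SEM over replicates, plus percent-of-max and corrected uptake."""
    vals = np.asarray(list(uptakes), dtype=float)
    if vals.size < 1:
        raise InputError("at least one replicate is required")
    if not np.all(np.isfinite(vals)):
        raise InputError("replicate uptakes must be finite")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else None
    mx = max_uptake(peptide)
    pct = 100.0 * mean / mx if mx > 0 else None
    flagged = pct is not None and pct > 110.0
    return UptakeSummary(
        peptide=peptide,
        state=state,
        exposure_min=exposure_min,
        mean_da=mean,
        sem_da=sem,
        n=int(vals.size),
        percent_of_max=pct,
        corrected_da=back_exchange_correct(mean, back_exchange),
        flagged_over_max=flagged,
    )


@dataclass(frozen=True)
class UptakeFit:
    """Single-exponential-to-plateau fit U(t) = A (1 - exp(-k t)).

    Presentational only: downstream statistics always use raw replicate
    means.  ``flagged`` marks non-convergence or an essentially flat curve.
    """

    amplitude_da: float
    rate_per_min: float
    flagged: bool
    message: str = ""

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.amplitude_da * (1.0 - np.exp(-self.rate_per_min * np.asarray(t)))


def fit_uptake_curve(
    exposures_min: Sequence[float],
    uptakes_da: Sequence[float],
    plateau_bound: float,
) -> UptakeFit:
    """Least-squares exponential fit with 0 <= A <= plateau_bound, k > 0."""
    t = np.asarray(exposures_min, dtype=float)
    u = np.asarray(uptakes_da, dtype=float)
    if t.size < 3 or 0.0 not in t:
        raise InputError("need >= 3 exposure points including the 0 min control")
    if t.shape != u.shape:
        raise InputError("exposures and uptakes must have equal length")
    umax = float(u.max())
    if umax <= 1e-9:
        return UptakeFit(0.0, 0.0, flagged=True, message="flat (all-zero uptake)")

    def model(tt, a, k):
        return a * (1.0 - np.exp(-k * tt))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model,
                t,
                u,
                p0=[min(umax, plateau_bound), 1.0],
                bounds=([0.0, 1e-9], [plateau_bound, np.inf]),
                maxfev=10000,
            )
    except (RuntimeError, ValueError) as exc:
        return UptakeFit(
            float("nan"), float("nan"), flagged=True, message=f"fit failed: {exc}"
        )
    return UptakeFit(float(popt[0]), float(popt[1]), flagged=False)


@dataclass(frozen=True)
class DifferentialUptake:
    """State-minus-reference uptake difference for one peptide/exposure."""

    peptide: Peptide
    exposure_min: float
    delta_da: float  # mean(state) - mean(reference)
    sem_da: float | None
    significant: bool


def differential_uptake(
    reference: UptakeSummary,
    other: UptakeSummary,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> DifferentialUptake:
    """Difference ``other - reference`` with propagated SEM.

    Significant when |delta| >= max(min_delta, 2 * SEM_delta); protection
    by an inhibitor therefore shows up as a negative delta against the apo
    reference.
    """
    if reference.peptide != other.peptide or reference.exposure_min != other.exposure_min:
        raise InputError("differential requires matching peptide and exposure")
    delta = other.mean_da - reference.mean_da
    if reference.sem_da is None or other.sem_da is None:
        sem = None
        significant = abs(delta) >= min_delta
    else:
        sem = math.sqrt(reference.sem_da**2 + other.sem_da**2)
        significant = abs(delta) >= max(min_delta, 2.0 * sem)
    return DifferentialUptake(
        peptide=reference.peptide,
        exposure_min=reference.exposure_min,
        delta_da=delta,
        sem_da=sem,
        significant=significant,
    )


# ---------------------------------------------------------------------------
# Tabular interface
# ---------------------------------------------------------------------------

STATE_DATA_COLUMNS = [
    "peptide_start",
    "peptide_end",
    "sequence",
    "charge",
    "state",
    "exposure_min",
    "replicate",
    "uptake_Da",
]


def read_state_data(path: str | Path) -> pd.DataFrame:
    """Read and validate a replicate-level uptake table.

    The layout follows the common per-state export of HDX workbench tools:
    one row per peptide x state x exposure x replicate with uptake in Da.
    Schema violations raise before any computation.
    """
    df = pd.read_csv(path)
    missing = [c for c in STATE_DATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    problems = []
    if df.empty:
        problems.append("table has no rows")
    if not df.empty:
        if (df["exposure_min"] < 0).any():
            problems.append("negative exposure times")
        if (df["peptide_end"] < df["peptide_start"]).any():
            problems.append("peptide_end < peptide_start")
        if df["uptake_Da"].isna().any() or ~np.isfinite(df["uptake_Da"]).all():
            problems.append("non-finite uptake values")
        lengths = df["peptide_end"] - df["peptide_start"] + 1
        if (lengths != df["sequence"].str.len()).any():
            problems.append("sequence length does not match residue range")
        dup = df.duplicated(
            subset=["peptide_start", "peptide_end", "state", "exposure_min", "replicate"]
        )
        if dup.any():
            problems.append("duplicate replicate ids within a peptide/state/exposure")
    if problems:
        raise SchemaError(f"{path}: " + "; ".join(problems))
    return df


def summarize_table(
    df: pd.DataFrame, back_exchange: float = DEFAULT_BACK_EXCHANGE
) -> list[UptakeSummary]:
    """Replicate summaries for every peptide/state/exposure group."""
    out = []
    keys = ["peptide_start", "peptide_end", "sequence", "charge", "state", "exposure_min"]
    for (start, end, seq, z, state, t), grp in df.groupby(keys, sort=True):
        pep = Peptide(int(start), int(end), str(seq), int(z))
        out.append(
            summarize_replicates(
                pep, str(state), float(t), grp["uptake_Da"].to_list(), back_exchange
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[UptakeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide_start": [s.peptide.start for s in summaries],
            "peptide_end": [s.peptide.end for s in summaries],
            "sequence": [s.peptide.sequence for s in summaries],
            "state": [s.state for s in summaries],
            "exposure_min": [s.exposure_min for s in summaries],
            "mean_Da": [s.mean_da for s in summaries],
            "sem_Da": [s.sem_da for s in summaries],
            "n": [s.n for s in summaries],
            "percent_of_max": [s.percent_of_max for s in summaries],
            "corrected_Da": [s.corrected_da for s in summaries],
        }
    )


def differential_table(
    summaries: Sequence[UptakeSummary],
    reference_state: str,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> pd.DataFrame:
    """Woods-plot-ready differentials of every other state vs the reference.

    Peptide/exposure pairs present in only one state are excluded (the
    intersection is reported); a missing reference state is an error that
    names the states actually present.
    """
    states = sorted({s.state for s in summaries})
    if reference_state not in states:
        raise InputError(
            f"reference state '{reference_state}' not in data; available: {states}"
        )
    index = {(s.peptide, s.exposure_min, s.state): s for s in summaries}
    rows = []
    for s in summaries:
        if s.state == reference_state:
            continue
        ref = index.get((s.peptide, s.exposure_min, reference_state))
        if ref is None:
            continue
        d = differential_uptake(ref, s, min_delta)
        rows.append(
            {
                "peptide_start": s.peptide.start,
                "peptide_end": s.peptide.end,
                "sequence": s.peptide.sequence,
                "state": s.state,
                "exposure_min": s.exposure_min,
                "delta_Da": d.delta_da,
                "sem_Da": d.sem_da,
                "significant": d.significant,
            }
        )
    return pd.DataFrame(rows)


def map_uptake_to_structure(
    per_peptide: dict[Peptide, float] | pd.DataFrame,
    topology_path: str | Path,
    out_path: str | Path,
    sentinel: float = UNCOVERED_SENTINEL,
) -> dict[int, float]:
    """Project per-peptide values onto residues and write them as B-factors.

    Residues covered by several peptides take the mean of the covering
    values; uncovered residues get the sentinel.  Accepts a
    ``{Peptide: value}`` mapping or a frame with peptide_start /
    peptide_end / a single value column (e.g. delta_Da).  Returns the
    per-residue map actually written.
    """
    import MDAnalysis as mda

    if isinstance(per_peptide, pd.DataFrame):
        value_col = next(
            c for c in per_peptide.columns
            if c not in ("peptide_start", "peptide_end", "sequence", "charge",
                         "state", "exposure_min", "sem_Da", "significant", "n")
        )
        ranges = [
            (int(r.peptide_start), int(r.peptide_end), float(getattr(r, value_col)))
            for r in per_peptide.itertuples()
        ]
    else:
        ranges = [(p.start, p.end, float(v)) for p, v in per_peptide.items()]
    if not ranges:
        raise InputError("no peptides to map")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path))
    resids = u.atoms.resids
    lo, hi = int(resids.min()), int(resids.max())
    for start, end, _ in ranges:
        if start < lo or end > hi:
            raise InputError(
                f"peptide {start}-{end} outside topology residue range {lo}-{hi}"
            )

    acc: dict[int, list[float]] = {}
    for start, end, val in ranges:
        for r in range(start, end + 1):
            acc.setdefault(r, []).append(val)
    per_residue = {r: float(np.mean(v)) for r, v in acc.items()}
    if not per_residue:
        raise InputError("no residue is covered by any peptide")

    if not hasattr(u.atoms, "tempfactors"):
        u.add_TopologyAttr("tempfactors", np.zeros(u.atoms.n_atoms))
    bfac = np.array(
        [per_residue.get(int(r), sentinel) for r in resids], dtype=float
    )
    u.atoms.tempfactors = bfac
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(out_path))
    return per_residue
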