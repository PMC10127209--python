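"""End-to-end pipeline orchestration from a single declarative config.

Two pipelines are composed from the library modules:

* landscape: (synthesize or load a boosted ensemble) → Maclaurin
  reweighting → free-energy landscape → state occupancies → QT cluster
  report;
* hdx: (synthesize or load a replicate uptake table) → per-peptide
  summaries → differentials vs a reference state → optional mapping onto
  a structure.

Every run writes a manifest listing parameters, the seed, and a SHA-256
hash of each output file; outputs are staged in a temporary directory and
moved into place only when the whole pipeline succeeds, so a failed run
leaves nothing behind.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .gamd_reweight import (
    DEFAULT_BINS,
    DEFAULT_MACLAURIN_ORDER,
    DEFAULT_MIN_COUNT,
    DEFAULT_TEMPERATURE,
    free_energy,
    kT_at,
    locate_minima,
    maclaurin_weights,
    plot_landscape,
    read_ensemble_csv,
    reweight_histogram,
    write_landscape_csv,
)
from .cv_engine import CVSeries
from .hdx_pipeline import (
    DEFAULT_BACK_EXCHANGE,
    DEFAULT_MIN_DELTA,
    Peptide,
    differential_table,
    map_uptake_to_structure,
    read_state_data,
    summaries_to_frame,
    summarize_table,
)
from .state_cluster import (
    DEFAULT_MAX_CLUSTERS,
    StateDefinition,
    assign_states,
    cluster_report,
    qt_cluster,
    state_occupancy,
)
from .synthetic_data import (
    BoostModel,
    HDXGroundTruth,
    double_well_1d,
    flat_surface,
    gen_boosted_ensemble,
    gen_hdx_dataset,
    harmonic_surface,
    two_basin_surface_2d,
    write_ensemble_csv,
)

logger = logging.getLogger(__name__)

_SURFACES = {
    "harmonic": harmonic_surface,
    "double_well": double_well_1d,
    "two_basin": two_basin_surface_2d,
    "flat": flat_surface,
}

_STATE_PRESETS = {
    # thresholds on ensemble CV axes; axis picks cv1 (0) or cv2 (1)
    "basin": {"name": "basin", "axis": 0, "threshold": 0.0,
              "below": "left", "above": "right"},
}


@dataclass
class LandscapeConfig:
    ensemble_csv: str | None = None
    surface: str = "two_basin"
    n_frames: int = 20000
    k0_total: float = 0.2
    k0_dihedral: float | None = 0.1
    temperature: float = DEFAULT_TEMPERATURE
    maclaurin_order: int = DEFAULT_MACLAURIN_ORDER
    bins: int = DEFAULT_BINS
    min_count: int = DEFAULT_MIN_COUNT
    states: list[dict] = field(default_factory=lambda: [dict(_STATE_PRESETS["basin"])])
    cluster_cutoff: float = 0.35
    max_clusters: int = DEFAULT_MAX_CLUSTERS
    cluster_sample: int = 400  # frames subsampled for O(N^2) clustering


@dataclass
class HDXConfig:
    input_csv: str | None = None
    back_exchange: float = DEFAULT_BACK_EXCHANGE
    reference_state: str = "apo"
    min_delta: float = DEFAULT_MIN_DELTA
    topology: str | None = None
    map_exposure: float = 2.0
    map_state: str | None = None


@dataclass
class RunConfig:
    """Validated run configuration; every field has a recorded default."""

    seed: int = 0
    output_dir: str = "confland_out"
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    hdx: HDXConfig = field(default_factory=HDXConfig)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        raw = dict(raw or {})
        known = {"seed", "output_dir", "landscape", "hdx"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")

        def build(dc, section: dict | None, label: str):
            section = dict(section or {})
            fields = {f.name for f in dc.__dataclass_fields__.values()}
            bad = set(section) - fields
            if bad:
                raise ConfigError(f"unknown keys in '{label}': {sorted(bad)}")
            return dc(**section)

        cfg = cls(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "confland_out")),
            landscape=build(LandscapeConfig, raw.get("landscape"), "landscape"),
            hdx=build(HDXConfig, raw.get("hdx"), "hdx"),
        )
        if cfg.landscape.surface not in _SURFACES:
            raise ConfigError(
                f"unknown surface '{cfg.landscape.surface}'; "
                f"choose from {sorted(_SURFACES)}"
            )
        if cfg.landscape.n_frames < 1:
            raise ConfigError("landscape.n_frames must be >= 1")
        if not (0 <= cfg.hdx.back_exchange < 1):
            raise ConfigError("hdx.back_exchange must lie in [0, 1)")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if raw is not None and not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _StagedRun:
    """Stage outputs in a temp dir; commit moves them into the final dir."""

    def __init__(self, out_dir: Path):
        self.final = Path(out_dir)
        self.final.mkdir(parents=True, exist_ok=True)
        self.tmp = Path(tempfile.mkdtemp(prefix=".confland-", dir=self.final.parent))
        self.outputs: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.tmp / name
        self.outputs.append(p)
        return p

    def commit(self, manifest: dict) -> dict:
        manifest["outputs"] = {
            p.name: _sha256(p) for p in self.outputs if p.exists()
        }
        (self.tmp / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for p in [*self.outputs, self.tmp / "manifest.json"]:
            if p.exists():
                shutil.move(str(p), str(self.final / p.name))
        shutil.rmtree(self.tmp, ignore_errors=True)
        return manifest

    def abort(self) -> None:
        shutil.rmtree(self.tmp, ignore_errors=True)


def run_landscape_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Synthetic-or-loaded ensemble → landscape, states, clusters.

    Returns the manifest.  All stage outputs (ensemble CSV when
    synthesized, landscape CSV/PNG, minima CSV, occupancy CSV, cluster
    report CSV) land in ``out_dir`` atomically.
    """
    lc = config.landscape
    out = Path(out_dir) if out_dir else Path(config.output_dir) / "landscape"
    run = _StagedRun(out)
    try:
        stage = "input"
        if lc.ensemble_csv:
            ensemble = read_ensemble_csv(lc.ensemble_csv, temperature=lc.temperature)
        else:
            surface = _SURFACES[lc.surface](temperature=lc.temperature)
            boost = BoostModel.for_surface(
                surface, k0_total=lc.k0_total, k0_dihedral=lc.k0_dihedral
            )
            ensemble = gen_boosted_ensemble(
                surface, boost, n_frames=lc.n_frames, seed=config.seed
            )
            write_ensemble_csv(ensemble, run.path("ensemble.csv"))
        logger.info("landscape stage %s: %d frames, %d CV axes",
                    stage, ensemble.n_frames, ensemble.ndim)

        stage = "reweight"
        kT = kT_at(lc.temperature)
        weights = maclaurin_weights(ensemble.dv_total, kT, lc.maclaurin_order)
        hist = reweight_histogram(ensemble, bins=lc.bins, weights=weights)
        landscape = free_energy(hist, kT, min_count=lc.min_count)
        write_landscape_csv(landscape, run.path("landscape.csv"))
        plot_landscape(landscape, run.path("landscape.png"))
        minima, flat = locate_minima(landscape)
        pd.DataFrame(
            [{"rank": i + 1,
              **{f"cv{d+1}": m.coords[d] for d in range(len(m.coords))},
              "depth_kcal_mol": m.depth}
             for i, m in enumerate(minima)]
        ).to_csv(run.path("minima.csv"), index=False)

        stage = "states"
        occ_rows = []
        for sdef in lc.states:
            axis = int(sdef.get("axis", 0))
            if axis >= ensemble.ndim:
                raise ConfigError(
                    f"state '{sdef.get('name')}' uses CV axis {axis} but the "
                    f"ensemble has {ensemble.ndim}"
                )
            definition = StateDefinition(
                name=str(sdef["name"]),
                cv_name=f"cv{axis+1}",
                threshold=float(sdef["threshold"]),
                below_label=str(sdef["below"]),
                above_label=str(sdef["above"]),
                dead_band=float(sdef.get("dead_band", 0.0)),
            )
            series = CVSeries(
                name=definition.cv_name,
                values=ensemble.cv[:, axis],
                units=definition.units,
            )
            st = assign_states(series, definition)
            for label, frac in state_occupancy(st, weights).items():
                occ_rows.append(
                    {"state_set": definition.name, "label": label,
                     "occupancy": frac}
                )
        pd.DataFrame(occ_rows).to_csv(run.path("state_occupancy.csv"), index=False)

        stage = "cluster"
        rng = np.random.default_rng(config.seed + 1)
        n_sub = min(lc.cluster_sample, ensemble.n_frames)
        sub = np.sort(rng.choice(ensemble.n_frames, size=n_sub, replace=False))
        result = qt_cluster(
            ensemble.cv[sub], cutoff=lc.cluster_cutoff,
            max_clusters=lc.max_clusters,
        )
        report = cluster_report(result)
        # map subsample indices back to original frame ids
        report["representative_frame"] = [
            int(sub[r]) if r >= 0 else -1 for r in report["representative_frame"]
        ]
        report.to_csv(run.path("cluster_report.csv"), index=False)

        manifest = {
            "pipeline": "landscape",
            "confland_version": __version__,
            "seed": config.seed,
            "parameters": asdict(lc),
            "n_frames": ensemble.n_frames,
            "n_minima": len(minima),
            "flat": flat,
            "stages": ["input", "reweight", "states", "cluster"],
        }
        return run.commit(manifest)
    except Exception:
        run.abort()
        logger.error("landscape pipeline failed at stage '%s'", stage)
        raise


def _demo_hdx_table(seed: int) -> pd.DataFrame:
    """Small three-state synthetic uptake dataset for the demo pipeline."""
    peptides = [
        Peptide(1948, 1958, "AQLEHGYVSAK", 2),  # synthetic proline-free linker
        Peptide(1990, 2002, "YIAPEVLRGKSYD", 2),
        Peptide(1436, 1449, "SGRELAYHINKTGQ", 2),
    ]
    base = [np.array([2.0, 0.9, 0.35]), np.array([1.2, 0.4]), np.array([1.5, 0.8])]
    frames = []
    for offset, (state, scale) in enumerate(
        (("apo", 1.0), ("MLi-2", 0.35), ("Rebastinib", 0.7))
    ):
        truth = HDXGroundTruth(
            rates=[r * scale for r in base],
            plateaus=[np.array([3.0, 1.5, 1.5]), np.array([2.0, 2.0]),
                      np.array([2.5, 2.0])],
            back_exchange=0.25,
            noise_sd=0.05,
        )
        frames.append(gen_hdx_dataset(peptides, truth, n_replicates=3,
                                      seed=seed * 17 + offset, state=state))
    return pd.concat(frames, ignore_index=True)


def run_hdx_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Uptake table → summaries → differentials → optional structure map."""
    hc = config.hdx
    out = Path(out_dir) if out_dir else Path(config.output_dir) / "hdx"
    run = _StagedRun(out)
    try:
        stage = "input"
        if hc.input_csv:
            df = read_state_data(hc.input_csv)
        else:
            df = _demo_hdx_table(config.seed)
            df.to_csv(run.path("state_data.csv"), index=False)
        logger.info("hdx stage %s: %d rows, states %s", stage, len(df),
                    sorted(df['state'].unique()))

        stage = "summaries"
        summaries = summarize_table(df, back_exchange=hc.back_exchange)
        summaries_to_frame(summaries).to_csv(
            run.path("uptake_summary.csv"), index=False
        )

        stage = "differential"
        diff = differential_table(summaries, hc.reference_state,
                                  min_delta=hc.min_delta)
        diff.to_csv(run.path("differential_uptake.csv"), index=False)

        stage = "mapping"
        if hc.topology:
            state = hc.map_state or (
                sorted(diff["state"].unique())[0] if len(diff) else None
            )
            sel = diff[
                (diff["state"] == state)
                & (diff["exposure_min"] == hc.map_exposure)
            ]
            if len(sel):
                map_uptake_to_structure(
                    sel[["peptide_start", "peptide_end", "delta_Da"]],
                    hc.topology,
                    run.path("differential_map.pdb"),
                )

        manifest = {
            "pipeline": "hdx",
            "confland_version": __version__,
            "seed": config.seed,
            "parameters": asdict(hc),
            "n_rows": int(len(df)),
            "states": sorted(map(str, df["state"].unique())),
            "stages": ["input", "summaries", "differential", "mapping"],
        }
        return run.commit(manifest)
    except Exception:
        run.abort()
        logger.error("hdx pipeline failed at stage '%s'", stage)
        raise


def run_demo(config: RunConfig | None = None) -> dict:
    """Fully synthetic end-to-end run of both pipelines."""
    config = config or RunConfig()
    m1 = run_landscape_pipeline(config)
    m2 = run_hdx_pipeline(config)
    return {"landscape": m1, "hdx": m2}
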