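"""End-to-end orchestration: encounters -> network -> communities -> habitat.

``run_all`` executes the stages in order (prepare, associate, cluster, geo,
mrqap, habitat), failing fast with the stage name on any error, and returns
a :class:`RunReport` whose every headline number is re-derivable from the
stage outputs it references.  With a ``synth`` config block, the input data
are generated by the simulator and the report additionally scores the
recovered partition against the planted subpopulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import association as _assoc
from . import community as _comm
from . import encounters as _enc
from . import habitat as _hab
from . import mrqap as _mrqap
from . import seascape as _sea
from . import synth as _synth

__all__ = ["RunReport", "StageError", "run_all", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("prepare", "associate", "cluster", "geo", "mrqap", "habitat")

_STAGE_DEPS = {
    "prepare": (),
    "associate": ("prepare",),
    "cluster": ("associate",),
    "geo": ("prepare",),
    "mrqap": ("cluster", "geo"),
    "habitat": ("cluster", "geo"),
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class ConfigError(ValueError):
    """The run configuration is invalid or incomplete."""


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config_hash: str
    seed: int | None
    stages: list[str]
    outputs: dict[str, str] = field(default_factory=dict)
    numbers: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "stages": self.stages,
                "outputs": self.outputs,
                "numbers": self.numbers,
            },
            indent=1,
            default=float,
        ))


def _close_stages(requested) -> list[str]:
    want: set[str] = set()

    def add(s: str) -> None:
        if s in want:
            return
        for dep in _STAGE_DEPS[s]:
            add(dep)
        want.add(s)

    for s in requested:
        if s not in _STAGE_DEPS:
            raise ConfigError(f"unknown stage {s!r}")
        add(s)
    return [s for s in DEFAULT_STAGES if s in want]


def run_all(
    config: dict | str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    stages=None,
) -> RunReport:
    """Run the pipeline per a config mapping (or YAML path).

    Config keys: ``synth`` (simulator parameters) *or* ``encounters`` (+
    optional ``schema``) with ``dem`` and ``lon0``/``lat0``; plus
    ``min_sightings`` (default 3), ``n_perm`` (default 1000), ``quantile``
    (default 0.9), ``isobath_m`` (default 200), ``min_edge`` (default 0),
    ``stages``.  ``seed`` overrides the simulator/permutation seeds.
    Numbers for stages that were not requested are omitted from the report.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    requested = list(stages or cfg.get("stages") or DEFAULT_STAGES)
    run_stages = _close_stages(requested)
    requested_set = set(requested)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    min_sightings = int(cfg.get("min_sightings", 3))
    n_perm = int(cfg.get("n_perm", 1000))
    quantile = float(cfg.get("quantile", 0.90))
    isobath_m = float(cfg.get("isobath_m", 200.0))
    min_edge = float(cfg.get("min_edge", 0.0))

    numbers: dict = {}
    outputs: dict[str, str] = {}
    truth = None
    grid = None

    # --- input acquisition -------------------------------------------------
    if "synth" in cfg:
        synth_kwargs = dict(cfg.get("synth") or {})
        if seed is not None:
            synth_kwargs["seed"] = seed
        sim = _synth.SimConfig(**synth_kwargs)
        grid = _synth.make_seascape(sim)
        registry, truth = _synth.simulate_population(sim)
        raw_records, tracks = _synth.simulate_encounters(registry, truth, grid, sim)
        lon0, lat0 = sim.lon0, sim.lat0
        config_hash = sim.config_hash()
        used_seed = sim.seed
        if out is not None:
            _enc.write_encounters(raw_records, out / "encounters.csv")
            grid.write_ascii(out / "seascape.asc")
            truth.to_json(out / "truth.json")
            outputs["encounters"] = str(out / "encounters.csv")
            outputs["seascape"] = str(out / "seascape.asc")
            outputs["truth"] = str(out / "truth.json")
    elif "encounters" in cfg:
        raw_records, rejected = _enc.read_encounters(cfg["encounters"], cfg.get("schema"))
        numbers["n_rejected_rows"] = len(rejected)
        tracks = []
        lon0 = cfg.get("lon0")
        lat0 = cfg.get("lat0")
        config_hash = "user-data"
        used_seed = seed
        needs_geo = bool({"geo", "mrqap", "habitat"} & set(run_stages))
        if needs_geo:
            if "dem" not in cfg:
                raise ConfigError("geospatial stages enabled but config has no 'dem' raster path")
            grid = _sea.read_ascii_grid(cfg["dem"])
            if lon0 is None or lat0 is None:
                raise ConfigError("'lon0'/'lat0' projection anchor required with a DEM")
    else:
        raise ConfigError("config must contain either a 'synth' block or an 'encounters' path")

    # --- stages ------------------------------------------------------------
    daily = assoc = result = covariates = None
    try:
        stage = "prepare"
        daily = _enc.consolidate_daily(raw_records)
        records, retained, excluded = _enc.filter_for_network(daily.records, min_sightings)
        if "prepare" in requested_set:
            numbers["n_raw_records"] = len(raw_records)
            numbers["n_daily_encounters"] = len(daily.records)
            numbers["n_individuals_seen"] = len(retained) + len(excluded)
            numbers["n_retained"] = len(retained)
            numbers["n_excluded"] = len(excluded)

        if "associate" in run_stages:
            stage = "associate"
            counts = _assoc.pair_counts(records, retained)
            assoc = _assoc.sri_matrix(counts)
            if out is not None:
                assoc.to_frame().to_csv(out / "sri_matrix.csv")
                outputs["sri_matrix"] = str(out / "sri_matrix.csv")
            if "associate" in requested_set:
                off = ~np.eye(assoc.n_individuals, dtype=bool)
                numbers["mean_nonzero_sri"] = float(assoc.sri[off][assoc.sri[off] > 0].mean())

        if "cluster" in run_stages:
            stage = "cluster"
            dend = _comm.average_linkage(assoc)
            result = _comm.best_partition(dend, assoc)
            if out is not None:
                result.to_json(out / "communities.json")
                (out / "dendrogram.nwk").write_text(_comm.to_newick(dend))
                _comm.export_network(assoc, result, min_edge, out / "network.graphml")
                outputs["communities"] = str(out / "communities.json")
                outputs["dendrogram"] = str(out / "dendrogram.nwk")
                outputs["network"] = str(out / "network.graphml")
            if "cluster" in requested_set:
                numbers["ccc"] = result.ccc
                numbers["q_max"] = result.q_max
                numbers["n_clusters"] = result.n_clusters
                numbers["cluster_sizes"] = sorted(result.cluster_sizes().values(), reverse=True)
                if truth is not None:
                    ids = list(result.partition)
                    found = [result.partition[i] for i in ids]
                    planted = [truth.subpopulation[i] for i in ids]
                    numbers["ari_vs_truth"] = float(adjusted_rand_score(planted, found))

        if "geo" in run_stages:
            stage = "geo"
            covariates = _sea.covariate_table(records, grid, lon0, lat0, retained, isobath_m)
            if out is not None:
                covariates.to_csv(out / "covariates.csv", index=False)
                outputs["covariates"] = str(out / "covariates.csv")
            if tracks:
                pts = np.column_stack(
                    _sea.lonlat_to_xy(
                        np.array([r.lon for r in records]),
                        np.array([r.lat for r in records]),
                        lon0, lat0,
                    )
                )
                effort, _, _ = _sea.effort_grid(tracks, pts)
                if "geo" in requested_set:
                    numbers["effort_total_points"] = int(effort.sum())
            if "geo" in requested_set:
                numbers["n_identifications"] = int(len(covariates))

        if "mrqap" in run_stages and "mrqap" in requested_set:
            stage = "mrqap"
            mr = _fit_mrqap_from_covariates(
                assoc, covariates, n_perm=n_perm,
                seed=used_seed if used_seed is not None else 0,
                include_matriline=cfg.get("matriline_predictor", False),
                matriline=(truth.matriline if truth is not None else None),
            )
            if out is not None:
                mr.to_json(out / "mrqap.json")
                outputs["mrqap"] = str(out / "mrqap.json")
            numbers["mrqap"] = mr.to_dict()

        if "habitat" in run_stages and "habitat" in requested_set:
            stage = "habitat"
            hab_numbers = _habitat_stage(
                records, covariates, result.partition, grid, quantile, isobath_m, out, outputs
            )
            numbers.update(hab_numbers)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - fail fast with the stage name
        raise StageError(stage, exc) from exc

    report = RunReport(
        config_hash=config_hash,
        seed=used_seed,
        stages=list(run_stages),
        outputs=outputs,
        numbers=numbers,
    )
    if out is not None:
        report.to_json(out / "report.json")
    return report


def _fit_mrqap_from_covariates(
    assoc, covariates, n_perm, seed, include_matriline=False, matriline=None
):
    """Habitat/geography predictor matrices from per-individual covariate means."""
    means = covariates.replace([np.inf, -np.inf], np.nan).groupby("individual")[
        ["depth_m", "dist_shore_km", "dist_shelf_km", "lat", "lon"]
    ].mean()
    means = means.reindex(assoc.ids)
    preds = [
        _mrqap.build_predictor(means["depth_m"].to_numpy(), "depth_similarity"),
        _mrqap.build_predictor(means["dist_shore_km"].to_numpy(), "shore_distance_similarity"),
        _mrqap.build_predictor(means["dist_shelf_km"].to_numpy(), "shelf_distance_similarity"),
        _mrqap.geographic_predictor(means["lat"].to_numpy(), means["lon"].to_numpy()),
    ]
    if include_matriline and matriline is not None:
        preds.append(_mrqap.same_group_predictor([matriline[i] for i in assoc.ids]))
    return _mrqap.fit_mrqap(assoc, preds, n_perm=n_perm, seed=seed)


def _habitat_stage(records, covariates, partition, grid, quantile, isobath_m, out, outputs):
    numbers: dict = {}
    labels = sorted(set(partition.values()))
    # identify inner (nearshore) vs outer cluster by mean shore distance
    cov = covariates.copy()
    cov["_cluster"] = cov["individual"].map(partition)
    by_cluster = cov.groupby("_cluster")["dist_shore_km"].mean()
    inner_label = int(by_cluster.idxmin())
    outer_label = int(by_cluster.idxmax())
    numbers["inner_cluster"] = inner_label
    numbers["outer_cluster"] = outer_label

    summaries = []
    for var in ("depth_m", "dist_shore_km", "dist_shelf_km"):
        summaries.extend(_hab.summarize(covariates, partition, var))
    numbers["habitat_summaries"] = [
        {
            "cluster": s.cluster, "variable": s.variable, "mean": s.mean,
            "se": s.se, "min": s.min, "max": s.max, "n": s.n,
        }
        for s in summaries
    ]
    inner_shore = cov.loc[cov["_cluster"] == inner_label, "dist_shore_km"].to_numpy()
    outer_shore = cov.loc[cov["_cluster"] == outer_label, "dist_shore_km"].to_numpy()
    if len(inner_shore) and len(outer_shore) and len(labels) >= 2:
        u, w, p = _hab.rank_sum_test(inner_shore, outer_shore)
        numbers["shore_distance_test"] = {"U": u, "W": w, "p": p}
        env = _hab.fit_envelope(covariates, partition, inner_label, outer_label, quantile)
        numbers["envelope_inner_shore_km"] = env.inner_shore_threshold_km
        numbers["envelope_outer_shelf_km"] = env.outer_shelf_threshold_km
        inside_inner = float((inner_shore <= env.inner_shore_threshold_km).mean())
        outer_shelf = np.abs(
            cov.loc[cov["_cluster"] == outer_label, "signed_shelf_km"].to_numpy()
        )
        inside_outer = float((outer_shelf <= env.outer_shelf_threshold_km).mean())
        numbers["envelope_coverage_inner"] = inside_inner
        numbers["envelope_coverage_outer"] = inside_outer
        if grid is not None:
            zones = _hab.envelope_zones(grid, env, isobath_m)
            numbers["overlap_cells"] = int((zones == 3).sum())
            if out is not None:
                zone_grid = _sea.SeascapeGrid(
                    origin=grid.origin, cell_size=grid.cell_size,
                    elevation=zones.astype(float), crs=grid.crs,
                )
                zone_grid.write_ascii(out / "envelope_zones.asc")
                outputs["envelope_zones"] = str(out / "envelope_zones.asc")

    count, proportion, _ = _hab.mixed_associations(records, partition)
    numbers["mixed_count"] = count
    numbers["mixed_pct"] = 100.0 * proportion
    prey = _hab.prey_composition(records, partition)
    if out is not None and not prey.empty:
        prey.to_csv(out / "prey_composition.csv", index=False)
        outputs["prey_composition"] = str(out / "prey_composition.csv")
    numbers["prey_events"] = int(prey["count"].sum()) if not prey.empty else 0
    return numbers
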