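"""End-to-end calibration workflow with reproducible seeding and a manifest.

The pipeline chains the full procedure: load (or simulate) the data, apply
the habit filter and rare-taxon cutoff, Hellinger- and environment-
transform, group correlated variables, forward-select within groups with
independence tests, partition variance and apply the lambda1/lambda2 gate,
run the model-selection grid with leave-one-out validation, screen
outliers (report-only), estimate optima/tolerances, score indicator
species, cluster sites, and — when coordinates exist — run the RNE
spatial-autocorrelation analysis.  Every stage gets a seed derived from
the master seed by stable hashing of the stage name, and a manifest
records configuration, seed and site/taxon bookkeeping per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import estimate_responses
from .community import cluster_sites, indval, temperature_classes
from .data_model import (
    Dataset,
    DataError,
    hellinger,
    load_dataset,
    rare_taxon_filter,
    relative_abundance,
    transform_env,
)
from .ordination import (
    correlation_groups,
    dca_gradient_length,
    forward_select,
    independence_test,
    lambda_ratio,
    variance_partition,
)
from .synthetic import SimConfig, make_benchmark
from .validation import DEFAULT_GRID, ModelSpec, model_selection_table, outlier_screen, rne_analysis

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_workflow", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(h[:8], 16) % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of the full workflow."""

    count_path: str | None = None
    env_path: str | None = None
    coords_path: str | None = None
    taxon_meta_path: str | None = None
    simulate: bool = False  # generate a synthetic benchmark instead of loading
    outdir: str = "diatomcal_out"
    seed: int = 0
    target_variable: str = "temperature"
    benthic_only: bool = True
    min_pct: float = 1.0
    min_occurrences: int = 2
    threshold_r: float = 0.8
    threshold_p: float = 0.001
    alpha: float = 0.01
    n_perm: int = 999
    rne_radii: tuple[float, ...] = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0)
    exclude_sites: tuple[str, ...] = ()
    forced_covariates: tuple[str, ...] = ()
    indicator_class_width: float = 1.0
    n_env_clusters: int = 3
    n_taxa_clusters: int = 6

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        cfg = cls(**doc)
        return cfg


def _write_tsv(df: pd.DataFrame, path: pathlib.Path, seed: int) -> None:
    header = f"# diatomcal {__version__}  master_seed={seed}\n"
    path.write_text(header + df.to_csv(sep="\t"))


def run_full_workflow(config: PipelineConfig) -> dict:
    """Execute the whole calibration workflow; returns the manifest dict."""
    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "version": __version__, "stages": {}}

    def record(stage: str, **info):
        manifest["stages"][stage] = info
        logger.info("stage %s: %s", stage, info)

    # --- load or simulate -------------------------------------------------
    if config.simulate:
        bench = make_benchmark(SimConfig(seed=stage_seed(config.seed, "simulate")), outdir=out / "synthetic")
        dataset = bench.dataset
    else:
        if config.count_path is None or config.env_path is None:
            raise DataError("count_path and env_path are required unless simulate=true")
        dataset = load_dataset(config.count_path, config.env_path, config.coords_path, config.taxon_meta_path)
    if config.exclude_sites:
        keep = [s for s in dataset.sites if s not in set(config.exclude_sites)]
        dataset = Dataset(
            type(dataset.counts)(dataset.counts.counts.loc[keep], dataset.counts.habit),
            type(dataset.env)(dataset.env.values.loc[keep]),
            None if dataset.coords is None else type(dataset.coords)(dataset.coords.values.loc[keep], dataset.coords.crs_mode),
        )
    record("load", n_sites=len(dataset.sites), n_taxa=len(dataset.counts.taxa))

    # --- preprocessing ----------------------------------------------------
    counts = dataset.counts
    if config.benthic_only:
        counts = counts.subset_habit("benthic")
    rel = relative_abundance(counts)
    rel, filt_report = rare_taxon_filter(rel, config.min_pct, config.min_occurrences)
    hel = hellinger(rel)
    env_t = transform_env(dataset.env)
    record(
        "preprocess",
        n_taxa_after_habit=len(counts.taxa),
        n_taxa_after_filter=len(rel.taxa),
        valve_fraction_retained=filt_report.fraction_of_valves,
    )

    # --- variable screening ----------------------------------------------
    groups = correlation_groups(env_t, config.threshold_r, config.threshold_p)
    length, recommendation = dca_gradient_length(hel)
    record("screen", n_groups=len(groups.groups), gradient_length_sd=length, method=recommendation)

    selected_all: list[str] = []
    sel_frames = []
    for gi, group in enumerate(groups.groups):
        rep = forward_select(
            hel, env_t, group, alpha=config.alpha, n_perm=config.n_perm,
            seed=stage_seed(config.seed, f"forward_select_{gi}"),
        )
        chosen = list(rep.selected)
        # pairwise independence check within the group's selections
        drop: set[str] = set()
        for i in range(len(chosen)):
            for j in range(i + 1, len(chosen)):
                a, b = chosen[i], chosen[j]
                if a in drop or b in drop:
                    continue
                verdict = independence_test(
                    hel, env_t, a, b, config.alpha, config.n_perm,
                    seed=stage_seed(config.seed, f"independence_{gi}_{a}_{b}"),
                )
                if verdict["verdict"] == "dependent":
                    drop.add(a if verdict["retain"] == b else b)
        selected_all.extend(v for v in chosen if v not in drop)
        sel_frames.append(rep.to_frame().assign(group=gi))
    sel_frames = [f for f in sel_frames if not f.empty]
    if sel_frames:
        _write_tsv(pd.concat(sel_frames, ignore_index=True), out / "selection_report.tsv", config.seed)
    record("forward_selection", selected=selected_all)

    covariates = [v for v in config.forced_covariates if v in env_t.variables and v not in selected_all]
    if not selected_all:
        raise DataError("forward selection retained no variables; cannot calibrate")
    part = variance_partition(
        hel, env_t, selected_all, covariates, config.n_perm, stage_seed(config.seed, "partition")
    )
    _write_tsv(part, out / "variance_partition.tsv", config.seed)
    usable = []
    for v in selected_all:
        ratio, ok = lambda_ratio(hel, env_t, v, [s for s in selected_all if s != v] + covariates)
        if ok:
            usable.append(v)
    record("variance_partition", usable_for_calibration=usable,
           joint_constrained_pct=part.attrs["joint_constrained_pct"])

    # --- calibration target ----------------------------------------------
    target = config.target_variable
    if target not in dataset.env.variables:
        raise DataError(f"target variable {target!r} not in environment table")
    if target not in usable:
        logger.warning("target %r did not pass the lambda1/lambda2 gate; proceeding as configured", target)
    x = dataset.env.values[target].to_numpy(dtype=float)

    grid = model_selection_table(rel, x, DEFAULT_GRID)
    _write_tsv(grid, out / "model_selection.tsv", config.seed)
    best = grid[grid["selected"]].iloc[0]
    spec = next(s for s in DEFAULT_GRID if s.label == best["model"])
    mat = hel if best["transform"] == "hellinger" else rel
    record("model_selection", model=best["model"], transform=best["transform"],
           rmsep=float(best["rmsep"]), r2_jack=float(best["r2_jack"]))

    screen = outlier_screen(spec, mat, x)
    record("outlier_screen", flagged=list(map(str, screen["flagged"])))

    resp = estimate_responses(mat, x)
    _write_tsv(resp, out / "optima_tolerances.tsv", config.seed)

    classes = temperature_classes(x, config.indicator_class_width)
    ind = indval(rel, classes.to_numpy(), config.n_perm, stage_seed(config.seed, "indval"))
    _write_tsv(ind, out / "indicators.tsv", config.seed)

    env_clusters = cluster_sites(env_t, min(config.n_env_clusters, len(dataset.sites)))
    taxa_clusters = cluster_sites(hel, min(config.n_taxa_clusters, len(dataset.sites)))
    _write_tsv(env_clusters.assignments.to_frame(), out / "clusters_env.tsv", config.seed)
    _write_tsv(taxa_clusters.assignments.to_frame(), out / "clusters_taxa.tsv", config.seed)
    record("cluster", env_k=env_clusters.k, taxa_k=taxa_clusters.k)

    if dataset.coords is not None:
        rne = rne_analysis(
            spec, mat, x, dataset.coords, list(config.rne_radii),
            seed=stage_seed(config.seed, "rne"),
        )
        _write_tsv(rne.table, out / "rne_curves.tsv", config.seed)
        record("rne", radii=list(config.rne_radii))
    else:
        logger.info("no coordinates supplied; RNE stage skipped")
        record("rne", skipped=True)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
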