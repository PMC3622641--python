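"""End-to-end run orchestration: config, manifests, persisted outputs.

``run_pipeline`` chains loading, filtering, size-factor estimation,
observed + permutation DE/DS scoring, normalization, the multi-weight
integration scan, enrichment testing and the saturation analysis, writing
every intermediate table to the output directory along with a manifest
that snapshots the effective configuration (defaults included) so a rerun
from the manifest reproduces the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .count_data import CountData, attach_size_factors, filter_low_expression, load_counts
from .gsea_engine import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_WEIGHT_ORDER,
    GeneSetCollection,
    compute_scores,
    read_gmt,
    saturation_analysis,
    weight_scan,
)
from .integration import LINEAR, STRATEGIES, normalize_scores

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; every field is echoed into the manifest."""

    counts: str = ""
    phenotype: str = ""
    gmt: str = ""
    strategies: tuple[str, ...] = (LINEAR,)
    alphas: tuple[float, ...] = DEFAULT_ALPHA_GRID
    n_perm: int = 1000
    fdr_cutoff: float = 0.05
    weight_exp: float = 1.0
    min_gene_total: int = 10
    min_subexon_total: int = 5
    min_set_size: int = 5
    max_set_size: int = 1000
    seed: int = 0
    saturation_order: tuple[float, ...] = DEFAULT_WEIGHT_ORDER

    def __post_init__(self) -> None:
        bad = [s for s in self.strategies if s not in STRATEGIES]
        if bad:
            raise ValueError(f"unknown strategies {bad}; choose from {STRATEGIES}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("strategies", "alphas", "saturation_order"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: RunConfig, out_dir: str, input_paths: dict[str, str]) -> str:
    """Write the run manifest (config snapshot, seed, input checksums, version)."""
    manifest = {
        "tool_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {name: {"path": p, "sha256": _sha256(p)} for name, p in input_paths.items()},
    }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")
    return path


def run_pipeline(config: RunConfig, out_dir: str) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and persist all tables under ``out_dir``.

    Returns the main result frames ({"scan", "saturation", "gene_scores"}).
    Stage failures abort with the stage name and the offending entity.
    """
    os.makedirs(out_dir, exist_ok=True)
    for name, path in (("counts", config.counts), ("phenotype", config.phenotype),
                       ("gene sets", config.gmt)):
        if not os.path.exists(path):
            raise FileNotFoundError(f"{name} file not found: {path}")

    def stage(name: str):
        logger.info("stage: %s", name)

    stage("load")
    cd = load_counts(config.counts, config.phenotype)
    collection = read_gmt(config.gmt)

    stage("filter")
    cd = filter_low_expression(cd, config.min_gene_total, config.min_subexon_total)

    stage("size-factors")
    cd = attach_size_factors(cd)

    return run_pipeline_on_data(cd, collection, config, out_dir,
                                inputs={"counts": config.counts,
                                        "phenotype": config.phenotype,
                                        "gmt": config.gmt})


def _write_group_details(cd: CountData, scored, out_dir: str) -> None:
    """Persist per-group estimation details behind the observed scores."""
    from .de_score import estimate_group

    label_a, _ = cd.group_labels
    mask = np.array([cd.groups[s] == label_a for s in cd.samples], dtype=bool)
    Y = cd.Y.values.astype(float)
    s = cd.size_factors.values.astype(float)
    est_a = estimate_group(Y[:, mask], s[mask])
    est_b = estimate_group(Y[:, ~mask], s[~mask])
    pd.DataFrame(
        {
            "gene_id": scored.genes,
            "q_hat_A": est_a.q_hat,
            "q_hat_B": est_b.q_hat,
            "var_A": est_a.var_q,
            "var_B": est_b.var_q,
            "S_DE": scored.de.s_obs,
        }
    ).to_csv(os.path.join(out_dir, "de_details.tsv"), sep="\t", index=False)

    n_used = (
        cd.ds_mask.groupby(level="gene_id", sort=False).sum().reindex(scored.genes).values
    )
    pd.DataFrame(
        {
            "gene_id": scored.genes,
            "N_subexons_used": n_used.astype(int),
            "S_DS": scored.ds.s_obs,
            "flag": scored.ds_flags,
        }
    ).to_csv(os.path.join(out_dir, "ds_details.tsv"), sep="\t", index=False)


def run_pipeline_on_data(
    cd: CountData,
    collection: GeneSetCollection,
    config: RunConfig,
    out_dir: str,
    inputs: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Pipeline stages downstream of loading, on in-memory data."""
    os.makedirs(out_dir, exist_ok=True)

    logger.info("stage: scoring (%d permutations)", config.n_perm)
    scored = compute_scores(cd, n_perm=config.n_perm, seed=config.seed)

    de_norm = normalize_scores(scored.de)
    ds_norm = normalize_scores(scored.ds)
    gene_scores = pd.DataFrame(
        {
            "gene_id": scored.genes,
            "S_DE": scored.de.s_obs,
            "S_DS": scored.ds.s_obs,
            "S_DE_norm": de_norm.s_obs,
            "S_DS_norm": ds_norm.s_obs,
            "ds_flag": scored.ds_flags,
        }
    )
    gene_scores.to_csv(os.path.join(out_dir, "gene_scores.tsv"), sep="\t", index=False)
    _write_group_details(cd, scored, out_dir)

    logger.info("stage: weight scan (%d strategies x %d alphas)",
                len(config.strategies), len(config.alphas))
    scan = weight_scan(
        scored,
        collection,
        strategies=config.strategies,
        alphas=config.alphas,
        fdr_cutoff=config.fdr_cutoff,
        weight_exp=config.weight_exp,
    )
    scan.to_csv(os.path.join(out_dir, "enrichment_scan.tsv"), sep="\t", index=False)

    logger.info("stage: saturation")
    sat_frames = []
    for strategy in config.strategies:
        order = [a for a in config.saturation_order
                 if any(np.isclose(a, list(config.alphas)))]
        sat = saturation_analysis(scan, weight_order=tuple(order), strategy=strategy)
        sat.insert(0, "strategy", strategy)
        sat_frames.append(sat)
    saturation = pd.concat(sat_frames, ignore_index=True)
    saturation.to_csv(os.path.join(out_dir, "saturation.tsv"), sep="\t", index=False)

    write_manifest(config, out_dir, inputs or {})
    return {"scan": scan, "saturation": saturation, "gene_scores": gene_scores}
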