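"""End-to-end pipeline orchestration, file I/O and reproducibility metadata.

``run_pipeline`` chains the full method on a synthetic scenario:
generate sources -> apportion prescribing -> small-area digital
estimates -> assemble the variable matrix -> screen / Box-Cox /
range-scale -> clustergram + two-tier k-means -> pen portraits and
summaries. ``write_outputs`` serialises every artefact as CSV with a
metadata header (config hash + seed) and a checksum manifest, so a
rerun under an identical config reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from ageplace import prescribing, sae
from ageplace.catalogue import variable_catalogue
from ageplace.cluster import ClusterHierarchy, build_clustergram, fit_two_tier
from ageplace.config import ScenarioConfig
from ageplace.preprocess import fit_transform_matrix, screen_variables
from ageplace.profiles import (
    cluster_zscores,
    pen_portrait_export,
    radar_data,
    standardise,
    summary_table,
)
from ageplace import synth


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    k_top: int = 5
    k_sub: Sequence[int] = (3, 2, 2, 3, 3)
    n_init: int = 100
    clustergram_n_init: int = 10
    clustergram_k_range: Sequence[int] = tuple(range(2, 11))
    corr_threshold: float = 0.9
    min_obs: int = 11
    n_years: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.k_sub) != self.k_top:
            raise ValueError("k_sub length must equal k_top")

    def config_hash(self) -> str:
        payload = yaml.safe_dump(
            {**asdict(self), "scenario": asdict(self.scenario)}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineBundle:
    """All artefacts of one pipeline run."""

    config: PipelineConfig
    population: pd.DataFrame
    matrix: pd.DataFrame
    scaled: pd.DataFrame
    screen: object
    transform_spec: object
    clustergram: object
    hierarchy: ClusterHierarchy
    portraits_super: pd.DataFrame
    portraits_group: pd.DataFrame
    summary: pd.DataFrame
    planted: pd.DataFrame
    rates: pd.DataFrame
    digital: pd.DataFrame


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Run the full classification chain on the configured scenario."""
    scn = config.scenario
    population = synth.generate_population(scn)
    survey, constraints = synth.generate_survey_and_constraints(scn, population)
    ledger, registration, _ = synth.generate_prescribing_sources(scn, population)

    rates = prescribing.area_rates(
        ledger, registration, population, n_years=config.n_years
    )
    digital = sae.estimate_digital_engagement(
        survey, constraints, min_obs=config.min_obs, seed=config.seed
    )
    matrix, planted = synth.assemble_variable_matrix(
        scn, population, rates, digital
    )

    screen = screen_variables(matrix, corr_threshold=config.corr_threshold)
    usable = matrix.drop(columns=screen.constant) if screen.constant else matrix
    scaled, spec = fit_transform_matrix(usable)

    clustergram = build_clustergram(
        scaled,
        k_range=config.clustergram_k_range,
        n_init=config.clustergram_n_init,
        seed=config.seed,
    )
    hierarchy = fit_two_tier(
        scaled, k_top=config.k_top, k_sub=config.k_sub,
        n_init=config.n_init, seed=config.seed,
    )

    X_std = standardise(scaled)
    assign = hierarchy.assignments.set_index("area_id")
    portraits_super = cluster_zscores(X_std, assign["supergroup"])
    if config.k_top > 1:
        portraits_group = cluster_zscores(
            X_std, assign["group"], reference="parent",
            parent_labels=assign["supergroup"],
        )
    else:
        portraits_group = cluster_zscores(X_std, assign["group"])
    summary = summary_table(population, hierarchy)

    return PipelineBundle(
        config=config,
        population=population,
        matrix=matrix,
        scaled=scaled,
        screen=screen,
        transform_spec=spec,
        clustergram=clustergram,
        hierarchy=hierarchy,
        portraits_super=portraits_super,
        portraits_group=portraits_group,
        summary=summary,
        planted=planted,
        rates=rates,
        digital=digital,
    )


def _write_csv(df: pd.DataFrame, path: Path, meta: str, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(meta)
        df.to_csv(fh, index=index)


def write_outputs(
    bundle: PipelineBundle,
    out_dir: str | Path,
    boundaries: str | Path | None = None,
) -> dict[str, str]:
    """Write the artefact bundle to ``out_dir``; returns checksums.

    Every CSV starts with a comment header recording the config hash and
    seed. If a GeoJSON boundary file is supplied, cluster codes are
    joined onto feature properties by ``area_id``; otherwise no GeoJSON
    output is produced (and no error raised).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = bundle.config.config_hash()
    meta = f"# ageplace config_hash={cfg_hash} seed={bundle.config.seed}\n"
    cat = variable_catalogue()

    _write_csv(bundle.population, out / "population.csv", meta, index=False)
    _write_csv(bundle.matrix, out / "variable_matrix.csv", meta, index=True)
    _write_csv(bundle.scaled, out / "scaled_matrix.csv", meta, index=True)
    _write_csv(
        bundle.hierarchy.assignments[["area_id", "supergroup", "group"]],
        out / "hierarchy.csv", meta, index=False,
    )
    _write_csv(bundle.clustergram.nodes, out / "clustergram_nodes.csv", meta, False)
    _write_csv(
        bundle.clustergram.transitions, out / "clustergram_transitions.csv", meta, False
    )
    _write_csv(bundle.portraits_super, out / "portraits_supergroups.csv", meta, True)
    _write_csv(bundle.portraits_group, out / "portraits_groups.csv", meta, True)
    _write_csv(bundle.summary, out / "summary.csv", meta, True)
    _write_csv(
        pen_portrait_export(bundle.portraits_super, cat),
        out / "salient_variables.csv", meta, False,
    )
    _write_csv(radar_data(bundle.portraits_super, cat), out / "radar_data.csv", meta, False)
    bundle.transform_spec.to_yaml(out / "transform_spec.yaml")

    if boundaries is not None:
        with open(boundaries) as fh:
            geo = json.load(fh)
        codes = bundle.hierarchy.assignments.set_index("area_id")
        for feat in geo.get("features", []):
            aid = feat.get("properties", {}).get("area_id")
            if aid in codes.index:
                feat["properties"]["supergroup"] = codes.loc[aid, "supergroup"]
                feat["properties"]["group"] = codes.loc[aid, "group"]
        with open(out / "classification.geojson", "w") as fh:
            json.dump(geo, fh)

    checksums = {}
    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            checksums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            {"config_hash": cfg_hash, "seed": bundle.config.seed,
             "checksums": checksums},
            fh, indent=2, sort_keys=True,
        )
    return checksums
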