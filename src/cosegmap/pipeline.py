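"""End-to-end study pipeline on one genotype matrix.

Chains the steps of the map-inflation study: curation (1:1 segregation
and missingness filter), linkage grouping, per-LG full-map construction,
optional double-recombinant correction, cluster detection, skeleton maps,
the sequential and sampled-proportion inflation experiments, summaries,
and the prediction-model comparison.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expansion, io, predict, skeleton
from .linkage import GeneticMap, GenotypeMatrix, build_map, correct_double_recombinants, group_markers, order_markers
from .simpop import TruthTable, segregation_filter, simulate_dh_population

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """Everything a pipeline run produces, ready to be written out."""

    config: io.RunConfig
    matrix: GenotypeMatrix
    truth: TruthTable | None
    filter_log: pd.DataFrame
    unplaced: list[str]
    full_maps: list[GeneticMap]
    correction_log: pd.DataFrame
    cluster_sets: list[skeleton.ClusterSet]
    skeleton_maps: list[GeneticMap]
    records: pd.DataFrame
    summaries: dict[str, pd.DataFrame]
    predictions: pd.DataFrame
    timings: dict[str, float] = field(default_factory=dict)


def load_or_simulate(config: io.RunConfig) -> tuple[GenotypeMatrix, TruthTable | None]:
    if config.genotypes:
        logger.info("reading genotypes from %s", config.genotypes)
        return io.read_genotypes_mstmap(config.genotypes), None
    matrix, truth = simulate_dh_population(config.sim)
    return matrix, truth


def run_study(
    config: io.RunConfig,
    run_phase1: bool = False,
    run_prediction: bool = True,
) -> StudyResult:
    """Run the full study on simulated or loaded genotypes.

    The sequential (one-marker-at-a-time) experiment is expensive — one
    map per co-segregating marker per LG — and is off by default; the
    sampled-proportion experiment and the prediction comparison run by
    default.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    matrix, truth = load_or_simulate(config)

    filtered, filter_log = segregation_filter(
        matrix, alpha=config.alpha, max_missing=config.max_missing
    )
    timings["curation_s"] = time.perf_counter() - t0

    groups, unplaced = group_markers(
        filtered,
        p_cutoff=config.p_cutoff,
        max_dist_cM=config.max_dist_cM,
        fn=config.mapping_function,
        min_informative=config.min_informative,
    )
    timings["grouping_s"] = time.perf_counter() - t0

    full_maps: list[GeneticMap] = []
    correction_logs: list[pd.DataFrame] = []
    cluster_sets: list[skeleton.ClusterSet] = []
    skeleton_maps: list[GeneticMap] = []
    all_records: list = []
    working = filtered
    rng_master = np.random.default_rng(config.seed)

    for gi, group in enumerate(groups):
        lg_id = f"LG{gi + 1:02d}"
        t_lg = time.perf_counter()
        order = order_markers(working, group, min_informative=config.min_informative)
        fmap = build_map(
            working, order, fn=config.mapping_function, lg_id=lg_id,
            min_informative=config.min_informative,
        )
        if config.correct_doubles:
            working, clog = correct_double_recombinants(
                working, fmap, window_cM=config.correction_window_cM
            )
            correction_logs.append(clog)
            # rebuild on corrected calls
            order = order_markers(working, group, min_informative=config.min_informative)
            fmap = build_map(
                working, order, fn=config.mapping_function, lg_id=lg_id,
                min_informative=config.min_informative,
            )
        full_maps.append(fmap)

        if config.cluster_source == "truth":
            if truth is None:
                raise ValueError("cluster_source='truth' requires simulated input")
            cs = skeleton.clusters_from_truth(
                working.subset(group), truth, truth.table.loc[group[0], "lg_id"],
                rng=np.random.default_rng(rng_master.integers(2**31)),
            )
            cs.lg_id = lg_id
        else:
            cs = skeleton.find_clusters(
                working, order, lg_id=lg_id,
                rng=np.random.default_rng(rng_master.integers(2**31)),
                min_informative=config.min_informative,
            )
        cluster_sets.append(cs)
        smap = skeleton.build_skeleton(
            working, cs, fn=config.mapping_function,
            min_informative=config.min_informative,
        )
        skeleton_maps.append(smap)
        if smap.flagged or smap.length <= 0 or cs.n_clusters < 3:
            logger.warning("%s: skeleton too small to compare orders; experiments skipped", lg_id)
            continue

        if run_phase1:
            all_records.extend(
                expansion.phase1_sequential(
                    working, cs, smap, fn=config.mapping_function,
                    seed=config.seed, min_informative=config.min_informative,
                )
            )
        all_records.extend(
            expansion.phase2_sampled(
                working, cs, smap, config.design, fn=config.mapping_function,
                min_informative=config.min_informative,
            )
        )
        timings[f"{lg_id}_s"] = time.perf_counter() - t_lg

    records = expansion.records_to_frame(all_records)
    summaries = (
        expansion.summarize(records[records["mode"] == "phaseII_sampled"])
        if (records["mode"] == "phaseII_sampled").any()
        else {}
    )

    predictions = pd.DataFrame()
    if run_prediction and not records.empty and (records["mode"] == "phaseII_sampled").any():
        table = predict.make_dataset(records)
        if len(table) >= 50:
            frames = [
                predict.fit_models(table, design=d, seed=config.seed)
                for d in config.prediction_designs
            ]
            predictions = pd.concat(frames, ignore_index=True)
        else:
            logger.warning("too few sampled maps (%d) for prediction models", len(table))

    timings["total_s"] = time.perf_counter() - t0
    return StudyResult(
        config=config,
        matrix=working,
        truth=truth,
        filter_log=filter_log,
        unplaced=unplaced,
        full_maps=full_maps,
        correction_log=(
            pd.concat(correction_logs, ignore_index=True)
            if correction_logs
            else pd.DataFrame(columns=["line", "marker", "old", "new"])
        ),
        cluster_sets=cluster_sets,
        skeleton_maps=skeleton_maps,
        records=records,
        summaries=summaries,
        predictions=predictions,
        timings=timings,
    )


def write_outputs(result: StudyResult, out_dir) -> dict[str, str]:
    """Write all study artefacts plus the resolved config and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _save(name: str, writer) -> None:
        p = out / name
        writer(p)
        paths[name] = str(p)

    _save("config.yaml", result.config.to_yaml)
    _save("genotypes.txt", lambda p: io.write_genotypes_mstmap(
        result.matrix, p,
        cut_off_p_value=result.config.p_cutoff,
        no_map_dist=result.config.max_dist_cM,
    ))
    if result.truth is not None:
        _save("truth.tsv", result.truth.to_tsv)
    _save("filter_log.tsv", lambda p: result.filter_log.to_csv(p, sep="\t", index=False))
    if result.full_maps:
        _save("full_map.tsv", lambda p: io.write_map(result.full_maps, p))
    if result.skeleton_maps:
        _save("skeleton_map.tsv", lambda p: io.write_map(result.skeleton_maps, p))
    if result.cluster_sets:
        report = pd.concat([cs.report() for cs in result.cluster_sets], ignore_index=True)
        _save("clusters.tsv", lambda p: report.to_csv(p, sep="\t", index=False))
    _save("correction_log.tsv", lambda p: result.correction_log.to_csv(p, sep="\t", index=False))
    if not result.records.empty:
        _save("records.tsv", lambda p: io.write_records(result.records, p))
    for name, table in result.summaries.items():
        _save(f"summary_{name}.tsv", lambda p, t=table: t.to_csv(p, sep="\t", index=False))
    if not result.predictions.empty:
        _save("predictions.tsv", lambda p: result.predictions.to_csv(p, sep="\t", index=False))
    manifest = {
        "outputs": sorted(paths),
        "seed": result.config.seed,
        "timings_s": {k: round(v, 3) for k, v in result.timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    paths["manifest.json"] = str(out / "manifest.json")
    return paths
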