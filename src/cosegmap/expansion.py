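"""Map-inflation experiments: sequential maps, inflation factor, collinearity.

Two resampling experiments quantify how adding co-segregating markers back
onto a skeleton map inflates its length:

* the *sequential* experiment adds the LG's co-segregating markers one at
  a time in a seeded random order, rebuilding the map after each addition
  (as many maps as there are co-segregating markers);
* the *sampled-proportion* experiment draws a fixed percentage (levels
  10..80% by default, 50 replicates each) of the co-segregating markers
  and rebuilds the map per draw, with a reduced fallback design (levels
  10..60%, 20 replicates) for LGs whose own co-segregation proportion is
  below the top level.

Every rebuilt map is fully re-ordered with the same engine that built the
skeleton, so any length difference is attributable to the added markers,
not to a change of algorithm. Each map yields an inflation factor

    IF = ((L_seq - L_sket) / L_sket) * 100

and the absolute Spearman correlation between the delegate markers' order
in the rebuilt map and in the skeleton (order collinearity).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .linkage import (
    DEFAULT_MAPPING_FN,
    DEFAULT_MIN_INFORMATIVE,
    GeneticMap,
    GenotypeMatrix,
    build_map,
    order_markers,
)
from .skeleton import ClusterSet, coseg_proportion

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "lg_id",
    "mode",
    "proportion_pct",
    "markers_added",
    "replicate",
    "L_seq",
    "L_sket",
    "IF",
    "spearman_rho",
]


@dataclass
class ExperimentDesign:
    """Design of the sampled-proportion experiment.

    LGs whose available co-segregation proportion reaches the top level
    run the full design; the others run the fallback design, with any
    remaining infeasible level skipped (and logged).
    """

    levels: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80)
    replicates: int = 50
    fallback_levels: tuple[int, ...] = (10, 20, 30, 40, 50, 60)
    fallback_replicates: int = 20
    master_seed: int = 0

    def __post_init__(self) -> None:
        for seq in (self.levels, self.fallback_levels):
            if list(seq) != sorted(set(seq)):
                raise ValueError("levels must be strictly increasing")
            if any(not (0 < lv <= 100) for lv in seq):
                raise ValueError("levels must lie in (0, 100]")
        if self.replicates < 1 or self.fallback_replicates < 1:
            raise ValueError("replicates must be >= 1")

    def for_lg(self, available_pct: float) -> tuple[tuple[int, ...], int]:
        """Levels and replicate count applicable to an LG with the given
        co-segregation proportion (percent)."""
        if available_pct >= max(self.levels):
            return self.levels, self.replicates
        levels = tuple(lv for lv in self.fallback_levels if lv <= available_pct)
        return levels, self.fallback_replicates


@dataclass
class SequentialMapRecord:
    """One rebuilt map of the resampling experiments."""

    lg_id: str
    mode: str  # "phaseI_sequential" | "phaseII_sampled"
    proportion_pct: float
    markers_added: int
    replicate: int
    L_seq: float
    L_sket: float
    IF: float
    spearman_rho: float

    def to_dict(self) -> dict:
        return {c: getattr(self, c) for c in RECORD_COLUMNS}


def records_to_frame(records: list[SequentialMapRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records], columns=RECORD_COLUMNS)


def inflation_factor(L_seq: float, L_sket: float) -> float:
    """Inflation factor IF = ((L_seq - L_sket) / L_sket) * 100, in percent.

    May be negative (a rebuilt map can come out shorter); undefined for a
    zero-length skeleton.
    """
    if L_sket <= 0:
        raise ValueError("inflation factor undefined: skeleton length must be > 0")
    return (L_seq - L_sket) / L_sket * 100.0


def order_collinearity(map_seq: GeneticMap, map_sket: GeneticMap) -> float:
    """Absolute Spearman correlation of shared-marker order between maps.

    Computed on the markers the two maps share (the skeleton delegates),
    using their ranks in each map; ties get average ranks. Reported as
    |rho| so that a fully reversed (re-oriented) map scores 1.
    """
    shared = [m for m in map_sket.markers if m in set(map_seq.markers)]
    if len(shared) < 3:
        raise ValueError("order collinearity undefined: <3 shared markers")
    rank_seq = map_seq.rank_of()
    rank_sket = map_sket.rank_of()
    x = [rank_sket[m] for m in shared]
    y = [rank_seq[m] for m in shared]
    rho = spearmanr(x, y).statistic
    return abs(float(rho))


def _rebuild(
    matrix: GenotypeMatrix,
    markers: list[str],
    skeleton_map: GeneticMap,
    fn: str,
    min_informative: int,
) -> tuple[float, float]:
    """Re-order and rebuild a map on ``markers``; return (length, |rho|)."""
    order = order_markers(matrix, markers, min_informative=min_informative)
    gmap = build_map(
        matrix, order, fn=fn, lg_id=skeleton_map.lg_id, min_informative=min_informative
    )
    return gmap.length, order_collinearity(gmap, skeleton_map)


def _lg_seed_seq(master_seed: int, lg_id: str, *key: int) -> np.random.SeedSequence:
    """Deterministic per-(LG, level, replicate) seed derivation."""
    return np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(zlib.crc32(lg_id.encode()), *key)
    )


def phase1_sequential(
    matrix: GenotypeMatrix,
    clusters: ClusterSet,
    skeleton_map: GeneticMap,
    fn: str = DEFAULT_MAPPING_FN,
    seed: int = 0,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> list[SequentialMapRecord]:
    """Add co-segregating markers back one at a time, rebuilding each time.

    A seeded random permutation of the LG's co-segregating (non-delegate)
    markers is drawn; for k = 1..n_coseg the map is fully re-ordered and
    rebuilt on the delegates plus the first k markers of the permutation.
    Emits one record per k (n_coseg records in total).
    """
    coseg = list(clusters.coseg_markers)
    if not coseg:
        return []
    rng = np.random.default_rng(_lg_seed_seq(seed, clusters.lg_id, 0))
    perm = list(rng.permutation(coseg))
    delegates = list(clusters.delegates)
    L_sket = skeleton_map.length
    n_total = clusters.n_markers
    records: list[SequentialMapRecord] = []
    for k in range(1, len(perm) + 1):
        markers = delegates + perm[:k]
        try:
            L_seq, rho = _rebuild(matrix, markers, skeleton_map, fn, min_informative)
        except ValueError as exc:
            logger.error("%s: sequential map k=%d aborted: %s", clusters.lg_id, k, exc)
            raise
        records.append(
            SequentialMapRecord(
                lg_id=clusters.lg_id,
                mode="phaseI_sequential",
                proportion_pct=coseg_proportion(k, n_total),
                markers_added=k,
                replicate=0,
                L_seq=L_seq,
                L_sket=L_sket,
                IF=inflation_factor(L_seq, L_sket),
                spearman_rho=rho,
            )
        )
    return records


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def phase2_sampled(
    matrix: GenotypeMatrix,
    clusters: ClusterSet,
    skeleton_map: GeneticMap,
    design: ExperimentDesign,
    fn: str = DEFAULT_MAPPING_FN,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> list[SequentialMapRecord]:
    """Rebuild maps on the delegates plus sampled co-segregating markers.

    For each feasible proportion level p and replicate,
    round-half-up(p/100 x n_coseg) co-segregating markers are drawn
    uniformly without replacement, with the RNG seeded from
    (master seed, LG, level, replicate) so any single record is
    reproducible in isolation.
    """
    coseg = sorted(clusters.coseg_markers)
    n_coseg = len(coseg)
    if n_coseg == 0:
        logger.info("%s: no co-segregating markers; nothing to sample", clusters.lg_id)
        return []
    available_pct = coseg_proportion(n_coseg, clusters.n_markers)
    levels, replicates = design.for_lg(available_pct)
    delegates = list(clusters.delegates)
    L_sket = skeleton_map.length
    records: list[SequentialMapRecord] = []
    for level in levels:
        n_sample = _round_half_up(level / 100.0 * n_coseg)
        if n_sample < 1 or n_sample > n_coseg:
            logger.info(
                "%s: level %d%% infeasible (%d of %d markers); skipped",
                clusters.lg_id, level, n_sample, n_coseg,
            )
            continue
        for rep in range(replicates):
            rng = np.random.default_rng(
                _lg_seed_seq(design.master_seed, clusters.lg_id, level, rep)
            )
            sample = list(rng.choice(coseg, size=n_sample, replace=False))
            L_seq, rho = _rebuild(
                matrix, delegates + sample, skeleton_map, fn, min_informative
            )
            records.append(
                SequentialMapRecord(
                    lg_id=clusters.lg_id,
                    mode="phaseII_sampled",
                    proportion_pct=float(level),
                    markers_added=n_sample,
                    replicate=rep,
                    L_seq=L_seq,
                    L_sket=L_sket,
                    IF=inflation_factor(L_seq, L_sket),
                    spearman_rho=rho,
                )
            )
    return records


def summarize(records: pd.DataFrame | list[SequentialMapRecord]) -> dict[str, pd.DataFrame]:
    """Mean/SD inflation summaries of experiment records.

    Returns ``by_level`` (level, n_maps, mean IF, sample SD — the layout
    of a per-population inflation summary), ``by_lg_level`` and ``by_lg``
    tables.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")

    def _agg(group_cols: list[str]) -> pd.DataFrame:
        g = df.groupby(group_cols, as_index=False).agg(
            n_maps=("IF", "size"),
            mean_IF=("IF", "mean"),
            sd_IF=("IF", lambda s: s.std(ddof=1)),
            mean_rho=("spearman_rho", "mean"),
        )
        return g

    return {
        "by_level": _agg(["proportion_pct"]),
        "by_lg_level": _agg(["lg_id", "proportion_pct"]),
        "by_lg": _agg(["lg_id"]),
    }
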