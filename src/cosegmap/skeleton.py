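"""Co-segregation clusters, delegate markers, and the skeleton map.

At high marker density many markers show zero recombination with each
other and map to a single position; each such set is a cluster (bin).
A skeleton map keeps one *delegate* per cluster — the most informative
member (highest polymorphism information content, fewest missing calls,
random among ties) — and is the backbone against which the length of
denser maps is compared.

Cluster membership is defined by zero *estimated* recombination, not by
byte-identical genotype columns, so markers differing only at missing
positions cluster together.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .linkage import (
    DEFAULT_MAPPING_FN,
    DEFAULT_MIN_INFORMATIVE,
    MISSING,
    A_CALL,
    B_CALL,
    GeneticMap,
    GenotypeMatrix,
    build_map,
    order_markers,
    pairwise_linkage_matrix,
)

logger = logging.getLogger(__name__)

_PIC_TOL = 1e-12


@dataclass
class ClusterSet:
    """Partition of one linkage group's markers into co-segregation bins.

    ``clusters`` is a list of marker lists (a partition of the LG's
    markers); ``delegates`` holds one delegate per cluster, aligned with
    ``clusters``. ``marker_stats`` is indexed by marker with columns
    ``cluster_id`` (int), ``pic`` and ``missing_fraction``.
    """

    lg_id: str
    clusters: list[list[str]]
    delegates: list[str]
    marker_stats: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.delegates) != len(self.clusters):
            raise ValueError("one delegate required per cluster")
        for d, c in zip(self.delegates, self.clusters):
            if d not in c:
                raise ValueError(f"delegate {d!r} not a member of its cluster")

    @property
    def n_markers(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_coseg(self) -> int:
        """Count of co-segregating markers: total markers - clusters."""
        return self.n_markers - self.n_clusters

    @property
    def coseg_markers(self) -> list[str]:
        """All non-delegate markers (the ones a sequential map can add back)."""
        out: list[str] = []
        for cluster, delegate in zip(self.clusters, self.delegates):
            out.extend(m for m in cluster if m != delegate)
        return out

    def report(self) -> pd.DataFrame:
        """Tab-friendly cluster report: marker, lg_id, cluster_id, is_delegate, PIC, missing."""
        rows = []
        delegates = set(self.delegates)
        for cid, cluster in enumerate(self.clusters):
            for m in cluster:
                rows.append(
                    {
                        "marker": m,
                        "lg_id": self.lg_id,
                        "cluster_id": cid,
                        "is_delegate": m in delegates,
                        "PIC": self.marker_stats.loc[m, "pic"],
                        "missing_fraction": self.marker_stats.loc[m, "missing_fraction"],
                    }
                )
        return pd.DataFrame(rows)


def compute_pic(matrix: GenotypeMatrix, marker: str) -> float:
    """Polymorphism information content of a biallelic marker.

    PIC = 1 - p^2 - q^2 with p, q the A/B allele frequencies over
    non-missing calls; 0.5 is the maximum for a biallelic marker.
    Raises for an all-missing marker (undefined).
    """
    col = matrix.column(marker)
    n_a = int((col == A_CALL).sum())
    n_b = int((col == B_CALL).sum())
    n = n_a + n_b
    if n == 0:
        raise ValueError(f"PIC undefined: marker {marker!r} has no observed calls")
    p = n_a / n
    q = n_b / n
    return 1.0 - p * p - q * q


def _pic_vector(matrix: GenotypeMatrix, markers: list[str]) -> np.ndarray:
    sub = matrix.subset(markers)
    n_a = (sub.calls == A_CALL).sum(axis=0)
    n_b = (sub.calls == B_CALL).sum(axis=0)
    n = n_a + n_b
    if np.any(n == 0):
        bad = [m for m, k in zip(markers, n) if k == 0]
        raise ValueError(f"PIC undefined for all-missing markers: {bad}")
    p = n_a / n
    q = n_b / n
    return 1.0 - p**2 - q**2


def select_delegate(
    cluster: list[str],
    pic: dict[str, float],
    missing_fraction: dict[str, float],
    rng: np.random.Generator,
) -> str:
    """Pick the delegate of a cluster.

    Filter to markers of maximal PIC, then minimal missing fraction, then
    choose uniformly at random (seeded) among the remainder.
    """
    if not cluster:
        raise ValueError("empty cluster")
    best_pic = max(pic[m] for m in cluster)
    pool = [m for m in cluster if pic[m] >= best_pic - _PIC_TOL]
    best_miss = min(missing_fraction[m] for m in pool)
    pool = [m for m in pool if missing_fraction[m] <= best_miss + _PIC_TOL]
    pool.sort()
    return str(rng.choice(pool))


def find_clusters(
    matrix: GenotypeMatrix,
    lg_markers: list[str],
    lg_id: str = "LG1",
    rng: np.random.Generator | int | None = None,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> ClusterSet:
    """Detect co-segregation clusters on one linkage group.

    Clusters are connected components of the graph joining marker pairs
    with an estimated recombination fraction of exactly zero (no
    discordant calls among pairwise-complete observations, with at least
    ``min_informative`` shared lines). Markers are co-segregating iff
    their cluster has size >= 2. Delegates are selected per cluster via
    :func:`select_delegate`.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    _, _, n_inf, n_disc = pairwise_linkage_matrix(
        matrix, markers=lg_markers, min_informative=min_informative
    )
    adj = (n_disc == 0) & (n_inf >= min_informative)
    np.fill_diagonal(adj, False)
    _, labels = connected_components(
        sparse.csr_matrix(adj), directed=False, connection="weak"
    )
    pic = _pic_vector(matrix, lg_markers)
    miss = matrix.subset(lg_markers).missing_fraction()
    pic_d = dict(zip(lg_markers, pic.tolist()))
    miss_d = dict(zip(lg_markers, miss.tolist()))

    clusters: list[list[str]] = []
    for c in sorted(set(labels.tolist())):
        members = [lg_markers[j] for j in np.flatnonzero(labels == c)]
        clusters.append(members)
    # deterministic cluster order: by first member's position in lg_markers
    first_idx = {tuple(c): min(lg_markers.index(m) for m in c) for c in clusters}
    clusters.sort(key=lambda c: first_idx[tuple(c)])
    delegates = [select_delegate(c, pic_d, miss_d, rng) for c in clusters]

    stats = pd.DataFrame(
        {
            "cluster_id": {
                m: cid for cid, cluster in enumerate(clusters) for m in cluster
            },
            "pic": pic_d,
            "missing_fraction": miss_d,
        }
    )
    cs = ClusterSet(lg_id=lg_id, clusters=clusters, delegates=delegates, marker_stats=stats)
    logger.info(
        "%s: %d markers in %d clusters (%d co-segregating)",
        lg_id, cs.n_markers, cs.n_clusters, cs.n_coseg,
    )
    return cs


def clusters_from_truth(
    matrix: GenotypeMatrix,
    truth,
    lg_id: str,
    rng: np.random.Generator | int | None = None,
) -> ClusterSet:
    """Build a ClusterSet from a simulation's ground-truth loci.

    Markers sharing a true locus form one cluster regardless of the noise
    in their observed calls; delegates are still chosen from the observed
    data by the PIC / missing-fraction / seeded-random rule. This is the
    cluster source for simulation experiments that study how scoring
    errors on genuinely co-located markers inflate a map: with a nonzero
    miscall rate, co-located markers are no longer column-identical, so
    the zero-recombination detection rule (:func:`find_clusters`) would
    not recover them — exactly the unlinking effect under study.

    ``truth`` is the :class:`~cosegmap.simpop.TruthTable` of the simulated
    population that produced ``matrix``.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    cluster_map = truth.clusters_of_lg(lg_id)
    present = set(matrix.markers)
    clusters = [
        [m for m in members if m in present] for members in cluster_map.values()
    ]
    clusters = [c for c in clusters if c]
    lg_markers = [m for c in clusters for m in c]
    pic = _pic_vector(matrix, lg_markers)
    miss = matrix.subset(lg_markers).missing_fraction()
    pic_d = dict(zip(lg_markers, pic.tolist()))
    miss_d = dict(zip(lg_markers, miss.tolist()))
    delegates = [select_delegate(c, pic_d, miss_d, rng) for c in clusters]
    stats = pd.DataFrame(
        {
            "cluster_id": {
                m: cid for cid, cluster in enumerate(clusters) for m in cluster
            },
            "pic": pic_d,
            "missing_fraction": miss_d,
        }
    )
    return ClusterSet(lg_id=lg_id, clusters=clusters, delegates=delegates, marker_stats=stats)


def coseg_proportion(n_coseg: int, n_total: int) -> float:
    """Proportion of co-segregating markers, in percent."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_coseg <= n_total):
        raise ValueError("n_coseg must lie in [0, n_total]")
    return 100.0 * n_coseg / n_total


def build_skeleton(
    matrix: GenotypeMatrix,
    clusters: ClusterSet,
    fn: str = DEFAULT_MAPPING_FN,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> GeneticMap:
    """Order and map the delegate markers of one linkage group.

    The skeleton keeps exactly one delegate per cluster; its length
    L_sket is the reference for the inflation factor. An LG with fewer
    than 2 clusters yields a zero-length, flagged map.
    """
    delegates = list(clusters.delegates)
    if len(delegates) < 2:
        logger.warning("%s: <2 clusters; zero-length skeleton", clusters.lg_id)
        return GeneticMap(
            lg_id=clusters.lg_id,
            markers=delegates,
            positions=np.zeros(len(delegates)),
            fn=fn,
            flagged=True,
        )
    order = order_markers(matrix, delegates, min_informative=min_informative)
    gmap = build_map(matrix, order, fn=fn, lg_id=clusters.lg_id, min_informative=min_informative)
    return gmap
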