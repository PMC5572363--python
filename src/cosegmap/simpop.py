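"""Simulation of doubled-haploid (DH) genotype data with known truth.

A DH biparental population is fully homozygous: every line carries, at
each locus, one of the two parental alleles (coded A and B), expected to
segregate 1:1. High-density SNP panels place many markers at identical
genetic positions ("co-segregating" markers), so the simulator places a
configurable fraction of markers as extra copies at existing loci.

Meiosis is modelled without crossover interference: per line and linkage
group the crossover count is Poisson(L/100) with positions uniform on the
group — the model underlying the Haldane mapping function. Scoring errors
are symmetric A<->B flips applied independently per call after
inheritance; missing data are masked completely at random.

The generator returns both the genotype matrix and a :class:`TruthTable`
carrying true positions, cluster memberships, and the exact error /
missing placements, so parameter recovery can be tested against ground
truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .linkage import A_CALL, B_CALL, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def _as_per_lg(value, n_lg: int, name: str) -> list:
    """Broadcast a scalar or per-LG sequence to a list of length n_lg."""
    if np.isscalar(value):
        return [value] * n_lg
    out = list(value)
    if len(out) != n_lg:
        raise ValueError(f"{name} must be scalar or length n_lg={n_lg}")
    return out


@dataclass
class SimConfig:
    """Configuration of a simulated DH mapping population.

    Parameters
    ----------
    n_lines
        Number of DH individuals.
    n_lg
        Number of linkage groups (chromosomes).
    lg_length_cM
        True genetic length per LG in centiMorgans (scalar or per-LG list).
    n_unique_loci
        Number of distinct marker positions per LG (scalar or per-LG list).
    coseg_proportion
        Target fraction of markers that are extra copies at existing loci,
        in [0, 1). The realized marker count per LG is
        round(n_unique_loci / (1 - coseg_proportion)).
    miscall_rate
        Per-call probability of flipping A<->B, in [0, 0.5).
    missing_rate
        Per-call probability of masking a call to U, in [0, 0.1].
    seed
        RNG seed; identical seeds give bit-identical output.
    locus_positions
        Optional explicit locus positions (cM) per LG: a list of ``n_lg``
        ascending sequences. Overrides ``n_unique_loci`` and the default
        placement (ends anchored, interior uniform).
    """

    n_lines: int = 200
    n_lg: int = 14
    lg_length_cM: float | list = 100.0
    n_unique_loci: int | list = 20
    coseg_proportion: float = 0.85
    miscall_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    locus_positions: list | None = None

    def __post_init__(self) -> None:
        if self.locus_positions is not None:
            if len(self.locus_positions) != self.n_lg:
                raise ValueError("locus_positions must give one sequence per LG")
            self.locus_positions = [
                np.asarray(p, dtype=float) for p in self.locus_positions
            ]
            for g, p in enumerate(self.locus_positions):
                if np.any(np.diff(p) < 0) or np.any(p < 0):
                    raise ValueError("locus positions must be ascending and >= 0")
            self.n_unique_loci = [len(p) for p in self.locus_positions]
        if self.n_lines < 1 or self.n_lg < 1:
            raise ValueError("n_lines and n_lg must be positive")
        if not (0.0 <= self.coseg_proportion < 1.0):
            raise ValueError("coseg_proportion must lie in [0, 1)")
        if not (0.0 <= self.miscall_rate < 0.5):
            raise ValueError("miscall_rate must lie in [0, 0.5)")
        if not (0.0 <= self.missing_rate <= 0.1):
            raise ValueError("missing_rate must lie in [0, 0.1]")
        self._lengths = [float(x) for x in _as_per_lg(self.lg_length_cM, self.n_lg, "lg_length_cM")]
        self._n_unique = [int(x) for x in _as_per_lg(self.n_unique_loci, self.n_lg, "n_unique_loci")]
        for u in self._n_unique:
            if u < 2:
                raise ValueError("n_unique_loci must be >= 2 per LG")
        for L in self._lengths:
            if L <= 0:
                raise ValueError("lg_length_cM must be positive")
        if self.locus_positions is not None:
            for p, L in zip(self.locus_positions, self._lengths):
                if p[-1] > L:
                    raise ValueError("locus positions must not exceed lg_length_cM")
        for m in self.markers_per_lg():
            if m < 3:
                raise ValueError(
                    f"realized marker count per LG must be >= 3 (got {m}); "
                    "increase n_unique_loci or coseg_proportion"
                )

    def markers_per_lg(self) -> list[int]:
        """Realized marker count per LG: round(n_unique / (1 - coseg))."""
        return [
            int(np.floor(u / (1.0 - self.coseg_proportion) + 0.5))
            for u in self._n_unique
        ]

    @property
    def lg_lengths(self) -> list[float]:
        return self._lengths

    @property
    def n_unique(self) -> list[int]:
        return self._n_unique


@dataclass
class TruthTable:
    """Ground truth of a simulated population.

    ``table`` is indexed by marker with columns ``lg_id``,
    ``true_position_cM`` and ``cluster_id``; markers sharing a cluster_id
    share their true position exactly. ``error_mask`` / ``missing_mask``
    are boolean line x marker arrays of the calls that were flipped /
    masked. ``xo_counts`` holds the realized crossover count per line and
    LG, for checking the meiosis model.
    """

    table: pd.DataFrame
    error_mask: np.ndarray
    missing_mask: np.ndarray
    xo_counts: np.ndarray
    lg_ids: list[str]

    def markers_of_lg(self, lg_id: str) -> list[str]:
        return list(self.table.index[self.table["lg_id"] == lg_id])

    def clusters_of_lg(self, lg_id: str) -> dict[str, list[str]]:
        sub = self.table[self.table["lg_id"] == lg_id]
        out: dict[str, list[str]] = {}
        for marker, cid in sub["cluster_id"].items():
            out.setdefault(cid, []).append(marker)
        return out

    def to_tsv(self, path) -> None:
        df = self.table.reset_index(names="marker")
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def simulate_dh_population(config: SimConfig) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate a DH biparental population with co-segregating markers.

    For each line and LG one gamete is drawn: crossover count ~
    Poisson(lg_length/100), positions uniform on the LG (no interference),
    starting parental allele Bernoulli(1/2). All markers at a locus
    inherit that locus's allele before noise; miscalls then flip calls
    independently with probability ``miscall_rate`` and calls are masked
    to missing independently with probability ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_lines
    lines = [f"dh{num + 1:04d}" for num in range(n)]
    lg_ids = [f"LG{g + 1:02d}" for g in range(config.n_lg)]

    marker_names: list[str] = []
    truth_rows: list[dict] = []
    call_blocks: list[np.ndarray] = []
    xo_counts = np.zeros((n, config.n_lg), dtype=np.int64)

    for g, lg in enumerate(lg_ids):
        L = config.lg_lengths[g]
        u = config.n_unique[g]
        m = config.markers_per_lg()[g]

        # locus positions: explicit, or LG ends anchored + interior uniform
        if config.locus_positions is not None:
            locus_pos = np.asarray(config.locus_positions[g], dtype=float)
        elif u == 2:
            locus_pos = np.array([0.0, L])
        else:
            interior = np.sort(rng.uniform(0.0, L, size=u - 2))
            locus_pos = np.concatenate(([0.0], interior, [L]))

        # assign extra marker copies to loci uniformly at random
        locus_of_marker = np.concatenate(
            (np.arange(u), rng.integers(0, u, size=m - u))
        )
        locus_of_marker.sort()

        # meiosis: one gamete per line
        locus_alleles = np.empty((n, u), dtype=np.int8)
        k = rng.poisson(L / 100.0, size=n)
        start = rng.integers(0, 2, size=n).astype(np.int8)
        xo_counts[:, g] = k
        for li in range(n):
            xos = np.sort(rng.uniform(0.0, L, size=k[li]))
            parity = np.searchsorted(xos, locus_pos, side="right") % 2
            locus_alleles[li] = (start[li] + parity) % 2

        calls = locus_alleles[:, locus_of_marker]
        call_blocks.append(calls)
        for j, locus in enumerate(locus_of_marker):
            name = f"{lg.lower()}m{j + 1:04d}"
            marker_names.append(name)
            truth_rows.append(
                {
                    "marker": name,
                    "lg_id": lg,
                    "true_position_cM": float(locus_pos[locus]),
                    "cluster_id": f"{lg.lower()}c{locus + 1:04d}",
                }
            )

    calls = np.concatenate(call_blocks, axis=1).astype(np.int8)

    # symmetric scoring errors, then missing masking
    error_mask = rng.random(calls.shape) < config.miscall_rate
    calls[error_mask] ^= 1
    missing_mask = rng.random(calls.shape) < config.missing_rate
    calls[missing_mask] = MISSING

    matrix = GenotypeMatrix(lines, marker_names, calls)
    truth = TruthTable(
        table=pd.DataFrame(truth_rows).set_index("marker"),
        error_mask=error_mask,
        missing_mask=missing_mask,
        xo_counts=xo_counts,
        lg_ids=lg_ids,
    )
    logger.info(
        "simulated %d lines x %d markers on %d LGs (seed=%d)",
        n, len(marker_names), config.n_lg, config.seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Data curation: segregation / missingness filter
# ---------------------------------------------------------------------------


def segregation_filter(
    matrix: GenotypeMatrix,
    alpha: float = 0.05,
    max_missing: float = 0.10,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop monomorphic, high-missing and segregation-distorted markers.

    A DH population segregates 1:1, so each marker's non-missing A/B
    counts are tested against 1:1 with a 1-df chi-square; markers with
    p < ``alpha`` are dropped as distorted. Markers with a missing-call
    fraction >= ``max_missing`` or with only one observed allele
    (monomorphic) are also dropped.

    Returns the filtered matrix and a per-marker disposition log with
    columns marker, n_A, n_B, missing_fraction, chi2, p, disposition.
    """
    calls = matrix.calls
    n_a = (calls == A_CALL).sum(axis=0)
    n_b = (calls == B_CALL).sum(axis=0)
    n_obs = n_a + n_b
    miss_frac = (calls == MISSING).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(n_obs > 0, (n_a - n_b) ** 2 / np.maximum(n_obs, 1), np.nan)
    pval = chi2.sf(stat, df=1)

    disposition = np.full(matrix.n_markers, "retained", dtype=object)
    disposition[pval < alpha] = "distorted"
    disposition[(n_a == 0) | (n_b == 0)] = "monomorphic"
    disposition[miss_frac >= max_missing] = "high_missing"

    log = pd.DataFrame(
        {
            "marker": matrix.markers,
            "n_A": n_a,
            "n_B": n_b,
            "missing_fraction": miss_frac,
            "chi2": stat,
            "p": pval,
            "disposition": disposition,
        }
    )
    keep = [m for m, d in zip(matrix.markers, disposition) if d == "retained"]
    dropped = matrix.n_markers - len(keep)
    if dropped:
        logger.info("segregation filter dropped %d of %d markers", dropped, matrix.n_markers)
    if not keep:
        logger.warning("segregation filter removed every marker")
        return GenotypeMatrix(list(matrix.lines), [], calls[:, :0]), log
    return matrix.subset(keep), log
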