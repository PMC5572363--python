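"""Linkage-mapping engine for doubled-haploid (DH) populations.

Implements the core machinery for building genetic maps from biallelic
A/B genotype calls on fully homozygous DH lines:

* pairwise recombination-fraction estimation with an exact binomial test
  of independence,
* Haldane / Kosambi mapping functions,
* linkage-group detection by graph connectivity,
* marker ordering by minimum spanning tree + 2-opt refinement of the sum
  of adjacent recombination fractions (SARF),
* map assembly (cumulative cM positions), and
* double-recombinant correction by flanking genotype.

Genotype calls are coded internally as ``int8``: 0 = A, 1 = B,
-1 = missing (U).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import binom

logger = logging.getLogger(__name__)

# Call codes
A_CALL: int = 0
B_CALL: int = 1
MISSING: int = -1

#: recombination fractions at or above 0.5 are clamped to this value before
#: conversion to map distance (Haldane diverges at r = 0.5)
R_CLAMP: float = 0.4999

#: minimum shared non-missing lines for a usable pairwise estimate
DEFAULT_MIN_INFORMATIVE: int = 20

DEFAULT_P_CUTOFF: float = 1e-10
DEFAULT_MAX_DIST_CM: float = 15.0
DEFAULT_MAPPING_FN: str = "kosambi"


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------

_CALL_TO_CHAR = {A_CALL: "A", B_CALL: "B", MISSING: "U"}
_CHAR_TO_CALL = {"A": A_CALL, "B": B_CALL, "U": MISSING, "-": MISSING}


@dataclass
class GenotypeMatrix:
    """Lines x markers table of DH genotype calls.

    Parameters
    ----------
    lines
        Unique line (individual) identifiers, one per row.
    markers
        Unique marker identifiers, one per column.
    calls
        ``int8`` array of shape ``(n_lines, n_markers)`` with values in
        ``{0 (A), 1 (B), -1 (missing)}``.
    """

    lines: list[str]
    markers: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.lines), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.markers)} markers"
            )
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("line identifiers are not unique")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker identifiers are not unique")
        bad = ~np.isin(self.calls, (A_CALL, B_CALL, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0, 1, -1}")
        self._marker_index = {m: j for j, m in enumerate(self.markers)}

    # -- basic accessors ----------------------------------------------------

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_index(self, marker: str) -> int:
        try:
            return self._marker_index[marker]
        except KeyError:
            raise KeyError(f"unknown marker {marker!r}") from None

    def column(self, marker: str) -> np.ndarray:
        return self.calls[:, self.marker_index(marker)]

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def subset(self, markers: list[str]) -> "GenotypeMatrix":
        """New matrix restricted to ``markers`` (in the given order)."""
        idx = [self.marker_index(m) for m in markers]
        return GenotypeMatrix(list(self.lines), list(markers), self.calls[:, idx])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.lines), list(self.markers), self.calls.copy())

    # -- conversion ---------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Character-coded DataFrame (lines x markers, values A/B/U)."""
        chars = np.vectorize(_CALL_TO_CHAR.get)(self.calls)
        return pd.DataFrame(chars, index=self.lines, columns=self.markers)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        """Build from a character-coded DataFrame (values A/B/U/-, case-insensitive)."""
        raw = df.to_numpy(dtype=str)
        calls = np.empty(raw.shape, dtype=np.int8)
        for char, code in _CHAR_TO_CALL.items():
            calls[np.char.upper(raw) == char] = code
        known = np.isin(np.char.upper(raw), list(_CHAR_TO_CALL))
        if not known.all():
            bad = sorted(set(raw[~known].tolist()))
            raise ValueError(f"unknown call symbols: {bad}")
        return cls([str(i) for i in df.index], [str(c) for c in df.columns], calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.lines == other.lines
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# Pairwise recombination fractions
# ---------------------------------------------------------------------------


@dataclass
class PairwiseLinkage:
    """Pairwise recombination estimate between two markers.

    ``r_hat`` is the discordant-call fraction among lines non-missing at
    both markers, clamped to [0, 0.5]; ``r_raw`` keeps the unclamped value.
    ``p_indep`` is the exact two-sided binomial tail probability of the
    observed discordant count under r = 0.5 (independence).
    ``informative`` is False when fewer than ``min_informative`` lines are
    jointly observed; such pairs are treated as unlinked.
    """

    marker_i: str
    marker_j: str
    r_hat: float
    r_raw: float
    n_informative: int
    n_discordant: int
    p_indep: float
    informative: bool


def _pairwise_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Informative and discordant counts for all marker pairs.

    Returns ``(n_informative, n_discordant)``, each ``(m, m)``.
    """
    valid = (calls != MISSING)
    a = (calls == A_CALL) & valid
    b = (calls == B_CALL) & valid
    af = a.astype(np.float64)
    bf = b.astype(np.float64)
    vf = valid.astype(np.float64)
    n_inf = vf.T @ vf
    concordant = af.T @ af + bf.T @ bf
    n_disc = n_inf - concordant
    return np.rint(n_inf).astype(np.int64), np.rint(n_disc).astype(np.int64)


def _binom_p_two_sided(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Exact two-sided tail P(|X - n/2| >= |k - n/2|), X ~ Binomial(n, 1/2).

    For the symmetric binomial this equals twice the smaller one-sided
    tail, capped at 1.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    kmin = np.minimum(k, n - k)
    with np.errstate(invalid="ignore"):
        p = 2.0 * binom.cdf(kmin, np.maximum(n, 1), 0.5)
    p = np.where(n > 0, p, 1.0)
    return np.minimum(p, 1.0)


def pairwise_linkage_matrix(
    matrix: GenotypeMatrix,
    markers: list[str] | None = None,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pairwise estimates for a set of markers.

    Returns
    -------
    r : (m, m) array
        Recombination-fraction estimates clamped to [0, 0.5];
        NaN for uninformative pairs.
    p : (m, m) array
        Two-sided binomial p-values; 1.0 for uninformative pairs.
    n_inf : (m, m) int array
    n_disc : (m, m) int array
    """
    sub = matrix if markers is None else matrix.subset(markers)
    n_inf, n_disc = _pairwise_counts(sub.calls)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n_inf > 0, n_disc / np.maximum(n_inf, 1), np.nan)
    p = _binom_p_two_sided(n_disc, n_inf)
    uninformative = n_inf < min_informative
    r = np.where(uninformative, np.nan, np.minimum(r, 0.5))
    p = np.where(uninformative, 1.0, p)
    np.fill_diagonal(r, 0.0)
    return r, p, n_inf, n_disc


def estimate_r(
    matrix: GenotypeMatrix,
    marker_i: str,
    marker_j: str,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> PairwiseLinkage:
    """Estimate the recombination fraction between two markers.

    In a DH population r is estimated as the discordant-genotype fraction
    over lines non-missing at both markers. The independence test is the
    exact two-sided binomial test of the discordant count against
    Binomial(n_informative, 1/2).
    """
    ci = matrix.column(marker_i)
    cj = matrix.column(marker_j)
    both = (ci != MISSING) & (cj != MISSING)
    n = int(both.sum())
    disc = int((ci[both] != cj[both]).sum())
    informative = n >= min_informative
    if n > 0:
        r_raw = disc / n
        p = float(_binom_p_two_sided(np.array(disc), np.array(n)))
    else:
        r_raw = float("nan")
        p = 1.0
    if not informative:
        logger.debug(
            "pair (%s, %s) uninformative: %d shared lines", marker_i, marker_j, n
        )
    r_hat = min(r_raw, 0.5) if n > 0 else float("nan")
    if marker_i == marker_j:
        r_hat, r_raw, disc = 0.0, 0.0, 0
    return PairwiseLinkage(
        marker_i=marker_i,
        marker_j=marker_j,
        r_hat=r_hat,
        r_raw=r_raw,
        n_informative=n,
        n_discordant=disc,
        p_indep=p if informative else 1.0,
        informative=informative,
    )


# ---------------------------------------------------------------------------
# Mapping functions
# ---------------------------------------------------------------------------


def map_distance(r, fn: str = DEFAULT_MAPPING_FN):
    """Convert a recombination fraction to map distance in centiMorgans.

    Haldane (no crossover interference): d = -50 ln(1 - 2r).
    Kosambi (partial interference):      d = 25 ln((1 + 2r)/(1 - 2r)).

    Accepts scalars or arrays; ``r`` must lie in [0, 0.5) — callers clamp
    at ``R_CLAMP`` first.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0.0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    if fn == "haldane":
        d = -50.0 * np.log1p(-2.0 * r)
    elif fn == "kosambi":
        d = 25.0 * (np.log1p(2.0 * r) - np.log1p(-2.0 * r))
    else:
        raise ValueError(f"unknown mapping function {fn!r}")
    return float(d) if d.ndim == 0 else d


def inverse_map_distance(d, fn: str = DEFAULT_MAPPING_FN):
    """Map distance (cM) back to recombination fraction."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("map distance must be non-negative")
    if fn == "haldane":
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    elif fn == "kosambi":
        r = 0.5 * np.tanh(2.0 * d / 100.0)
    else:
        raise ValueError(f"unknown mapping function {fn!r}")
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# Linkage grouping
# ---------------------------------------------------------------------------


def group_markers(
    matrix: GenotypeMatrix,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    max_dist_cM: float = DEFAULT_MAX_DIST_CM,
    fn: str = DEFAULT_MAPPING_FN,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> tuple[list[list[str]], list[str]]:
    """Partition markers into linkage groups.

    Two markers are joined when the exact binomial test rejects
    independence at ``p_cutoff`` AND their map distance is at most
    ``max_dist_cM``; linkage groups are the connected components of the
    resulting graph.

    Returns
    -------
    groups : list of marker lists
        Components of size >= 2, largest first; markers keep matrix order.
    unplaced : list of str
        Singleton components (markers with no significant close linkage).
    """
    r, p, _, _ = pairwise_linkage_matrix(matrix, min_informative=min_informative)
    with np.errstate(invalid="ignore"):
        r_c = np.minimum(np.nan_to_num(r, nan=0.5), R_CLAMP)
        d = map_distance(r_c, fn)
    adj = (p < p_cutoff) & (d <= max_dist_cM) & ~np.isnan(r)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(
        sparse.csr_matrix(adj), directed=False, connection="weak"
    )
    groups: list[list[str]] = []
    unplaced: list[str] = []
    for c in range(n_comp):
        members = [matrix.markers[j] for j in np.flatnonzero(labels == c)]
        if len(members) == 1:
            unplaced.append(members[0])
        else:
            groups.append(members)
    groups.sort(key=lambda g: (-len(g), matrix.marker_index(g[0])))
    if unplaced:
        logger.info("%d markers unplaced (singleton components)", len(unplaced))
    return groups, unplaced


# ---------------------------------------------------------------------------
# Marker ordering: MST + 2-opt on SARF
# ---------------------------------------------------------------------------


def _prim_mst(w: np.ndarray) -> list[list[int]]:
    """Deterministic Prim MST on a dense symmetric weight matrix.

    Ties are broken by (weight, smaller incident index, vertex index), so
    the tree is a pure function of the weights and the marker order.
    Returns an adjacency list.
    """
    m = w.shape[0]
    in_tree = np.zeros(m, dtype=bool)
    best_w = np.full(m, np.inf)
    best_from = np.full(m, -1, dtype=np.int64)
    adj: list[list[int]] = [[] for _ in range(m)]
    in_tree[0] = True
    best_w[0] = -np.inf
    cur = 0
    for _ in range(m - 1):
        upd = w[cur] < best_w
        upd &= ~in_tree
        best_w[upd] = w[cur][upd]
        best_from[upd] = cur
        # next vertex: min weight, tie-break on smaller parent index then vertex index
        cand = np.flatnonzero(~in_tree)
        order = np.lexsort((cand, best_from[cand], best_w[cand]))
        nxt = cand[order[0]]
        in_tree[nxt] = True
        adj[nxt].append(int(best_from[nxt]))
        adj[int(best_from[nxt])].append(int(nxt))
        cur = int(nxt)
    return adj


def _farthest(adj: list[list[int]], w: np.ndarray, start: int) -> int:
    """Farthest vertex from ``start`` in the tree by summed edge weight."""
    m = len(adj)
    dist = np.full(m, -1.0)
    dist[start] = 0.0
    stack = [start]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + w[u, v]
                stack.append(v)
    far = np.flatnonzero(dist == dist.max())
    return int(far[0])


def _dfs_path(adj: list[list[int]], w: np.ndarray, root: int) -> list[int]:
    """Depth-first preorder from ``root``; children visited lightest-edge first."""
    m = len(adj)
    seen = np.zeros(m, dtype=bool)
    order: list[int] = []
    stack = [root]
    while stack:
        u = stack.pop()
        if seen[u]:
            continue
        seen[u] = True
        order.append(u)
        children = sorted(
            (v for v in adj[u] if not seen[v]),
            key=lambda v: (w[u, v], v),
            reverse=True,  # stack pops lightest first
        )
        stack.extend(children)
    return order


def sarf(order: list[int] | np.ndarray, w: np.ndarray) -> float:
    """Sum of adjacent recombination fractions for an order."""
    o = np.asarray(order)
    return float(w[o[:-1], o[1:]].sum())


def _two_opt_pass(o: list[int], w: np.ndarray) -> bool:
    """One first-improvement 2-opt sweep (segment reversals). Returns True
    if any move was applied."""
    m = len(o)
    improved = False
    for i in range(m - 1):
        for j in range(i + 1, m):
            # reversing o[i..j] changes edges (i-1,i) and (j,j+1)
            delta = 0.0
            if i > 0:
                delta += w[o[i - 1], o[j]] - w[o[i - 1], o[i]]
            if j < m - 1:
                delta += w[o[i], o[j + 1]] - w[o[j], o[j + 1]]
            if delta < -1e-12:
                o[i : j + 1] = reversed(o[i : j + 1])
                improved = True
    return improved


def _or_opt_pass(o: list[int], w: np.ndarray, max_seg: int = 3) -> bool:
    """One first-improvement Or-opt sweep: relocate segments of length
    1..max_seg to another position. Returns True if any move was applied."""
    m = len(o)
    improved = False
    for seg in range(1, max_seg + 1):
        i = 0
        while i + seg <= m:
            a, b = o[i], o[i + seg - 1]  # segment endpoints
            # cost of removing the segment
            gain = 0.0
            if i > 0:
                gain += w[o[i - 1], a]
            if i + seg < m:
                gain += w[b, o[i + seg]]
            if i > 0 and i + seg < m:
                gain -= w[o[i - 1], o[i + seg]]
            rest = o[:i] + o[i + seg :]
            segment = o[i : i + seg]
            moved = False
            for k in range(len(rest) + 1):
                if k == i:
                    continue
                for piece in (segment, segment[::-1]):
                    cost = 0.0
                    if k > 0:
                        cost += w[rest[k - 1], piece[0]]
                    if k < len(rest):
                        cost += w[piece[-1], rest[k]]
                    if k > 0 and k < len(rest):
                        cost -= w[rest[k - 1], rest[k]]
                    if cost < gain - 1e-12:
                        o[:] = rest[:k] + piece + rest[k:]
                        improved = True
                        moved = True
                        break
                if moved:
                    break
            if not moved:
                i += 1
    return improved


def _refine_order(order: list[int], w: np.ndarray) -> list[int]:
    """SARF local search: alternate 2-opt (segment reversal) and Or-opt
    (segment relocation) sweeps until a full round applies no move."""
    o = list(order)
    while True:
        any_move = _two_opt_pass(o, w)
        any_move |= _or_opt_pass(o, w)
        if not any_move:
            return o


def _nn_path(w: np.ndarray, start: int) -> list[int]:
    """Greedy nearest-neighbour path from ``start``; ties by vertex index."""
    m = w.shape[0]
    unvisited = set(range(m))
    unvisited.discard(start)
    o = [start]
    while unvisited:
        cur = o[-1]
        nxt = min(unvisited, key=lambda v: (w[cur, v], v))
        o.append(nxt)
        unvisited.discard(nxt)
    return o


def order_markers(
    matrix: GenotypeMatrix,
    group: list[str],
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> list[str]:
    """Order the markers of one linkage group.

    Builds the complete graph weighted by pairwise r estimates, takes a
    deterministic minimum spanning tree, and — unless the tree is already
    a Hamiltonian path (in which case it is already the minimum-SARF
    order) — extracts an initial path by depth-first traversal from one
    endpoint of the tree diameter, then refines it by 2-opt (segment
    reversal) and Or-opt (segment relocation) moves on the sum of
    adjacent recombination fractions (SARF) until a local optimum.

    Marker ordering is a special case of the traveling salesman problem;
    this is the standard MST heuristic family. The result is canonically
    oriented: the lexicographically smaller terminal marker comes first.
    Uninformative pairs weigh 0.5 (unlinked).
    """
    if len(group) < 2:
        raise ValueError("need at least 2 markers to order")
    r, _, _, _ = pairwise_linkage_matrix(
        matrix, markers=group, min_informative=min_informative
    )
    w = np.nan_to_num(r, nan=0.5)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    if len(group) == 2:
        order = [0, 1]
    else:
        adj = _prim_mst(w)
        degrees = np.array([len(a) for a in adj])
        if degrees.max() <= 2:
            # MST is a Hamiltonian path: walk it from one endpoint
            start = int(np.flatnonzero(degrees == 1)[0])
            order = _dfs_path(adj, w, start)
        else:
            end_a = _farthest(adj, w, 0)
            end_b = _farthest(adj, w, end_a)
            # deterministic multi-start: DFS paths from both diameter
            # endpoints and greedy nearest-neighbour paths from the same
            # endpoints, each refined to a local optimum; keep the best
            starts = [
                _dfs_path(adj, w, end_a),
                _dfs_path(adj, w, end_b),
                _nn_path(w, end_a),
                _nn_path(w, end_b),
            ]
            candidates = [_refine_order(s, w) for s in starts]
            scored = sorted(
                (sarf(c, w), tuple(c)) for c in candidates
            )
            order = list(scored[0][1])
    if group[order[0]] > group[order[-1]]:
        order = order[::-1]
    return [group[i] for i in order]


# ---------------------------------------------------------------------------
# Map assembly
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """One linkage group's map: ordered markers with cumulative cM positions."""

    lg_id: str
    markers: list[str]
    positions: np.ndarray
    fn: str = DEFAULT_MAPPING_FN
    flagged: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.markers) != len(self.positions):
            raise ValueError("markers and positions length mismatch")
        if len(self.positions) > 0:
            if self.positions[0] != 0.0:
                raise ValueError("first map position must be 0")
            if np.any(np.diff(self.positions) < 0):
                raise ValueError("map positions must be non-decreasing")

    @property
    def length(self) -> float:
        """Total map length (cM) = position of the last marker."""
        return float(self.positions[-1]) if len(self.positions) else 0.0

    def rank_of(self) -> dict[str, int]:
        return {m: k for k, m in enumerate(self.markers)}


def build_map(
    matrix: GenotypeMatrix,
    ordered_markers: list[str],
    fn: str = DEFAULT_MAPPING_FN,
    lg_id: str = "LG1",
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> GeneticMap:
    """Assemble a map from an ordered marker list.

    Positions are cumulative: position(k) = position(k-1) +
    map_distance(clamp(r_hat(k-1, k))), with position(0) = 0. Adjacent r
    estimates are clamped at ``R_CLAMP`` before conversion.
    """
    if len(ordered_markers) < 1:
        raise ValueError("empty marker order")
    sub = matrix.subset(ordered_markers)
    positions = np.zeros(len(ordered_markers))
    for k in range(1, len(ordered_markers)):
        pl = estimate_r(
            sub, ordered_markers[k - 1], ordered_markers[k], min_informative
        )
        if not pl.informative:
            raise ValueError(
                f"adjacent pair ({pl.marker_i}, {pl.marker_j}) is uninformative "
                f"({pl.n_informative} shared lines)"
            )
        positions[k] = positions[k - 1] + map_distance(min(pl.r_hat, R_CLAMP), fn)
    return GeneticMap(lg_id=lg_id, markers=list(ordered_markers), positions=positions, fn=fn)


# ---------------------------------------------------------------------------
# Double-recombinant correction
# ---------------------------------------------------------------------------


def correct_double_recombinants(
    matrix: GenotypeMatrix,
    gmap: GeneticMap,
    window_cM: float = 10.0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Replace apparent double recombinants by the flanking genotype.

    For each line and each non-terminal marker of the map, the nearest
    non-missing flanking neighbours within ``window_cM`` on each side are
    located; when both exist, agree with each other, and differ from the
    focal (non-missing) call, the focal call is an error candidate and is
    replaced by the flanking genotype. A genuine double crossover within a
    few cM is vanishingly rare in a DH line, so at high marker density
    such calls are almost always scoring errors.

    One pass in map order; decisions are taken on the input calls so the
    outcome does not depend on scan direction. Terminal markers are never
    modified; missing focal calls are never imputed.

    Returns the corrected matrix and a log of changes
    (line, marker, old, new).
    """
    cols = [matrix.marker_index(m) for m in gmap.markers]
    pos = gmap.positions
    calls = matrix.calls
    new_calls = calls.copy()
    changes: list[dict] = []
    mcount = len(cols)
    for li in range(matrix.n_lines):
        row = calls[li]
        obs = np.flatnonzero(row[cols] != MISSING)  # indices into map order
        if len(obs) < 3:
            continue
        obs_pos = pos[obs]
        obs_calls = row[np.asarray(cols)[obs]]
        for t in range(1, len(obs) - 1):
            k = obs[t]
            if k == 0 or k == mcount - 1:
                continue  # terminal markers never modified
            left, right = obs_calls[t - 1], obs_calls[t + 1]
            if left != right or left == obs_calls[t]:
                continue
            if (obs_pos[t] - obs_pos[t - 1] > window_cM) or (
                obs_pos[t + 1] - obs_pos[t] > window_cM
            ):
                continue
            col = cols[k]
            changes.append(
                {
                    "line": matrix.lines[li],
                    "marker": gmap.markers[k],
                    "old": _CALL_TO_CHAR[int(obs_calls[t])],
                    "new": _CALL_TO_CHAR[int(left)],
                }
            )
            new_calls[li, col] = left
    log = pd.DataFrame(changes, columns=["line", "marker", "old", "new"])
    logger.info("double-recombinant correction: %d calls replaced", len(log))
    return GenotypeMatrix(list(matrix.lines), list(matrix.markers), new_calls), log
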