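"""Readers, writers and run configuration.

The genotype dialect is the plain-text format used by MST-based mapping
tools: a block of ``key value`` header lines (population type, clustering
cut-offs, declared dimensions) followed by one row per marker — the
marker identifier, then one call per individual in {A, B, U, -}
(case-insensitive; U and - both mean missing). A plain delimited
lines x markers table is supported as an alternative. Maps, cluster
reports and experiment records are tab-separated.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expansion import ExperimentDesign, RECORD_COLUMNS
from .linkage import (
    DEFAULT_MAPPING_FN,
    DEFAULT_MAX_DIST_CM,
    DEFAULT_MIN_INFORMATIVE,
    DEFAULT_P_CUTOFF,
    MISSING,
    A_CALL,
    B_CALL,
    GeneticMap,
    GenotypeMatrix,
)
from .simpop import SimConfig

logger = logging.getLogger(__name__)

_HEADER_KEYS = {
    "population_type",
    "population_name",
    "distance_function",
    "cut_off_p_value",
    "no_map_dist",
    "no_map_size",
    "missing_threshold",
    "estimation_before_clustering",
    "detect_bad_data",
    "objective_function",
    "number_of_loci",
    "number_of_individual",
}

_CALL_CODE = {"A": A_CALL, "B": B_CALL, "U": MISSING, "-": MISSING}
_CODE_CALL = {A_CALL: "A", B_CALL: "B", MISSING: "U"}


class MSTMapParseError(ValueError):
    """Malformed genotype file; message carries the offending line number."""


def read_genotypes_mstmap(path) -> GenotypeMatrix:
    """Parse a genotype file in the MST mapping-tool dialect.

    Header ``key value`` lines are validated (population_type must be DH;
    declared number_of_loci / number_of_individual must match the parsed
    dimensions). Data rows are ``marker call call ...`` with calls in
    {A, B, U, -}, case-insensitive. A ``# individuals:`` comment, when
    present, names the individuals; otherwise names are generated.
    """
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[str, list[str]]] = []
    individuals: list[str] | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("individuals:"):
                    individuals = body.split(":", 1)[1].split()
                continue
            tokens = line.split()
            if tokens[0] in _HEADER_KEYS:
                if len(tokens) < 2:
                    raise MSTMapParseError(f"line {lineno}: header key without value")
                header[tokens[0]] = tokens[1]
                continue
            if len(tokens) < 2:
                raise MSTMapParseError(f"line {lineno}: marker row with no calls")
            calls = [t.upper() for t in tokens[1:]]
            for t in calls:
                if t not in _CALL_CODE:
                    raise MSTMapParseError(
                        f"line {lineno}: unknown call symbol {t!r} (expected A/B/U/-)"
                    )
            rows.append((tokens[0], calls))

    ptype = header.get("population_type", "DH").upper()
    if ptype != "DH":
        raise MSTMapParseError(f"population_type must be DH, got {ptype!r}")
    if not rows:
        raise MSTMapParseError("no marker rows found")
    n_ind = len(rows[0][1])
    for marker, calls in rows:
        if len(calls) != n_ind:
            raise MSTMapParseError(
                f"marker {marker!r} has {len(calls)} calls, expected {n_ind}"
            )
    if "number_of_loci" in header and int(header["number_of_loci"]) != len(rows):
        raise MSTMapParseError(
            f"header declares number_of_loci={header['number_of_loci']} "
            f"but file has {len(rows)} marker rows"
        )
    if "number_of_individual" in header and int(header["number_of_individual"]) != n_ind:
        raise MSTMapParseError(
            f"header declares number_of_individual={header['number_of_individual']} "
            f"but rows carry {n_ind} calls"
        )
    if individuals is not None and len(individuals) != n_ind:
        raise MSTMapParseError("individuals comment length does not match call count")
    lines = individuals or [f"ind{j + 1:04d}" for j in range(n_ind)]
    markers = [m for m, _ in rows]
    calls_arr = np.array(
        [[_CALL_CODE[c] for c in calls] for _, calls in rows], dtype=np.int8
    ).T
    return GenotypeMatrix(lines, markers, calls_arr)


def write_genotypes_mstmap(
    matrix: GenotypeMatrix,
    path,
    population_name: str = "simulated",
    distance_function: str = DEFAULT_MAPPING_FN,
    cut_off_p_value: float = DEFAULT_P_CUTOFF,
    no_map_dist: float = DEFAULT_MAX_DIST_CM,
    no_map_size: int = 0,
    missing_threshold: float = 0.10,
) -> None:
    """Write a genotype matrix in the MST mapping-tool dialect.

    Round-trip safe: reading the written file recovers the matrix exactly,
    including line identifiers (kept in a ``# individuals:`` comment) and
    the missing mask.
    """
    if matrix.n_markers == 0 or matrix.n_lines == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"population_type DH\n")
        fh.write(f"population_name {population_name}\n")
        fh.write(f"distance_function {distance_function}\n")
        fh.write(f"cut_off_p_value {cut_off_p_value:g}\n")
        fh.write(f"no_map_dist {no_map_dist:g}\n")
        fh.write(f"no_map_size {no_map_size}\n")
        fh.write(f"missing_threshold {missing_threshold:g}\n")
        fh.write(f"number_of_loci {matrix.n_markers}\n")
        fh.write(f"number_of_individual {matrix.n_lines}\n")
        fh.write(f"# individuals: {' '.join(matrix.lines)}\n")
        for j, marker in enumerate(matrix.markers):
            calls = "\t".join(_CODE_CALL[int(c)] for c in matrix.calls[:, j])
            fh.write(f"{marker}\t{calls}\n")


def read_genotypes_table(path, sep: str = "\t") -> GenotypeMatrix:
    """Read a plain delimited lines x markers call table (A/B/U/-)."""
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    return GenotypeMatrix.from_dataframe(df)


def write_genotypes_table(matrix: GenotypeMatrix, path, sep: str = "\t") -> None:
    matrix.to_dataframe().to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Maps, reports, records
# ---------------------------------------------------------------------------


def write_map(maps: list[GeneticMap] | GeneticMap, path) -> None:
    """Write maps as TSV: lg_id, marker, position_cM (3 decimals)."""
    if isinstance(maps, GeneticMap):
        maps = [maps]
    rows = []
    for gmap in maps:
        for marker, pos in zip(gmap.markers, gmap.positions):
            rows.append({"lg_id": gmap.lg_id, "marker": marker, "position_cM": pos})
    pd.DataFrame(rows, columns=["lg_id", "marker", "position_cM"]).to_csv(
        path, sep="\t", index=False, float_format="%.3f"
    )


def read_map(path, fn: str = DEFAULT_MAPPING_FN) -> list[GeneticMap]:
    """Read maps written by :func:`write_map`."""
    df = pd.read_csv(path, sep="\t", dtype={"lg_id": str, "marker": str})
    maps = []
    for lg_id, sub in df.groupby("lg_id", sort=False):
        maps.append(
            GeneticMap(
                lg_id=str(lg_id),
                markers=sub["marker"].tolist(),
                positions=sub["position_cM"].to_numpy(dtype=float),
                fn=fn,
            )
        )
    return maps


def write_records(records: pd.DataFrame, path) -> None:
    records[RECORD_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run; serialized next to outputs."""

    sim: SimConfig = field(default_factory=SimConfig)
    genotypes: str | None = None  # input file overrides simulation
    mapping_function: str = DEFAULT_MAPPING_FN
    p_cutoff: float = DEFAULT_P_CUTOFF
    max_dist_cM: float = DEFAULT_MAX_DIST_CM
    min_informative: int = DEFAULT_MIN_INFORMATIVE
    alpha: float = 0.05
    max_missing: float = 0.10
    correct_doubles: bool = True
    correction_window_cM: float = 10.0
    cluster_source: str = "detected"  # "detected" (r=0 rule) or "truth" (simulated)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    prediction_designs: tuple[str, ...] = ("holdout_80_20", "cv10x5")
    seed: int = 0
    out_dir: str = "cosegmap_out"
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["design"]["levels"] = list(self.design.levels)
        data["design"]["fallback_levels"] = list(self.design.fallback_levels)
        data["prediction_designs"] = list(self.prediction_designs)
        if data["sim"].get("locus_positions") is not None:
            data["sim"]["locus_positions"] = [
                [float(x) for x in p] for p in data["sim"]["locus_positions"]
            ]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        if "sim" in kwargs and isinstance(kwargs["sim"], dict):
            kwargs["sim"] = SimConfig(**kwargs["sim"])
        if "design" in kwargs and isinstance(kwargs["design"], dict):
            d = dict(kwargs["design"])
            for k in ("levels", "fallback_levels"):
                if k in d:
                    d[k] = tuple(d[k])
            kwargs["design"] = ExperimentDesign(**d)
        if "prediction_designs" in kwargs:
            kwargs["prediction_designs"] = tuple(kwargs["prediction_designs"])
        return cls(**kwargs)
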