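"""Tabular, set-library and network I/O shared by every pipeline stage.

All tables travel as tab-separated text with features in rows and samples in
columns (an ``orientation`` flag accepts transposed input). Set libraries use
the Broad GMT dialect. Networks are written as GraphML or a flat edge TSV.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import sys
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("guildlink")

_REL_TOL = 1e-6


def setup_logging(level: str = "INFO") -> None:
    """Configure structured logging to stderr for CLI entry points."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


class ValueKind(str, enum.Enum):
    """What the numbers in an abundance matrix mean."""

    intensity = "intensity"
    relative_abundance = "relative_abundance"
    scaled = "scaled"


@dataclasses.dataclass
class AbundanceTable:
    """Feature × sample numeric matrix with identifier bookkeeping.

    Parameters
    ----------
    values
        DataFrame with feature identifiers as the index and sample
        identifiers as columns.
    value_kind
        One of :class:`ValueKind`. Non-``scaled`` tables must be
        non-negative; ``relative_abundance`` columns must each sum to at
        most 1 (within 1e-6).
    """

    values: pd.DataFrame
    value_kind: ValueKind = ValueKind.intensity

    def __post_init__(self) -> None:
        self.value_kind = ValueKind(self.value_kind)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifiers: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            bad = self.values.columns[np.isnan(arr).any(axis=0)].tolist()
            raise ValueError(f"missing values in samples {bad}; impute or drop first")
        if self.value_kind is not ValueKind.scaled and (arr < 0).any():
            bad = self.values.columns[(arr < 0).any(axis=0)].tolist()
            raise ValueError(f"negative values in samples {bad} for kind {self.value_kind.value}")
        if self.value_kind is ValueKind.relative_abundance:
            sums = arr.sum(axis=0)
            over = sums > 1 + _REL_TOL
            if over.any():
                bad = self.values.columns[over].tolist()
                raise ValueError(
                    f"relative-abundance columns must sum to <= 1: samples {bad}"
                )

    # -- identifiers ------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.values.loc[:, list(sample_ids)], self.value_kind)

    def subset_features(self, feature_ids: Sequence[str]) -> "AbundanceTable":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return AbundanceTable(self.values.loc[list(feature_ids)], self.value_kind)


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample group labels, optional subgroups and clinical indices.

    ``table`` is indexed by sample id and holds a mandatory ``group`` column
    (values ``case``/``control``), an optional ``subgroup`` column, binary
    clinical indices (0/1, NaN for missing) and continuous covariates.
    """

    table: pd.DataFrame
    binary_indices: list[str] = dataclasses.field(default_factory=list)
    continuous_indices: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers in metadata: {dups}")
        if "group" not in self.table.columns:
            raise ValueError("metadata must contain a 'group' column")
        groups = set(self.table["group"].dropna().unique())
        if not groups <= {"case", "control"}:
            raise ValueError(f"group labels must be case/control, got {sorted(groups)}")
        if self.table["group"].isna().any():
            bad = self.table.index[self.table["group"].isna()].tolist()
            raise ValueError(f"samples with missing group label: {bad}")
        for col in self.binary_indices:
            vals = set(self.table[col].dropna().unique())
            if not vals <= {0, 1, 0.0, 1.0}:
                raise ValueError(f"binary index {col!r} has non-0/1 values {sorted(vals)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    def group_labels(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        if sample_ids is None:
            return self.table["group"]
        return self.table.loc[list(sample_ids), "group"]

    def case_samples(self) -> list[str]:
        return self.table.index[self.table["group"] == "case"].tolist()

    def control_samples(self) -> list[str]:
        return self.table.index[self.table["group"] == "control"].tolist()

    def y_binary(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Group labels encoded case=1, control=0 in the given sample order."""
        g = self.table.loc[list(sample_ids), "group"]
        return (g == "case").to_numpy(dtype=float)


SetLibrary = dict[str, list[str]]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(
    path: str | Path,
    value_kind: ValueKind | str = ValueKind.intensity,
    orientation: str = "features_in_rows",
    impute_min_half: bool = False,
) -> AbundanceTable:
    """Read a tab-delimited feature × sample table.

    The first column holds feature identifiers and the header row sample
    identifiers. Missing entries ("" or "NA") are a hard error unless
    ``impute_min_half`` replaces them per feature with half the feature's
    observed minimum (metabolite-intensity tables only, by caller policy).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA"], keep_default_na=False)
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "features_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    non_numeric = [c for c in df.columns if not np.issubdtype(
        pd.to_numeric(df[c], errors="coerce").dtype, np.number)]
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad_cells = coerced.isna() & df.notna()
    if bad_cells.to_numpy().any():
        rows, cols = np.nonzero(bad_cells.to_numpy())
        loc = [(df.index[r], df.columns[c]) for r, c in zip(rows[:5], cols[:5])]
        raise ValueError(f"non-numeric entries at (feature, sample): {loc}")
    del non_numeric
    if coerced.isna().to_numpy().any():
        if impute_min_half:
            mins = coerced.min(axis=1)
            fill = mins / 2.0
            coerced = coerced.apply(lambda row: row.fillna(fill[row.name]), axis=1)
            logger.warning("imputed missing intensities with per-feature min/2")
        else:
            rows = coerced.index[coerced.isna().any(axis=1)].tolist()
            raise ValueError(f"missing values in features {rows[:10]}")
    df = coerced.astype(float)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceTable(df, ValueKind(value_kind))


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    df = table.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata TSV (sample_id, group, subgroup, indices).

    Columns named ``bin_*`` are treated as binary clinical indices and
    ``cov_*`` as continuous covariates; anything else (beyond group and
    subgroup) is inferred: {0,1}-valued columns are binary, numeric columns
    continuous.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    binary, continuous = [], []
    for col in df.columns:
        if col in ("group", "subgroup"):
            continue
        series = pd.to_numeric(df[col], errors="coerce")
        df[col] = series
        vals = set(series.dropna().unique())
        if vals <= {0.0, 1.0} or col.startswith("bin_"):
            binary.append(col)
        else:
            continuous.append(col)
    return SampleMetadata(df, binary_indices=binary, continuous_indices=continuous)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_set_library(path: str | Path) -> SetLibrary:
    """Read a GMT file: ``name<TAB>description<TAB>member1<TAB>member2...``.

    Empty member lists are skipped with a warning; duplicate set names are a
    hard error.
    """
    library: SetLibrary = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: GMT lines need name and description")
            name = parts[0]
            members = [m for m in parts[2:] if m]
            if name in library:
                raise ValueError(f"duplicate set name {name!r} at line {lineno}")
            if not members:
                logger.warning("GMT set %r at line %d has no members; skipped", name, lineno)
                continue
            library[name] = members
    return library


def write_set_library(library: SetLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in library.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ["source", "target", "rho", "q", "sign"]


def write_network(
    edges: Iterable[Mapping],
    path: str | Path,
    fmt: str = "edge_tsv",
    node_attrs: Mapping[str, Mapping] | None = None,
) -> None:
    """Write an edge list (dicts with source/target/rho/q/sign) to disk.

    ``fmt`` is ``graphml`` (loadable by Cytoscape/igraph/networkx) or
    ``edge_tsv`` (flat table, round-trips via :func:`read_network_edges`).
    """
    edges = list(edges)
    if fmt == "edge_tsv":
        df = pd.DataFrame(edges, columns=_EDGE_COLUMNS)
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    elif fmt == "graphml":
        g = nx.Graph()
        if node_attrs:
            for node, attrs in node_attrs.items():
                g.add_node(node, **dict(attrs))
        for e in edges:
            g.add_edge(e["source"], e["target"],
                       rho=float(e["rho"]), q=float(e["q"]), sign=str(e["sign"]))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network_edges(path: str | Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t")
    return df.to_dict(orient="records")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Load a YAML configuration file holding pipeline thresholds."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
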