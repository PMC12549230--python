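"""Reading and writing of on-disk artifacts.

TSV is the canonical interchange format (QIIME / HUMAnN3-style exports).
Networks are exported as GraphML (full attributes) or SIF (topology only).
All validation errors are raised here, before any computation stage sees a
malformed table.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .datamodel import (
    DuplicateIdError,
    FeatureTable,
    MissingValueError,
    NegativeValueError,
    NonNumericValueError,
    RaggedTableError,
    ValidationError,
)

log = logging.getLogger("mbcca")

ORIENTATIONS = ("features_as_rows", "samples_as_rows")


def read_feature_table(
    path,
    orientation: str = "features_as_rows",
    value_kind: str = "count",
    sample_meta: pd.DataFrame | None = None,
    feature_meta: pd.DataFrame | None = None,
) -> FeatureTable:
    """Read a TSV abundance table into a validated :class:`FeatureTable`.

    ``orientation`` states how the file is laid out; the returned table is
    always samples x features. Duplicate ids, ragged rows, and
    non-numeric / missing / negative cells each raise a distinct
    validation error naming the offending location.
    """
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"orientation must be one of {ORIENTATIONS}")
    path = Path(path)
    try:
        raw = pd.read_csv(
            path, sep="\t", index_col=0, dtype=str, engine="python"
        )
    except pd.errors.ParserError as exc:
        raise RaggedTableError(f"{path}: inconsistent row lengths: {exc}") from exc
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].tolist()
        raise DuplicateIdError(f"{path}: duplicate row ids: {dupes}")
    if raw.columns.has_duplicates:
        # pandas mangles duplicate header names to "x.1"; detect via the file
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        dupes = [h for h in set(header) if header.count(h) > 1]
        raise DuplicateIdError(f"{path}: duplicate column ids: {dupes}")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = [x[0] for x in bad.to_numpy().nonzero()]
        row, col = raw.index[r], raw.columns[c]
        cell = raw.iat[r, c]
        if pd.isna(cell):
            raise MissingValueError(
                f"{path}: missing value at row {row!r}, column {col!r}"
            )
        raise NonNumericValueError(
            f"{path}: non-numeric value {cell!r} at row {row!r}, column {col!r}"
        )
    if (numeric.to_numpy() < 0).any():
        r, c = [x[0] for x in (numeric.to_numpy() < 0).nonzero()]
        raise NegativeValueError(
            f"{path}: negative value at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}"
        )
    if orientation == "features_as_rows":
        numeric = numeric.T
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    table = FeatureTable(numeric, value_kind, sample_meta, feature_meta)
    log.info(
        "read %s: %d samples x %d features",
        path.name,
        table.n_samples,
        table.n_features,
    )
    return table


def write_feature_table(
    table: FeatureTable, path, orientation: str = "features_as_rows"
) -> None:
    """Write a feature table as TSV (inverse of :func:`read_feature_table`)."""
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"orientation must be one of {ORIENTATIONS}")
    df = table.data.T if orientation == "features_as_rows" else table.data
    df.to_csv(path, sep="\t")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV (sample id index; e.g. group, timepoint)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise DuplicateIdError(f"{path}: duplicate sample ids")
    return meta


def read_feature_metadata(path) -> pd.DataFrame:
    """Read a feature-metadata TSV (feature id index; taxon, EC, is_aaRS...)."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    if meta.index.has_duplicates:
        raise DuplicateIdError(f"{path}: duplicate feature ids")
    if "is_aaRS" in meta:
        meta["is_aaRS"] = meta["is_aaRS"].astype(bool)
    return meta


def read_go_annotation(path) -> pd.DataFrame:
    """Read a two-column gene -> GO-term annotation TSV.

    Expected columns: ``gene`` and ``go_term`` (one row per pair; a gene
    may carry several terms).
    """
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "go_term"}
    if not required.issubset(ann.columns):
        raise ValidationError(
            f"{path}: annotation table needs columns {sorted(required)}"
        )
    return ann[["gene", "go_term"]]


def write_results_table(result, path) -> None:
    """Write any result object exposing ``to_frame()`` as a deterministic TSV.

    Rows come out sorted by feature/node id unless the result is a ranked
    report (which defines its own deterministic order).
    """
    if hasattr(result, "to_frame"):
        df = result.to_frame()
    elif isinstance(result, pd.DataFrame):
        df = result
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    df.to_csv(path, sep="\t", index=False)


def export_network(net, path, format: str = "graphml") -> None:
    """Export an association network as GraphML or SIF.

    GraphML carries node attributes (layer/type, centralities, cluster) and
    edge attributes (rho, p, weight = -log10 p); SIF carries topology only.
    """
    graph = net.graph if hasattr(net, "graph") else net
    if format == "graphml":

        def plain(attrs):
            out = {}
            for k, v in attrs.items():
                if v is None:
                    continue
                if hasattr(v, "item"):  # numpy scalar -> python scalar
                    v = v.item()
                out[k] = v
            return out

        g = nx.Graph()
        for node, attrs in graph.nodes(data=True):
            g.add_node(node, **plain(attrs))
        for a, b, attrs in graph.edges(data=True):
            g.add_edge(a, b, **plain(attrs))
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(map(sorted, graph.edges())):
                fh.write(f"{a}\tassoc\t{b}\n")
            for node in sorted(n for n in graph.nodes() if graph.degree(n) == 0):
                fh.write(f"{node}\n")
    else:
        raise ValidationError(f"unknown network format {format!r}")
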