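"""Readers and writers for the plain-text formats the pipeline touches.

Tabular inputs (counts, metadata, taxonomy) are tab-separated text; networks
are exported as GraphML (canonical), GEXF, or paired node/edge CSVs.  No
science lives here.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .tables import CountTable, SampleMetadata, TaxonomyMap

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "write_network",
    "read_network",
]

NODE_ATTRS = ("abundance", "family", "lineage", "degree", "betweenness", "community")


def read_count_table(path: str | Path,
                     orientation: str = "taxa_by_samples") -> CountTable:
    """Read a tab-separated count table.

    The first column holds row identifiers and the header row holds column
    identifiers.  ``orientation`` says whether rows are taxa
    (``taxa_by_samples``) or samples (``samples_by_taxa``); the returned
    table is always taxa × samples.
    """
    if orientation not in ("taxa_by_samples", "samples_by_taxa"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples_by_taxa":
        df = df.T
    return CountTable(df)


def write_count_table(table: CountTable, path: str | Path,
                      orientation: str = "taxa_by_samples") -> None:
    df = table.frame
    if orientation == "samples_by_taxa":
        df = df.T
    df.to_csv(path, sep="\t", index_label="id")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read per-sample metadata (tab-separated, first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample")


def read_taxonomy(path: str | Path, sep: str = ";") -> TaxonomyMap:
    """Read taxonomy as a two-column TSV: taxon id, delimited lineage string."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = df.columns[0]
    return TaxonomyMap.from_strings({str(t): str(v) for t, v in df[col].items()},
                                    sep=sep)


def write_taxonomy(tax: TaxonomyMap, path: str | Path, sep: str = ";") -> None:
    rows = {t: sep.join(lin) for t, lin in tax.lineages.items()}
    pd.Series(rows, name="lineage").rename_axis("taxon").to_csv(path, sep="\t")


def _sanitized(net: nx.Graph) -> nx.Graph:
    """Copy with attribute values coerced to GraphML-safe python scalars."""
    g = nx.Graph()
    for n, d in net.nodes(data=True):
        attrs = {}
        for k, v in d.items():
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            elif not isinstance(v, (int, float, str, bool)):
                v = str(v)
            attrs[k] = v
        g.add_node(str(n), **attrs)
    for u, v, d in net.edges(data=True):
        rho = float(d.get("weight", 0.0))
        sign = d.get("sign", "negative" if rho < 0 else "positive")
        g.add_edge(str(u), str(v), weight=rho, sign=sign)
    return g


def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> list[Path]:
    """Write a co-occurrence network; returns the paths written.

    ``format`` is one of ``graphml``, ``gexf`` or ``edge_csv`` (which writes
    a ``*_edges.csv`` / ``*_nodes.csv`` pair next to ``path``).
    """
    path = Path(path)
    if net.number_of_nodes() == 0:
        warnings.warn("writing an empty network", stacklevel=2)
    g = _sanitized(net)
    if format == "graphml":
        nx.write_graphml(g, path)
        return [path]
    if format == "gexf":
        nx.write_gexf(g, path)
        return [path]
    if format == "edge_csv":
        stem = path.with_suffix("")
        epath = Path(f"{stem}_edges.csv")
        npath = Path(f"{stem}_nodes.csv")
        erows = [
            {"source": u, "target": v, "rho": d["weight"], "sign": d["sign"]}
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(erows, columns=["source", "target", "rho", "sign"]).to_csv(
            epath, index=False)
        nrows = []
        for n, d in g.nodes(data=True):
            row = {"id": n}
            for k in NODE_ATTRS:
                if k in d:
                    row[k] = d[k]
            nrows.append(row)
        pd.DataFrame(nrows).to_csv(npath, index=False)
        return [epath, npath]
    raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> nx.Graph:
    """Read a network written by :func:`write_network` (GraphML or GEXF)."""
    path = Path(path)
    if path.suffix == ".gexf":
        g = nx.read_gexf(path)
    else:
        g = nx.read_graphml(path)
    g = nx.Graph(g)
    # gexf round-trips can relabel; ensure string node ids
    return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
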