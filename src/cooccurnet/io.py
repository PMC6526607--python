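"""Plain-text readers and writers for the pipeline's tables."""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_traits",
    "write_traits",
    "write_edges",
    "read_edges",
    "write_graphml",
    "write_labels",
    "read_labels",
]


def read_otu_table(path) -> pd.DataFrame:
    """TSV with first column `taxon_id`, remaining columns sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_otu_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="taxon_id")


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index_label="sample_id")


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_graphml(edges, path) -> None:
    from .network import graph_from_edges

    nx.write_graphml(graph_from_edges(edges), path)


def write_labels(labels, path) -> None:
    with open(path, "w") as fh:
        for taxon in sorted(labels):
            fh.write(f"{taxon}\n")


def read_labels(path) -> frozenset:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())
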