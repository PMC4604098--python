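"""Thresholded Pearson co-expression networks and their modules.

Given a normalized genes x arrays expression compendium, an undirected edge
joins two genes whose expression profiles correlate at or above a threshold
(default r >= 0.7, signed).  A *module* is a set of genes with no connection
to the rest of the network, i.e. a connected component.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "pearson_matrix",
    "build_network",
    "find_modules",
    "network_stats",
    "export_network",
]


def pearson_matrix(
    compendium: pd.DataFrame, genes: Sequence[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Pearson correlations between gene profiles.

    Returns ``(corr, excluded)`` where ``excluded`` lists requested genes with
    zero-variance profiles (correlation undefined; dropped with a report
    rather than an error).  Requires >= 3 arrays.
    """
    if compendium.shape[1] < 3:
        raise ValueError("at least 3 arrays are required")
    if genes is None:
        genes = list(compendium.index)
    else:
        missing = sorted(set(genes) - set(compendium.index))
        if missing:
            raise KeyError(f"genes absent from compendium: {missing[:5]}"
                           + ("..." if len(missing) > 5 else ""))
    sub = compendium.loc[list(genes)]
    var = sub.var(axis=1, ddof=0)
    excluded = sorted(sub.index[var == 0.0])
    sub = sub.loc[var > 0.0]
    if len(sub) == 0:
        return pd.DataFrame(index=[], columns=[], dtype=float), excluded
    corr = np.corrcoef(sub.to_numpy())
    corr = np.clip(np.atleast_2d(corr), -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=sub.index, columns=sub.index), excluded


def build_network(
    corr: pd.DataFrame, threshold: float = 0.7, absolute: bool = False
) -> tuple[nx.Graph, list[str]]:
    """Threshold a correlation matrix into an undirected weighted graph.

    Edge (i, j) exists iff r_ij >= threshold (or |r_ij| >= threshold with
    ``absolute=True``).  Nodes are only the endpoints of surviving edges;
    the second return value lists input genes left without any edge.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    genes = list(corr.index)
    g = nx.Graph()
    vals = corr.to_numpy()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = vals[i, j]
            if (abs(r) if absolute else r) >= threshold:
                g.add_edge(genes[i], genes[j], weight=float(r))
    unconnected = sorted(set(genes) - set(g.nodes))
    return g, unconnected


def find_modules(net: nx.Graph) -> list[set[str]]:
    """Connected components, largest first (ties by smallest member id)."""
    comps = [set(c) for c in nx.connected_components(net)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def network_stats(
    net: nx.Graph, modules: list[set[str]] | None = None
) -> dict:
    """Node/edge/module counts; module sizes listed in partition order."""
    if modules is None:
        modules = find_modules(net)
    covered = set().union(*modules) if modules else set()
    if covered != set(net.nodes):
        raise ValueError("module partition does not cover the node set")
    return {
        "nodes": net.number_of_nodes(),
        "edges": net.number_of_edges(),
        "modules": len(modules),
        "module_sizes": [len(m) for m in modules],
    }


def _sorted_edges(net: nx.Graph) -> list[tuple[str, str, float]]:
    edges = []
    for a, b, d in net.edges(data=True):
        a, b = sorted((a, b))
        edges.append((a, b, float(d.get("weight", 1.0))))
    return sorted(edges)


def export_network(
    net: nx.Graph,
    modules: list[set[str]] | None,
    fmt: str,
    path,
) -> None:
    """Write the network as ``sif``, ``graphml`` or ``tsv`` (edge list).

    Output ordering is lexicographic, hence byte-stable.  GraphML carries the
    correlation weight per edge and the module index per node.
    """
    if modules is None:
        modules = find_modules(net)
    module_of = {g: i for i, mod in enumerate(modules) for g in mod}
    edges = _sorted_edges(net)
    if fmt == "sif":
        with open(path, "w") as fh:
            for a, b, _ in edges:
                fh.write(f"{a} cx {b}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tr\n")
            for a, b, r in edges:
                fh.write(f"{a}\t{b}\t{r:.6g}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for n in sorted(net.nodes):
            g.add_node(n, module=module_of[n])
        for a, b, r in edges:
            g.add_edge(a, b, weight=r)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; use sif, graphml or tsv")


def write_modules(modules: list[set[str]], path) -> None:
    """Gene -> module-index TSV (indices follow the partition order)."""
    with open(path, "w") as fh:
        fh.write("gene\tmodule\n")
        for i, mod in enumerate(modules):
            for g in sorted(mod):
                fh.write(f"{g}\t{i}\n")


def write_stats(stats: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
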