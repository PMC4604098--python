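import networkx as nx

from fepi.ontology import GoDag


def dag_from_edges(terms, edges):
    """Build a GoDag from (child, parent) pairs without round-tripping OBO."""
    g = nx.MultiDiGraph()
    for t in terms:
        g.add_node(t, name=f"term {t}", namespace="biological_process")
    for child, parent in edges:
        g.add_edge(child, parent, key="is_a")
    return GoDag(g)
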