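"""GO over-representation analysis: classic Fisher and the elim algorithm.

The ontology is a DAG of terms linked child -> parent by ``is_a`` (and,
treated identically, ``part_of``).  Annotations obey the true-path rule after
propagation: a gene annotated to a term is annotated to every ancestor.

The classic test for a term is the one-sided hypergeometric (Fisher) tail:
with ``N`` universe genes of which ``K`` carry the term, and ``n`` study
genes of which ``k`` carry it, ``p = P(X >= k)`` for
``X ~ Hypergeom(N, K, n)``.

The elim variant decorrelates the DAG: terms are visited most-specific first
(deepest by longest path to the root, ties by id); whenever a term tests
significant (p below the elim cutoff), the genes currently annotated to it
are removed from all of its strict ancestors before those are tested, so
enrichment signal is credited to the most specific term that explains it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import obonet
from scipy import stats

__all__ = [
    "GoDag",
    "EnrichmentResult",
    "parse_obo",
    "propagate_annotations",
    "read_annotations",
    "fisher_term",
    "elim_enrich",
]


@dataclass
class GoDag:
    """Acyclic ontology; ``graph`` holds child -> parent edges."""

    graph: nx.MultiDiGraph

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def ancestors(self, term: str) -> set[str]:
        """All strict ancestors (terms reachable via is_a/part_of)."""
        return nx.descendants(self.graph, term)

    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def depth(self, term: str) -> int:
        """Longest is_a/part_of path from ``term`` up to a root."""
        return self._depths()[term]

    def _depths(self) -> dict[str, int]:
        if not hasattr(self, "_depth_cache"):
            depths: dict[str, int] = {}
            for t in reversed(list(nx.topological_sort(self.graph))):
                parents = list(self.graph.successors(t))
                depths[t] = 1 + max(depths[p] for p in parents) if parents else 0
            self._depth_cache = depths
        return self._depth_cache


def parse_obo(source) -> GoDag:
    """Parse a (minimal OBO 1.2) ontology into a validated DAG.

    Obsolete terms are skipped.  Raises on cycles (naming an offending edge)
    and on parents referenced but never defined.
    """
    graph = obonet.read_obo(source, ignore_obsolete=True)
    dangling = [t for t, d in graph.nodes(data=True) if "name" not in d]
    if dangling:
        raise ValueError(f"dangling parent terms without stanzas: {sorted(dangling)}")
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"ontology contains a cycle through edge {cycle[0][:2]}")
    # keep only is_a / part_of links for ancestry
    drop = [
        (u, v, k) for u, v, k in graph.edges(keys=True)
        if k not in ("is_a", "part_of")
    ]
    graph.remove_edges_from(drop)
    return GoDag(graph)


def read_annotations(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) -> gene -> term-set mapping."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            gene, term = ln.split("\t")[:2]
            if gene == "gene_id":  # optional header
                continue
            out.setdefault(gene, set()).add(term)
    return out


def propagate_annotations(
    dag: GoDag, direct: Mapping[str, Iterable[str]]
) -> dict[str, set[str]]:
    """Close each gene's term set under ancestry (true-path rule); idempotent."""
    unknown = sorted(
        {t for terms in direct.values() for t in terms} - dag.terms)
    if unknown:
        raise ValueError(f"annotations reference unknown terms: {unknown}")
    anc_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        closed: set[str] = set()
        for t in terms:
            if t not in anc_cache:
                anc_cache[t] = dag.ancestors(t) | {t}
            closed |= anc_cache[t]
        out[gene] = closed
    return out


def fisher_term(
    universe_size: int, term_in_universe: int,
    study_size: int, term_in_study: int,
) -> float:
    """One-sided over-representation p-value, P(X >= term_in_study)."""
    N, K, n, k = universe_size, term_in_universe, study_size, term_in_study
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("inconsistent universe/term/study sizes")
    if not (0 <= k <= min(K, n)):
        raise ValueError("term_in_study exceeds term_in_universe or study_size")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    annotated_universe: int
    annotated_study: int
    p_classic: float
    p_elim: float


def elim_enrich(
    dag: GoDag,
    annotations: Mapping[str, Iterable[str]],
    study: Iterable[str],
    universe: Iterable[str],
    cutoff: float = 0.01,
    elim_cutoff: float | None = None,
) -> list[EnrichmentResult]:
    """Score every annotated term with classic Fisher and elim p-values.

    ``annotations`` must already be propagated (gene -> term set).  ``cutoff``
    is both the elim significance threshold and, unless ``elim_cutoff`` is
    given separately, the pruning trigger: after a term tests below it, the
    term's currently annotated genes are removed from all strict ancestors
    before those are tested.  Classic p-values always use the unpruned sets.
    Results are sorted by p_elim ascending, ties by term id; all annotated
    terms are returned (filter on ``p_elim`` for reporting).
    """
    study = set(study)
    universe = set(universe)
    stray = study - universe
    if stray:
        raise ValueError(f"study genes absent from universe: {sorted(stray)[:5]}")
    if elim_cutoff is None:
        elim_cutoff = cutoff

    term_genes: dict[str, set[str]] = {}
    for gene in universe:
        for t in annotations.get(gene, ()):
            term_genes.setdefault(t, set()).add(gene)

    N, n = len(universe), len(study)
    order = sorted(term_genes, key=lambda t: (-dag.depth(t), t))
    current = {t: set(g) for t, g in term_genes.items()}
    results = []
    for t in order:
        K0 = len(term_genes[t])
        k0 = len(term_genes[t] & study)
        K = len(current[t])
        k = len(current[t] & study)
        p_classic = fisher_term(N, K0, n, k0)
        p_elim = fisher_term(N, K, n, k)
        results.append(EnrichmentResult(
            t, dag.name(t), K0, k0, p_classic, p_elim))
        if p_elim < elim_cutoff:
            pruned = set(current[t])
            for anc in dag.ancestors(t):
                if anc in current:
                    current[anc] -= pruned
    results.sort(key=lambda r: (r.p_elim, r.term))
    return results


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    """Enrichment table TSV: term, p_elim, name, counts, p_classic."""
    with open(path, "w") as fh:
        fh.write("term\tp_elim\tname\tannotated_universe\tannotated_study\tp_classic\n")
        for r in results:
            fh.write(f"{r.term}\t{r.p_elim:.6g}\t{r.name}\t"
                     f"{r.annotated_universe}\t{r.annotated_study}\t"
                     f"{r.p_classic:.6g}\n")
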