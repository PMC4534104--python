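"""GO term enrichment by Fisher's exact test with the elim decorrelation.

Terms are tested one-sided for over-representation (hypergeometric upper
tail). The elim algorithm walks the DAG from the most specific terms upward;
whenever a term is significant at the elim cutoff, its currently annotated
genes are removed from all of its ancestors before those are tested, which
suppresses the cascade of significance that true-path propagation otherwise
induces along is_a chains.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom


class GoDag:
    """A Gene Ontology fragment: terms with is_a edges (child -> parent)."""

    def __init__(self, terms: dict[str, tuple[str, str]], parents: dict[str, set[str]]):
        self.terms = dict(terms)
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in parents.items():
            for p in ps:
                if child not in self.terms or p not in self.terms:
                    raise ValueError(f"is_a edge references unknown term: {child} -> {p}")
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("GO graph contains a cycle")
        self.graph = g
        self._depth: dict[str, int] | None = None

    @classmethod
    def from_obo(cls, path) -> "GoDag":
        import obonet

        g = obonet.read_obo(path)
        terms = {}
        parents: dict[str, set[str]] = {}
        for node, data in g.nodes(data=True):
            terms[node] = (data.get("name", node), data.get("namespace", ""))
            parents[node] = set(g.successors(node))  # obonet edges point child->parent
        return cls(terms, parents)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)  # along child->parent edges

    def roots(self) -> list[str]:
        return sorted(t for t in self.terms if not self.parents(t))

    def depth(self, term: str) -> int:
        """Length of the longest is_a path from a root down to the term."""
        if self._depth is None:
            depth: dict[str, int] = {}
            for t in reversed(list(nx.topological_sort(self.graph))):
                ps = self.parents(t)
                depth[t] = 0 if not ps else 1 + max(depth[p] for p in ps)
            self._depth = depth
        return self._depth[term]


def annotate_ancestors(
    annotations: dict[str, set[str]], dag: GoDag
) -> dict[str, set[str]]:
    """True-path propagation: each gene inherits every ancestor of its terms."""
    out: dict[str, set[str]] = {}
    cache: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        full: set[str] = set()
        for t in terms:
            if t not in dag:
                raise ValueError(f"annotation to unknown GO term {t} (gene {gene})")
            if t not in cache:
                cache[t] = {t} | dag.ancestors(t)
            full |= cache[t]
        out[gene] = full
    return out


def fisher_term(
    study_count: int, study_total: int, pop_count: int, pop_total: int
) -> float:
    """One-sided over-representation p-value: P(X >= study_count) with X
    hypergeometric(pop_total, pop_count, study_total)."""
    if not (
        0 <= study_count <= study_total <= pop_total
        and study_count <= pop_count <= pop_total
    ):
        raise ValueError("inconsistent contingency counts")
    return float(hypergeom.sf(study_count - 1, pop_total, pop_count, study_total))


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    name: str
    study_count: int
    study_total: int
    pop_count: int
    pop_total: int
    p_classic: float
    p_elim: float


def elim_enrich(
    dag: GoDag,
    annotations: dict[str, set[str]],
    study_set: set[str],
    population: set[str] | None = None,
    elim_cutoff: float = 0.01,
) -> list[EnrichmentResult]:
    """Classic and elim Fisher enrichment over every annotated term.

    `annotations` are raw gene -> term assignments (propagated internally).
    The population defaults to all annotated genes; the study set must be a
    subset of the population. Terms are processed most-specific-first
    (decreasing DAG depth, ties by term id); a term significant at elim_cutoff
    has its current genes removed from its ancestors' sets before those are
    tested.
    """
    propagated = annotate_ancestors(annotations, dag)
    if population is None:
        population = set(propagated)
    else:
        if not set(study_set) <= set(population):
            raise ValueError("study set must be a subset of the population")
        population = set(population) & set(propagated)
    # only annotated ("feasible") genes enter the contingency tables
    study = set(study_set) & population
    term_genes: dict[str, set[str]] = {}
    for gene in population:
        for t in propagated[gene]:
            term_genes.setdefault(t, set()).add(gene)
    pop_total = len(population)
    study_total = len(study)
    order = sorted(term_genes, key=lambda t: (-dag.depth(t), t))
    current = {t: set(g) for t, g in term_genes.items()}
    results = []
    for t in order:
        classic_genes = term_genes[t]
        cur = current[t]
        p_classic = fisher_term(
            len(study & classic_genes), study_total, len(classic_genes), pop_total
        )
        p_elim = fisher_term(len(study & cur), study_total, len(cur), pop_total)
        results.append(
            EnrichmentResult(
                t,
                dag.terms[t][0],
                len(study & classic_genes),
                study_total,
                len(classic_genes),
                pop_total,
                p_classic,
                p_elim,
            )
        )
        if p_elim < elim_cutoff:
            for anc in dag.ancestors(t):
                if anc in current:
                    current[anc] -= cur
    return results


def enriched_terms(
    results: list[EnrichmentResult], alpha: float = 1e-2, method: str = "elim"
) -> pd.DataFrame:
    """Terms significant at p < alpha (strict), sorted by ascending p."""
    key = "p_elim" if method == "elim" else "p_classic"
    df = pd.DataFrame([r.__dict__ for r in results])
    if df.empty:
        return df
    df = df[df[key] < alpha].sort_values([key, "term_id"]).reset_index(drop=True)
    return df


def load_annotation_tsv(path) -> dict[str, set[str]]:
    """Read a two-plus-column TSV (gene_id, term_id[, ...]) into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    ann: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        ann.setdefault(gene, set()).add(term)
    return ann
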