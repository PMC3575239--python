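"""GO-term enrichment of positively selected codon sites.

Annotations are propagated up the ontology (every gene annotated to a term
is implicitly annotated to all of that term's ancestors via is_a links, and
optionally part_of).  For each term, the universe is all filtered codon
sites of all tested genes — the test asks whether positively selected sites
concentrate in genes carrying the term, counting sites rather than genes so
that pervasively selected genes weigh more.  The p-value is the
hypergeometric upper tail; Bonferroni correction multiplies by the number
of terms actually tested (by default, terms with at least one annotated
site; counting all terms is available via a flag).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class EnrichmentResult:
    term: str
    n_term_sites: int
    k_term_ps: int
    N_total_sites: int
    K_total_ps: int
    p_raw: float
    p_bonferroni: float

    def __post_init__(self):
        if self.k_term_ps > min(self.n_term_sites, self.K_total_ps):
            raise ValueError("inconsistent counts: k > min(n, K)")


def load_dag(obo) -> nx.MultiDiGraph:
    """Read an OBO ontology (path, file handle or literal text)."""
    if hasattr(obo, "read"):
        return obonet.read_obo(obo)
    text = str(obo)
    if "[Term]" in text:
        return obonet.read_obo(io.StringIO(text))
    return obonet.read_obo(text)


def _parent_graph(dag: nx.MultiDiGraph,
                  relations=("is_a",)) -> nx.DiGraph:
    """Child -> parent digraph restricted to the requested relations."""
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    for u, v, key in dag.edges(keys=True):
        if key in relations:
            g.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("ontology is_a graph is cyclic")
    return g


def propagate_annotations(annotations: dict, dag,
                          relations=("is_a",)) -> dict:
    """Transitive closure of gene annotations over parental links.

    Idempotent: propagating twice changes nothing.  Terms absent from the
    DAG are kept as-is (self only).
    """
    if isinstance(dag, nx.MultiDiGraph):
        g = _parent_graph(dag, relations)
    elif isinstance(dag, nx.DiGraph):
        g = dag
    else:
        raise TypeError("dag must be a networkx (Multi)DiGraph")
    closure_cache: dict[str, set] = {}

    def closure(term: str) -> set:
        if term not in closure_cache:
            if term in g:
                closure_cache[term] = {term} | nx.descendants(g, term)
            else:
                closure_cache[term] = {term}
        return closure_cache[term]

    return {gene: set().union(*(closure(t) for t in terms)) if terms else set()
            for gene, terms in annotations.items()}


def site_hypergeometric(n_term_sites: int, k_term_ps: int,
                        N_total_sites: int, K_total_ps: int,
                        term: str = "", m_tests: int = 1
                        ) -> EnrichmentResult:
    """Upper-tail hypergeometric probability of >= k selected sites.

    p = sum_{j >= k} C(K, j) C(N-K, n-j) / C(N, n): the chance of seeing at
    least this many positively selected sites in the term's genes if the
    K selected sites were scattered randomly over all N sites.
    """
    if N_total_sites < 1:
        raise ValueError("universe must contain at least one site")
    if k_term_ps > min(n_term_sites, K_total_ps):
        raise ValueError("inconsistent counts: k > min(n, K)")
    p = float(hypergeom.sf(k_term_ps - 1, N_total_sites, K_total_ps,
                           n_term_sites))
    p = min(1.0, max(p, 0.0))
    return EnrichmentResult(term, n_term_sites, k_term_ps, N_total_sites,
                            K_total_ps, p, min(1.0, m_tests * p))


def enrich(site_table: dict, annotations: dict, dag,
           relations=("is_a",), correct_all_terms: bool = False
           ) -> pd.DataFrame:
    """Rank GO terms by enrichment of positively selected sites.

    ``site_table`` maps gene -> (total filtered sites, positively selected
    sites); ``annotations`` maps gene -> set of directly assigned terms.
    Annotations are propagated, every term with at least one annotated site
    is tested, and Bonferroni corrects over the tested terms (or all DAG
    terms when ``correct_all_terms``).  Returns a DataFrame sorted by
    adjusted then raw p.
    """
    ann = propagate_annotations(annotations, dag, relations)
    N = sum(n for n, _ in site_table.values())
    K = sum(k for _, k in site_table.values())
    term_n: dict[str, int] = {}
    term_k: dict[str, int] = {}
    for gene, (n_sites, k_ps) in site_table.items():
        for term in ann.get(gene, ()):
            term_n[term] = term_n.get(term, 0) + n_sites
            term_k[term] = term_k.get(term, 0) + k_ps
    tested = [t for t, n in term_n.items() if n > 0]
    if correct_all_terms:
        m = len(getattr(dag, "nodes", tested)) or len(tested)
    else:
        m = len(tested)
    rows = []
    for t in tested:
        res = site_hypergeometric(term_n[t], term_k.get(t, 0), N, K,
                                  term=t, m_tests=m)
        rows.append({"term": t, "n_term_sites": res.n_term_sites,
                     "k_term_ps": res.k_term_ps, "N_total_sites": N,
                     "K_total_ps": K, "p_raw": res.p_raw,
                     "p_bonferroni": res.p_bonferroni})
    df = pd.DataFrame(rows, columns=["term", "n_term_sites", "k_term_ps",
                                     "N_total_sites", "K_total_ps",
                                     "p_raw", "p_bonferroni"])
    return df.sort_values(["p_bonferroni", "p_raw", "term"],
                          kind="stable").reset_index(drop=True)


def read_annotations_tsv(path) -> dict:
    """gene<TAB>term rows (one pair per line) -> gene -> set of terms."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, set()).add(term.strip())
    return out


def read_site_table_tsv(path) -> dict:
    """gene<TAB>total_sites<TAB>ps_sites rows -> gene -> (n, k)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, n, k = line.split("\t")[:3]
            out[gene] = (int(n), int(k))
    return out
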