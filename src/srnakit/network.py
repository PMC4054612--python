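"""miRNA-mRNA regulatory network construction by database voting and
inverse expression, hypergeometric GO enrichment, and GO-category
sub-networks with protein-protein interaction edges.

An edge miRNA -> gene is accepted iff (1) at least ``min_db_support``
distinct interaction databases attest the pair and (2) the pair is
inversely expressed: the miRNA is significantly down and the gene is in
the upregulated list, or vice versa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr


@dataclass(frozen=True)
class NetworkEdge:
    mirna: str
    gene: str
    support: int
    mirna_direction: str  # {"up", "down"}
    gene_direction: str


def load_interactions(table: pd.DataFrame) -> pd.DataFrame:
    """Canonicalise an interaction-evidence table.

    Expects columns ``mirna``, ``gene``, ``database``; names are
    case-normalised (miRNA lower, gene upper) and duplicate
    (mirna, gene, database) triples are dropped.
    """
    required = {"mirna", "gene", "database"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    out = table.copy()
    out["mirna"] = out["mirna"].astype(str).str.strip().str.lower()
    out["gene"] = out["gene"].astype(str).str.strip().str.upper()
    out["database"] = out["database"].astype(str).str.strip()
    return out.drop_duplicates(["mirna", "gene", "database"]).reset_index(drop=True)


def build_network(
    de_mirnas: Mapping[str, str] | pd.Series,
    up_genes: Iterable[str],
    down_genes: Iterable[str],
    interactions: pd.DataFrame,
    min_db_support: int = 3,
) -> list[NetworkEdge]:
    """Vote-and-direction-filtered miRNA -> gene edges.

    ``de_mirnas`` maps each significantly deregulated miRNA to its
    direction ("up"/"down"); ``up_genes``/``down_genes`` are the
    differentially expressed gene lists (disjoint).  Matching is
    case-insensitive exact.
    """
    mirna_dir = {str(m).lower(): d for m, d in dict(de_mirnas).items()}
    up = {str(g).upper() for g in up_genes}
    down = {str(g).upper() for g in down_genes}
    clash = up & down
    if clash:
        raise ValueError(f"genes in both up and down lists: {sorted(clash)[:5]}")
    inter = load_interactions(interactions)
    if inter.empty:
        warnings.warn("empty interaction table: network will be empty")
        return []
    support = (
        inter.groupby(["mirna", "gene"])["database"].nunique().rename("support")
    )
    edges: list[NetworkEdge] = []
    for (mirna, gene), n_db in support.items():
        d_mir = mirna_dir.get(mirna)
        if d_mir is None or n_db < min_db_support:
            continue
        if gene in up:
            d_gene = "up"
        elif gene in down:
            d_gene = "down"
        else:
            continue
        if d_mir == d_gene:  # inverse-expression criterion
            continue
        edges.append(NetworkEdge(mirna, gene, int(n_db), d_mir, d_gene))
    edges.sort(key=lambda e: (e.mirna, e.gene))
    return edges


def target_counts(edges: Sequence[NetworkEdge]) -> tuple[pd.Series, pd.Series]:
    """(targets per miRNA, regulators per gene), sorted descending."""
    per_mirna = pd.Series([e.mirna for e in edges]).value_counts()
    per_gene = pd.Series([e.gene for e in edges]).value_counts()
    return per_mirna, per_gene


# ---------------------------------------------------------------------------
# GO enrichment (hypergeometric)
# ---------------------------------------------------------------------------

def go_enrichment(
    gene_list: Iterable[str],
    go_map: pd.DataFrame,
    universe: Iterable[str] | None = None,
    go_fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-term hypergeometric upper-tail enrichment with BH correction.

    ``go_map`` has columns ``gene``, ``term``.  The universe defaults to
    every gene in ``go_map``; terms with no annotated gene are skipped.
    p = P(X >= k) with N universe genes, K term genes, n list genes.
    """
    gmap = go_map.copy()
    gmap["gene"] = gmap["gene"].astype(str).str.upper()
    genes = {str(g).upper() for g in gene_list}
    univ = (
        {str(g).upper() for g in universe}
        if universe is not None
        else set(gmap["gene"])
    )
    if not genes <= univ:
        raise ValueError("gene list is not a subset of the universe")
    gmap = gmap[gmap["gene"].isin(univ)]
    N = len(univ)
    n = len(genes)
    rows = []
    for term, members in gmap.groupby("term")["gene"]:
        member_set = set(members)
        K = len(member_set)
        if K == 0:
            continue
        k = len(member_set & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "pvalue": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "pvalue"])
    if len(result):
        result["fdr"] = bh_fdr(result["pvalue"].to_numpy())
        result["enriched"] = result["fdr"] < go_fdr
        result = result.sort_values("pvalue").reset_index(drop=True)
    return result


def category_subnetwork(
    term: str,
    enrichment: pd.DataFrame,
    gene_list: Iterable[str],
    ppi_edges: pd.DataFrame,
    network_edges: Sequence[NetworkEdge],
    go_map: pd.DataFrame,
    go_fdr: float = 0.05,
) -> nx.Graph:
    """Sub-network of one enriched GO category.

    Nodes: the category's genes that are in the DE gene list, plus every
    miRNA targeting one of them.  Edges: PPI edges among those genes
    (columns ``geneA``, ``geneB``) plus the targeting edges.  Refuses a
    term that is not enriched at ``go_fdr``.
    """
    row = enrichment[enrichment["term"] == term]
    if row.empty:
        raise ValueError(f"term {term!r} not present in the enrichment results")
    fdr = float(row["fdr"].iloc[0])
    if fdr >= go_fdr:
        raise ValueError(f"term {term!r} not enriched (FDR = {fdr:.4g} >= {go_fdr})")
    genes = {str(g).upper() for g in gene_list}
    members = {
        str(g).upper()
        for g in go_map.loc[go_map["term"] == term, "gene"]
    } & genes

    g = nx.Graph()
    for gene in sorted(members):
        g.add_node(gene, node_type="gene")
    for _, r in ppi_edges.iterrows():
        a, b = str(r["geneA"]).upper(), str(r["geneB"]).upper()
        if a in members and b in members and a != b:
            g.add_edge(a, b, relation="interacts")
    for e in network_edges:
        if e.gene in members:
            g.add_node(e.mirna, node_type="miRNA")
            g.add_edge(e.mirna, e.gene, relation="targets", support=e.support)
    return g


def degree_report(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"node": n, "node_type": g.nodes[n].get("node_type", ""), "degree": d}
        for n, d in sorted(g.degree, key=lambda x: (-x[1], x[0]))
    ]
    return pd.DataFrame(rows, columns=["node", "node_type", "degree"])
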