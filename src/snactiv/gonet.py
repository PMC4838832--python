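"""Parent-weighted GO cosine-similarity gene networks.

Each gene is a binary vector over GO terms; each term is weighted by its
number of parents in the ontology (a proxy for specificity: deeper, more
specific terms carry more weight). Pairwise weighted cosine similarity is
thresholded (strictly greater) into an undirected network whose edge
distance is one minus similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core import ValidationError

DEFAULT_THRESHOLD = 0.5


@dataclass
class GOAnnotationSet:
    """gene -> set of term ids, plus term -> set of direct parent term ids."""

    gene_terms: dict[str, set[str]]
    term_parents: dict[str, set[str]]

    def __post_init__(self) -> None:
        for gene, terms in self.gene_terms.items():
            missing = terms - self.term_parents.keys()
            if missing:
                raise ValidationError(
                    f"gene {gene!r} annotated with terms absent from the parent "
                    f"table: {sorted(missing)[:5]}"
                )

    @classmethod
    def from_tsv(cls, annotation_path: str | Path, parent_path: str | Path) -> "GOAnnotationSet":
        """Two 2-column TSVs: (gene, term) and (term, parent). A term with no
        parents appears with an empty second column or only as a parent."""
        ann = pd.read_csv(annotation_path, sep="\t", header=None, names=["gene", "term"])
        par = pd.read_csv(
            parent_path, sep="\t", header=None, names=["term", "parent"],
            keep_default_na=False,
        )
        gene_terms: dict[str, set[str]] = {}
        for gene, term in zip(ann["gene"], ann["term"]):
            gene_terms.setdefault(str(gene), set()).add(str(term))
        term_parents: dict[str, set[str]] = {}
        for term, parent in zip(par["term"], par["parent"]):
            term_parents.setdefault(str(term), set())
            if parent:
                term_parents[str(term)].add(str(parent))
                term_parents.setdefault(str(parent), set())
        return cls(gene_terms, term_parents)


def parent_weights(annot: GOAnnotationSet, mode: str = "direct") -> dict[str, float]:
    """Per-term weight: the number of direct parents, or of all distinct
    ancestors under ``mode='ancestors'``. Roots weigh 0; cycles are an error."""
    graph = nx.DiGraph()
    graph.add_nodes_from(annot.term_parents)
    for term, parents in annot.term_parents.items():
        for parent in parents:
            graph.add_edge(term, parent)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValidationError("parent graph contains a cycle")
    if mode == "direct":
        return {t: float(len(ps)) for t, ps in annot.term_parents.items()}
    if mode == "ancestors":
        return {t: float(len(nx.descendants(graph, t))) for t in graph.nodes}
    raise ValueError(f"unknown mode {mode!r}")


def weighted_cosine(x: set[str], y: set[str], w: dict[str, float]) -> float:
    """Weighted cosine between two binary term sets:
    sum(w_j) over the intersection / sqrt(sum w over x) / sqrt(sum w over y);
    zero when either weighted norm vanishes."""
    wx = sum(w.get(t, 0.0) for t in x)
    wy = sum(w.get(t, 0.0) for t in y)
    if wx <= 0 or wy <= 0:
        return 0.0
    wxy = sum(w.get(t, 0.0) for t in x & y)
    return wxy / np.sqrt(wx * wy)


@dataclass
class GeneNetwork:
    edges: pd.DataFrame      # gene1, gene2, similarity, distance
    isolated: list[str]      # genes with no retained edge (incl. unannotated)
    threshold: float

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.isolated)
        for _, row in self.edges.iterrows():
            g.add_edge(
                row["gene1"], row["gene2"],
                similarity=float(row["similarity"]), distance=float(row["distance"]),
            )
        return g

    def write_edge_list(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_graph(), str(path))


def build_network(
    genes: list[str],
    annot: GOAnnotationSet,
    threshold: float = DEFAULT_THRESHOLD,
    weight_mode: str = "direct",
) -> GeneNetwork:
    """All-pairs weighted cosine network, keeping similarities strictly above
    the threshold; edge distance is 1 - similarity."""
    if len(genes) < 2:
        raise ValidationError("need >= 2 genes")
    w = parent_weights(annot, mode=weight_mode)
    rows = []
    connected: set[str] = set()
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1 :]:
            sim = weighted_cosine(
                annot.gene_terms.get(g1, set()), annot.gene_terms.get(g2, set()), w
            )
            if sim > threshold:
                rows.append(
                    {"gene1": g1, "gene2": g2, "similarity": sim, "distance": 1.0 - sim}
                )
                connected.update((g1, g2))
    edges = pd.DataFrame(rows, columns=["gene1", "gene2", "similarity", "distance"])
    return GeneNetwork(
        edges=edges,
        isolated=[g for g in genes if g not in connected],
        threshold=threshold,
    )
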