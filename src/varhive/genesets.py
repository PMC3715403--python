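"""Pathway and protein-interaction views of one sample's variant load.

Gene sets (pathway catalogs) come from a two-column TSV ``set_id<TAB>gene``;
interaction networks from a two-column edge list ``geneA<TAB>geneB``. Gene
matching is by uppercased symbol — no alias resolution is attempted, so a
catalog and a VCF annotated against different symbol vintages will simply
miss each other (a data problem, not one this module can repair).

A "functional" variant defaults to primary-impact severity MED or higher;
carrying one means the sample is HET or HOM_ALT at the site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .gtstore import HET, HOM_ALT
from .session import FrameworkSession, open_session

__all__ = [
    "GeneSetCatalog",
    "read_gene_sets",
    "read_interactions",
    "sample_pathways",
    "interactions",
]

_SEVERITY_RANK = {"HIGH": 3, "MED": 2, "LOW": 1}


@dataclass
class GeneSetCatalog:
    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def sets_for(self, gene: str) -> list[str]:
        g = gene.upper()
        return sorted(s for s, genes in self.sets.items() if g in genes)


def read_gene_sets(path: str) -> GeneSetCatalog:
    """Parse ``set_id<TAB>gene`` pairs; symbols uppercased, sets nonempty."""
    acc: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'set_id<TAB>gene'")
            acc.setdefault(cols[0], set()).add(cols[1].upper())
    return GeneSetCatalog({k: frozenset(v) for k, v in acc.items()})


def read_interactions(path: str) -> nx.Graph:
    """Parse an undirected simple edge list; self-loops dropped."""
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'geneA<TAB>geneB'")
            a, b = cols[0].upper(), cols[1].upper()
            if a != b:
                graph.add_edge(a, b)
    return graph


def _as_session(db) -> tuple[FrameworkSession, bool]:
    if isinstance(db, FrameworkSession):
        return db, False
    return open_session(db), True


def _qualifying_variants(session: FrameworkSession, sample: str, min_severity: str):
    """(variant_id, gene) pairs where the sample carries an alt allele at a
    site whose primary impact reaches min_severity."""
    rank = _SEVERITY_RANK.get(min_severity)
    if rank is None:
        raise ValueError(f"unknown severity {min_severity!r}")
    if sample not in session.sample_index:
        raise KeyError(f"unknown sample {sample!r}")
    si = session.sample_index[sample]
    out = []
    for row in session.variants("gene IS NOT NULL AND impact_severity IS NOT NULL"):
        if _SEVERITY_RANK.get(row.impact_severity, 0) < rank:
            continue
        if row.gt_types[si] in (HET, HOM_ALT):
            out.append((row.variant_id, row.gene.upper()))
    return out


def sample_pathways(
    db, sample: str, catalog: GeneSetCatalog, min_severity: str = "MED"
) -> list[tuple[int, str, str]]:
    """(variant_id, gene, set_id) rows: the sample's functional variants
    mapped onto every gene set containing their gene."""
    session, own = _as_session(db)
    try:
        rows = []
        for vid, gene in _qualifying_variants(session, sample, min_severity):
            for set_id in catalog.sets_for(gene):
                rows.append((vid, gene, set_id))
        return rows
    finally:
        if own:
            session.close()


def interactions(
    db, sample: str, graph: nx.Graph, k: int = 1, min_severity: str = "MED"
) -> list[tuple[str, int, str, tuple[int, ...]]]:
    """(seed_gene, order, neighbor_gene, neighbor_variant_ids) rows.

    For every gene where the sample carries a qualifying variant, lists the
    other such genes at shortest-path distance 1..k in the interaction
    network. Symmetric by construction: (g1, d, g2) implies (g2, d, g1).
    """
    if k < 1:
        raise ValueError("radius k must be >= 1")
    session, own = _as_session(db)
    try:
        quals = _qualifying_variants(session, sample, min_severity)
    finally:
        if own:
            session.close()
    variants_by_gene: dict[str, list[int]] = {}
    for vid, gene in quals:
        variants_by_gene.setdefault(gene, []).append(vid)
    hit_genes = set(variants_by_gene)
    rows = []
    for seed in sorted(hit_genes):
        if seed not in graph:
            continue
        distances = nx.single_source_shortest_path_length(graph, seed, cutoff=k)
        for neighbor, dist in sorted(distances.items()):
            if dist == 0 or neighbor not in hit_genes:
                continue
            rows.append(
                (seed, dist, neighbor, tuple(sorted(variants_by_gene[neighbor])))
            )
    return rows
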