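"""Ortholog families across multiple genomes.

Genes are vertices, syntenic homology relationships (block anchors and
completions, pooled over every pairwise comparison) are edges.  A family is
a connected component that contains exactly one gene from every input
genome; components with duplicated or missing genomes are discarded, which
restricts the output to unambiguous single-copy orthologs — the gene sets
typically wanted for phylogenetic reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .genome_io import Genome
from .homology import HomologyPair


@dataclass
class OrthologFamily:
    members: dict[str, str]  # genome id -> gene id
    supporting_edges: list[HomologyPair]


def build_families(pairwise_results: list[list[HomologyPair]],
                   genomes: list[Genome],
                   min_genomes: int | None = None) -> list[OrthologFamily]:
    """Single-copy ortholog families by transitive closure of syntenic edges.

    ``pairwise_results`` holds, for each genome pair compared, the homology
    pairs that ended up inside synteny blocks.  ``min_genomes`` relaxes the
    all-genomes requirement (components still must hold at most one gene
    per genome); by default a family must cover every input genome.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    by_id = {g.id: g for g in genomes}
    need = len(genomes) if min_genomes is None else min_genomes

    graph = nx.Graph()
    for g in genomes:
        for gene in g.genes():
            graph.add_node((g.id, gene.id))
    for pairs in pairwise_results:
        for p in pairs:
            for gene in (p.gene_a, p.gene_b):
                if gene.genome_id not in by_id or gene.id not in by_id[gene.genome_id]:
                    raise ValueError(
                        f"edge references unknown gene {gene.id!r} "
                        f"({gene.genome_id!r})")
            graph.add_edge((p.gene_a.genome_id, p.gene_a.id),
                           (p.gene_b.genome_id, p.gene_b.id), pair=p)

    families: list[OrthologFamily] = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        per_genome: dict[str, list[str]] = {}
        for genome_id, gene_id in comp:
            per_genome.setdefault(genome_id, []).append(gene_id)
        if any(len(v) > 1 for v in per_genome.values()):
            continue  # duplicated genes -> discarded
        if len(per_genome) < need:
            continue
        edges = [graph.edges[e]["pair"] for e in graph.subgraph(comp).edges]
        families.append(OrthologFamily(
            members={gid: genes[0] for gid, genes in sorted(per_genome.items())},
            supporting_edges=edges))
    families.sort(key=lambda f: sorted(f.members.items()))
    return families


def write_families(families: list[OrthologFamily], genome_ids: list[str],
                   path) -> Path:
    """One row per family, one column per genome ('.' where absent)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(genome_ids) + "\n")
        for fam in families:
            fh.write("\t".join(fam.members.get(g, ".") for g in genome_ids) + "\n")
    return path
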