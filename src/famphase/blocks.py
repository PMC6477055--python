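"""Haplotype blocks from the SNP-connectivity graph.

Two SNPs are connected when at least one fragment covers both; the haplotype
blocks of a region are the connected components of this graph.  Blocks are
built from the POOLED fragments of the whole population: parental phasing
uses every read, and offspring blocks inherit the parental partition.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .popdata import FragmentMatrix, SNPSite


def connectivity_graph(
    fragment_matrices: Iterable[FragmentMatrix], n_snps: int
) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(range(n_snps))
    for mat in fragment_matrices:
        for frag in mat.fragments:
            idx = frag.indices
            # consecutive edges suffice: co-coverage is transitive within a fragment
            graph.add_edges_from(zip(idx, idx[1:]))
    return graph


def find_blocks(
    fragment_matrices: Iterable[FragmentMatrix], n_snps: int
) -> list[list[int]]:
    """Partition SNP indices into haplotype blocks (connected components).

    Singleton SNPs covered by no multi-SNP fragment form singleton blocks.
    Blocks are ordered by their smallest SNP index and sorted internally.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    graph = connectivity_graph(fragment_matrices, n_snps)
    comps = [sorted(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: c[0])


def ngps(partition: Sequence[Sequence[int]], l: int) -> float:
    """Number of phasing gaps per SNP: (number of blocks - 1) / l."""
    if l < 1:
        raise ValueError("l must be >= 1")
    return (len(partition) - 1) / l


def partition_to_table(
    sites: Sequence[SNPSite], partition: Sequence[Sequence[int]]
) -> pd.DataFrame:
    """BED-like block table: chrom, start, end (0-based half-open), block id, n SNPs."""
    rows = []
    for bid, block in enumerate(partition):
        first, last = sites[block[0]], sites[block[-1]]
        rows.append(
            {
                "chrom": first.chrom,
                "start": first.pos - 1,
                "end": last.pos,
                "block_id": bid,
                "n_snps": len(block),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "block_id", "n_snps"])
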