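"""Fragment geometry on protein coordinates.

Maps genomic fragments onto 1-based inclusive amino-acid intervals, computes
inter-fragment similarity, collapses redundant (overlapping) fragments, and
computes Pfam-style domain coverage. These interval operations are the
substrate of the domain- and motif-level analyses: the screen names fragments
by their protein interval (e.g. ``Sbp1(28-197)``), considers fragments >= 90%
similar as one observation, and calls a domain represented when a fragment
covers at least 75% of it.

Coordinates are 1-based inclusive throughout, matching the fragment naming
convention; conversion to half-open happens only at BED export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import networkx as nx
import pandas as pd

from .errors import MappingError

logger = logging.getLogger(__name__)

__all__ = [
    "DomainAnnotation",
    "FragmentCluster",
    "map_fragment_to_protein",
    "fragment_similarity",
    "interval_similarity",
    "collapse_fragments",
    "domain_coverage",
]


@dataclass(frozen=True)
class DomainAnnotation:
    """One Pfam-style domain instance on a protein (1-based inclusive)."""

    protein_id: str
    family_id: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.aa_start <= self.aa_end:
            raise ValueError(
                f"invalid domain interval {self.aa_start}-{self.aa_end} "
                f"for {self.protein_id}/{self.family_id}"
            )


@dataclass
class FragmentCluster:
    """A group of mutually overlapping fragments and its representative."""

    members: list[str]
    representative: str
    similarity_threshold: float

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("cluster representative must be a member")


def map_fragment_to_protein(start: int, end: int, strand: str, gene) -> tuple[int, int]:
    """Map a genomic fragment to protein coordinates of ``gene``.

    The fragment is read in the vector phase: codon 1 begins at the
    fragment's first base in its tethering orientation. The fragment is
    in-frame with the gene's CDS when orientations match and the codon grids
    align; the returned interval covers the CDS codons fully contained in
    the fragment (edge codons rounded inward), clipped to the protein
    (the stop codon is never part of the protein interval).

    Parameters
    ----------
    start, end
        1-based inclusive genomic coordinates, ``end >= start``.
    strand
        Fragment orientation relative to the tethering vector, '+' or '-'.
    gene
        Object with ``strand``, ``cds_start``, ``cds_end`` and
        ``protein_seq`` attributes (see :class:`tetherscore.library.GeneModel`).

    Returns
    -------
    (aa_start, aa_end)
        1-based inclusive protein coordinates.

    Raises
    ------
    MappingError
        If the fragment is on the wrong strand, out of phase, or contains no
        complete codon of the protein.
    """
    if end < start:
        raise MappingError(f"invalid fragment interval {start}-{end}")
    if strand != gene.strand:
        raise MappingError("fragment orientation does not match the gene strand")
    n_codons = (end - start + 1) // 3
    if n_codons == 0:
        raise MappingError("fragment shorter than one codon")
    protein_len = len(gene.protein_seq)

    if strand == "+":
        if (start - gene.cds_start) % 3 != 0:
            raise MappingError("fragment is out of phase with the CDS")
        first = (start - gene.cds_start) // 3  # 0-based CDS codon of fragment codon 1
    else:
        if (gene.cds_end - end) % 3 != 0:
            raise MappingError("fragment is out of phase with the CDS")
        first = (gene.cds_end - end) // 3

    aa_start = max(0, first) + 1
    aa_end = min(protein_len - 1, first + n_codons - 1) + 1
    if aa_start > aa_end:
        raise MappingError("fragment contains no complete protein codon")
    return aa_start, aa_end


def interval_similarity(
    a: tuple[int, int], b: tuple[int, int], metric: str = "jaccard"
) -> float:
    """Similarity of two 1-based inclusive intervals on the same protein."""
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    la = a[1] - a[0] + 1
    lb = b[1] - b[0] + 1
    if metric == "containment":
        return inter / min(la, lb)
    return inter / (la + lb - inter)


def fragment_similarity(f1, f2, metric: str = "jaccard") -> float:
    """Overlap similarity of two protein-mapped fragments, in [0, 1].

    Fragments of different proteins have similarity 0. ``f1``/``f2`` are
    mappings (e.g. DataFrame rows) with ``gene_id``, ``aa_start``, ``aa_end``.
    """
    for f in (f1, f2):
        if f["gene_id"] is None or pd.isna(f["gene_id"]) or pd.isna(f["aa_start"]):
            raise MappingError("fragment is not mapped to a protein")
    if f1["gene_id"] != f2["gene_id"]:
        return 0.0
    return interval_similarity(
        (int(f1["aa_start"]), int(f1["aa_end"])),
        (int(f2["aa_start"]), int(f2["aa_end"])),
        metric=metric,
    )


def collapse_fragments(
    fragments: pd.DataFrame,
    threshold: float,
    metric: str = "jaccard",
    reads_col: str = "total_reads",
) -> list[FragmentCluster]:
    """Group fragments into overlap clusters and pick representatives.

    Clusters are the connected components of the graph whose edges join
    same-protein fragment pairs with similarity >= ``threshold``; the
    representative is the most highly sequenced member (``reads_col``),
    ties broken toward the lower ``aa_start`` (logged).

    ``fragments`` needs columns ``fragment_id``, ``gene_id``, ``aa_start``,
    ``aa_end`` and ``reads_col``.
    """
    g = nx.Graph()
    g.add_nodes_from(fragments["fragment_id"])
    for _, grp in fragments.groupby("gene_id", sort=False):
        ids = grp["fragment_id"].to_numpy()
        lo = grp["aa_start"].to_numpy(int)
        hi = grp["aa_end"].to_numpy(int)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                sim = interval_similarity((lo[i], hi[i]), (lo[j], hi[j]), metric)
                if sim >= threshold:
                    g.add_edge(ids[i], ids[j])

    by_id = fragments.set_index("fragment_id")
    clusters: list[FragmentCluster] = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        sub = by_id.loc[members]
        best = sub.sort_values(
            [reads_col, "aa_start"], ascending=[False, True], kind="mergesort"
        )
        top = best.iloc[0]
        n_tied = int((sub[reads_col] == top[reads_col]).sum())
        if len(members) > 1 and n_tied > 1:
            logger.info(
                "collapse tie: %d members of a cluster share max reads; "
                "keeping lowest aa_start (%s)", n_tied, best.index[0]
            )
        clusters.append(
            FragmentCluster(
                members=members,
                representative=str(best.index[0]),
                similarity_threshold=float(threshold),
            )
        )
    return clusters


def domain_coverage(
    fragment_interval: tuple[int, int], domain_interval: tuple[int, int]
) -> float:
    """Fraction of the domain covered by the fragment (same protein)."""
    inter = min(fragment_interval[1], domain_interval[1]) - max(
        fragment_interval[0], domain_interval[0]
    ) + 1
    if inter <= 0:
        return 0.0
    return inter / (domain_interval[1] - domain_interval[0] + 1)
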