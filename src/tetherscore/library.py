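"""Synthetic barcoded fragment library.

Emulates the construction of the tethering library: a compact, intron-free
genome with CDSs on both strands; random ~500 bp tagmentation fragments in
both orientations; selection of fragments that read through stop-free in the
vector phase (the in-frame selection that a downstream marker enforces);
random 25-nt barcodes, on average three per fragment; and ground-truth
regulatory activities attached to elements embedded in a subset of proteins,
so parameter recovery can be measured against a known answer.

Fragments are held in a DataFrame with the FragmentRecord schema
(``fragment_id, chrom, start, end, strand, gene_id, in_frame, aa_start,
aa_end, true_activity``); coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotation import map_fragment_to_protein
from .config import LibraryConfig
from .errors import (
    CoordinateError,
    GenerationError,
    InputError,
    MappingError,
    SizingError,
)
from .rng import substream

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "RegulatoryElement",
    "FRAGMENT_COLUMNS",
    "generate_genome",
    "fragment_genome",
    "select_in_frame",
    "assign_barcodes",
    "assign_true_activity",
    "build_library",
    "SyntheticLibrary",
    "domain_annotations_from_genes",
    "simulate_rbp_flags",
    "simulate_interaction_table",
]

FRAGMENT_COLUMNS = [
    "fragment_id", "chrom", "start", "end", "strand",
    "gene_id", "in_frame", "aa_start", "aa_end", "true_activity",
]

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
# codon value = 16*a + 4*b + c with A,C,G,T -> 0..3
_STOP_PLUS = np.array([48, 50, 56])   # TAA, TAG, TGA on the + strand
_STOP_MINUS = np.array([60, 28, 52])  # TTA, CTA, TCA (revcomp of stops)

_CODON_TABLE = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
    return _CODON_TABLE


@dataclass(frozen=True)
class RegulatoryElement:
    """A protein interval carrying a true regulatory effect (z units)."""

    aa_start: int
    aa_end: int
    true_effect: float
    family_id: str = ""


@dataclass
class GeneModel:
    """An intron-free protein-coding gene on the synthetic genome."""

    gene_id: str
    chrom: str
    strand: str
    cds_start: int  # 1-based inclusive, includes the stop codon
    cds_end: int
    protein_seq: str
    regulatory_elements: list[RegulatoryElement] = field(default_factory=list)

    def __post_init__(self) -> None:
        cds_len = self.cds_end - self.cds_start + 1
        if cds_len % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {cds_len} not divisible by 3")
        if len(self.protein_seq) != cds_len // 3 - 1:
            raise ValueError(f"{self.gene_id}: protein length inconsistent with CDS")
        for el in self.regulatory_elements:
            if not 1 <= el.aa_start <= el.aa_end <= len(self.protein_seq):
                raise ValueError(f"{self.gene_id}: element outside protein")


# ---------------------------------------------------------------------------
# genome generation


def _random_cds(rng: np.random.Generator, protein_len: int) -> tuple[str, str]:
    """Return (cds_nt, protein_aa): ATG + random sense codons + stop."""
    table = _codon_table()
    sense = sorted(table.keys())  # 61 sense codons
    idx = rng.integers(0, len(sense), size=protein_len - 1)
    body = [sense[i] for i in idx]
    stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    cds = "ATG" + "".join(body) + stop
    protein = "M" + "".join(table[c] for c in body)
    return cds, protein


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _element_probability(config: LibraryConfig) -> float:
    """Per-gene element probability targeting ``frac_null_fragments``.

    Approximates the chance that a uniformly placed in-frame fragment covers
    >= the coverage threshold of a single element, and inverts it; the
    realized null fraction tracks the target to within a few percent.
    """
    frag_aa = config.fragment_size_mean / 3.0
    need = np.ceil(config.element_coverage_threshold * config.element_length)
    span = max(1.0, frag_aa - need + (config.element_length - need) + 1)
    starts = max(1.0, config.protein_length_mean - frag_aa + 1)
    # 0.57: containment/length-spread correction — in-frame fragments are
    # biased short (they must sit wholly inside a CDS), so fewer reach the
    # coverage threshold than the mean-length geometry suggests
    p_hit = min(1.0, 0.57 * span / starts)
    target_active = 1.0 - config.frac_null_fragments
    return float(min(1.0, target_active / p_hit))


def generate_genome(config: LibraryConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate the synthetic genome and its gene models.

    Genes are placed non-overlapping on a single chromosome, alternating
    strands at random, separated by random intergenic spacers; a configurable
    subset of proteins carries one embedded regulatory element whose effect
    magnitude is drawn uniformly from ``effect_size_range`` with a random
    sign, and whose family label is drawn from a small recurring pool.
    Deterministic given ``config.rng_seed``.
    """
    rng = substream(config.rng_seed, "genome")
    lengths = rng.normal(config.protein_length_mean, config.protein_length_sd,
                         size=config.n_genes)
    lengths = np.maximum(config.protein_length_min, np.round(lengths)).astype(int)
    cds_lengths = 3 * (lengths + 1)
    min_gap = 20
    required = int(cds_lengths.sum() + min_gap * (config.n_genes + 1))
    if required > config.genome_length:
        raise SizingError(
            f"{config.n_genes} genes need >= {required} nt but genome_length is "
            f"{config.genome_length}"
        )

    # distribute the slack over the n_genes+1 spacers
    slack = config.genome_length - required
    cuts = np.sort(rng.integers(0, slack + 1, size=config.n_genes))
    extra = np.diff(np.concatenate(([0], cuts, [slack])))
    gaps = min_gap + extra  # n_genes + 1 spacers

    p_elem = 0.0 if config.frac_null_fragments >= 1.0 else _element_probability(config)
    lo, hi = config.effect_size_range

    chrom = "chr1"
    parts: list[str] = []
    genes: list[GeneModel] = []
    pos = 0  # 0-based cursor
    for i in range(config.n_genes):
        spacer = _NT[rng.integers(0, 4, gaps[i])].tobytes().decode()
        parts.append(spacer)
        pos += int(gaps[i])
        cds, protein = _random_cds(rng, int(lengths[i]))
        strand = "+" if rng.random() < 0.5 else "-"
        start = pos + 1  # 1-based
        end = pos + len(cds)
        parts.append(cds if strand == "+" else _revcomp(cds))
        pos = end

        elements: list[RegulatoryElement] = []
        if rng.random() < p_elem:
            elen = min(config.element_length, len(protein))
            estart = int(rng.integers(1, len(protein) - elen + 2))
            effect = float(rng.uniform(lo, hi)) * (1.0 if rng.random() < 0.5 else -1.0)
            fam = f"EF{int(rng.integers(1, config.n_element_families + 1)):02d}"
            elements.append(RegulatoryElement(estart, estart + elen - 1, effect, fam))
        genes.append(GeneModel(
            gene_id=f"GENE{i + 1:04d}", chrom=chrom, strand=strand,
            cds_start=start, cds_end=end, protein_seq=protein,
            regulatory_elements=elements,
        ))
    parts.append(_NT[rng.integers(0, 4, gaps[-1])].tobytes().decode())
    genome = {chrom: "".join(parts)}
    assert len(genome[chrom]) == config.genome_length
    n_with = sum(bool(g.regulatory_elements) for g in genes)
    logger.info("generated genome: %d nt, %d genes (%d with regulatory elements)",
                config.genome_length, config.n_genes, n_with)
    return genome, genes


# ---------------------------------------------------------------------------
# fragmentation


def fragment_genome(genome: dict[str, str], config: LibraryConfig) -> pd.DataFrame:
    """Draw random tagmentation-style fragments from the genome.

    Start positions are uniform, orientations equiprobable, lengths from a
    normal(mean, sd) truncated to >= 3 nt; fragments are clipped to fit the
    chromosome by redrawing the start. Returns a FragmentRecord DataFrame
    with ``in_frame`` False and protein fields unset.
    """
    if not genome:
        raise InputError("empty genome")
    chrom = next(iter(genome))
    glen = len(genome[chrom])
    rng = substream(config.rng_seed, "fragmentation")
    n = config.n_fragments
    lengths = rng.normal(config.fragment_size_mean, config.fragment_size_sd, size=n)
    while True:
        bad = lengths < 3
        if not bad.any():
            break
        lengths[bad] = rng.normal(config.fragment_size_mean, config.fragment_size_sd,
                                  size=int(bad.sum()))
    lengths = np.minimum(np.round(lengths).astype(int), glen)
    starts = (rng.random(n) * (glen - lengths + 1)).astype(int) + 1
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    df = pd.DataFrame({
        "fragment_id": [f"frag{i + 1:06d}" for i in range(n)],
        "chrom": chrom,
        "start": starts,
        "end": starts + lengths - 1,
        "strand": strands,
        "gene_id": pd.Series([None] * n, dtype=object),
        "in_frame": False,
        "aa_start": pd.Series([np.nan] * n, dtype=float),
        "aa_end": pd.Series([np.nan] * n, dtype=float),
        "true_activity": 0.0,
    })
    return df


# ---------------------------------------------------------------------------
# in-frame selection


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    lut[ord("A")] = 0
    lut[ord("C")] = 1
    lut[ord("G")] = 2
    lut[ord("T")] = 3
    return lut[arr]


def _stop_cumsums(code: np.ndarray, stop_values: np.ndarray) -> list[np.ndarray]:
    """Per-phase cumulative counts of stop-codon triplet start positions."""
    n = len(code)
    vals = 16 * code[: n - 2] + 4 * code[1: n - 1] + code[2:]
    is_stop = np.isin(vals, stop_values)
    mods = np.arange(n - 2) % 3
    return [np.cumsum(is_stop & (mods == m)) for m in range(3)]


def _range_count(cum: np.ndarray, lo: int, hi: int) -> int:
    """Stops with triplet start in [lo, hi] (0-based), using a cumsum."""
    if hi < lo or hi >= len(cum):
        hi = min(hi, len(cum) - 1)
        if hi < lo:
            return 0
    upper = cum[hi]
    lower = cum[lo - 1] if lo > 0 else 0
    return int(upper - lower)


def select_in_frame(
    fragments: pd.DataFrame,
    genome: dict[str, str],
    genes: list[GeneModel],
) -> pd.DataFrame:
    """Apply the in-frame selection and annotate protein coordinates.

    A fragment passes when (i) reading its vector-sense sequence in the
    fixed vector phase (codon 1 at the fragment's first base) hits no stop
    codon over all complete codons, and (ii) it aligns to a CDS in matching
    orientation and phase, in which case protein coordinates are assigned
    via :func:`tetherscore.annotation.map_fragment_to_protein`. Stop-free
    fragments without a CDS match (rare chance read-throughs) are excluded
    and tallied in ``df.attrs['n_stop_free_unmapped']``.
    """
    chrom = next(iter(genome))
    seq = genome[chrom]
    glen = len(seq)
    if ((fragments["start"] < 1) | (fragments["end"] > glen)).any():
        raise CoordinateError("fragment outside genome bounds")

    code = _encode(seq)
    cum_plus = _stop_cumsums(code, _STOP_PLUS)
    cum_minus = _stop_cumsums(code, _STOP_MINUS)

    starts = fragments["start"].to_numpy(int) - 1  # 0-based
    ends = fragments["end"].to_numpy(int) - 1
    n_codons = (ends - starts + 1) // 3
    is_plus = (fragments["strand"] == "+").to_numpy()

    stop_free = np.zeros(len(fragments), dtype=bool)
    # + orientation: codon starts at s, s+3, ...
    for m in range(3):
        sel = is_plus & (n_codons >= 1) & (starts % 3 == m)
        idx = np.nonzero(sel)[0]
        for i in idx:
            lo = starts[i]
            hi = starts[i] + 3 * (n_codons[i] - 1)
            stop_free[i] = _range_count(cum_plus[m], lo, hi) == 0
    # - orientation: reading-order codons have 0-based leftmost e-2, e-5, ...
    for m in range(3):
        sel = (~is_plus) & (n_codons >= 1) & ((ends - 2) % 3 == m)
        idx = np.nonzero(sel)[0]
        for i in idx:
            hi = ends[i] - 2
            lo = ends[i] - 2 - 3 * (n_codons[i] - 1)
            stop_free[i] = _range_count(cum_minus[m], lo, hi) == 0

    # CDS assignment for stop-free fragments
    order = sorted(range(len(genes)), key=lambda k: genes[k].cds_start)
    gene_starts = np.array([genes[k].cds_start for k in order])
    gene_ends = np.array([genes[k].cds_end for k in order])

    out = fragments.loc[stop_free].copy()
    gene_ids: list[Optional[str]] = []
    aa_lo: list[float] = []
    aa_hi: list[float] = []
    for row in out.itertuples(index=False):
        j = int(np.searchsorted(gene_starts, row.end, side="right"))
        best = None
        for k in range(max(0, j - 3), j):
            g = genes[order[k]]
            if gene_ends[k] < row.start:
                continue
            try:
                lo_hi = map_fragment_to_protein(row.start, row.end, row.strand, g)
            except MappingError:
                continue
            width = lo_hi[1] - lo_hi[0]
            if best is None or width > best[2]:
                best = (g.gene_id, lo_hi, width)
        if best is None:
            gene_ids.append(None)
            aa_lo.append(np.nan)
            aa_hi.append(np.nan)
        else:
            gene_ids.append(best[0])
            aa_lo.append(float(best[1][0]))
            aa_hi.append(float(best[1][1]))
    out["gene_id"] = gene_ids
    out["aa_start"] = aa_lo
    out["aa_end"] = aa_hi
    mapped = out["gene_id"].notna()
    n_unmapped = int((~mapped).sum())
    out = out.loc[mapped].copy()
    out["in_frame"] = True
    out.attrs["n_input"] = len(fragments)
    out.attrs["n_stop_free"] = int(stop_free.sum())
    out.attrs["n_stop_free_unmapped"] = n_unmapped
    logger.info("in-frame selection: %d/%d stop-free, %d mapped to a CDS "
                "(%d stop-free read-throughs discarded)",
                int(stop_free.sum()), len(fragments), len(out), n_unmapped)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# barcodes


def _zero_truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Sample a zero-truncated Poisson with the given (truncated) mean."""
    if mean <= 1.0:
        return np.ones(size, dtype=int)
    lam = brentq(lambda L: L / (1.0 - np.exp(-L)) - mean, 1e-9, mean)
    k = rng.poisson(lam, size=size)
    while True:
        zero = k == 0
        if not zero.any():
            return k
        k[zero] = rng.poisson(lam, size=int(zero.sum()))


def assign_barcodes(fragments: pd.DataFrame, config: LibraryConfig) -> pd.DataFrame:
    """Assign random 25-nt barcodes, zero-truncated-Poisson many per fragment.

    Returns the BarcodeMap DataFrame (``barcode``, ``fragment_id``); every
    barcode is distinct and every fragment receives at least one barcode.
    """
    if fragments.empty:
        raise InputError("no fragments to barcode")
    rng = substream(config.rng_seed, "barcodes")
    counts = _zero_truncated_poisson(rng, config.mean_barcodes_per_fragment,
                                     len(fragments))
    total = int(counts.sum())
    for _attempt in range(5):
        mat = rng.integers(0, 4, size=(total, 25), dtype=np.uint8)
        seqs = _NT[mat].view("S25").ravel().astype(str)
        if len(set(seqs)) == total:
            break
    else:
        raise GenerationError("barcode space collision persisted after retries")
    return pd.DataFrame({
        "barcode": seqs,
        "fragment_id": np.repeat(fragments["fragment_id"].to_numpy(), counts),
    })


# ---------------------------------------------------------------------------
# ground truth


def assign_true_activity(
    fragments: pd.DataFrame,
    genes: list[GeneModel],
    config: LibraryConfig,
) -> pd.DataFrame:
    """Set ``true_activity`` from regulatory-element coverage.

    A fragment inherits an element's effect when it covers at least
    ``element_coverage_threshold`` of the element (default 0.75, mirroring
    the domain-coverage convention of the analysis); otherwise 0. When a
    fragment qualifies for several elements the best-covered one wins.
    """
    out = fragments.copy()
    out["true_activity"] = 0.0
    thr = config.element_coverage_threshold
    by_gene = {g.gene_id: g for g in genes}
    for gene_id, idx in out.groupby("gene_id", sort=False).groups.items():
        gene = by_gene.get(gene_id)
        if gene is None or not gene.regulatory_elements:
            continue
        lo = out.loc[idx, "aa_start"].to_numpy(float)
        hi = out.loc[idx, "aa_end"].to_numpy(float)
        best_cov = np.zeros(len(idx))
        best_eff = np.zeros(len(idx))
        for el in gene.regulatory_elements:
            inter = np.minimum(hi, el.aa_end) - np.maximum(lo, el.aa_start) + 1
            cov = np.clip(inter, 0, None) / (el.aa_end - el.aa_start + 1)
            better = cov > best_cov
            best_eff = np.where(better, el.true_effect, best_eff)
            best_cov = np.maximum(best_cov, cov)
        out.loc[idx, "true_activity"] = np.where(best_cov >= thr, best_eff, 0.0)
    return out


# ---------------------------------------------------------------------------
# one-call library builder


@dataclass
class SyntheticLibrary:
    """A complete synthetic library: genome, genes, fragments, barcodes."""

    genome: dict[str, str]
    genes: list[GeneModel]
    fragments: pd.DataFrame       # all raw fragments
    in_frame: pd.DataFrame        # the in-frame, truth-annotated subset
    barcode_map: pd.DataFrame     # barcode -> fragment_id


def build_library(config: LibraryConfig) -> SyntheticLibrary:
    """Run the four generator stages end to end."""
    genome, genes = generate_genome(config)
    frags = fragment_genome(genome, config)
    in_frame = select_in_frame(frags, genome, genes)
    in_frame = assign_true_activity(in_frame, genes, config)
    barcodes = assign_barcodes(in_frame, config)
    return SyntheticLibrary(genome, genes, frags, in_frame, barcodes)


# ---------------------------------------------------------------------------
# synthetic annotation tables (domains / RBP flags / interactions)


def domain_annotations_from_genes(
    genes: list[GeneModel],
    seed: int = 0,
    decoy_fraction: float = 0.5,
    n_decoy_families: int = 6,
    decoy_length: int = 60,
) -> pd.DataFrame:
    """Domain table: regulatory elements plus inert decoy domains.

    Elements become domain instances labelled by their family; a random
    subset of genes additionally receives one decoy domain from a small
    family pool, so enrichment runs see represented-but-inactive families.
    """
    rng = substream(seed, "synthetic-domains")
    rows = []
    for g in genes:
        for el in g.regulatory_elements:
            rows.append((g.gene_id, el.family_id or "EF00", el.aa_start, el.aa_end))
        if rng.random() < decoy_fraction:
            plen = len(g.protein_seq)
            dlen = min(decoy_length, plen)
            s = int(rng.integers(1, plen - dlen + 2))
            fam = f"DECOY{int(rng.integers(1, n_decoy_families + 1)):02d}"
            rows.append((g.gene_id, fam, s, s + dlen - 1))
    return pd.DataFrame(rows, columns=["protein_id", "family_id", "aa_start", "aa_end"])


def simulate_rbp_flags(
    genes: list[GeneModel],
    seed: int = 0,
    p_flag_active: float = 0.6,
    p_flag_background: float = 0.08,
) -> pd.DataFrame:
    """Four boolean dataset memberships per gene, biased toward element genes.

    Mimics compiling RBPs from four RNA-protein interaction datasets: genes
    carrying regulatory elements are flagged more often, so the >=2-of-4 set
    is enriched for truly active proteins.
    """
    rng = substream(seed, "synthetic-rbp")
    rows = []
    for g in genes:
        p = p_flag_active if g.regulatory_elements else p_flag_background
        flags = rng.random(4) < p
        rows.append((g.gene_id, *flags.astype(bool)))
    return pd.DataFrame(rows, columns=["protein_id", "dataset1", "dataset2",
                                       "dataset3", "dataset4"])


def simulate_interaction_table(
    genes: list[GeneModel],
    seed: int = 0,
    n_hubs: int = 2,
    p_edge_active: float = 0.6,
    p_edge_background: float = 0.05,
    n_random_pairs: int = 100,
) -> pd.DataFrame:
    """Undirected physical-interaction pairs with planted activator hubs.

    ``n_hubs`` genes preferentially interact with element-bearing genes
    (probability ``p_edge_active`` vs ``p_edge_background``), on top of a
    uniform background of random pairs — enough structure for the
    over-representation test to find the hubs.
    """
    rng = substream(seed, "synthetic-ppi")
    ids = [g.gene_id for g in genes]
    active = {g.gene_id for g in genes if g.regulatory_elements}
    hubs = list(rng.choice(ids, size=min(n_hubs, len(ids)), replace=False))
    pairs = set()
    for hub in hubs:
        for g in ids:
            if g == hub:
                continue
            p = p_edge_active if g in active else p_edge_background
            if rng.random() < p:
                pairs.add(tuple(sorted((hub, g))))
    for _ in range(n_random_pairs):
        a, b = rng.choice(ids, size=2, replace=False)
        pairs.add(tuple(sorted((a, b))))
    df = pd.DataFrame(sorted(pairs), columns=["interactor_a", "interactor_b"])
    df["experimental_system_type"] = "physical"
    df.attrs["hubs"] = hubs
    return df
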