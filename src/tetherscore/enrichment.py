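"""Statistical analyses over scored fragments.

Implements the global analyses of the screen: the |score| > 1 active set;
Pfam-family enrichment (fragments covering >= 75% of a domain, collapsed at
90% similarity, Mann-Whitney U against the whole library, Benjamini-Hochberg
across families); BioGRID-style protein-interaction over-representation
(hypergeometric tail over activator/repressor fragments among a hub's
interactors, with fold enrichment); the >= 2-of-4 RBP set comparison; and
MEME/FIMO pre- and post-processing (input FASTA preparation with 50%
collapse, single-source and low-complexity motif filters, and a log-odds
PWM scanner for peptide motifs).

Rank and exact statistics are delegated to scipy/statsmodels; the test
suite checks them against enumeration oracles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import collapse_fragments, domain_coverage
from .config import EnrichmentConfig
from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "MotifMatrix",
    "select_active",
    "mann_whitney_u",
    "bh_adjust",
    "hypergeom_tail",
    "domain_enrichment",
    "ppi_enrichment",
    "build_rbp_set",
    "compare_rbp_activity",
    "prepare_motif_input",
    "filter_motif_results",
    "pwm_scan",
    "composition_entropy",
    "parse_meme_motifs",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MotifMatrix:
    """A peptide position weight matrix (columns sum to 1 per position)."""

    motif_id: str
    pwm: np.ndarray  # shape (L, 20), alphabet order AMINO_ACIDS
    source_proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != len(AMINO_ACIDS):
            raise InputError("PWM must be L x 20 over the amino-acid alphabet")
        if self.pwm.shape[0] < 3:
            raise InputError("motif length must be >= 3")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-4):
            raise InputError("PWM rows must sum to 1")

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.pwm.argmax(axis=1))


# ---------------------------------------------------------------------------
# core statistics


def select_active(scores: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Active fragments: score > +threshold (activators) or < -threshold
    (repressors); boundary values are excluded (strict inequality)."""
    s = scores["score"]
    out = scores.loc[s.abs() > threshold].copy()
    out["direction"] = np.where(out["score"] > 0, "activator", "repressor")
    return out


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (midrank ties).

    Exact enumeration when min(n, m) <= 8 and the data are tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    Returns ``(U, p)`` with U the statistic of ``x``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


# ---------------------------------------------------------------------------
# domain enrichment


def domain_enrichment(
    scores: pd.DataFrame,
    fragments: pd.DataFrame,
    domains: pd.DataFrame,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> pd.DataFrame:
    """Per-family activity enrichment among active fragments.

    Active fragments (|score| > threshold) are collapsed at 90% similarity,
    keeping the most highly sequenced representative per overlap group. A
    family is represented when a representative covers at least 75% of one
    of its domain instances on the same protein. For each represented
    family: the mean activity of its representing fragments, a two-sided
    Mann-Whitney U of those scores against the entire library's scores, and
    a BH-adjusted q across families; families with q < ``q_threshold`` are
    flagged ``significant``.

    ``fragments`` must carry ``fragment_id, gene_id, aa_start, aa_end``;
    ``domains`` must carry ``protein_id, family_id, aa_start, aa_end``.
    """
    merged = fragments.merge(scores.reset_index(), on="fragment_id", how="inner")
    active = select_active(merged, config.active_score_threshold)
    if active.empty:
        logger.info("domain enrichment: no active fragments")
        return _empty_domain_result()

    clusters = collapse_fragments(
        active, config.collapse_similarity_domains, metric=config.similarity_metric)
    reps = active.set_index("fragment_id").loc[[c.representative for c in clusters]]

    lib_scores = merged["score"].to_numpy(float)
    rows = []
    for family_id, dom_grp in domains.groupby("family_id", sort=True):
        rep_ids: list[str] = []
        for fid, frag in reps.iterrows():
            doms = dom_grp[dom_grp["protein_id"] == frag["gene_id"]]
            for d in doms.itertuples(index=False):
                cov = domain_coverage(
                    (int(frag["aa_start"]), int(frag["aa_end"])),
                    (int(d.aa_start), int(d.aa_end)))
                if cov >= config.domain_coverage_threshold:
                    rep_ids.append(fid)
                    break
        if not rep_ids:
            continue
        fam_scores = reps.loc[rep_ids, "score"].to_numpy(float)
        U, p = mann_whitney_u(fam_scores, lib_scores)
        rows.append((family_id, len(rep_ids), float(fam_scores.mean()), U, p))
    if not rows:
        logger.info("domain enrichment: no family represented at >= %.0f%% coverage",
                    100 * config.domain_coverage_threshold)
        return _empty_domain_result()
    out = pd.DataFrame(rows, columns=["family_id", "n_fragments", "mean_activity",
                                      "U", "p"])
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < config.q_threshold
    return out.sort_values("q", kind="mergesort").reset_index(drop=True)


def _empty_domain_result() -> pd.DataFrame:
    return pd.DataFrame(columns=["family_id", "n_fragments", "mean_activity",
                                 "U", "p", "q", "significant"])


# ---------------------------------------------------------------------------
# protein-protein interaction over-representation


def ppi_enrichment(
    scores: pd.DataFrame,
    fragments: pd.DataFrame,
    interactions: pd.DataFrame,
    direction: str = "activator",
    config: EnrichmentConfig = EnrichmentConfig(),
) -> pd.DataFrame:
    """Hubs over-represented for active fragments among their interactors.

    The universe is every scored, gene-mapped fragment (or gene, with
    ``ppi_granularity='gene'``). For each hub protein, its interactor
    fragments are those from genes listed as physical partners; the overlap
    with the activator (or repressor) set is tested with the upper
    hypergeometric tail, fold enrichment is the active fraction among
    interactor fragments over the library-wide active fraction, and BH runs
    across hubs. Hubs without interactor fragments are skipped (logged).
    """
    if direction not in ("activator", "repressor"):
        raise InputError("direction must be 'activator' or 'repressor'")
    merged = fragments.merge(scores.reset_index(), on="fragment_id", how="inner")
    merged = merged[merged["gene_id"].notna()]
    active = select_active(merged, config.active_score_threshold)
    active = active[active["direction"] == direction]

    if config.ppi_granularity == "gene":
        universe = merged.drop_duplicates("gene_id")
        active_units = set(active["gene_id"].unique())
        unit_gene = universe["gene_id"]
        unit_ids = universe["gene_id"]
    else:
        universe = merged
        active_units = set(active["fragment_id"])
        unit_gene = universe["gene_id"]
        unit_ids = universe["fragment_id"]

    N = len(universe)
    K = len(active_units)
    partners: dict[str, set[str]] = {}
    for a, b in interactions[["interactor_a", "interactor_b"]].itertuples(index=False):
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    background_rate = K / N if N else 0.0
    rows = []
    for hub, inters in sorted(partners.items()):
        mask = unit_gene.isin(inters).to_numpy()
        n = int(mask.sum())
        if n == 0:
            logger.debug("hub %s has no interactor fragments; skipped", hub)
            continue
        ids = unit_ids[mask]
        k = int(ids.isin(active_units).sum())
        p = hypergeom_tail(k, N, K, n)
        fold = (k / n) / background_rate if background_rate > 0 else np.nan
        rows.append((hub, n, k, fold, p))
    out = pd.DataFrame(rows, columns=["hub_protein_id", "n_interactor_fragments",
                                      "n_active_among", "fold_enrichment", "p"])
    if not out.empty:
        out["q"] = bh_adjust(out["p"])
        out["significant"] = out["q"] < config.q_threshold
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    out.attrs["direction"] = direction
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# RBP set


def build_rbp_set(membership: pd.DataFrame, min_datasets: int = 2) -> set[str]:
    """Proteins present in >= ``min_datasets`` of the four source datasets.

    ``membership``: ``protein_id`` plus four boolean dataset columns.
    """
    flag_cols = [c for c in membership.columns if c != "protein_id"]
    if len(flag_cols) != 4:
        raise InputError("membership table must have exactly 4 dataset columns")
    counts = membership[flag_cols].astype(bool).sum(axis=1)
    return set(membership.loc[counts >= min_datasets, "protein_id"])


def compare_rbp_activity(
    scores: pd.DataFrame,
    fragments: pd.DataFrame,
    rbp_set: set[str],
) -> dict:
    """Mann-Whitney comparison of |score| for RBP vs non-RBP fragments."""
    merged = fragments.merge(scores.reset_index(), on="fragment_id", how="inner")
    merged = merged[merged["gene_id"].notna()]
    is_rbp = merged["gene_id"].isin(rbp_set)
    a = merged.loc[is_rbp, "score"].abs().to_numpy()
    b = merged.loc[~is_rbp, "score"].abs().to_numpy()
    if a.size == 0 or b.size == 0:
        raise InputError("one of the RBP / non-RBP groups is empty")
    U, p = mann_whitney_u(a, b)
    return {
        "U": U,
        "p": p,
        "n_rbp_fragments": int(a.size),
        "n_other_fragments": int(b.size),
        "median_abs_score_rbp": float(np.median(a)),
        "median_abs_score_other": float(np.median(b)),
    }


# ---------------------------------------------------------------------------
# motif pre/post-processing


def prepare_motif_input(
    scores: pd.DataFrame,
    fragments: pd.DataFrame,
    proteome: Mapping[str, str],
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[tuple[str, str]]:
    """Peptides for motif discovery: active fragments collapsed at 50%.

    Returns ``(header, peptide)`` records, header styled
    ``<gene>(<aa_start>-<aa_end>)``; use :func:`tetherscore.io.write_fasta`
    to serialize. Raises on an empty active set.
    """
    merged = fragments.merge(scores.reset_index(), on="fragment_id", how="inner")
    active = select_active(merged, config.active_score_threshold)
    if active.empty:
        raise InputError("no active fragments for motif input")
    clusters = collapse_fragments(
        active, config.collapse_similarity_motifs, metric=config.similarity_metric)
    reps = active.set_index("fragment_id").loc[[c.representative for c in clusters]]
    records = []
    for fid, row in reps.sort_index().iterrows():
        gene = row["gene_id"]
        lo, hi = int(row["aa_start"]), int(row["aa_end"])
        peptide = proteome[gene][lo - 1: hi]
        records.append((f"{gene}({lo}-{hi})", peptide))
    return records


def composition_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the residue composition of ``seq``."""
    if not seq:
        return 0.0
    _, counts = np.unique(list(seq), return_counts=True)
    f = counts / counts.sum()
    return float(-(f * np.log2(f)).sum())


def filter_motif_results(
    motifs: Sequence[MotifMatrix],
    alignments: Optional[pd.DataFrame] = None,
    entropy_threshold_bits: float = 1.5,
) -> tuple[list[MotifMatrix], Optional[pd.DataFrame]]:
    """Post-filter discovered motifs and their proteome alignments.

    Drops motifs supported by fewer than two distinct source proteins (no
    consensus from a single peptide) and motifs whose consensus is
    low-complexity (composition entropy below the threshold, default 1.5
    bits — the operational reading of 'highly repetitive'). Alignments
    (columns ``motif_id, protein_id, start, matched_seq``) in low-complexity
    target windows are dropped by the same criterion. Removals are logged.
    """
    kept: list[MotifMatrix] = []
    for m in motifs:
        n_src = len(set(m.source_proteins))
        if n_src < 2:
            logger.info("motif %s removed: single source protein", m.motif_id)
            continue
        ent = composition_entropy(m.consensus)
        if ent < entropy_threshold_bits:
            logger.info("motif %s removed: low-complexity consensus (%.2f bits)",
                        m.motif_id, ent)
            continue
        kept.append(m)
    kept_ids = {m.motif_id for m in kept}
    out_aln = None
    if alignments is not None:
        ok = alignments["motif_id"].isin(kept_ids)
        ent_ok = alignments["matched_seq"].map(
            lambda s: composition_entropy(str(s)) >= entropy_threshold_bits)
        n_drop = int((~(ok & ent_ok)).sum())
        if n_drop:
            logger.info("%d alignments removed (filtered motif or repetitive target)",
                        n_drop)
        out_aln = alignments.loc[ok & ent_ok].reset_index(drop=True)
    return kept, out_aln


def pwm_scan(
    sequence: str,
    motif: MotifMatrix,
    background: Optional[Sequence[float]] = None,
    threshold: float = 0.0,
) -> list[tuple[int, float]]:
    """Scan a protein sequence with a PWM (log2-odds, FIMO-style).

    Returns ``(start, score)`` hits with 1-based starts where the window
    score ``sum_i log2(pwm[i, aa_i] / bg[aa_i])`` reaches ``threshold``.
    Peptides have no reverse strand; only the forward reading is scanned.
    """
    if background is None:
        bg = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    else:
        bg = np.asarray(background, float)
        if bg.shape != (len(AMINO_ACIDS),) or (bg <= 0).any() or not math.isclose(
                bg.sum(), 1.0, abs_tol=1e-6):
            raise InputError("background must be 20 positive frequencies summing to 1")
    L = motif.pwm.shape[0]
    idx_of = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    enc = np.array([idx_of.get(c, -1) for c in sequence])
    if len(enc) < L:
        return []
    with np.errstate(divide="ignore"):
        logodds = np.log2(motif.pwm) - np.log2(bg)[None, :]
    hits = []
    for s in range(len(enc) - L + 1):
        window = enc[s: s + L]
        if (window < 0).any():
            continue
        score = float(logodds[np.arange(L), window].sum())
        if score >= threshold:
            hits.append((s + 1, score))
    return hits


def parse_meme_motifs(text: str) -> list[MotifMatrix]:
    """Minimal MEME-format parser: letter-probability matrix blocks only.

    Understands the ``ALPHABET``, ``MOTIF`` and ``letter-probability
    matrix`` records of MEME's text output for protein alphabets.
    """
    lines = text.splitlines()
    alphabet = AMINO_ACIDS
    motifs: list[MotifMatrix] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip()
            if alpha:
                alphabet = alpha
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                    "letter-probability matrix"):
                j += 1
            if j >= len(lines):
                break
            rows = []
            j += 1
            while j < len(lines):
                parts = lines[j].split()
                if len(parts) != len(alphabet):
                    break
                rows.append([float(v) for v in parts])
                j += 1
            mat = np.array(rows)
            if alphabet != AMINO_ACIDS:
                # reorder columns into canonical alphabet order
                order = [alphabet.index(a) for a in AMINO_ACIDS]
                mat = mat[:, order]
            motifs.append(MotifMatrix(motif_id=motif_id, pwm=mat))
            i = j
            continue
        i += 1
    return motifs
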