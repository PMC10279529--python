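"""Per-fragment activity scores from binned barcode counts.

The central statistic of the screen: for each fragment, a maximum-likelihood
estimate of its mean fluorescence (log YFP/RFP ratio, population-z units)
under a Gaussian-within-gates read model, expressed as a z-score relative to
the overall population.

Model. A fragment with mean mu sends a cell into gate b with probability
``q_b(mu) = Phi((c_b - mu)/sigma_w) - Phi((c_{b-1} - mu)/sigma_w)`` where
c_1 < c_2 < c_3 are the gate cuts (c_0 = -inf, c_4 = +inf). Reads in gate b
are proportional to cell counts times a per-gate sequencing depth d_b, so
counts are first depth-normalized (n_b / d_b, depths scaled to mean 1) and
the estimator maximizes ``sum_b (n_b/d_b + alpha) log q_b(mu)`` over a
bounded interval. This reduces to the plain multinomial MLE for equal
depths and is exactly invariant under scaling one gate's counts and depth
together. The likelihood is unimodal in mu; a pseudocount alpha regularizes
all-in-one-gate fragments so saturating fragments pin at the bound.

Filters follow the screen's standard analysis: barcodes lacking >= 32 reads in some
gate are dropped before aggregation; replicate correlation is restricted to
fragments with >= 1,000 total reads in both replicates.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

from .config import EstimatorConfig, GateBoundaries
from .errors import (
    ConfigError,
    DegeneratePopulationError,
    EstimationError,
    FormatError,
    InsufficientOverlapError,
    InputError,
)
from .screen import BIN_COLUMNS, FLANK_5P

logger = logging.getLogger(__name__)

__all__ = [
    "count_barcodes_from_fastq",
    "filter_barcodes",
    "aggregate_to_fragments",
    "bin_probabilities",
    "estimate_mu",
    "score_fragments",
    "standardize_scores",
    "replicate_correlation",
    "choose_reference_replicate",
]


# ---------------------------------------------------------------------------
# counting


def count_barcodes_from_fastq(
    fastq_paths: Sequence, barcode_map: pd.DataFrame, flank_5p: str = FLANK_5P
) -> pd.DataFrame:
    """Exact-match barcode counting from per-gate FASTQ files.

    The 25-nt barcode is extracted immediately after the 5' flank; reads
    with no flank or an unknown barcode are tallied as unmatched (stored in
    ``df.attrs``). Raises :class:`FormatError` when more than half of all
    reads lack the flank.
    """
    if len(fastq_paths) != 4:
        raise InputError("expected one FASTQ per gate (4 files)")
    known = set(barcode_map["barcode"])
    index = pd.Index(barcode_map["barcode"].drop_duplicates(), name="barcode")
    counts = pd.DataFrame(0, index=index, columns=BIN_COLUMNS, dtype=np.int64)
    n_reads = n_noflank = n_unknown = 0
    for col, path in zip(BIN_COLUMNS, fastq_paths):
        tally: dict[str, int] = {}
        for rec in SeqIO.parse(str(path), "fastq"):
            n_reads += 1
            seq = str(rec.seq)
            i = seq.find(flank_5p)
            if i < 0:
                n_noflank += 1
                continue
            bc = seq[i + len(flank_5p): i + len(flank_5p) + 25]
            if bc in known:
                tally[bc] = tally.get(bc, 0) + 1
            else:
                n_unknown += 1
        if tally:
            s = pd.Series(tally)
            counts.loc[s.index, col] = s.astype(np.int64)
    if n_reads and n_noflank > 0.5 * n_reads:
        raise FormatError(
            f"no recognizable flank in {n_noflank}/{n_reads} reads")
    counts.attrs["n_reads"] = n_reads
    counts.attrs["n_no_flank"] = n_noflank
    counts.attrs["n_unknown_barcode"] = n_unknown
    if n_noflank or n_unknown:
        logger.info("barcode counting: %d reads, %d without flank, %d unmatched",
                    n_reads, n_noflank, n_unknown)
    return counts


# ---------------------------------------------------------------------------
# filtering and aggregation


def filter_barcodes(table: pd.DataFrame, config: EstimatorConfig) -> pd.DataFrame:
    """Drop under-sequenced barcodes.

    Default reading of the gate-count rule: a barcode is retained iff its
    count reaches ``min_gate_count`` (32) in at least one gate; set
    ``gate_filter_mode='every_gate'`` for the stricter alternative reading.
    """
    if config.gate_filter_mode == "any_gate":
        keep = table[BIN_COLUMNS].max(axis=1) >= config.min_gate_count
    else:
        keep = table[BIN_COLUMNS].min(axis=1) >= config.min_gate_count
    out = table.loc[keep].copy()
    out.attrs.update(table.attrs)
    out.attrs["n_barcodes_removed"] = int((~keep).sum())
    logger.info("barcode filter (%s >= %d): kept %d of %d barcodes",
                config.gate_filter_mode, config.min_gate_count,
                int(keep.sum()), len(table))
    return out


def aggregate_to_fragments(
    table: pd.DataFrame, barcode_map: pd.DataFrame
) -> pd.DataFrame:
    """Sum surviving barcodes to fragment x gate counts.

    Barcodes absent from the map are excluded and listed in
    ``df.attrs['orphan_barcodes']``. Adds an ``n_barcodes`` column.
    """
    mapping = barcode_map.set_index("barcode")["fragment_id"]
    fragment = mapping.reindex(table.index)
    orphans = table.index[fragment.isna()].tolist()
    if orphans:
        logger.warning("%d barcodes missing from the map; excluded", len(orphans))
    ok = table.loc[fragment.notna(), BIN_COLUMNS].copy()
    ok["fragment_id"] = fragment.dropna()
    agg = ok.groupby("fragment_id", sort=True)[BIN_COLUMNS].sum()
    agg["n_barcodes"] = ok.groupby("fragment_id", sort=True).size()
    agg.attrs["orphan_barcodes"] = orphans
    return agg


# ---------------------------------------------------------------------------
# the estimator


def _gate_probs(mu: float, cuts: np.ndarray, sigma_w: float) -> np.ndarray:
    cdf = ndtr((cuts - mu) / sigma_w)
    return np.diff(np.concatenate(([0.0], cdf, [1.0])))


def bin_probabilities(
    mu: float,
    config: EstimatorConfig,
    depth_factors: Sequence[float] | None = None,
) -> np.ndarray:
    """Read-generating gate probabilities for a fragment with mean ``mu``.

    ``p~_b = d_b q_b(mu) / sum_c d_c q_c(mu)``; sums to 1. With equal depths
    this is the cell-level gate occupancy ``q_b``.
    """
    if config.sigma_w <= 0:
        raise ConfigError("sigma_w must be positive")
    cuts = (config.boundaries or GateBoundaries.theoretical()).as_array()
    q = _gate_probs(mu, cuts, config.sigma_w)
    d = np.ones(4) if depth_factors is None else np.asarray(depth_factors, float)
    p = d * q
    return p / p.sum()


def _normalized_depths(
    counts: pd.DataFrame | np.ndarray, config: EstimatorConfig
) -> np.ndarray:
    if config.depth_factors is not None:
        d = np.asarray(config.depth_factors, float)
    else:
        arr = np.asarray(counts, float)
        totals = arr.sum(axis=0) if arr.ndim == 2 else arr
        d = np.where(totals > 0, totals, 1.0)
    return d / d.mean()


def estimate_mu(
    counts: Sequence[float],
    config: EstimatorConfig,
    depth_factors: Sequence[float] | None = None,
) -> float:
    """Bounded ML estimate of a fragment's mean fluorescence (z units).

    Maximizes ``sum_b (n_b/d_b + alpha) log q_b(mu)`` over
    ``config.mu_bounds`` by bounded 1-D optimization, comparing the interior
    optimum against both bounds (the likelihood is monotone beyond the
    extreme cuts, so saturating fragments land exactly on a bound).

    Depth factors are used exactly as passed — the pseudocount alpha is "one
    read per gate at unit depth", so multiplying one gate's counts and its
    depth factor by the same constant leaves the estimate unchanged exactly.
    Depths estimated from gate totals are normalized to mean 1 once, at the
    table level (see :func:`score_fragments`).
    """
    n = np.asarray(counts, dtype=float)
    if n.shape != (4,) or (n < 0).any():
        raise InputError(f"expected 4 non-negative gate counts, got {counts!r}")
    if depth_factors is None:
        d = np.ones(4) if config.depth_factors is None else np.asarray(
            config.depth_factors, float)
    else:
        d = np.asarray(depth_factors, float)
    w = n / d + config.pseudocount
    if w.sum() <= 0:
        raise EstimationError("all-zero counts with zero pseudocount")
    cuts = (config.boundaries or GateBoundaries.theoretical()).as_array()
    sig = config.sigma_w
    lo, hi = config.mu_bounds

    def nll(mu: float) -> float:
        q = np.clip(_gate_probs(mu, cuts, sig), 1e-300, None)
        return -float(w @ np.log(q))

    res = minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    best_mu, best_val = float(res.x), float(res.fun)
    for edge in (lo, hi):
        v = nll(edge)
        if v < best_val:
            best_mu, best_val = float(edge), v
    return best_mu


def score_fragments(
    table: pd.DataFrame,
    barcode_map: pd.DataFrame,
    config: EstimatorConfig,
    boundaries: GateBoundaries | Sequence[float] | None = None,
    replicate_id: str = "rep1",
) -> pd.DataFrame:
    """Full scoring path for one replicate's barcode count table.

    filter barcodes -> aggregate to fragments -> estimate mu per fragment ->
    standardize to activity scores. Returns the ActivityScore table
    (``fragment_id`` index; ``mu_hat``, ``score``, ``total_reads``,
    ``n_barcodes``, ``replicate_id``) with filter tallies in ``attrs``.
    """
    import dataclasses

    if boundaries is not None and not isinstance(boundaries, GateBoundaries):
        boundaries = GateBoundaries(tuple(boundaries))
    if boundaries is not None:
        config = dataclasses.replace(config, boundaries=boundaries)

    filtered = filter_barcodes(table, config)
    frag = aggregate_to_fragments(filtered, barcode_map)
    counts = frag[BIN_COLUMNS].to_numpy(float)
    d = _normalized_depths(counts, config)
    mu_hat = np.array([
        estimate_mu(counts[i], config, depth_factors=d)
        for i in range(len(frag))
    ])
    out = pd.DataFrame({
        "mu_hat": mu_hat,
        "total_reads": counts.sum(axis=1).astype(np.int64),
        "n_barcodes": frag["n_barcodes"].to_numpy(int),
    }, index=frag.index)
    out = standardize_scores(out)
    out["replicate_id"] = replicate_id
    out.attrs["n_barcodes_removed"] = filtered.attrs.get("n_barcodes_removed")
    out.attrs["depth_factors"] = d.tolist()
    return out


def standardize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Standardize raw mu estimates into activity scores.

    ``score = (mu_hat - m) / s`` with m, s the read-weighted mean and
    (population) standard deviation of mu_hat over all passing fragments —
    the read weighting approximates standardizing against the sorted cell
    population. The calibration constants are stored in ``attrs``.
    """
    if len(scores) < 2:
        raise EstimationError("need >= 2 fragments to standardize")
    mu = scores["mu_hat"].to_numpy(float)
    w = scores["total_reads"].to_numpy(float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    m = float(np.average(mu, weights=w))
    s = float(np.sqrt(np.average((mu - m) ** 2, weights=w)))
    if s == 0:
        raise DegeneratePopulationError("zero-variance score population")
    out = scores.copy()
    out["score"] = (mu - m) / s
    out.attrs.update(scores.attrs)
    out.attrs["standardization_mean"] = m
    out.attrs["standardization_sd"] = s
    return out


# ---------------------------------------------------------------------------
# replicate logic


def replicate_correlation(
    scores_rep1: pd.DataFrame,
    scores_rep2: pd.DataFrame,
    config: EstimatorConfig,
) -> tuple[float, int]:
    """Pearson r of activity scores between replicates.

    Restricted to fragments with >= ``min_total_reads_replicate_corr``
    (default 1,000) total reads in *both* replicates.
    """
    joined = scores_rep1.join(scores_rep2, how="inner", lsuffix="_1", rsuffix="_2")
    thr = config.min_total_reads_replicate_corr
    ok = (joined["total_reads_1"] >= thr) & (joined["total_reads_2"] >= thr)
    sub = joined.loc[ok]
    if len(sub) < 3:
        raise InsufficientOverlapError(
            f"only {len(sub)} fragments pass the {thr}-read threshold in both replicates")
    r = float(np.corrcoef(sub["score_1"], sub["score_2"])[0, 1])
    return r, int(len(sub))


def choose_reference_replicate(
    scores_rep1: pd.DataFrame, scores_rep2: pd.DataFrame
) -> str:
    """Pick the replicate with broader dynamic range (larger sd of mu_hat)."""
    sd1 = float(np.std(scores_rep1["mu_hat"]))
    sd2 = float(np.std(scores_rep2["mu_hat"]))
    if sd1 == sd2:
        logger.info("replicate dynamic ranges tie (sd=%.4g); choosing rep1", sd1)
        return str(scores_rep1["replicate_id"].iloc[0])
    if sd1 > sd2:
        return str(scores_rep1["replicate_id"].iloc[0])
    return str(scores_rep2["replicate_id"].iloc[0])
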