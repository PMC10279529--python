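"""Pooled sort-seq screen simulator.

Models the measurement arc of the screen: each cell carries one barcoded
tethering construct and emits a log YFP/RFP fluorescence z-value distributed
Normal(true activity of its fragment, sigma_w^2); FACS splits the pooled
population into four equal-occupancy gates at the empirical quartiles of the
realized ratio distribution; barcodes in each gate are amplified and
sequenced, giving a barcode x gate count table per replicate. Replicate 2
applies a linear rescaling gamma to true activities before cell simulation,
reproducing the compression/saturation of extremes observed between the two
replicate screens. Reads can optionally be emitted as raw FASTQ to exercise
the counting path.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScreenConfig
from .errors import FormatError, InputError
from .rng import substream

logger = logging.getLogger(__name__)

__all__ = [
    "BIN_COLUMNS",
    "ReplicateScreen",
    "sample_barcode_abundance",
    "simulate_cell_population",
    "sample_reads",
    "simulate_replicates",
    "emit_fastq",
    "FLANK_5P",
    "FLANK_3P",
]

#: bin columns in ascending fluorescence-ratio order
BIN_COLUMNS = ["bin1", "bin2", "bin3", "bin4"]

#: fixed adapter flanks around the 25-nt barcode in emitted reads
FLANK_5P = "ACGACTCACTATAGCACG"
FLANK_3P = "GATCCTGTAGCCCTAGAC"


@dataclass
class ReplicateScreen:
    """One replicate's sorted-and-sequenced output."""

    replicate_id: str
    counts: pd.DataFrame          # barcode x bin read counts
    boundaries: tuple[float, float, float]  # realized gate cuts (z units)
    occupancy: pd.DataFrame       # barcode x bin cell counts


def sample_barcode_abundance(
    n_barcodes: int, concentration: float, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet barcode abundances (library representation skew)."""
    w = rng.gamma(concentration, 1.0, size=n_barcodes)
    total = w.sum()
    if total == 0:
        return np.full(n_barcodes, 1.0 / n_barcodes)
    return w / total


def simulate_cell_population(
    barcode_mu: np.ndarray,
    config: ScreenConfig,
    rng: np.random.Generator,
    abundance: np.ndarray | None = None,
    boundaries: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sort a simulated cell population and return per-barcode gate counts.

    Cells are allotted to barcodes by a Dirichlet-multinomial abundance
    model; each cell's fluorescence z-value is Normal(mu of its barcode's
    fragment, sigma_w^2); the gate boundaries are the empirical quartiles of
    the realized pooled population, so the four gates receive equal cell
    numbers by construction (within interpolation rounding of +/-1). Fixed
    cuts may be supplied instead (``boundaries``) for analytic work.

    Returns
    -------
    occupancy : (n_barcodes, 4) int array of cell counts per gate
    boundaries : (3,) gate cuts used, in z units
    """
    k = len(barcode_mu)
    if k == 0:
        raise InputError("empty barcode map")
    if abundance is None:
        abundance = sample_barcode_abundance(
            k, config.barcode_abundance_dispersion, rng)
    total_cells = config.n_cells_per_gate * config.n_gates
    cells = rng.multinomial(total_cells, abundance)
    z = np.repeat(barcode_mu, cells)
    z = z + config.within_fragment_sd * rng.standard_normal(total_cells)
    if boundaries is None:
        boundaries = np.quantile(z, [0.25, 0.5, 0.75])
    else:
        boundaries = np.asarray(boundaries, dtype=float)
    gate = np.searchsorted(boundaries, z, side="left")
    owner = np.repeat(np.arange(k), cells)
    occ = np.bincount(owner * 4 + gate, minlength=4 * k).reshape(k, 4)
    return occ, boundaries


def sample_reads(
    occupancy: np.ndarray,
    config: ScreenConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sequence each gate: multinomial reads proportional to cell counts.

    Gate ``b`` receives ``reads_total * d_b / sum(d)`` reads; a gate with no
    cells but nonzero depth yields zero counts (logged).
    """
    if (occupancy < 0).any():
        raise InputError("negative occupancy")
    d = np.asarray(config.per_gate_depth_factors, dtype=float)
    per_gate = np.round(config.reads_total * d / d.sum()).astype(int)
    out = np.zeros_like(occupancy, dtype=np.int64)
    for b in range(occupancy.shape[1]):
        col = occupancy[:, b].astype(float)
        tot = col.sum()
        if tot == 0:
            if per_gate[b] > 0:
                logger.warning("gate %d has zero occupancy; emitting zero counts", b + 1)
            continue
        out[:, b] = rng.multinomial(per_gate[b], col / tot)
    return out


def simulate_replicates(
    barcode_map: pd.DataFrame,
    fragment_truth: pd.DataFrame,
    config: ScreenConfig,
) -> list[ReplicateScreen]:
    """Run the two replicate screens of one library.

    The barcode abundance vector is drawn once (both replicates come from
    the same transformation pool); cell allotment, sorting and sequencing
    are independent per replicate. Replicate 2 scales every true activity by
    ``config.replicate_scale`` before cell simulation.
    """
    if barcode_map.empty:
        raise InputError("empty barcode map")
    truth = fragment_truth.set_index("fragment_id")["true_activity"]
    mu = truth.reindex(barcode_map["fragment_id"]).to_numpy(float)
    if np.isnan(mu).any():
        raise InputError("barcode map references fragments without a true activity")

    abundance = sample_barcode_abundance(
        len(barcode_map), config.barcode_abundance_dispersion,
        substream(config.rng_seed, "abundance"))

    reps = []
    for rep, scale in (("rep1", 1.0), ("rep2", config.replicate_scale)):
        occ, cuts = simulate_cell_population(
            mu * scale, config, substream(config.rng_seed, f"cells-{rep}"),
            abundance=abundance)
        counts = sample_reads(occ, config, substream(config.rng_seed, f"reads-{rep}"))
        index = pd.Index(barcode_map["barcode"], name="barcode")
        counts_df = pd.DataFrame(counts, index=index, columns=BIN_COLUMNS)
        counts_df.attrs["replicate_id"] = rep
        occ_df = pd.DataFrame(occ, index=index, columns=BIN_COLUMNS)
        reps.append(ReplicateScreen(rep, counts_df, tuple(float(c) for c in cuts), occ_df))
        logger.info("%s: sorted %d cells, sequenced %d reads",
                    rep, int(occ.sum()), int(counts.sum()))
    return reps


def emit_fastq(
    counts: pd.DataFrame,
    outdir,
    prefix: str = "screen",
    compress: bool = False,
    quality_char: str = "I",
) -> list[Path]:
    """Write one FASTQ per gate; each barcode appears exactly its count.

    Read sequences are the 25-nt barcode between the fixed flanks
    :data:`FLANK_5P` and :data:`FLANK_3P`; qualities are constant. Barcodes
    must be 25-nt ACGT strings.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    barcodes = counts.index.to_numpy(str)
    for bc in barcodes:
        if len(bc) != 25 or set(bc) - set("ACGT"):
            raise FormatError(f"malformed barcode at emission: {bc!r}")
    qual = quality_char * (len(FLANK_5P) + 25 + len(FLANK_3P))
    paths = []
    for gi, col in enumerate(BIN_COLUMNS):
        suffix = ".fastq.gz" if compress else ".fastq"
        path = outdir / f"{prefix}_{col}{suffix}"
        opener = gzip.open if compress else open
        n = 0
        with opener(path, "wt") as fh:
            for bc, c in zip(barcodes, counts[col].to_numpy(int)):
                seq = FLANK_5P + bc + FLANK_3P
                for j in range(c):
                    fh.write(f"@{col}:{bc}:{j}\n{seq}\n+\n{qual}\n")
                    n += 1
        logger.debug("wrote %d reads to %s", n, path)
        paths.append(path)
    return paths
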