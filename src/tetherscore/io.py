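"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, GFF3 (1-based inclusive CDS features; parsed with
gffutils), BED (0-based half-open, export only at the boundary), and the
TSV schemas for fragments, barcode maps, bin-count tables, scores and
domain annotations. Validation errors name the offending column and row.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import SchemaError
from .library import FRAGMENT_COLUMNS, GeneModel
from .screen import BIN_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "write_fasta", "read_fasta",
    "write_gff3", "read_gff3", "gff3_to_bed", "bed_to_gff3",
    "write_fragments", "read_fragments",
    "write_barcode_map", "read_barcode_map",
    "write_counts", "read_counts",
    "write_scores", "read_scores",
    "read_domains", "write_domains",
    "read_biogrid_tab3",
]


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {id: sequence}; mixed case is upper-cased (logged)."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq.isupper():
            logger.info("FASTA record %s: normalizing to upper case", rec.id)
            seq = seq.upper()
        out[rec.id] = seq
    return out


# ---------------------------------------------------------------------------
# GFF3 / BED


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene CDS features as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID=cds-{g.gene_id};gene_id={g.gene_id}"
            fh.write("\t".join([
                g.chrom, "tetherscore", "CDS", str(g.cds_start), str(g.cds_end),
                ".", g.strand, "0", attrs,
            ]) + "\n")


def read_gff3(path) -> pd.DataFrame:
    """Read CDS features from a GFF3 file (gene_id, chrom, start, end, strand)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("CDS", order_by="start"):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        rows.append((gene_id, feat.seqid, feat.start, feat.end, feat.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def gff3_to_bed(gff3_path, bed_path) -> None:
    """CDS features to 6-column BED (0-based half-open)."""
    df = read_gff3(gff3_path)
    bed = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"] - 1,
        "end": df["end"],
        "name": df["gene_id"],
        "score": 0,
        "strand": df["strand"],
    })
    bed.to_csv(bed_path, sep="\t", header=False, index=False)


def bed_to_gff3(bed_path, gff3_path) -> None:
    """6-column BED intervals back to GFF3 CDS features."""
    bed = pd.read_csv(bed_path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"])
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in bed.itertuples(index=False):
            attrs = f"ID=cds-{row.name};gene_id={row.name}"
            fh.write("\t".join([
                str(row.chrom), "tetherscore", "CDS", str(row.start + 1),
                str(row.end), ".", str(row.strand), "0", attrs,
            ]) + "\n")


# ---------------------------------------------------------------------------
# TSV schemas


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _check_non_negative_int(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            row = df.index[bad][0]
            raise SchemaError(
                f"{what}: column '{col}', row {row!r}: "
                f"expected a non-negative integer, got {df.loc[row, col]!r}")


def write_fragments(fragments: pd.DataFrame, path, bed_path=None) -> None:
    fragments.to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        bed = pd.DataFrame({
            "chrom": fragments["chrom"],
            "start": fragments["start"] - 1,
            "end": fragments["end"],
            "name": fragments["fragment_id"],
            "score": 0,
            "strand": fragments["strand"],
        })
        bed.to_csv(bed_path, sep="\t", header=False, index=False)


def read_fragments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, FRAGMENT_COLUMNS, "fragment table")
    _check_non_negative_int(df, ["start", "end"], "fragment table")
    if (df["end"] < df["start"]).any():
        row = df.index[df["end"] < df["start"]][0]
        raise SchemaError(f"fragment table: row {row!r}: end < start")
    return df


def write_barcode_map(barcode_map: pd.DataFrame, path) -> None:
    barcode_map.to_csv(path, sep="\t", index=False)


def read_barcode_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["barcode", "fragment_id"], "barcode map")
    bad = ~df["barcode"].astype(str).str.fullmatch("[ACGT]{25}")
    if bad.any():
        row = df.index[bad][0]
        raise SchemaError(f"barcode map: column 'barcode', row {row!r}: "
                          f"not a 25-nt ACGT string")
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise SchemaError(f"barcode map: barcode {dup!r} maps to multiple fragments")
    return df


def write_counts(counts: pd.DataFrame, path, replicate_id: str | None = None) -> None:
    out = counts.reset_index()
    out["replicate"] = replicate_id or counts.attrs.get("replicate_id", "rep1")
    out.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["barcode", *BIN_COLUMNS], "count table")
    _check_non_negative_int(df, BIN_COLUMNS, "count table")
    rep = str(df["replicate"].iloc[0]) if "replicate" in df.columns and len(df) else "rep1"
    out = df.set_index("barcode")[BIN_COLUMNS].astype(np.int64)
    out.attrs["replicate_id"] = rep
    return out


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.reset_index().rename(columns={"index": "fragment_id"}).to_csv(
        path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["fragment_id", "mu_hat", "score", "total_reads"],
                     "score table")
    return df.set_index("fragment_id")


def write_domains(domains: pd.DataFrame, path) -> None:
    domains.to_csv(path, sep="\t", index=False)


def read_domains(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["protein_id", "family_id", "aa_start", "aa_end"],
                     "domain table")
    _check_non_negative_int(df, ["aa_start", "aa_end"], "domain table")
    return df


def read_biogrid_tab3(path) -> pd.DataFrame:
    """Physical interaction pairs from a BioGRID TAB3-style table.

    Accepts either BioGRID's column headers ('Systematic Name Interactor A/B',
    'Experimental System Type') or the package's compact equivalents
    (interactor_a/interactor_b/experimental_system_type); keeps physical
    interactions only.
    """
    df = pd.read_csv(path, sep="\t")
    renames = {
        "Systematic Name Interactor A": "interactor_a",
        "Systematic Name Interactor B": "interactor_b",
        "Experimental System Type": "experimental_system_type",
    }
    df = df.rename(columns=renames)
    _require_columns(df, ["interactor_a", "interactor_b"], "interaction table")
    if "experimental_system_type" in df.columns:
        df = df[df["experimental_system_type"].str.lower() == "physical"]
    return df[["interactor_a", "interactor_b"]].drop_duplicates().reset_index(drop=True)
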