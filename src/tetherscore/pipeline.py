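"""End-to-end orchestration of the simulated screen and its analysis.

simulate-library -> simulate two replicate screens -> filter/score each
replicate -> choose the broader-dynamic-range reference replicate and the
replicate correlation -> fragment annotation -> domain / PPI / RBP / motif
analyses. Every stage's inputs and outputs land on disk under the output
directory, and a JSON run report records the seed, thresholds, filter
tallies and calibration constants.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .config import GateBoundaries, PipelineConfig, save_config
from .errors import StageError, TetherscoreError
from .library import (
    build_library,
    domain_annotations_from_genes,
    simulate_interaction_table,
    simulate_rbp_flags,
)
from .screen import simulate_replicates
from .scoring import (
    choose_reference_replicate,
    replicate_correlation,
    score_fragments,
)
from .enrichment import (
    build_rbp_set,
    compare_rbp_activity,
    domain_enrichment,
    ppi_enrichment,
    prepare_motif_input,
)
from . import io as tio

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "simulate_and_score"]


def simulate_and_score(config: PipelineConfig):
    """Library -> two replicates -> scored tables; the computational core.

    Returns ``(library, replicates, scores_by_rep, report_fields)`` without
    touching the filesystem; ``run_pipeline`` wraps this with on-disk
    outputs and the annotation/enrichment stages.
    """
    lib = build_library(config.library)
    reps = simulate_replicates(lib.barcode_map, lib.in_frame, config.screen)
    scores = {}
    for rep in reps:
        scores[rep.replicate_id] = score_fragments(
            rep.counts, lib.barcode_map, config.estimator,
            boundaries=GateBoundaries(rep.boundaries),
            replicate_id=rep.replicate_id)
    r, n = replicate_correlation(scores["rep1"], scores["rep2"], config.estimator)
    reference = choose_reference_replicate(scores["rep1"], scores["rep2"])
    report = {
        "replicate_correlation_r": r,
        "replicate_correlation_n": n,
        "reference_replicate": reference,
    }
    return lib, reps, scores, report


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run the whole arc and write all artifacts under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.getLogger("tetherscore").setLevel(config.log_level)
    report: dict = {
        "tetherscore_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "min_gate_count": config.estimator.min_gate_count,
            "min_total_reads_replicate_corr":
                config.estimator.min_total_reads_replicate_corr,
            "active_score_threshold": config.enrichment.active_score_threshold,
            "domain_coverage_threshold": config.enrichment.domain_coverage_threshold,
            "collapse_similarity_domains": config.enrichment.collapse_similarity_domains,
            "collapse_similarity_motifs": config.enrichment.collapse_similarity_motifs,
            "q_threshold": config.enrichment.q_threshold,
        },
    }
    save_config(config, out / "config.yaml")

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage: %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
        return _Ctx()

    with stage("simulate-library"):
        lib = build_library(config.library)
        libdir = out / "library"
        libdir.mkdir(exist_ok=True)
        tio.write_fasta(lib.genome.items(), libdir / "genome.fasta")
        tio.write_gff3(lib.genes, libdir / "genes.gff3")
        tio.write_fragments(lib.in_frame, libdir / "fragments.tsv",
                            bed_path=libdir / "fragments.bed")
        tio.write_barcode_map(lib.barcode_map, libdir / "barcode_map.tsv")
        report["library"] = {
            "n_fragments_raw": len(lib.fragments),
            "n_fragments_in_frame": len(lib.in_frame),
            "n_barcodes": len(lib.barcode_map),
            "n_stop_free_unmapped": lib.in_frame.attrs.get("n_stop_free_unmapped"),
            "mean_fragment_length": float(
                (lib.fragments["end"] - lib.fragments["start"] + 1).mean()),
        }

    with stage("simulate-screen"):
        reps = simulate_replicates(lib.barcode_map, lib.in_frame, config.screen)
        screendir = out / "screen"
        screendir.mkdir(exist_ok=True)
        for rep in reps:
            tio.write_counts(rep.counts, screendir / f"counts_{rep.replicate_id}.tsv",
                             replicate_id=rep.replicate_id)
        with open(screendir / "boundaries.json", "w") as fh:
            json.dump({r.replicate_id: list(r.boundaries) for r in reps}, fh, indent=1)

    with stage("score"):
        scoredir = out / "scores"
        scoredir.mkdir(exist_ok=True)
        scores = {}
        for rep in reps:
            sc = score_fragments(rep.counts, lib.barcode_map, config.estimator,
                                 boundaries=GateBoundaries(rep.boundaries),
                                 replicate_id=rep.replicate_id)
            scores[rep.replicate_id] = sc
            tio.write_scores(sc, scoredir / f"scores_{rep.replicate_id}.tsv")
        r, n = replicate_correlation(scores["rep1"], scores["rep2"], config.estimator)
        reference = choose_reference_replicate(scores["rep1"], scores["rep2"])
        ref_scores = scores[reference]
        report["scoring"] = {
            "replicate_correlation_r": r,
            "replicate_correlation_n": n,
            "reference_replicate": reference,
            "standardization_mean": ref_scores.attrs.get("standardization_mean"),
            "standardization_sd": ref_scores.attrs.get("standardization_sd"),
            "n_barcodes_removed": {
                rep_id: sc.attrs.get("n_barcodes_removed")
                for rep_id, sc in scores.items()
            },
        }

    with stage("annotate"):
        anndir = out / "annotation"
        anndir.mkdir(exist_ok=True)
        domains = domain_annotations_from_genes(lib.genes, seed=config.seed)
        tio.write_domains(domains, anndir / "domains.tsv")

    with stage("enrich"):
        enrdir = out / "enrichment"
        enrdir.mkdir(exist_ok=True)
        frag_cols = lib.in_frame[["fragment_id", "gene_id", "aa_start", "aa_end"]]
        dom = domain_enrichment(ref_scores, frag_cols, domains, config.enrichment)
        dom.to_csv(enrdir / "domain_enrichment.tsv", sep="\t", index=False)

        ppi = simulate_interaction_table(lib.genes, seed=config.seed)
        ppi.to_csv(enrdir / "interactions.tsv", sep="\t", index=False)
        for direction in ("activator", "repressor"):
            res = ppi_enrichment(ref_scores, frag_cols, ppi, direction,
                                 config.enrichment)
            res.to_csv(enrdir / f"ppi_{direction}s.tsv", sep="\t", index=False)

        flags = simulate_rbp_flags(lib.genes, seed=config.seed)
        flags.to_csv(enrdir / "rbp_flags.tsv", sep="\t", index=False)
        rbp = build_rbp_set(flags, config.enrichment.rbp_min_datasets)
        rbp_cmp = compare_rbp_activity(ref_scores, frag_cols, rbp)
        report["enrichment"] = {
            "n_significant_domain_families": int(dom["significant"].sum())
            if len(dom) else 0,
            "rbp_comparison": rbp_cmp,
        }
        try:
            proteome = {g.gene_id: g.protein_seq for g in lib.genes}
            records = prepare_motif_input(ref_scores, frag_cols, proteome,
                                          config.enrichment)
            tio.write_fasta(records, enrdir / "motif_input.fasta")
            report["enrichment"]["n_motif_input_peptides"] = len(records)
        except TetherscoreError as err:
            logger.info("motif input skipped: %s", err)

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    logger.info("pipeline complete: %s", out)
    return out
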