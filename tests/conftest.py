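"""Shared fixtures.

``default_run`` executes the full default-scale simulation once per session
(the study conditions of the screen: 50,000 raw fragments, four-gate sort,
two replicates) and is shared by the calibration-style tests;
``tiny_config`` is a seconds-scale configuration for smoke and CLI tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tetherscore import (
    EstimatorConfig,
    LibraryConfig,
    PipelineConfig,
    ScreenConfig,
)
from tetherscore.library import GeneModel, RegulatoryElement, build_library
from tetherscore.pipeline import simulate_and_score


@pytest.fixture(scope="session")
def default_run():
    """Full default-condition simulation, scored, with ground truth."""
    cfg = PipelineConfig().with_seed(101)
    lib, reps, scores, report = simulate_and_score(cfg)
    return {"config": cfg, "library": lib, "replicates": reps,
            "scores": scores, "report": report}


@pytest.fixture(scope="session")
def tiny_library_config():
    return LibraryConfig(
        n_fragments=4_000,
        n_genes=30,
        genome_length=60_000,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_config(tiny_library_config):
    cfg = PipelineConfig(
        library=tiny_library_config,
        screen=ScreenConfig(n_cells_per_gate=1_000, reads_total=400_000, rng_seed=7),
    )
    return cfg


@pytest.fixture(scope="session")
def tiny_library(tiny_library_config):
    return build_library(tiny_library_config)


@pytest.fixture()
def simple_gene():
    """A + strand gene with a known protein, CDS 1001..1900 (300 codons)."""
    rng = np.random.default_rng(0)
    from tetherscore.library import _random_cds

    cds, protein = _random_cds(rng, 299)  # CDS length 900 incl. stop
    return GeneModel(
        gene_id="GENEX", chrom="chr1", strand="+",
        cds_start=1001, cds_end=1900, protein_seq=protein,
        regulatory_elements=[RegulatoryElement(50, 109, 1.5, "EF01")],
    )


def make_fragment_frame(rows):
    """Build a fragment DataFrame from (id, gene, aa_start, aa_end, reads)."""
    return pd.DataFrame(
        [{"fragment_id": r[0], "gene_id": r[1], "aa_start": r[2],
          "aa_end": r[3], "total_reads": r[4]} for r in rows]
    )
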