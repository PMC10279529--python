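# Methods

## The measurement model

Each cell carries one barcoded λN-fragment construct and one dual-reporter
cassette. The phenotype is the log YFP/RFP fluorescence ratio, expressed in
population-z units. A fragment with true regulatory effect μ produces cells
with phenotype `z ~ Normal(μ, σ_w²)`; the within-fragment spread σ_w is fixed
at 1, i.e. the single-construct cell-to-cell noise defines the unit of the
z scale. Estimating σ_w per fragment is not attempted: for fragments sorted
almost entirely into one extreme gate the pair (μ, σ_w) is unidentifiable
from four bin counts.

FACS splits the pooled population into four gates at the empirical quartiles
of the realized ratio distribution, so the gates have equal occupancy by
construction (to ±1 cell) regardless of the library's activity composition.
The theoretical cuts for a standard-normal population, (−0.6745, 0,
+0.6745), are exposed separately for analytic tests; the simulator's realized
cuts are wider because the pooled population mixes fragments of different μ.

Sequencing reads in gate *b* are drawn multinomially, proportional to each
barcode's cell count in that gate, with a per-gate total `reads_total ·
d_b / Σd`. Equal cell numbers per gate do not imply equal read numbers —
the depth factors d_b exist precisely because scoring must tolerate unequal
per-gate sequencing depth.

## The activity estimator

For fragment counts `n = (n_1..n_4)` and gate cuts `c`, the gate
probabilities are `q_b(μ) = Φ((c_b−μ)/σ_w) − Φ((c_{b−1}−μ)/σ_w)`. The
estimator maximizes

    ℓ(μ) = Σ_b (n_b / d_b + α) · log q_b(μ)

over `mu_bounds` (default [−3, 3]) with a bounded scalar optimizer
(`xatol = 1e-8`), comparing the interior optimum against both endpoints;
the likelihood is unimodal in μ and monotone beyond the extreme cuts, so
fragments with essentially all reads in one extreme gate land exactly on
the bound. A dense-grid search is kept in the test suite as an independent
oracle (agreement within 1e-4 on 1,000 random count vectors).

Depth handling deserves a note. The profile multinomial MLE — maximizing
`Σ n_b log p̃_b(μ)` with `p̃_b = d_b q_b / Σ d_c q_c` — is *not* exactly
invariant under scaling one gate's counts and its depth factor together
(the argmax shifts by O(1e-2) for a 7-fold scaling). The estimator instead
maximizes the likelihood of depth-normalized counts `n_b/d_b`, which is
exactly invariant by construction, reduces to the plain multinomial MLE for
equal depths, and is consistent under the read model (E[n_b/d_b] ∝ q_b(μ)
because gate occupancies are equalized by the sort). Depth factors supplied
explicitly are used as-is — the pseudocount α is "one read per gate at unit
depth" — while depths estimated from a count table (each gate's read total)
are normalized to mean 1 once per table.

The pseudocount α = 1 regularizes all-in-one-gate fragments: together with
the bounded optimizer it yields finite, saturating estimates. For very low
counts (≲ 400 reads all in one extreme gate) the pseudocount pulls the
optimum slightly inside the bound; deeply covered saturated fragments pin
exactly at it, which produces the characteristic score plateau.

**Standardization.** Scores are z-scores of μ̂ against the population:
`score_f = (μ̂_f − m)/s`, where m and s are the mean and population standard
deviation of μ̂ over all passing fragments weighted by total reads. The read
weighting approximates standardizing against the sorted *cell* population
(reads are the only available proxy for cell representation). Under this
reading, the maximum attainable score is `(bound − m)/s`: the estimator
bound, not the data, sets the plateau. m and s are recorded in the run
report.

**Filters.** A barcode is retained iff some gate has ≥ `min_gate_count`
(default 32) reads — the stated rule ("lacked at least 32 counts in one of
the sorted gates") is ambiguous between any-gate and every-gate readings;
the any-gate reading is the default and the alternative is a config switch
(`gate_filter_mode`). Surviving barcodes are summed to fragment level before
estimation (read-weighted pooling extracts more information from unevenly
covered barcodes than averaging per-barcode scores would). Replicate
correlation is computed over fragments with ≥ 1,000 total reads in both
replicates; downstream analysis uses the replicate whose raw μ̂ has the
larger standard deviation (broader dynamic range), ties going to replicate 1.

## The synthetic library

The generator emulates the library construction steps as a parametric
simulation:

- **Genome**: one chromosome (default 260 kb), 150 non-overlapping
  intron-free genes on both strands, protein lengths ~ Normal(400, 100²) aa
  (min 150), random sense codons, random intergenic spacers. Introns are
  deliberately absent — the assay design depends on an intron-poor genome.
- **Fragments**: 50,000 uniform start positions, equiprobable orientations,
  lengths ~ Normal(500, 150²) nt truncated at 3 nt. Only a mean size is
  specified by the assay design; the spread is a stand-in for gel size selection. No insertion
  sequence bias is modeled.
- **In-frame selection**: a fragment survives iff its vector-sense sequence,
  read in the fixed vector phase from its first base, contains no stop codon
  over all complete codons — the minimal condition for expressing a
  downstream selectable marker. Surviving fragments are assigned protein
  coordinates when they align to a CDS in matching orientation and phase
  (edge codons rounded inward, 1-based inclusive, `Gene(aa_start-aa_end)`
  naming). Stop-free fragments with no CDS alignment — chance read-throughs
  of non-coding sequence, a fraction ≲ 1e-3 at 500 bp — are dropped and
  tallied. Roughly 6–8% of raw fragments survive overall (strand × phase ×
  containment), giving ~3,000–3,700 in-frame fragments from 50,000.
- **Barcodes**: zero-truncated Poisson count per fragment calibrated to a
  truncated mean of 3; 25-nt uniform-random sequences, uniqueness enforced.
- **Ground truth**: a subset of proteins carries one embedded regulatory
  element (default 60 aa, a domain-scale region). A fragment inherits the
  element's effect iff it covers ≥ 75% of the element — the same coverage
  convention the domain analysis uses — otherwise its true activity is 0.
  Effect magnitudes are uniform on `effect_size_range` with random sign.
  `frac_null_fragments` sets the *target* null fraction; the generator
  inverts an approximate containment-geometry formula (with a fixed
  empirical correction for the shorter-than-average length of in-frame
  fragments) to choose the per-gene element probability, so the realized
  null fraction tracks the target to within a few percent and saturates
  near ~0.66 (one element per gene at most).

## Screen simulation and replicate structure

Barcode abundances are Dirichlet with per-barcode concentration 2.0 (a
transformation pool is far from uniform); the abundance vector is drawn once
per library and shared by both replicates, while cell allotment, sorting and
read sampling are independent per replicate. Replicate 2 scales every true
activity by γ = `replicate_scale` before cell simulation — a single linear
rescaling that, combined with estimator saturation, compresses extremes in
one replicate relative to the other. No richer replicate noise (culture
drift, sorting day effects) is modeled.

Read sampling is plain multinomial; PCR jackpot overdispersion is not
simulated (the Dirichlet abundance skew already produces realistic
barcode-to-barcode depth variation).

## Default study conditions and their calibration

The defaults are desk-scale: cell numbers are reduced far more than read
numbers so that the *absolute* read thresholds of the analysis (32 per
gate, 1,000 total) keep their absolute meaning, while cell-counting noise
takes over the role of the unmodeled biological replicate variation.
Defaults were fixed once, by calibrating three summary statistics of the
simulated screen against the reference values of the real assay, and are not
seed-tuned:

- `n_cells_per_gate = 3,600` (14,400 cells over ~3,300 fragments, ~4 cells
  per fragment) sets the sampling-noise share so that the true-vs-recovered
  score correlation stays ≥ 0.9 among well-covered fragments while the
  replicate correlation lands near the reference r ≈ 0.7;
- `replicate_scale γ = 0.5`: the real screen's rescaling factor is unknown;
  γ was chosen so the replicate correlation centers in the 0.7 band. With
  recovery constrained to ≥ 0.9, the model's feasible replicate r sits at
  ~0.75–0.80 — the correlation and the recovery share one noise ratio, so
  r ≈ 0.7 exactly is not reachable without sacrificing recovery;
- `frac_null_fragments = 0.60`, `effect_size_range = (0.5, 4.2)`: reproduce
  the saturated score plateau near ±1.9–2.0 under the read-weighted
  standardization. This requires a substantially larger active fraction
  (~1/3 of in-frame fragments) than a real proteome-wide screen has —
  standardizing against the fragment-score population makes the plateau
  height depend on the activity variance, which is the main respect in
  which passing tests here do *not* certify behavior on real data with a
  sparse active set.

At these conditions (measured over ten held-out seeds): replicate r =
0.767 ± 0.020, saturation score 2.01 (range 1.86–2.21), truth recovery
0.923 (range 0.898–0.939).

## Enrichment analyses

- **Active set**: |score| > 1, strict inequalities (boundary values
  excluded).
- **Similarity**: Jaccard overlap of protein-coordinate intervals; fragments
  of different proteins have similarity 0. For same-gene genomic fragments,
  coordinate overlap and sequence identity coincide, so the coordinate
  metric is used; a containment variant is available by config. Overlap
  groups are connected components at the threshold (90% for domain work,
  50% for motif input), the representative being the most highly sequenced
  member (tie → lower aa_start).
- **Domain enrichment**: a family is represented when an active
  representative covers ≥ 75% of one of its domain instances; per family,
  the mean activity of representing fragments and a two-sided Mann–Whitney
  U of their scores against the entire library's scores (the family's own
  fragments are not excluded from the library side); BH across families,
  q < 0.05 flagged.
- **PPI over-representation**: upper hypergeometric tail of
  activator (or repressor) fragments among a hub's interactor fragments,
  with the scored fragment set as the universe; fold enrichment is the
  active fraction among interactor fragments over the library-wide active
  fraction; BH within each direction. A gene-granularity mode is provided.
  Screens of this design report fold enrichment without naming a test;
  the hypergeometric tail is the natural exact choice for set
  over-representation.
- **RBP set**: proteins in ≥ 2 of 4 membership datasets; comparison is
  Mann–Whitney on |score| of RBP-derived vs other fragments.
- **Motif pre/post-processing**: motif discovery itself (MEME) and genome
  scanning (FIMO) are external tools; the package prepares their input
  (active set collapsed at 50%, representative peptides as FASTA) and
  applies the standard post-filters: motifs from a single source protein
  are dropped, and "highly repetitive" motifs/alignment targets are
  operationalized as composition Shannon entropy < 1.5 bits over the
  consensus or target window. A log₂-odds PWM scanner (uniform default
  background, no reverse-strand semantics for peptides) stands in for FIMO
  in tests.
- **Statistics**: Mann–Whitney U uses exact enumeration when
  min(n, m) ≤ 8 with no ties, else the normal approximation with tie and
  continuity corrections (which tracks the exact distribution to ~0.01 in p
  at the branch point); BH is the standard step-up; all three are backed by
  enumeration oracles in the test suite.

## Numerical and degenerate-input choices

- Gate probabilities are floored at 1e-300 before logs; σ_w ≤ 0, unordered
  cuts, and negative counts raise typed errors.
- All-zero counts with α = 0 raise an estimation error; a zero-variance
  score population raises a degenerate-population error; replicate
  correlation with < 3 shared fragments raises an insufficient-overlap
  error; a gate with zero occupancy but nonzero depth yields zero counts
  with a logged warning.
- All randomness derives from one integer seed through CRC-named
  substreams (`genome`, `fragmentation`, `barcodes`, `abundance`,
  `cells-rep1`, ...), so any stage can be reproduced in isolation.
- Coordinates are 1-based inclusive everywhere except BED export
  (0-based half-open).

## Problem sizes

The default configuration — 50,000 raw fragments, ~3,300 scored fragments,
14,400 cells and 6M reads per replicate — runs in a few seconds per
replicate on one CPU; the test suite and the reproduction script each use
a handful of such runs. These sizes are the package's chosen study
conditions: large enough for the calibration statistics to stabilize
(±0.02 in r across seeds), small enough to iterate on a laptop.

## Known limitations

- No biological replicate noise beyond the γ rescaling; no PCR
  overdispersion; no FACS instrument model (scatter gating, doublets,
  spectral overlap).
- No tagmentation sequence bias; fragment starts are uniform.
- The activity scale is one-dimensional: no expression/abundance dimension
  per fragment, no bimodal phenotypes.
- Score standardization against the fragment population (read-weighted)
  rather than the cell population is one of two defensible readings of
  "z-score relative to the overall population"; the choice changes the
  plateau height and is recorded in the run report via (m, s).
- HMM-based domain detection is out of scope; domain annotations are
  consumed, not computed.
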