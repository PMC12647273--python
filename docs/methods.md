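# Methods

This note documents the modelling and numerical choices behind each stage,
what the synthetic generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design and preprocessing

The screen assumes an 8-sample, one-channel microarray design: two
replicate cortex samples at each of four lesion-severity levels, encoded as
an ordinal covariate (control = 0, weak = 1, moderate = 2, severe = 3).
Four filters are applied in a fixed order — confidence → biotype →
replicate outlier → low expression — and each returns an audit record so
the funnel telescopes exactly.

* **Confidence** (`min_level`, default 2 on a 0/1/2 scale): a probe
  survives if *any* sample reaches the level. Disabling requires passing no
  confidence matrix explicitly; silent skipping is not allowed.
* **Replicate outlier** (`k_sd`, default 1.0; `require`, default `all`):
  the source rule speaks of replicates without fixing the grouping for a
  2-per-condition design, so the filter is defined over *all
  within-condition sample pairs*: per pair, the per-probe absolute
  difference `d` is pooled across probes, and a probe is flagged where `d`
  is outside mean ± k·sd. `require="all"` (remove only probes aberrant in
  every comparison) is the default because with four independent
  comparisons a single excursion is weak evidence; `"any"` is available. A
  comparison with sd(d) = 0 flags nothing, so degenerate toy tables are not
  emptied.
* **Low expression** (`threshold` 100, strict `<`): the literal reading —
  below threshold in *any* sample removes the probe — is the default
  (`mode="any"`); `mode="all"` keeps the alternative reading available.
* **Z-score**: per-probe, population (divisor-N) standard deviation. The
  convention is configurable in the sense that switching to divisor-(N−1)
  rescales every row by the same factor and provably changes no downstream
  ranking (asserted in the tests); zero-variance rows are removed with a
  logged id rather than emitted as NaN.

## PCA selection

Probes are observations, the 8 samples variables: that is the only
orientation yielding one loading per sample and one score per probe, which
is how the screen reads its components. Rows are already standardized, and
no re-centering across probes is applied; the decomposition is the
eigenstructure of the sample-by-sample second-moment matrix `ZᵀZ/n`,
computed by SVD for stability. Contribution ratios are eigenvalue/trace;
loading rows are unit-norm, so `scores × loadings` reconstructs the input
when all components are kept.

The lesion-discriminating component is chosen automatically as the one
whose loading vector has the largest |Spearman correlation| with severity,
rather than hard-coding the first component: on synthetic data the variance
ordering can differ, while on data matching the screen's description the
first component is recovered. Orientation is fixed so control/weak samples
carry positive loadings; probes are ranked by oriented score, ties broken
lexicographically by probe id (logged). Hierarchical clustering for the
heatmap uses average linkage on Euclidean distances (the linkage was an
open choice; both are configurable).

## Consensus runs

A column's consensus is the unique modal base if its frequency is ≥ the
threshold (inclusive at exactly the threshold); two or more bases tying at
the maximum give `+` regardless of frequency, and `+` never joins a run —
the tie marker denotes positional ambiguity, not absence of conservation.
Gaps count in the frequency denominator by default (the convention of the
alignment viewers this stage mirrors, where heavily gapped columns dilute
every base); `count_gaps=False` is available. T and U are one symbol; runs
are emitted in the RNA alphabet with 0-based half-open column coordinates.
The "complementary sequence" of a run is its reverse complement — every
published pair this package reproduces satisfies reverse-complement, not
plain complement.

Alignment construction itself is an external input (a Clustal or
aligned-FASTA file); no aligner is implemented, and the synthetic generator
produces pre-aligned, gapless sequences.

## Complement matching

For 11–15-nt motifs at ≥ 85% identity (at most two mismatches), gapped
alignment is meaningless; the search is therefore an exhaustive ungapped
Hamming scan of every full-length window on the sense strand only
("sequence direction matched"), with identity = (length − mismatches) /
length. This is a deliberate mechanism substitution for a seeded heuristic
search engine: the criteria (threshold, strand, header and whitelist
filters) are unchanged, and an exhaustive scan is a strict superset of any
seeded search at the same threshold. Partial windows at transcript ends are
not scored; transcripts shorter than the motif are skipped. Summaries count
genes (best hit per transcript retained), reported per motif and in total
both with and without cross-motif deduplication.

## Enrichment

DAVID-style contingency semantics: within a category, PT = background genes
with ≥ 1 annotation in the category, PH = background genes on the term,
LT/LH the same restricted to the query list. These semantics were adopted
because they reproduce reference fold-enrichment values exactly from their
printed integer counts (the prose definitions circulating with such tables
are circular). Fold = (LH/LT)/(PH/PT). The p-value is the one-sided
hypergeometric upper tail; the default EASE variant replaces LH by
max(LH − 1, 0) and is never anti-conservative relative to the exact tail.
FDR is Benjamini–Hochberg, adjusted within each category family (matching
how such reports group their tables); the variant name is written into the
output header since upstream tools do not always state theirs. The
significance filter fold ≥ 2.0 ∧ FDR ≤ 0.05 is inclusive on both bounds.
Published FDR columns from server-side annotation catalogs are not
reproducible without those catalogs; the *procedure* is what this module
implements, and fold values are catalog-independent.

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input with planted truth:

* **Expression**: suppressive probes have mean `base·(1 − δ·severity)` with
  `δ = effect_size / base_intensity`, i.e. the expected drop per severity
  step equals `effect_size` (naturally quoted as a multiple of `noise_sd`;
  the reference condition uses 5× = 250 on base 1000, noise sd 50).
  Intensities are log-normal with that mean and sd `noise_sd`, clipped at a
  floor of 1 — microarray intensities are positive and the screen filters
  at 100. Configurable fractions of background probes deliberately fail
  each filter (defaults 5% low-confidence, 10% non-lncRNA, 5% low
  expression, 2% replicate outlier). The raw-intensity distribution of the
  real platform is not modelled; log-normal is a stand-in, not an
  inference.
* **Probe sequences**: 60-nt, gapless, pre-aligned; every suppressive probe
  carries each planted motif verbatim at its planted column (optionally
  corrupted per-base). Real probe sets have gapped, shifted alignments,
  GC/chemistry bias and homologous families — none are emulated.
* **mRNA database**: target transcripts embed the reverse complement of a
  planted motif (a quarter with one mismatch, still above threshold);
  decoys are verified clean by exhaustive scan at generation time and
  resampled otherwise; ~30% of decoy headers are labelled
  `PREDICTED`/`cDNA`; the whitelist covers all target genes and 80% of
  decoys by default. Annotation terms are planted over each motif's target
  genes plus 30 random background terms in one category.

**Consensus threshold under the synthetic conditions.** With a gapless
alignment of ~50 sequences, every column's modal base exceeds 10% by
construction, so the 10% rule — calibrated for sparse, heavily gapped
alignment columns — saturates and extracts everything. The synthetic
pipeline condition therefore uses a column threshold of 0.9 (near
unanimity), which reproduces the sparse-consensus regime the 10% rule
addresses; the module default for real alignments remains 0.10. Passing
tests on synthetic data consequently demonstrate the machinery (ranking,
run extraction, scanning, statistics), not that a 10% threshold is
well-calibrated for any particular real alignment.

All randomness flows from one explicit seed (iteration is over sorted
collections wherever Python set order could leak in), so identical seeds
give byte-identical output files.

## Problem sizes

The reference condition used throughout the tests and the acceptance script
is 1000 probes × 8 samples, 50 planted suppressive probes, 2 planted
motifs, 12 target transcripts per motif and 200 decoys of 400 nt — large
enough that the planted/background separation, the filter fractions and the
enrichment background behave like a (small) real screen, while a full
end-to-end run takes about a second. The exhaustive hypergeometric
cross-check enumerates every contingency with PT ≤ 60 against exact
rational arithmetic.

## Known limitations

* No background correction, quantile normalization or batch correction (the
  screen applies none); no rotation or probabilistic PCA.
* No multiple-sequence-alignment algorithm and no RNA secondary-structure or
  thermodynamic binding model; complementarity is purely sequence-level.
* Dataset-level counts from the original accession (e.g. a 16,251 → 12,135
  probe funnel) depend on that dataset and on the annotation snapshot of
  the external search set; the package reproduces the procedure and logs
  the equivalent funnel so such a comparison can be made by a user holding
  the data.
* Gene-level summaries assume the `transcript_id|gene_symbol|description`
  header convention; many-to-one transcript→gene mapping is supported, but
  no symbol harmonization beyond case folding is attempted.
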