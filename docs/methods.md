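# Methods

This note documents the models, parameter choices and numerical conventions
behind `riboarch`, and what the synthetic-data tests do and do not
demonstrate about real genome collections.

## Coordinates and dataset assembly

All internal intervals are 0-based half-open; GFF3 and Infernal tblout
conventions (1-based inclusive, minus-strand hits with reversed seq-from/
seq-to) are converted exactly once, at the I/O boundary. One representative
genome is kept per species — the strain with the most annotated genes, with
lexicographic genome-id tie-breaks so builds are deterministic.

Each gene gets one upstream intergenic region in its transcription
direction, bounded by the nearest annotated gene body on either strand (or
the contig edge); zero-length gaps yield no region, and no maximum length is
imposed. Minus-strand regions are stored reverse-complemented so that
position 0 is always the 5′-most transcribed position: all later windowing
(junction gaps, terminator windows) is therefore orientation-free. When two
divergently transcribed genes share a gap, each gene receives its own
(possibly overlapping) upstream region — attribution to one gene or the
other cannot be decided from the annotation alone.

## Empirical bit-score cutoffs

Curated per-model gathering thresholds can exclude bona fide aptamers of
some classes (T-box is the classic example), so cutoffs are re-derived
empirically. Each intergenic region is shuffled `n_shuffles` times
(default 100) preserving its overlapping-dinucleotide multiset, using the
Euler-path construction: the sequence is a walk on the graph whose edges
are its dinucleotides; a uniformly random Eulerian walk with the same start
vertex is drawn by sampling a random in-tree of "last exits" toward the
final letter and permuting the remaining edges. This preserves length,
mononucleotide composition, first and last letter, and local dinucleotide
statistics simultaneously. Shuffling the region's own sequence (rather
than resampling genome-wide composition at fixed length) is the default
because it preserves both properties at once; genome-level resampling can
be composed from `markov_background` if desired.

The per-model cutoff is the maximum bit score any shuffle achieves — by
construction the strongest score attainable by compositional noise — and
candidate hits must score **strictly above** it (the maximum itself is, by
definition, noise-attainable). When no shuffle produces a hit the cutoff
falls to a configurable floor of 0.0 bits; the floor is permissive so that
a curated threshold supplied by the caller dominates. Cutoffs are per
model, matching per-family threshold reporting. Non-ACGT characters are
rejected rather than resampled: silent composition distortion is worse
than an explicit failure, and ambiguous regions should be hard-masked or
dropped upstream. Randomness flows from one root seed through
per-(region, replicate) streams keyed by a CRC of the region id, so results
are independent of iteration order and parallelization.

## Intrinsic terminator model

A Rho-independent terminator is modeled as a stem-loop immediately followed
by a U-rich run. Within a 50-nt window downstream of an aptamer (clipped at
the region end and at the next aptamer's start — the scan never reads into
coding sequence or a downstream aptamer):

- **T-runs**: every placement of a 6-nt sliding window containing ≥ 5 T is
  marked; overlapping placements are merged and each merged interval is
  trimmed to its outermost T residues. Both numbers are parameters; 6/5 is
  the standard intrinsic-terminator heuristic for a U-tail with at most one
  interruption.
- **Hairpin**: for each T-run (5′→3′) and each gap 0..2 nt, the engine folds
  the best single stem-loop whose 3′ base ends exactly `gap` nt before the
  run. A call requires ΔG° strictly below −10 kcal/mol; among qualifying
  hairpins the one nearest the run wins (ties: lower ΔG°, then 5′-most
  span), and the first T-run with a qualifying hairpin yields the call.

### Hairpin-only MFE engine

Terminator hairpins are single stem-loops, so the engine implements exactly
that structure class and nothing more: nested pairs forming one stem, with
bulges/internal loops of at most 3 nt per side, no multiloops, minimum stem
3 bp, minimum loop 3 nt. Energies are nearest-neighbor free energies at
37 °C: Watson–Crick and G·U stack terms from the standard Turner-style
table, tabulated hairpin-loop initiation penalties (Jacobson–Stockmayer
extrapolation beyond 9 nt), and tabulated bulge/internal-loop initiation by
defect size (stacking is not scored across a defect; coaxial terms, dangles
and terminal-mismatch bonuses are omitted). DNA input is folded as its
transcript (T ≡ U).

The optimum is found by a memoized inward dynamic program over (5′ index,
3′ index, pairs-still-required); an exhaustive structure-by-structure
enumeration oracle in the test suite confirms exact agreement on random
15–25-mers, and an independent folding program reproduces the same
structures with ΔG° on the same scale (within the expected offset of the
reduced loop tables) on clean stem-loops. The restriction to single stems
keeps ΔG° on the kcal/mol scale the −10 threshold assumes while removing
any external folding dependency; `call_terminator` accepts a `fold` backend
for callers who want a full secondary-structure engine instead.

## Architecture classification

Hits sharing one intergenic region (and hence one regulated gene) form a
contiguous group. Overlapping matches are deduplicated first: hits whose
intervals overlap by more than half the shorter hit compete within
transitive-overlap clusters, and only the best hit survives (bit score,
then E-value, then model name) — otherwise one aptamer matched by several
related models would masquerade as a contiguous pair.

Junction gaps are measured end-of-upstream-aptamer to start-of-downstream-
aptamer, the only reading under which a terminator can physically sit
"between" the aptamers. The distance rule is authoritative: a junction is
*adjacent* when its gap is < 20 nt and *tandem* at ≥ 20 nt (the threshold
itself derives from the minimum terminator footprint, so a gap of exactly
20 is tandem). Terminator calls are annotated as per-junction evidence but
never override distance — making both criteria authoritative would
contradict itself for wide junctions whose terminator is simply missed.
Groups whose junctions disagree get an explicit `mixed` class. Homogeneity
compares ligand *families* (so two different SAM-sensing classes are
homogeneous), and the architecture string joins family names 5′→3′.

The regulated gene set defaults to the single downstream gene. Operon
extension (adding same-strand downstream genes within a gap limit) is
deliberately not performed: operon membership in real collections comes
from curation this package does not reproduce, and gene-denominated
enrichment counts treat each annotated gene individually.

## Enrichment analyses

Thirteen analysis ids (S6, S7, S9–S19) define stratified one-sided
upper-tail hypergeometric tests; each id fixes what counts as the
population, the successes, and the stratum:

| ids | population (N / K) | strata (n / k) |
|---|---|---|
| S6, S7, S9, S10 | all genes / riboswitch instances (all, contiguous, tandem, adjacent) | per phylum |
| S11–S13 | all instances / contiguous (tandem, adjacent) instances | per family |
| S14, S15 | all instances / instances per family | per family × phylum |
| S16, S18 | all genes / distinct (contiguously) regulated genes | per COG |
| S17, S19 | genes in the COG / regulated genes in the COG | per COG × phylum |

Riboswitch-denominated rows count deduplicated aptamer instances;
gene-denominated rows count distinct regulated genes (a gene under two
aptamers counts once). The composite rows follow the variable table
literally: S14/S15 keep the whole collection as population with the phylum
only in the group columns, while S17/S19 restrict the population to the
COG. The upper tail P(X ≥ k) is accumulated in log space from
`log C(K,j) + log C(N−K,n−j) − log C(N,n)` (switching to a survival-
function evaluation only for tails wider than 2×10⁵ terms) and is exact to
~10⁻¹³ relative error against rational-arithmetic summation on the full
N ≤ 60 grid. Raw p-values are primary — one-sided, uncorrected — with
Benjamini–Hochberg available as an opt-in column that never affects
ordering.

## Synthetic collections

The generator emulates the statistical structure the analyses assume, not
genome biology: genomes are one plus-strand contig of head-to-tail genes,
each preceded by its intergenic region; background sequence is a
first-order Markov chain with configurable GC and a self-persistence term
(locally correlated composition keeps terminator false positives
realistic). Defaults, chosen once as the study conditions: 5 phyla × 4
genomes × 500 genes; per-gene regulation probability 0.0036 (the survey-
wide prevalence of ~0.36% riboswitches per gene), scaled by per-phylum and
per-COG multipliers; architecture mix 50% single / 25% tandem pair / 20%
adjacent pair / 5% tandem triple; tandem gaps 30–45 nt and adjacent gaps
3–15 nt (≥ 5 nt clear of the 20-nt threshold, so recovery failures indicate
classifier defects rather than boundary noise); canonical terminators
(8-bp G:C stem, 4-nt GNRA-style loop, 8-nt T tail; ΔG° = −16.48 kcal/mol
under the packaged tables) planted at every tandem junction; planted bit
scores uniform 5–40 bits above a 20-bit nominal cutoff, with optional
sub-cutoff decoys to exercise filtering.

A counts-level fast path (`simulate_phylum_counts`) draws per-genome
regulated-gene and instance totals directly (binomial/multinomial) for
survey-scale power and calibration studies — statistically identical to
aggregating the sequence-level generator, without materializing 2-million-
gene collections per replicate. The type-I calibration of S6 uses a
single-aptamer architecture mix: with multi-aptamer groups, instances
cluster on genes and overdisperse the stratum counts relative to the
hypergeometric null, so instance-level S6 is calibrated only when
instances and regulated genes coincide; with clustering, hypergeometric
p-values on instance counts are anti-conservative by construction and
should be read as ranking scores rather than exact tail probabilities.

What passing these tests shows: the pipeline recovers exactly what was
planted under clear margins, the detectors' false-positive behaviour on
composition-matched noise, and the test statistic's calibration under its
own sampling model. What they do not show: performance on real covariance-
model score distributions (planted hits are coordinates with scores, not
sequence motifs), phylogenetically correlated genome evolution, operonic
gene structure, or terminators whose stems diverge from the single
stem-loop model.

## Problem sizes and determinism

Default problem sizes — a 10,000-gene default collection, the full N ≤ 60
hypergeometric grid, 1,000 hairpin-oracle sequences, 10,000 shuffle checks,
200 null and 20 planted enrichment replicates at 20 phyla × 50 genomes ×
2,000 genes — were chosen so the whole verification runs in about a minute
on one CPU while keeping every check at the size its statistical statement
requires. All stages are pure functions of (inputs, parameters, seed);
rerunning any stage with the same seed reproduces outputs byte-for-byte,
and the all-in-one runner writes a manifest with parameter values and
input digests.

## Known limitations

- The hairpin engine's reduced loop tables shift ΔG° by up to a few
  kcal/mol relative to full nearest-neighbor implementations on structures
  with defects; the −10 kcal/mol threshold is calibrated for this scale but
  borderline terminators may differ from full-engine calls.
- T-run detection uses a fixed 6-nt/5-T window heuristic; organisms with
  atypical U-tail composition may need the parameters loosened.
- Enrichment p-values are raw and one-sided; depletion is not tested.
- The per-model cutoff calibration assumes the scanner is deterministic
  and scores shuffled sequences on the same scale as real ones.
- Hits are attributed to regions by target name; hits spanning two genes'
  overlapping upstream regions are counted once per region they were
  reported on.
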