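# Methods

This note documents the models and procedures implemented in `wgdkit`, the
parameter defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions adopted
where the underlying methods are usually left unstated.

## k-mer genome-size estimation (`wgdkit.kmer`)

Shotgun reads are decomposed into k-mers (default k = 17, odd so that no
k-mer equals its own reverse complement) counted canonically — each
occurrence recorded under the lexicographic minimum of the k-mer and its
reverse complement — because shotgun sequencing samples strands
symmetrically.  The histogram maps multiplicity to the number of distinct
k-mers observed that many times; the estimator is

    genome size = total k-mer frequency / primary peak depth,

rounded to the nearest base.  The expected peak depth is `C·(L−k+1)/L` for
sequencing depth `C` and read length `L`, which is why the estimate recovers
the *true* (pre-collapse) genome length rather than the assembly length.

**Error-region exclusion.**  Real histograms have an enormous
low-multiplicity spike of error k-mers.  The peak search scans
multiplicities in ascending order and starts at the first local minimum of
the counts; a histogram that only decreases raises an unresolvable-peak
error rather than returning the error spike.  With error-free synthetic
reads the "error region" is just the multiplicity-1 sampling tail, which the
same rule skips.

**Not modelled:** heterozygosity and repeat shoulders (no mixture-model
fitting à la GenomeScope).  On a highly repetitive real genome the single
primary peak is still well defined, but the estimator inherits its biases.

## Collapsed/repeat detection (`wgdkit.corefind`)

Three coverage tracks per base: `r0` (uniquely mapping reads), `r1`
(multi-mapping reads placed at one random locus), `r2` (all loci).  By
construction `r0 ≤ r1 ≤ r2` everywhere; this is asserted on every input.

Per-position predicates, with each track compared to its own overall
median (genome-wide by default, `per_sequence=True` optional):

* `coll`: `r0 > 2·med(r0)` and `r1 > 2·med(r1)` and `r2 > 2·med(r2)`;
* `rnc`: `0 ≤ r0 ≤ 2` and `r1 ≥ 2` and `r2 ≥ 0.5·med(r2)`.

The per-track reading of "the overall median" was chosen because a single
pooled median would make the `r2` half-median test nearly vacuous in
repeat-rich genomes.  The `r2` condition is a lower bound (≥), screening out
low-coverage junk; strict equality would match almost nothing.  Runs of
equal flag become regions; same-kind regions separated by ≤ 100 bp merge
(`merge_gap`).  No region-level median re-test is applied after merging —
flagging is strictly per-position, then run-merging.  When `med(r0) ≥ 2` the
two predicates are mutually exclusive (coll needs `r0 > 4`); in the
degenerate low-median case coll takes precedence.

**Copy number** is `median(r2 over region) / med(r2)`, reported to two
decimals.  The ratio-to-median form is the natural estimator given the
tracks; published copy-number ranges (≈1.6–172) cannot distinguish between
reasonable variants of this formula.

**Mapping emulator.**  Reads generated by this package are error-free, so
mapping is exact full-length string matching on both strands; a read with
one locus increments all three tracks, with several loci increments `r2`
everywhere and `r1` at one seeded-uniform choice, with none counts as
unmapped.  Real-data users supply the five-column per-base coverage table
(sequence, 1-based position, r0, r1, r2) produced by an aligner run in the
three reporting modes.

**Sensitivity limits.**  A 2-fold collapse sits exactly at the
"greater than twice the median" boundary in expectation and is not reliably
detected; tests use ≥3-fold collapses.  Region boundaries are fuzzy by up to
one read length on each side (a read overlapping a repeat edge maps
uniquely), so recovery tests use 1.5-kb units with 50-bp reads at 20×, where
the planted-interval overlap of recovered regions exceeds 90%.  These sizes
(30-kb genomes, 20× depth) keep the whole recovery suite to seconds while
leaving every effect an order of magnitude above its detection threshold.

## Ks estimation (`wgdkit.ks`)

Pairwise Ka/Ks uses Nei–Gojobori (1986) counting with the Jukes–Cantor
correction `d = −(3/4)·ln(1 − (4/3)p)`, a deterministic closed-form stand-in
for ML codon models; an external Ks table (e.g. from codeml) can be ingested
downstream of this step, since blocks, medians, histograms and peaks only
need per-pair values.

Conventions, stated because NG86 implementations differ:

* synonymous site fractions per codon count each of the nine single-base
  changes; changes creating a stop codon count as nonsynonymous;
* codons containing gaps or ambiguity codes in either sequence, and stop
  codons, are excluded pairwise;
* codons differing at 2–3 positions average the synonymous/nonsynonymous
  step counts over all orderings of single-step pathways, excluding
  pathways through stop codons (if all are blocked, all pathways are used
  with a warning so difference mass is conserved);
* `p ≥ 3/4` raises a saturation error — the correction is undefined there,
  and saturated anchors are excluded from block medians (logged).

S + N = 3 × countable codons by construction; the estimator is symmetric
under sequence swap; Ks is strictly increasing in ps on [0, 3/4).  All three
properties are tested, and the whole estimator is verified against an
independent brute-force site/pathway enumeration oracle to 1e-12.

**Chaining.**  Anchors (gene pairs with positions in two genomes) chain by
the standard sparse DAG dynamic program:
`chain(i) = score(i) + max_j [chain(j) − gap_penalty·(gap_a + gap_b)]` over
predecessors `j` collinear with `i` (strictly increasing on both genomes,
gaps ≤ `max_gap`); forward and reverse orientations chain separately (the
B axis is reflected for reverse chains so gap geometry is symmetric).  The
best chain is extracted, its anchors removed, and the process repeats —
best-first extraction without anchor reuse — until no chain reaches
`min_block` anchors (default 5).  The DP optimum equals exhaustive search
on all anchor sets small enough to enumerate.

**Histograms and peaks.**  Block medians are binned into half-open bins of
width 0.01 (proportions, summing to 1); peaks are local maxima of a centred
moving average (5 bins, edge-replicated padding so flat histograms stay
flat) with prominence ≥ 0.002.  None of these three values is prescribed by
the methods this package follows; they were fixed once at values that
resolve peaks 0.1 apart in 10 000-value samples and are exposed as
parameters.

**Anchor provenance.**  All-vs-all peptide search is out of scope; anchors
arrive as a TSV.  The "top matches" retention rule is available as a filter
keeping each query's best-scoring hit per target chromosome (so WGD
homoeologs on different chromosomes all survive).  Reciprocal-best filtering
is *not* applied.

## Chronology (`wgdkit.chronology`)

The event tree is rooted at a whole-genome duplication; duplication nodes
(WGD/WGT) are unary — they mark an event on a lineage without bifurcating
the species tree.  Each non-root node owns the branch above it, giving one
unknown Ks length per non-root node (11 on the five-taxon legume demo
topology with its three duplication nodes).

Observation equations:

* `ortholog(X, Y) = Σ b_i` over both tip-to-MRCA paths (optionally forced
  through the root for WGD-derived "old ortholog" peaks);
* `paralog(tip, E) = 2·Σ b_i` over the tip-to-event path.  The two
  post-duplication paralog lineages live in one genome and are approximated
  by the same branches — hence the factor 2.  This is a modelling choice;
  the alternative (two independent post-event lineages) would double the
  unknown count without adding observations.

The stacked system solves by least squares (exact when consistent; residual
reported); rank deficiency raises an error listing unresolved branches;
negative solved lengths trigger a nonnegative least-squares refit, flagged.

**Dating.**  With the root calibrated (58 Mya for the papilionoid WGD in
the demo), `age(n) = cal · mean over descendant tips t of
Ks(t→n)/Ks(t→root)` — per-lineage proportional scaling averaged over tips, a
relaxed-clock-by-lineage rule; branch rates are Ks/duration.  On the
two-observation reduction (WGT paralog peak 0.30, root paralog peak 0.74)
this gives a WGT age of 58·0.15/0.37 ≈ 23.5 Mya; richer multi-species
systems shift such estimates by a few My (published analyses of the same
triplication give ≈24.6 Mya), so agreement is expected in magnitude, not to
the decimal.

The synthetic observation generator emits the full observation set (all tip
pairs, through-root variants, and every tip-to-ancestral-duplication
paralog peak) plus Gaussian noise; with noise sd 0.01 the median internal
node age error on the legume topology is well under 3 My over 50
replicates.  Real modal-peak reading error is not Gaussian and peaks can be
missing; the solver tolerates any subset of observations that keeps the
system full rank.

## Synteny depth (`wgdkit.syndepth`)

Depth at each base = number of synteny-block *footprints* covering it
(block spans, not individual anchors — matching the use of a per-base
coverage tool on block intervals), computed on a difference array and
run-length encoded; fractions per depth level are over total genome length.
Trivial self-match blocks (identical spans on the same chromosome) are
excluded when profiling a self-comparison.  The output table has one row
per depth level (including empty intermediate levels) and one column per
comparison, percentages to one decimal.

## Assembly/map statistics (`wgdkit.metrics`)

* N50: sort descending; N50 length is the length at which cumulative length
  first reaches total/2, N50 count its 1-based rank (ties break at first
  reach).  Both are reported since assembly tables print both.
* Filtering: drop sequences < 200 bp or ≥ 50% masked (repeats, simple
  repeats or N bases), with a per-sequence reason report.
* Percentages round half-up at the presentation layer only.
* Genetic map: total length is the sum of per-group maximum positions; a
  group with k loci contributes k−1 intervals, so the mean interval divides
  by (loci − groups).  On the published numbers (2500.8 cM, 2959 loci, 20
  groups) dividing by loci alone also rounds to 0.85 cM, so that choice is
  documented but not decisive.
* Window tracks: non-overlapping windows tiled from 0 (default 100 kb);
  count tracks scale to per-Mb using each window's true width (the last
  window may be partial), so window counts sum to the total; GC% is over
  non-N bases.

## Marker placement (`wgdkit.markers`)

Each primer may match with ≤2 mismatches and ≤2 gaps — unit-cost edit
operations with *separate* caps, summed for ranking.  ("Hamming distance
(mismatches+gaps)" is self-contradictory read literally; capped edit
distance is the only consistent interpretation.)  Matching uses a
vectorised semi-global DP over the text to find end positions within
distance 4, then a small constrained DP to recover feasible
(mismatch, gap) splits.  Candidates pair inward-facing sites on opposite
strands within the platform amplicon range (10–1000 bp Fluidigm,
10–5000 bp otherwise; either primer may prime either end).

Placement: a unique minimum-distance candidate places the marker (method
`epcr`); if PCR finds nothing, a known-amplicon similarity search (exact
21-mer seed matches grouped by diagonal; "unambiguous top hit" = best score
unique by ≥1) places it (method `sequence_hit`); otherwise the marker is
ambiguous or unplaced.  PCR wins whenever it produces a unique answer.  The
decision function is total: every marker ends in exactly one of the three
states.

## Synthetic data (`wgdkit.simulate`)

What the generators emulate, and what they deliberately do not:

* **Genomes**: i.i.d. bases at a requested GC; planted repeat copies are
  exact duplicates by default (an identity < 1 option exists to stress
  unique mapping).  No indels, no compositional heterogeneity, no nested
  repeats.
* **Reads**: single-end, uniform positions, equiprobable strands,
  substitution errors only, no quality model.  Single-end suffices because
  the coverage classifier never uses pairing.
* **Codon pairs**: a random sense-codon ancestor with synonymous
  single-base substitutions at distinct codons, count chosen to invert the
  JC correction at the target Ks; no nonsynonymous divergence, no
  transition/transversion bias.  Targets above Ks = 3 are rejected (the
  implied p approaches the 3/4 saturation bound).
* **Synteny**: each event claims a disjoint slice of the reference; every
  one of its `multiplicity` query copies carries a collinear anchor run
  whose footprint is exactly that slice, so true depth fractions are exact;
  per-anchor Ks ~ Normal(median, 0.03) truncated at 0.
* **Modal distances**: exact path sums plus Gaussian noise.

Passing tests therefore demonstrate correctness of the *computations* under
idealised inputs, not robustness to alignment artefacts, repeat-mediated
mismapping, fragmented block structure or skewed Ks distributions — the
things that dominate uncertainty on real genomes.  Problem sizes in the
test and acceptance runs (30-kb genomes at 20×, 1-Mb synteny references,
10 000-value histograms, 50 noise replicates) were chosen as the smallest
sizes at which every effect is an order of magnitude above its detection
threshold.

## Degenerate inputs and tie-breaks

* All-zero coverage or zero unique-mode median: classification refuses to
  run (medians are meaningless).
* Histogram with no post-error-region peak: explicit error, never a silent
  fallback to the error spike.
* Blocks whose anchors are all Ks-saturated are dropped with a warning.
* Zero-length root-to-tip Ks paths make rates undefined: explicit error.
* `Ka/Ks` is NaN when Ks = 0 (identical sequences).
* Equal-scoring chain extractions resolve by anchor order (stable sort on
  genome-A position).
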