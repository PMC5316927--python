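# wgdkit

Draft-genome validation and whole-genome-duplication (WGD) dating, as used in
draft plant genome projects such as the narrow-leafed lupin (*Lupinus
angustifolius*) assembly.  The package reimplements, as one tested pipeline
driven by synthetic data with known ground truth:

* **k-mer genome-size estimation** — `genome size = total k-mer frequency /
  primary peak depth` from a 17-mer histogram of shotgun reads;
* **collapsed/repeat region detection** (a CoReFinder-style classifier) —
  reads are mapped in three modes (`r0` unique only, `r1` one random hit,
  `r2` all hits); positions where all three coverages exceed twice their
  overall medians are *collapsed* ("coll": multiple true copies assembled as
  one), and positions with `r0 ∈ [0,2]`, `r1 ≥ 2` and `r2 ≥ 0.5·median` are
  *repeated, non-collapsed* ("rnc"); flagged runs within 100 bp merge, and
  copy number is `median(r2 in region)/median(r2)`;
* **Ks molecular evolution** — Nei–Gojobori (1986) counting with the
  Jukes–Cantor correction `d = −(3/4)·ln(1 − (4/3)p)` for pairwise Ka/Ks,
  DAG-chaining of gene anchors into synteny blocks, block-median Ks,
  proportion histograms and modal-peak detection;
* **WGD/WGT chronology** — observed modal Ks values are path sums on a
  rooted species/duplication tree (ortholog peaks: both tip-to-MRCA paths;
  paralog peaks: twice the tip-to-event path); branch lengths solve by least
  squares and convert to ages against a root calibration (58 Mya for the
  papilionoid WGD in the legume demo topology);
* **synteny coverage depth** — per-base stacking of block footprints,
  summarised as the fraction of the genome at each depth level (the
  depth-3 signal of a triplication);
* **assembly/map statistics and marker placement** — N50 statistics,
  filtering rules, percentage arithmetic, genetic-map summaries, 100-kb
  window tracks, and in-silico PCR placement of primer-pair markers
  (≤2 mismatches, ≤2 gaps per primer, platform-specific amplicon ranges).

## Worked example

```python
from wgdkit import simulate, kmer, corefind

gt = simulate.simulate_genome(
    30_000,
    [simulate.FeatureSpec("collapsed", 1500, 3, 1),           # 3 true copies, 1 assembled
     simulate.FeatureSpec("repeated_non_collapsed", 1500, 2)],  # 2 copies, both assembled
    seed=11,
)
reads = simulate.simulate_reads(gt, depth=20, read_length=50, seed=12)

hist = kmer.count_kmers([s for _, s in reads], k=17)
peak = kmer.primary_peak(hist)
print(peak, kmer.estimate_genome_size(hist, peak), gt.truth_length)

tracks = corefind.coverage_from_reads(reads, gt.assembly, seed=13)
for r in corefind.classify_regions(tracks):
    print(f"{r.kind}\t{r.sequence}:{r.start}-{r.end}\tcopy number {r.copy_number}")
```

prints

```
13 34523 33000
rnc	chr1:17437-18844	copy number 1.86
coll	chr1:20132-21572	copy number 2.86
rnc	chr1:26078-27492	copy number 1.86
```

The 17-mer peak sits at 13× (sequencing depth 20 × 34/50 informative k-mers
per base) and the size estimate lands within 5% of the 33-kb true genome —
note it recovers the *true* length, including the two repeat copies missing
from the 30-kb assembly.  The classifier flags the planted collapsed repeat
(coverage ≈ 3× median in all modes, copy number ≈ 3) and both retained
copies (unique coverage ≈ 0, all-hits coverage ≈ 2× median).

The published worked example reproduces exactly:

```python
>>> kmer.estimate_genome_size(37_098_706_666, 39)
951248889
```

A full end-to-end run on synthetic data, with every recovered quantity
checked against the generator manifest:

```sh
wgdkit demo --seed 1 --out demo_out/
```

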