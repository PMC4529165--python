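# Methods

This note records the models, parameter choices and numerical decisions
behind `charkit`, and what the synthetic-data experiments do and do not
demonstrate.

## Flow-cytometric genome sizing

A histogram of propidium-iodide fluorescence from a co-chopped sample
contains two dominant G1 peaks: the target accession and the internal
standard (soybean, 2C = 2.5 pg).  The estimator is the peak-position ratio
scaled by the standard's 2C; it is invariant to any linear rescaling of the
fluorescence axis.

**Peak fitting.** The instrument software used for the original
measurements is not specified, so peak statistics are computed here as:
moving-average smoothing (default 5 bins), local-maximum candidates above a
noise floor (default 5% of the smoothed maximum), greedy selection of the
tallest candidates at least 10 bins apart (suppressing noise twins on a
peak's flank), then a least-squares Gaussian fit over ±3 half-widths at
half height.  The fitted mean is the peak statistic; CV = 100·σ/µ.
Parameter-recovery tests show the generating 2C is recovered within 1% for
CV ≤ 3% with 5,000 nuclei per peak, the nuclei count used per measurement.

**Replicate aggregation.** Three plants per accession, each measured three
times: plant means are computed first, and the accession mean and sample SD
are taken across the three plant means.  The monoploid genome size is
1Cx = 2C/2 × 978 Mbp, rounded half-up to an integer (plain banker's
rounding would mis-round values ending in .5, which occur in this panel).

**Letter grouping.** All-pairwise t statistics use the pooled one-way-ANOVA
error MS; p-values are Bonferroni-multiplied and compared with the
familywise α = 0.01.  The compact letter display uses insert-and-absorb in
ascending order of group mean: two accessions share a letter iff their
pairwise test is non-significant (verified against the brute-force pairwise
test matrix).

When only published means and SDs are available, per-plant values are
reconstructed as the deterministic triplet {m − s′, m, m + s′}, whose
sample mean is m and sample SD exactly s′.  The published "mean ± SD"
column is read as the SD of all nine individual measurements, so the three
plant means carry s′ = s/√3; the alternative reading (SD of the three plant
means, s′ = s) is available via `reconstruct_plant_means(..., sd_of=
"plant_means")`.  The measurement-SD reading was adopted because it is the
only one under which the named test approaches the published grouping: it
yields 11 letter groups on the bundled panel, one fewer than the published
12, while the plant-mean reading yields 9.  The residual gap is expected —
the exact per-plant values are not recoverable from two printed digits.

**Correlation.** Spearman's correlation uses average ranks for ties
(chromosome number takes only three values here) and Pearson's formula on
the ranks.  For the two accessions whose chromosomes could not be counted,
the analysis imputes the section-typical 2n = 20 (both are Callimusa
species outside the *M. beccarii* group, whose members uniformly have
2n = 20); with this panel of 21 the correlation is −0.88.  Omitting the two
uncounted accessions instead gives −0.86.

## SSR genotyping

Allele calls are sets of fragment sizes per locus; a single observed size
is treated as homozygous (standard SSR scoring convention).  Binary coding
produces one column per observed locus:allele pair.

Nei's standard distance (1972) is the default: within-accession allele
frequencies weight each carried allele 1/k at a k-allele locus; the
identity terms Jxy, Jx, Jy are averaged over loci scored in both accessions
(pairwise deletion) before the log ratio.  A pair sharing no alleles at any
locus has infinite distance; it is capped (default 10.0) with a warning so
clustering remains computable.  A shared-band (Dice-complement) coefficient
is selectable where band-presence data rather than allele frequencies are
appropriate.

UPGMA uses size-weighted arithmetic-mean linkage (scipy's average linkage)
with leaves at half the merge height, so the dendrogram is ultrametric to
numerical precision; ties are resolved by scipy's deterministic merge
order.  BioNJ serves the ITS arm: neighbor joining with the standard Q
criterion, but with reduced distances combined by a variance-minimizing
weight λ (first-order variances initialised to the distances).  Both are
exact on their respective ideal inputs — UPGMA on ultrametric and BioNJ on
additive matrices — which the property tests exploit.

## ITS analysis

**Delineation.** The 5.8S gene is located by semi-global (infix) alignment
of a reference 5.8S profile (edlib); identity below 70% raises an
annotation failure.  ITS1 is everything upstream, ITS2 everything
downstream.  Canonical 5.8S lengths are 153/155 bp; other lengths are
flagged as deletion-bearing.

**Reference configuration.** The three conserved 5.8S motifs default to
the widely used angiosperm blocks (16, 14 and 10 nt).  The default 5.8S
reference profile is a *synthetic* construct carrying those motifs at fixed
offsets inside designed hairpins, with GC content (54.2%) inside the
functional range; it exists so the pipeline runs self-contained, and real
analyses should substitute a curated profile through `RunConfig`.

**Motif scanning.** Each motif is placed by best ungapped match inside the
5.8S span; mismatches are reported 1-based within the motif (`nt-9 'A'`).
A best match below 70% identity is classed as lost to deletion: spurious
rediscovery of a deleted motif elsewhere in the gene tops out near 60%
identity, while genuinely changed motifs (≤ 3 substitutions) stay at ≥ 80%.

**Folding.** The built-in engine maximizes base pairs (Nussinov dynamic
programme, minimum hairpin loop 3, Watson-Crick + G·U) and, among
count-optimal structures, maximizes stacked pair adjacencies.  The
stacking tie-break matters: plain pair maximization is massively
degenerate, and count-neutral rematchings otherwise fragment or enclose
the true stems.  Helices are chains of nested pairs bridging interior
loops/bulges of ≤ 3 nt per side, kept at ≥ 3 pairs.  ITS2 "forms" when
exactly four helices radiate from the exterior loop; helix II is checked
for an interior loop whose unpaired bases are all pyrimidines and helix III
for TGGT on its 5' arm.  A 5.8S fold "forms" when ≥ 50% of the reference
profile's base pairs (mapped through a global alignment) are recovered.
An MFE backend can replace the engine through the same `FoldResult`
interface; thermodynamically accurate parameterization is out of scope.

**Pseudogene rule.** A copy is a putative pseudogene when any criterion
triggers: ITS2 not formed; 5.8S not formed; 5.8S GC below 48%; ≥ 5 changed
motif positions across M1–M3; or a motif lost to deletion.  The thresholds
are calibrated on the bundled 51-row feature table: the GC floor sits just
below the lowest GC among copies retaining both structures (48.95%), and
the change floor above the largest change count seen in structure-retaining
copies (4), so isolated motif polymorphisms never trigger the call on
their own.  With these defaults the classifier reproduces the published
pseudogene notes for 49/51 rows.  The two exceptions are the 1534 pair,
internally inconsistent in the source table: 1534_type1 is annotated as a
pseudogene although both structures form, while 1534_type2 (ITS2 not
formed, 5.8S GC 46.45%) carries no annotation.  The classifier makes no
attempt to guess the intent behind that pair.

**Type collapsing.** Clone reads cluster by single linkage at ≥ 99%
pairwise identity (edlib global alignment); the consensus is the
per-column majority over reads of the modal length.  The 99% threshold
separates biological ITS types (≳ 1% divergence) from clone/sequencing
errors (~0.1%); the collapse criterion used for the original clone data is
not recorded, so this is a package choice.

**Diversity and trees.** π is the average pairwise proportion of differing
sites with pairwise gap deletion; segregating sites count columns with ≥ 2
non-gap states; haplotypes are exact-match groups.  Jukes-Cantor distances
raise a saturation error at p ≥ 0.75 unless a cap is configured (the
bootstrap uses cap 5.0 substitutions/site so occasional saturated
pseudoreplicates do not abort the run).  Bootstrap supports resample
alignment columns with replacement, rebuild JC + BioNJ per replicate, and
report per-bipartition frequencies on the full-data tree; a single seed
drives the resampling, and replicate trees are discarded after bipartition
counting.  For an alignment of identical sequences every replicate yields
the same zero-length topology, so all supports are trivially 100% — a
degenerate but deterministic outcome.

## Synthetic data: what it emulates and what it does not

The generators define the test conditions for every stage:

* **Histograms** place the standard G1 peak at channel 500 of 1024 (linear
  scale), the sample peak proportionally to its 2C, draw 5,000 nuclei per
  peak (the per-measurement count used for the real panel) with Gaussian
  spread at the specified CV, and optionally add uniform debris.  Not
  modelled: G2/S populations, instrument drift, nonlinearity, or
  debris-shape physics — so passing recovery tests show correctness of the
  estimator, not robustness to every real-world artefact.
* **SSR panels** plant group structure through group-private core alleles
  (within-group sharing 0.9 by default) with a fraction of conserved loci
  shared across groups (0.05); they do not model mutation processes,
  allele-size homoplasy or scoring error.
* **ITS families** build a functional template — ITS1 of 219 nt at 61% GC,
  the 155-nt reference 5.8S, and a designed 210-nt ITS2 whose four stems
  are C-backbone arms with helix-specific G "poison" offsets joined by
  inert all-A linkers (helix II carries a C·C mismatch, helix III the TGGT;
  stems of 14–24 pairs, loops of 5 nt).  The poison offsets make any
  cross-helix pairing strictly lose pairs, so the designed four-helix fold
  is the unique optimum of the folding engine.  Types derive from the
  template by motif substitutions, helix III arm scrambles (re-drawn until
  the fold is verifiably broken, so the planted truth holds for every
  seed), GC erosion of the 5.8S, 5.8S deletions, and neutral ITS1
  divergence marking each type; reads add uniform substitution errors
  (default 0.1%).  Lengths respect the observed envelopes (ITS1 215–223,
  ITS2 205–218, 5.8S 153/155).  Not modelled: indel sequencing errors,
  PCR chimeras, coalescent-realistic divergence — recovery results
  demonstrate the pipeline's logic, not its performance on noisy real
  clone libraries.

All generators are deterministic under a fixed seed.

## Problem sizes

The bundled analyses run on the 21-accession table and 51-row ITS feature
table directly.  Synthetic experiments use 2×5-accession SSR panels over
19 loci, 28-read clone families with up to 4 planted types, and bootstrap
panels of 6–8 sequences at 100 pseudoreplicates; the full test suite and
the acceptance script each complete in well under a minute on one CPU.

## Known limitations

* The consensus step assumes substitution-dominated read error; families
  with frequent indel errors would need a proper multiple alignment.
* The compact letter display reports one valid minimal letter assignment;
  other letterings of the same non-significance graph exist.
* Published-panel reconstructions (triplets from mean ± SD) can approach
  but not exactly reproduce statistics computed on the unpublished raw
  measurements; the letter-group count is the visible consequence.
* The classifier's thresholds are calibrated to one published table and
  are exposed as configuration for transfer to other clades.
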