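# Methods

## Problem

Somatic variants at ~1% allele fraction sit below the raw error floor of
short-read sequencing (base-calling errors ~1e-3/base, PCR errors
accumulated over ~30 cycles). Molecular barcodes (UMIs) attached to each
original DNA molecule before amplification let every read be traced back to
its source molecule, so sequencing errors — which hit individual reads — can
be separated from true variants — which appear on every read of a molecule.
`umicall` scores this barcode-grouped evidence with a Bayesian model rather
than collapsing each barcode to a consensus sequence first, so read-level
quality information is never discarded.

## The model

At a target locus the allele space Θ contains the nucleotides observed at
the locus, every distinct observed indel allele, and always the reference
allele; the prior over Θ is uniform. For the family of read pairs sharing
barcode k, the likelihood of the observed bases given true allele X is
approximated by a weighted sum of two error channels:

    P(BC_k | X) ≈ α · C_p · Π_{Y∈Θ} Π_{i=1..n_Y} e_{(Y)i}^{1−1[Y=X]} (1−e_{(Y)i})^{1[Y=X]}
                + (1−α) · Π_{Y∈Θ} Π_i (1−e_{(Y)i}) · min_{Y∈Θ∖{X}} 10^{−6(0.5+n_Y)/Σ_{Z∈Θ}(0.5+n_Z)}

where `e = 10^(−q/10)` is the Phred-derived base-calling error probability,
`n_Y` the family's read count of allele Y, `C_p = 3e-5` the probability of a
PCR error over the whole amplification (30 cycles × 1e-6 per cycle per
base), and α = 0.5 weighs the two channels (the posterior is invariant
between α = 0.5 and an unweighted channel sum, which the tests verify).
The first channel says discordant reads are independent sequencing
miscalls; the second says no base was miscalled and a PCR error explains
the discordant reads, with a pseudo-count of 0.5 regularizing the heuristic
exponent. The `min` term is written over all competing alleles including
indels; the published form over {G,T,C} is its SNV special case.

Posteriors follow by Bayes rule; the locus-level *prediction index* of
allele A over N families is

    I(A) = −Σ_{k=1..N} log10(1 − P(A | BC_k)),

the log-scale probability that at least one molecule truly carries A. A
non-reference allele with I(A) at or above the preselected threshold is a
candidate variant.

Numerical choices: all likelihoods are evaluated in log space;
`1 − P(A|BC)` is computed from the log-likelihoods of the competing alleles
(never as `1 − p` in floating point), and floored at `posterior_clamp`
(default 1e-6) so one molecule contributes at most 6 index units. A family
whose every allele is contradicted by a Q0 read degenerates to the uniform
prior. Ties in the `min` term are value-identical, so no tie-break is
needed; allele ordering (A < C < G < T < indel tokens by string) is fixed
for deterministic output. If Θ has a single allele the PCR channel's `min`
over the empty set is taken as 1 (there is no competing allele to blame).

## Pileup construction

Reads are pre-filtered (MAPQ ≥ 17 by default; unmapped, secondary,
supplementary, QC-fail, duplicate, and optionally non-proper-pair records
rejected). Base observations below Q20 are dropped individually. Barcodes
come from an alignment tag (MI, falling back to BX) or a read-name suffix.
Overlapping mates are consolidated to one vote per read pair: agreeing
mates keep the higher quality, disagreeing mates are discarded. A read
whose CIGAR places an insertion or deletion immediately after a base
reports the indel allele (anchored VCF-style at that base) instead of the
matched base. Within each target region, barcodes within Levenshtein
distance 1 are merged directionally — into the higher-count barcode when
`count_major ≥ 2·count_minor − 1`, transitively outward from the
highest-count seed — which conserves total read count and never increases
the number of barcodes. Clustering is per region, since identical barcodes
on different amplicons are distinct molecules.

## Post-filters

Candidates are annotated (never deleted) with any failed filter label:

* **StrongBarcode** — fewer than m = 2 barcodes with per-barcode evidence
  ≥ τ = 2.0 index units. A single molecule, however convincing, can be a
  first-cycle PCR error.
* **StrandBias** — two-sided Fisher exact test on the 2×2 ref/alt ×
  forward/reverse table of *barcode* counts (barcodes, not reads, are the
  independent units). Fails only when p < 1e-5 **and** the alt
  forward:reverse ratio (0.5 continuity correction) is beyond 5-fold in a
  direction the reference does not share. First-cycle errors and DNA damage
  are strand-asymmetric; real variants are not.
* **Homopolymer / LowComplexity / Repeat** — the variant lies in or adjacent
  to a single-base run ≥ 8; the ±50 bp window has overlapping-dinucleotide
  Shannon entropy < 1.0 bits; or ≥ 80% of the window is covered by a tandem
  repeat of period 2–6 (exhaustive scan; homopolymer tracts are left to the
  homopolymer label rather than double-counted as period-2 repeats).

All post-filter parameterizations are reconstructed defaults — the original
tool's exact thresholds are not public — and every one is exposed in
`FilterConfig` and the key=value config file.

## Cutoff recommendation and detection limits

The optimal prediction-index cutoff grows linearly with barcode depth x;
the published fits are `y = 14 + 0.012x` (20 FP/Mb), `y = 15 + 0.0092x`
(50 FP/Mb) and `y = 13 + 0.0088x` (100 FP/Mb), with the integer cutoff
being the ceiling of y (ceiling is the unique rounding consistent with all
21 published table cells). No interpolation is offered for other rates.

The detection limit f* at a locus with barcode depth d, in a run with
average depth D, is the smallest allele fraction such that
`P(X ≥ k) ≥ 0.95` for `X ~ Binomial(d, f)`, where `k = ceil(cutoff / Ī)`
variant barcodes are needed and Ī ≈ 3.5 is the typical index contribution
of a well-supported variant molecule. Solved by bisection (the tail is
increasing in f) to 1e-5 and cross-checked in the tests against a
brute-force 1e-4 grid scan of the exact binomial tail.

Which depth feeds the cutoff and which feeds the binomial is genuinely
ambiguous in the source description: the formula as printed takes the
cutoff from the *locus* depth and samples from the *run-average* depth,
while the prose twice describes the opposite (a deeper run demands a
stricter cutoff; a deeper locus has more power). The default
(`convention="narrative"`) follows the prose — cutoff from D, sampling from
Binomial(d, f) — and `convention="literal"` reproduces the printed formula.

## Simulator

The generator's defaults are the observed conditions of the benchmarked
runs: mean barcode depth 3612, mean rpb 8.6, 30 PCR cycles, 1e-6
per-cycle-per-base polymerase error, 1e-6 first-cycle error, constant Q30
qualities. Per locus: molecule count ~ Poisson(D); each molecule carries
the alt with probability f; a first-cycle error replaces the molecule's
allele (all reads inherit it — deliberately reproducing the detection floor
that consensus cannot correct); read-pair count ~ 1 + Poisson(rpb − 1)
(floor 1); each read passes a later-cycle PCR error stage
(cycles × rate) and a base-calling error stage (10^(−q/10)), each
substituting uniformly among the other three bases; strand is
Bernoulli(0.5) per molecule (reads of one molecule share an orientation
under single-primer enrichment). Substitution errors are not applied to
reads carrying indel alleles — an indel call at the locus is not undone by
a nearby miscalled base — which slightly favors indels; at the simulated
error rates the effect is < 1e-3 per read.

Two granularities share these distributions. The read-level path
materializes every read and feeds the full pileup → model → filters → VCF
pipeline. The composition-level path (`simulate_locus_indices`) draws
family *compositions* directly — the count of pure-reference families per
size n is multinomial, single-error families are split uniformly over the
three non-reference bases, and the rare multi-error, variant and
first-cycle-error families are drawn individually — and scores them with
evidence weights computed by the real model on explicitly constructed
families, cached per composition (the posterior depends on nothing else).
This path makes a half-megabase wild-type false-positive scan at barcode
depth 3000 run in seconds; the two paths are cross-checked for agreement
in the test suite. The family-size distribution is truncated at the
1 − 1e-12 Poisson quantile and renormalized.

Downsampling (reconstructions; the original procedures are not public):
barcode downsampling keeps each family independently with the given
probability (families are never split); rpb downsampling keeps each read
pair with probability p and re-instates one random read pair in emptied
families, with p solved on the empirical family-size distribution so the
expected mean lands on the target despite the floor.

What a green simulation test does *not* establish: the simulator has no
alignment errors, no position-dependent quality decay, no GC or
amplification bias, no DNA damage, and its truth variants are isolated
(no nearby-variant interference). Sensitivity and FP rates measured on it
characterize the statistical model under its own assumptions, not
performance on real libraries.

## Evaluation

Calls and truth match on normalized (contig, position, ref, alt) after
suffix-then-prefix trimming; haplotype-aware comparison of complex
representations is out of scope. Sensitivity = TP/(TP+FN), FP/Mb scaled by
the target size, PPV = TP/(TP+FP), one row per swept threshold.

## Known limitations

* The post-filter thresholds are reconstructed, not calibrated on real data.
* Germline diploid genotyping, tumor/normal paired calling and multi-sample
  joint calling are out of scope.
* Duplex (two-strand) barcode pairing is not implemented; the strand-bias
  filter is the population-level stand-in.
* The cutoff fits are used as published; no refitting from new downsampling
  runs is provided.
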