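# Methods

## Coordinate conventions

All coordinates are 0-based and half-open, internally and in BED output.
Codon indices are relative to `cds_start` on the transcript's codon grid:
codon 0 is the start codon, codon `L−1` the stop; negative indices address
the 18-nt (6-codon) UTR extension used to admit initiating and
terminating ribosomes. The field's 1-based "footprint position 16–18" and
"17–19" become the 0-based 5′-end offsets 15 and 16 used throughout.

## Site assignment

A footprint's reading frame is `(five_prime − cds_start) mod 3`. Frames 0
and 2 ("frame −1") have defined A-site offsets; frame +1 (3% of reads in
the default generator) has none and is discarded from site-level analyses
while remaining in QC tallies. Both offset formulas yield exact integer
codon indices in their frame, so the assignment is arithmetic, not a
search; a per-read brute-force oracle (locate the A-site nucleotides,
then floor-divide onto the codon grid) is kept in the test suite and must
agree exactly.

Short (21–22 nt) footprints use the same 5′-anchored offsets as long
footprints: no separate short-footprint offset is established for this
pipeline, and a single anchored rule keeps the assignment testable
against the generator, which inverts the same rule when emitting reads.
Assignments beyond the 6-codon UTR extension are dropped.

Two "long" ranges exist on purpose: occupancy/profile analyses use
29–31 nt (the dominant human lengths), while count matrices use the wider
28–32 nt gel range. `assign_sites` takes the range as a parameter; the
`counts` command assigns with 28–32.

## Density, metagene and confidence intervals

Per-gene normalization divides each codon's A-site count by the gene's
mean count, so mean density is exactly 1 for any gene with reads — this
conservation is asserted to 1e-9 and makes every downstream average
scale-invariant (duplicating a gene's reads changes nothing). The
metagene profile averages densities across genes with more than 64
assigned footprints and at least 200 codons (and at least `window`
codons, so every gene contributes every offset). The 95% interval at each
offset is the normal approximation `mean ± 1.96·SE` across genes, which
is adequate at the gene counts (hundreds) where the profile is meaningful.

## Codon occupancy

Occupancy renormalizes density over the retained window (codons 15 to
L−5 by default) before averaging, so the position-weighted mean occupancy
is exactly 1 by construction. The exclusion zones keep start/stop
accumulation out of codon preferences, mirroring the first-15-codon
exclusion used for count matrices. P- and E-site occupancy relabel each
position's density by the codon one or two positions upstream rather than
re-binning reads; the A-site density at position `j` *is* the density of
the ribosome whose P-site reads codon `j−1`. Codons with no contributing
positions are reported missing (NaN), never zero; under the default
exclusions stop codons have no positions and show as missing rows, and
comparisons drop them (and any missing codon) pairwise. Comparisons use
Pearson correlation on untransformed occupancies and report
`sign(r)·r²`, since plain R² cannot express the anti-correlated contrasts
that motivate the signed form.

## Wave profiles

For each occurrence of the query codon at position `k` in a passing gene
(occurrences within 20 codons of either ORF end are skipped), the profile
collects `D_i,(k+d)` for offsets `d` in [−20, 100] and averages across
occurrences; overlapping occurrences all count independently. The window
and edge exclusion are this package's reconstruction — they cover the
reported extent of inhibitor-induced waves (tens of codons) while keeping
anchors clear of start/stop effects. Under the generator's multiplicative
wave, the measured peak undershoots the injected kernel maximum slightly
(≈1.42 measured vs 1.45 kernel at α=0.5, τ=10) because the per-gene
normalization divides by a mean that the wave itself inflates; this is a
property of the estimator, shared with the field's practice of plotting
relative enrichment.

## Counting

Gene counts include footprints whose A-site codon lies in
`[exclude_first, L)`; 5′-UTR counts use `a_site_codon < 0`, i.e. UTR
membership is decided by the A-site, not the 5′ end, consistent with
every other site-level analysis. The differential test itself is out of
scope: the matrices are integer, uniquely labelled, and DESeq2-ready.

## The synthetic generator

The generator is the package's oracle: per gene `i` and codon `j` it
builds a dwell intensity `λ_ij = w_c · r(j) · s_start · s_stop · wave`,
draws A-site positions multinomially with probability ∝ expression ×
λ, then attaches footprint class (P(long)=0.8 by default), length
(uniform over 29–31 / 21–22 nt), and 5′-end frame (0.87/0.10/0.03),
finally inverting the assignment offsets to place the 5′ end. It emits
per-read truth (true A-site, class, frame) and the closed-form expected
density `λ_j·L/Σλ`, so estimator output can be compared to analytic
truth, not just to another sampler. Reads that would overhang transcript
ends are redrawn and counted (the default 60/30-nt UTRs make this rare
to impossible).

What it deliberately does **not** model: kinetic elongation and ribosome
interference, mRNA structure, tRNA pools, ligation/PCR bias, sequencing
errors, isoform ambiguity. Waves are a static multiplicative kernel
`1 + α·exp(−d/τ)` over the `D` codons downstream of each target
occurrence — sufficient to test detection and recovery, not a mechanism
model. Passing tests therefore demonstrate estimator correctness under
the stated statistical structure, not robustness to the full mess of
real libraries.

Defaults are chosen as plausible study conditions: ORFs uniform 200–600
codons with 60-nt 5′ UTRs, log-normal expression (σ=1), 80% long
footprints, 87/10/3% frame emission (the in-frame fraction reported for
stringently digested human libraries), 1% UTR dwell mass.

## Calibration problem sizes

The deep validation runs (test suite and `scripts/acceptance.py`) use
500 genes of 200–300 codons with equal expression, sampled at 2,000,000
long footprints. These sizes follow from the Monte-Carlo error budget:
the metagene mean has `Var(A_j) = (1/N²)·Σ_i L_i/n_i` under near-Poisson
counts, giving SD ≈ 0.011 at these conditions, so the flat-model profile
stays within 0.05 of 1 across all 400 start/stop offsets with large
margin; broad expression dispersion or long ORFs at the same total depth
would inflate the per-gene variance term without testing anything
additional. The comparison-calibration runs use 100 pairs of independent
20-gene, 30k-read flat libraries — occupancy noise level is irrelevant
to the null p-value distribution being checked, so these are kept small.

## Numerical and degenerate-input choices

- Zero-read genes yield all-zero density with a flag; genes with reads
  only inside exclusion zones are skipped in occupancy.
- Empty alignment tables give all-zero QC summaries with a logged
  warning; "no passing genes" and "no usable occurrences" are hard
  errors naming the filters.
- Adapter search is the left-most exact occurrence (synthetic reads are
  error-free); inserts outside 15–35 nt are dropped and counted. The
  15-nt floor is configurable — the minimum informative insert is not
  standardized.
- Adapter-less reads are dropped and counted by default;
  `require_adapter=False` passes them through unchanged, making
  re-clipping idempotent.
- The exact mapper requires a unique match across the entire transcript
  set; multi-mappers and no-hits are counted separately. It is built for
  synthetic-scale data (string search over a concatenated transcript
  text), not for genomes.
- All TSV output uses fixed float formatting; identical configs produce
  byte-identical files end to end.

## Known limitations

- Occupancy is a positional average of per-gene normalized density; an
  expected-frequency-normalized variant is not implemented.
- No offset calibration from periodicity: offsets are fixed by the frame
  rules, which is the point of this pipeline but unsuitable for
  libraries whose digestion deviates from that geometry.
- No smoothing of profiles and no isoform-level aggregation.
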