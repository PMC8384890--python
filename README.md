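# riboprof

Codon-level analysis of ribosome-profiling (Ribo-seq) libraries, built
around the two footprint size classes produced by translating ribosomes
(short, 21–22 nt; long, ~28–32 nt) and frame-dependent A-site assignment
— plus a ground-truth synthetic footprint generator so every stage of the
pipeline can be validated against a known generative model.

It is aimed at people who work with ribosome footprints in transcript
coordinates and want reproducible, testable versions of the standard
codon-resolved analyses:

- **Length/frame QC** — per-length read counts and the fraction of 5′
  ends in each reading frame (high in-frame fractions indicate stringent
  nuclease digestion and allow confident site assignment).
- **A/P/E-site assignment** — footprints whose 5′ end lies in frame 0
  decode footprint nucleotides 16–18 in the ribosomal A-site; 5′ ends in
  frame −1 decode nucleotides 17–19. In 0-based transcript coordinates
  the A-site codon index is `(five_prime − cds_start + 15) / 3` (frame 0)
  or `(+16) / 3` (frame −1); frame +1 footprints carry no defined offset
  and are discarded. P- and E-sites trail the A-site by one and two
  codons.
- **Per-gene density and metagene ramp** — footprint counts `F_ij` at
  codon `j` of gene `i` are normalized by the gene's mean coverage,

      D_ij = F_ij / ((Σ_j F_ij) / L_i),

  and averaged at each aligned offset over the `N` well-expressed genes
  (>64 reads, ≥200 codons),

      A_j = (Σ_i D_ij) / N,

  exposing the 5′ translation ramp and start/stop accumulation.
- **Codon occupancy** — the mean normalized density over all positions
  presenting a given codon in the A-, P- or E-site, transcriptome-wide;
  conditions are compared by signed R² (`sign(r)·r²` of the Pearson
  correlation over the 61 sense codons), keeping the sign because some
  treatment contrasts anti-correlate.
- **Wave profiles** — mean relative enrichment `D_i,(k+d)` at offsets `d`
  around every occurrence `k` of a query codon, the diagnostic for
  elongation-inhibitor artifacts that pile ribosomes up downstream of
  specific codons (e.g. CGA in budding yeast).
- **Count matrices** — gene-level and 5′-UTR integer counts (first 15
  codons excluded by default) ready for DESeq2-style differential
  translation analysis.

The synthetic generator emulates the statistical structure these
analyses assume — bimodal footprint lengths, dominant-frame 5′ ends,
codon-specific dwell weights, a 5′ ramp, start/stop accumulation,
injectable downstream waves, and a small 5′-UTR dwell mass — and emits
per-read and per-codon truth tables alongside FASTA/BED/FASTQ outputs.

## Worked example

```python
from riboprof import (SimulationConfig, simulate_transcriptome, simulate_footprints,
                      assign_sites, frame_length_qc, metagene_profile,
                      codon_occupancy, compare_occupancy, wave_profile)

cfg = SimulationConfig(seed=42, n_genes=200, orf_min_codons=200, orf_max_codons=400,
                       total_footprints=1_000_000, dwell_sigma=0.3,
                       ramp_amplitude=1.0, ramp_tau=50.0)
tx = simulate_transcriptome(cfg)
sim = simulate_footprints(tx, cfg)
aln = sim.alignments[["transcript_id", "five_prime", "length"]]

qc = frame_length_qc(aln, tx)
long_rows = qc.table[qc.table["length"].isin([29, 30, 31])]
frac0 = (long_rows.frac_frame0 * long_rows.n_framed).sum() / long_rows.n_framed.sum()
print(f"long footprints in frame 0: {100 * frac0:.1f}%")

assigned = assign_sites(aln, tx).assignments
print(f"assigned {len(assigned)} of {len(aln)} footprints to A-site codons")

ramp = metagene_profile(assigned, tx, anchor="start", window=200, footprint_class="long")
print(f"metagene ramp: A_1 = {ramp.values[0]:.2f}, A_200 = {ramp.values[199]:.2f} "
      f"(N = {ramp.n_genes} genes)")

occ_long = codon_occupancy(assigned, tx, site="A", footprint_class="long")
occ_short = codon_occupancy(assigned, tx, site="A", footprint_class="short")
res = compare_occupancy(occ_long, occ_short)
print(f"long vs short A-site occupancy: signed R2 = {res.signed_r2:.2f} "
      f"(p = {res.p_value:.2g}, n = {res.n_codons} codons)")

wave = wave_profile(assigned, tx, "CGA", footprint_class="long")
print(f"CGA wave profile: enrichment at d=1 is {wave.enrichment[21]:.2f} "
      f"({wave.n_occurrences} occurrences)")
```

Output:

```
long footprints in frame 0: 87.0%
assigned 970060 of 1000000 footprints to A-site codons
metagene ramp: A_1 = 1.35, A_200 = 0.91 (N = 200 genes)
long vs short A-site occupancy: signed R2 = 0.99 (p = 5.3e-57, n = 61 codons)
CGA wave profile: enrichment at d=1 is 0.95 (846 occurrences)
```

The 87.0% in-frame fraction recovers the configured frame-0 emission
probability; 3% of footprints (frame +1) are dropped at assignment. The
ramp starts at 1.35× the gene average and decays below 1 by codon 200,
reflecting the programmed `1 + exp(−j/50)` ramp after per-gene
normalization. Long and short footprints see the same dwell weights in
this model, so their A-site occupancies agree (signed R² = 0.99), and
with no wave injected the CGA profile stays at ~1.

The same stages are available on files from a shell:

```bash
riboprof simulate --config sim.json --out lib/
riboprof qc      --bed lib/footprints.bed --fasta lib/transcripts.fa --annot lib/annotation.tsv
riboprof assign  --bed lib/footprints.bed --fasta lib/transcripts.fa --annot lib/annotation.tsv
riboprof ramp    --bed ... --anchor start --window 200 --min-reads 64 --min-len 200
riboprof waves   --bed ... --codon CGA --dmin -20 --dmax 100
riboprof occupancy --bed ... --site A --class long
riboprof counts  --bed ... --class long --exclude-first 15
```

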