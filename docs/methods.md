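# Methods

## Model and procedure

The caller operates on properly-paired, MAPQ ≥ 60, match-only (M-CIGAR)
alignments of a PCR-free ~150 bp-insert paired-end library. Each read
pair is reduced to a *fragment observation*: its (contig, start, end)
footprint, the per-position base calls of both mates, and its strand of
origin, inferred from read 1's orientation (read 1 forward ⇒ the insert
derives from the reference-forward strand). Because the library is
PCR-free, two fragments with identical coordinates on opposite strands
are taken to be the two strands of one original duplex molecule; a
*consensus read group* is formed exactly when a fragment key holds two
such fragments (four reads). Keys with one fragment, two same-strand
fragments, or three or more coincident fragments form no group and are
counted in diagnostics.

At every group position the four calls are compared. Unanimous reference
⇒ the position is *analysed*; unanimous alternate ⇒ analysed plus a
candidate mutation; anything else (including positions some read does not
cover) is excluded from numerator *and* denominator — a disagreeing
position is neither confirmed reference nor confirmed variant, and
excluding it from both keeps the frequency unbiased. Under i.i.d.
per-read error *e* a false unanimous alternate arises with probability
3·(e/3)⁴ = e⁴/27 per covered position; this is the quantity the error-
suppression checks measure (the denominator is all consensus-covered
positions, not just analysed ones, matching the analytic formula's
unconditional form).

The analysed-base denominator is summed per group: two overlapping groups
that both interrogate a locus count it twice. It is a throughput measure
(how much duplex evidence was examined), not a genomic footprint.

### Filter chain

Stages run in a fixed order; each is a pure set reduction and reports
input/removed/surviving counts.

1. **Bulk-variant exclusion.** A frequency-threshold caller over the
   full (non-subsampled) read set blacklists (pos, alt) sites with
   ≥ `bulk_min_support` (default 2) supporting reads *and* a supporting
   fraction ≥ `bulk_min_fraction` (default 0.25) of the all-read depth.
   The fraction term is essential: a duplex-confirmed mutation always has
   its own four reads in the full pileup, so a pure count threshold would
   blacklist every true call. Inside the default depth window the
   self-support fraction is at most 4/31 ≈ 0.13, while germline alleles
   sit near 0.5 (het) or 1 (hom); 0.25 separates the two regimes.
2. **Depth window.** Candidates are kept only where the all-read depth is
   strictly between `depth_low` = 30 and `depth_high` = 100 ("more than
   30 and less than 100" read strictly). Mates are counted separately.
3. **Group mutation count.** Groups proposing more than
   `max_group_mutations` = 2 surviving candidates are discarded wholesale
   (mismapped or chimeric molecules). The tally counts survivors of stage
   2; the alternative pre-depth tally is reported as a diagnostic.
4. **External support.** A candidate carried by any read outside its own
   group's four reads is discarded — the backstop against germline
   alleles that slipped past stage 1.

The denominator passes through the chain unchanged by default.
`strict_denominator=True` restricts it to analysed positions inside the
depth window, matching the numerator's constraint; this is off by default
because the headline frequencies divide by total analysed bases.

Fragment subsampling (default 10%, the published operating point for
bounding compute on deep libraries) happens before grouping, at the
fragment level (a read pair is kept or dropped whole). Depth and bulk
variants always come from the full retained read set. The desk-scale
simulated runs in `peccseq.scenarios` set the fraction to 1.0 — the
libraries are already small — while the germline-rejection scenario keeps
the 10% default to exercise it.

### Statistics

Mutation frequency is the exact ratio mutations/analysed bases. Group
averages are the arithmetic mean of per-sample frequencies by default
(the convention of the summary tables this mirrors); pooled
Σmut/Σbases is available and always reported alongside. CV uses the
n−1 sample standard deviation. The group comparison is a one-sided
two-sample equal-variance Student's *t* (alternative: treated > control),
df = n₁+n₂−2. Cross-assay agreement is the squared Pearson correlation
of the simple least-squares line.

SBS96 classification collapses purine-centred substitutions onto the
pyrimidine strand (flanks complemented and swapped); categories follow
the conventional order (C>A, C>G, C>T, T>A, T>C, T>G × 4×4 flanks).
Per-category frequencies are normalised by *total* analysed bases, so the
96 frequencies sum exactly to the overall mutation frequency;
per-context-opportunity normalisation is deliberately not the default and
is left to the caller via the counts. Mutations at contig edges (no full
3-mer) are excluded from spectra and counted. Six-class summaries use
base-pair notation (T>A ≡ A:T>T:A, etc.). Fold changes default to ratios
of group-average class frequencies; a summed-count-ratio mode exists, and
with unequal denominators the two differ exactly by the bases ratio.

## The simulator

What it emulates: i.i.d. reference bases at a configurable GC fraction
(0.415 default, mammalian-like; the gpt transgene regime is ~0.519);
germline SNPs (het carried per molecule with probability 1/2, hom always;
defaults het 10⁻⁴ / hom 10⁻³, an inbred strain mapped against another
strain's assembly); fixed-length 150 bp fragments (optional Gaussian
jitter) uniform over the genome; duplex yield (probability both strands
are sequenced, default 1; single-strand families exercise the
no-consensus path); optional coordinate-coincident independent molecules
(off by default — PCR-free coincidence is assumed to imply a shared
molecule, and the confounder is only enabled to stress the grouping
rules); strand-private lesions at a per-strand-base rate; and i.i.d.
substitution sequencing error with uniform choice among the three
alternatives. Reads are emitted truth-aligned (MAPQ 60, proper-pair
flags, Q37 placeholder qualities — the pipeline never reads qualities) so
no aligner is involved; FASTQ is also written for users who want to run
one.

Somatic planting is a per-molecule Poisson process whose per-position
rate is proportional to signature[class]/N(context), where N(context) is
the genome-wide abundance of the position's collapsed trinucleotide
context. This makes the planted 96-category distribution equal the
signature exactly (not the signature modulated by genome composition)
while keeping the expected rate at `target_frequency` per base, which is
what makes "recovered spectrum vs planted signature" a well-posed
comparison. The mutagen-like preset puts 70% of mass on T>A, 12% on
T>G, 10% on T>C and 8% on the C-centred classes, uniform within class.

What it does not model: PCR amplification and duplicate families, indels,
quality-score error profiles, mapping error/clipping, GC-coverage bias,
fragment-end artefacts beyond the optional end-trim, and correlated
(context-dependent) sequencing error. Passing tests therefore demonstrate
the correctness of the consensus/filter logic and its statistical
behaviour under the stated generative model, not robustness to alignment
artefacts in real libraries.

## Numerical and design choices

* Coordinates are 0-based half-open internally; SAM/VCF 1-based
  conversion lives in the I/O layer only.
* "MAPQ more than 60" is read as ≥ 60: BWA caps MAPQ at 60, so a strict
  reading would retain nothing.
* Only M-only CIGARs are consumed; clipped/indel reads are dropped and
  counted (substitution-only scope).
* Reference operating points (`peccseq.scenarios`): ~60× raw coverage
  (molecules = genome/10) keeps all-read depth centred in the (30, 100)
  window; the treated arm uses a 4.5 Mb genome / 450 k molecules so that
  several hundred mutations survive the filters (a few hundred draws are
  needed before a 96-bin spectrum's cosine to its generator stabilises
  above 0.95), the control arm 1 Mb / 100 k.
* The t statistic and p-value come from `scipy.stats.ttest_ind`; spectra
  and summaries are plain numpy/pandas.
* Ties and degenerate inputs: empty groups raise; zero analysed bases
  make the frequency undefined (error, not 0); zero-denominator fold
  changes are NaN with a warning semantics ("NA"); CV requires n ≥ 2 and
  nonzero mean.

## Known limitations

* The bulk-variant caller is a frequency-threshold stand-in, not a
  genotype-likelihood caller; with very low depth or allele-fraction
  distortion its separation of germline from duplex self-support
  degrades. A heterozygous site whose every other covering molecule
  happens to lack the alternate allele (probability 2^−(M−1) for M
  covering molecules) is invisible to both the bulk and external-support
  filters; at the reference coverage this is a ≲10⁻³ event per candidate
  and is the dominant residual false-positive mechanism.
* Exact-coordinate grouping requires both fragment endpoints to match;
  real libraries with staggered ends would form fewer groups.
* Overlap of the analysed-base denominator with the depth window is only
  reconciled in `strict_denominator` mode.
* No multi-nucleotide variants, no signature decomposition (NMF/COSMIC
  fitting), no multiple-testing machinery — single planned comparison.
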