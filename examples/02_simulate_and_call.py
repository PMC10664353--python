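"""Simulate a small PCR-free duplex library and call mutations end to end.

A 100 kb genome is sequenced as ~60x of 150 bp duplex fragments with
germline SNPs, a planted T>A-dominant somatic signature at 1e-4 per base,
single-strand lesions and sequencing error — then run through consensus
grouping and the four-stage filter chain.  The truth table lets us score
the calls.
"""

from peccseq import (
    RunConfig,
    SomaticMutationModel,
    call_reads,
    generate_reference,
    plant_germline_variants,
    sequence_fragments,
    simulate_fragments,
)

ref = generate_reference(n_contigs=1, contig_length=100_000, gc_fraction=0.415, seed=1)
germline = plant_germline_variants(ref, seed=2)
model = SomaticMutationModel.den_like(target_frequency=1e-4)
families = simulate_fragments(
    ref, germline, model, n_molecules=10_000, lesion_rate=1e-5, seed=3
)
reads, truth = sequence_fragments(families, ref, error_rate=1e-3, seed=4)
print(f"{len(families)} molecules -> {len(reads)} reads; "
      f"{truth.count('somatic')} somatic mutations planted")

out = call_reads(reads, ref, RunConfig(subsample_fraction=1.0), sample="demo")
res = out.result
print(f"{out.n_groups} consensus groups, {res.analyzed_bases} analysed bases")
for stage in out.report.stages:
    print(f"  {stage.name}: in {stage.n_input}, removed {stage.n_removed}")
print(f"accepted {res.n_mutations} mutations "
      f"-> frequency {res.mutation_frequency:.2e} (planted 1.0e-04)")

somatic = truth.unique_sites({"somatic"})
accepted = {c.site for c in res.accepted}
print(f"true positives {len(accepted & somatic)}, "
      f"false positives {len(accepted - somatic)}")
print("Interpretation: 4-read agreement plus the filter chain recovers the "
      "planted per-base mutation rate while rejecting germline SNPs, "
      "single-strand damage and sequencing errors.")
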