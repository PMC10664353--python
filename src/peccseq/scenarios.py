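"""Canonical synthetic study conditions.

These functions bundle the simulator parameters the package treats as its
reference operating points — a mammalian-like 41.5% GC genome, ~150 bp
PCR-free duplex fragments at ~60x raw coverage, inbred-strain germline
rates, and the two exposure arms of a mutagenicity study: an untreated
control (flat spectrum at 1e-7 mutations/bp) and a mutagen-treated sample
(T>A-dominant spectrum at 1e-5 mutations/bp, the regime a strong liver
mutagen such as diethylnitrosamine produces).  Genome and library sizes
are scaled so the runs complete on a laptop while leaving enough accepted
mutations (several hundred in the treated arm) for spectra to be
statistically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import collect_candidates, form_consensus_groups
from .pipeline import CallOutput, RunConfig, call_reads
from .reference import ReferenceGenome, generate_reference
from .simulate import (
    SomaticMutationModel,
    TruthSet,
    plant_germline_variants,
    sequence_fragments,
    simulate_fragments,
)
from .alignment import pair_reads
from .stats import TrinucleotideSpectrum
from .sbs96 import cosine_similarity

GC_FRACTION = 0.415  # mammalian-genome-like base composition
SEQ_ERROR_RATE = 1e-3  # typical raw short-read substitution error
CONTROL_FREQUENCY = 1e-7
TREATED_FREQUENCY = 1e-5


@dataclass
class ErrorSuppressionRun:
    """Outcome of a pure-error duplex run (no planted variants)."""

    false_alt_agree_rate: float  # alt-agree calls per consensus-covered position
    expected_rate: float  # analytic e^4/27
    mc_sd: float  # Monte-Carlo SD of the observed rate
    analyzed_positions: int
    total_positions: int
    n_false_calls: int


def error_suppression_run(
    seed: int,
    n_molecules: int = 120_000,
    n_contigs: int = 2,
    contig_length: int = 1_000_000,
    error_rate: float = 0.1,
) -> ErrorSuppressionRun:
    """Measure how often all four reads agree on the same wrong base.

    With i.i.d. per-read substitution error e, a reference position is
    falsely called as a unanimous alternate with probability
    3*(e/3)^4 = e^4/27.  The default sizes give >1e7 analysed positions,
    enough to resolve the 3.7e-6 rate at e = 0.1.
    """
    ref = generate_reference(n_contigs, contig_length, 0.5, seed=seed)
    families = simulate_fragments(ref, None, None, n_molecules, seed=seed + 1)
    reads, _ = sequence_fragments(families, ref, error_rate=error_rate, seed=seed + 2)
    fragments, _ = pair_reads(reads)
    groups, _ = form_consensus_groups(fragments)
    pre = collect_candidates(groups, ref)
    total = sum(g.length for g in groups)
    p = error_rate**4 / 27
    return ErrorSuppressionRun(
        false_alt_agree_rate=len(pre.candidates) / total,
        expected_rate=p,
        mc_sd=float(np.sqrt(p * (1 - p) / total)),
        analyzed_positions=pre.analyzed_bases,
        total_positions=total,
        n_false_calls=len(pre.candidates),
    )


@dataclass
class StudySampleRun:
    """One simulated exposure arm, processed end to end."""

    output: CallOutput
    truth: TruthSet
    model: SomaticMutationModel
    planted_frequency: float
    ref: ReferenceGenome

    @property
    def recovered_frequency(self) -> float:
        return self.output.result.mutation_frequency

    def spectrum(self) -> TrinucleotideSpectrum:
        res = self.output.result
        return TrinucleotideSpectrum.from_mutations(
            res.accepted, res.analyzed_bases, sample=res.sample
        )

    def signature_cosine(self) -> float:
        return cosine_similarity(self.spectrum().normalized(), self.model.signature)


def study_sample_run(
    group: str,
    seed: int,
    n_molecules: int | None = None,
    n_contigs: int | None = None,
    contig_length: int | None = None,
) -> StudySampleRun:
    """Simulate and call one study arm at the reference operating point.

    ``group`` is ``"treated"`` (T>A-dominant signature at 1e-5) or
    ``"control"`` (flat spectrum at 1e-7).  Coverage is held at ~60x raw
    reads (molecules = genome length / 10) so the all-read depth sits
    inside the default (30, 100) window; the treated genome is larger so
    several hundred mutations survive the filters.  Consensus grouping
    runs on the full fragment set (no subsampling) — the simulated
    libraries are already desk-scale.
    """
    if group == "treated":
        n_contigs = n_contigs or 3
        contig_length = contig_length or 1_500_000
        n_molecules = n_molecules or 450_000
        model = SomaticMutationModel.den_like(TREATED_FREQUENCY)
    elif group == "control":
        n_contigs = n_contigs or 1
        contig_length = contig_length or 1_000_000
        n_molecules = n_molecules or 100_000
        model = SomaticMutationModel.flat(CONTROL_FREQUENCY)
    else:
        raise ValueError(f"unknown group {group!r}")
    ref = generate_reference(n_contigs, contig_length, GC_FRACTION, seed=seed)
    germline = plant_germline_variants(ref, seed=seed + 1)
    families = simulate_fragments(
        ref, germline, model, n_molecules, seed=seed + 2
    )
    reads, truth = sequence_fragments(
        families, ref, error_rate=SEQ_ERROR_RATE, seed=seed + 3, sample=group
    )
    config = RunConfig(subsample_fraction=1.0)
    output = call_reads(reads, ref, config, sample=group)
    return StudySampleRun(
        output=output,
        truth=truth,
        model=model,
        planted_frequency=model.target_frequency,
        ref=ref,
    )


@dataclass
class GermlineRejectionRun:
    output: CallOutput
    truth: TruthSet
    n_germline_candidates: int
    n_lesion_site_candidates: int


def germline_rejection_run(
    seed: int,
    n_molecules: int = 100_000,
    contig_length: int = 1_000_000,
    lesion_rate: float = 1e-4,
) -> GermlineRejectionRun:
    """No somatic mutations at all: germline SNPs and single-strand
    lesions only, sequenced without error, called at default settings
    (including the 10% fragment subsample).  Everything the pipeline
    accepts here is a false positive."""
    ref = generate_reference(1, contig_length, GC_FRACTION, seed=seed)
    germline = plant_germline_variants(ref, seed=seed + 1)
    families = simulate_fragments(
        ref, germline, None, n_molecules, lesion_rate=lesion_rate, seed=seed + 2
    )
    reads, truth = sequence_fragments(families, ref, error_rate=0.0, seed=seed + 3)
    output = call_reads(reads, ref, RunConfig(subsample_seed=seed + 4))
    germline_sites = truth.unique_sites({"germline_het", "germline_hom"})
    # a lesion can land on a germline site with the same alt by chance;
    # such a site is a legitimate (germline) candidate, so only
    # lesion-exclusive sites measure the 4-read rejection of damage
    lesion_sites = truth.unique_sites({"lesion"}) - germline_sites
    candidate_sites = {c.site for c in output.result.candidates}
    return GermlineRejectionRun(
        output=output,
        truth=truth,
        n_germline_candidates=len(candidate_sites & germline_sites),
        n_lesion_site_candidates=len(candidate_sites & lesion_sites),
    )
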