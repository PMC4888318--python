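# Methods

## Model and assumptions

`uidcall` treats a targeted deep-sequencing experiment as a population of
input DNA molecules, each tagged with a random UID before amplification.
Under the tagging assumption — all reads sharing a UID descend from one
input molecule, up to rare tag collisions — a variant present in the
original molecule should appear in essentially every read of its family,
while an amplification or sequencing error appears in only the subset of
reads descended from the erroneous copy. The caller therefore asks a
per-family question (is the variant concordant within this UID group?)
instead of a pooled one (what fraction of all reads carry it?). This is
what keeps sensitivity flat as the variant molecule becomes arbitrarily
rare: the within-family fraction does not depend on the dilution.

No base-quality model, genotype likelihood or position-specific error
model is used; the only evidence is read counts within families. The
method consequently cannot distinguish a variant present in the input
molecule from an error introduced in the very first PCR cycle (which
propagates to the whole family) — that residual error mode is inherent
to single-strand tagging.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_group_size` | 5 reads | smallest UID family that can vote |
| `min_variant_fraction` | 0.40 | within-family concordance required |
| `min_supermutants_per_group` | 2 molecules | independent families for a super group |
| `min_mean_quality` | Q20 | mean Phred below which a pair is dropped |
| `max_n_fraction` | 0.5 | N fraction above which a pair is dropped |
| `min_adapter_overlap` | 5 bases | shortest adapter prefix trimmed at a read 3' end |
| `min_score_fraction` | 0.6 | aligner score floor, as a fraction of read length |
| `min_base_quality` | 0 (off) | per-mismatch base-quality filter |

Both caller thresholds are inclusive: a 5-read group with 2 concordant
variant reads (40%) passes. The fraction comparison carries a 1e-9
tolerance so that ratios like 2/5 are robust against floating-point
division. All passing alleles in a group are reported, because the 40%
default exists precisely to tolerate two molecules sharing one UID.
Each mate counts as one read in the group denominator; with the default
simulation geometry (mates abutting, variant covered by exactly one
mate) a fully concordant molecule therefore shows a fraction of 0.5.
A `count_fragments` option collapses mates so overlapping pairs cannot
double-count, and `group_per_target` keys groups by (UID, chromosome)
for multi-amplicon panels where cross-target UID reuse is expected.

"Predominantly N" and "low quality" are not precisely defined by the
protocol this workflow supports, so both filters are explicit,
configurable parameters with the defaults above; the N filter's purpose
is to avoid forming UID families out of N-runs, and any pair whose
extracted UID contains an N is dropped outright (`UID_AMBIGUOUS`) rather
than grouped ambiguously. UID tag bases are taken literally as read
bases; no reverse-complementing of 3' tags is attempted, since tagging
chemistry varies and the four-field `UIDConfig` covers placement
variants directly.

## Alignment

The built-in aligner is deliberately minimal: ungapped scoring (+1
match, −1 mismatch) over both strands, which realises "permissive of
mismatches, maximally averse to gaps" exactly — it cannot open a gap at
all. Candidate placements come from exact 20-mer seeds at four evenly
spaced read offsets; by the pigeonhole principle any placement with
fewer than four mismatches is guaranteed to be found. An
`exhaustive=True` mode scores every offset with a vectorised sliding
window and implements the literal best-placement contract; it is the
oracle the seeded path is tested against, and the recommended mode only
for small references. Ties break by (chromosome, leftmost coordinate,
then + strand). Reads scoring below `min_score_fraction × length` are
reported unmapped. Real data should go through a production aligner via
the external command template (`--aligner external --aligner-cmd ...`);
indels in such alignments are handled by the CIGAR walk even though the
built-in aligner never emits them.

Variant identification is a direct comparison of aligned bases against
the reference while walking the CIGAR — the same information a
samtools-calmd/MD-tag round trip yields, computed in-process so the core
path has no external binary. Indels are reported left-anchored with one
reference base of context (VCF convention); no further normalisation
across homopolymers is attempted, a documented limitation that only
matters when comparing indel coordinates against callers that fully
left-align. BED input is 0-based half-open and merged; all reported
positions are 1-based.

## Simulation design

The generator emulates the dilution-series benchmark: a single random
reference slice (default 20 kb; a real chromosome FASTA can be
substituted), 100 bp paired-end reads, 10 bp UIDs realised as five
leading bases on each mate (mate2's 5' end reads the fragment's 3' end,
so this is dual-end tagging), fragments of 190 bp so the two usable
mate inserts abut and every fragment base is sequenced exactly once.
Variant molecules carry one uniform-random SNV (alternate allele
rejection-sampled to differ from the reference) and are duplicated
uniformly in [1, 50]; wild-type molecules are unique (duplication 1),
since PCR duplication is the error process under study for variant
reads. Sequencing error is an optional uniform per-base substitution
rate, default 0.

Dilution is enforced at molecule level: molecules are admitted whole, in
seeded random order, while their duplicates fit the variant-read budget
`round(n_total × (1 − level))`; when the budget at an extreme dilution is
smaller than one family, exactly one whole molecule is admitted and the
realised level is recorded in the truth metadata. Read-level subsampling
would break the very quantity under test (whole-family concordance).

What the simulation does **not** model: PCR chimeras, polymerase error
spectra, quality-score degradation along the read, adapter read-through,
coverage bias, and UID synthesis errors. Passing the synthetic benchmark
therefore demonstrates the grouping logic and its dilution behaviour,
not robustness to those artefacts; on real data the QC filters and an
external production aligner carry that weight.

## Evaluation

A called site matches a truth record on exact (chromosome, position,
alternate allele). False-negative rate is FN/(TP+FN) over truth sites;
false-positive rate is FP over all distinct called sites (0 when nothing
is called). The pooled baseline calls any site whose aggregate allele
fraction reaches 20% at the observed depth, ignoring UIDs — the shared
failure mode of conventional callers on diluted samples, standing in for
running the callers themselves.

## Problem sizes

The acceptance run simulates a wild-type background of 2×10⁵ read pairs
(standing in for a 10⁶-molecule input at the same molecule-level
dilution) on a 20 kb reference, a scale at which the whole pipeline
completes in well under a minute on one CPU; test fixtures use 10²–10³
pairs on 2–20 kb references. These sizes are the package's own choice of
desk-scale defaults; every size is a parameter, and nothing in the
implementation depends on them.

## Numerical and design notes

- Determinism: every generator is a pure function of (config, seed);
  the pipeline itself is deterministic, so reruns are checksum-identical.
- Reports are written to temporaries and renamed, so a file that exists
  is complete; the run log stores SHA-256 checksums of every step's
  inputs and outputs, and `resume` refuses to continue over a stale or
  tampered intermediate, naming the offending step.
- Group size denominator includes variant-free reads of the family —
  required for the reported fraction to mean "fraction of the molecule's
  reads supporting the variant".
- The super-group report carries both the number of supporting molecules
  and their total read count, covering either reading of a recurrence
  "frequency".
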