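# Methods

This note documents the models, conventions and numerical choices behind
`beditscan`, in the order the pipeline stages run.

## Amplicon editing quantification

Reads are aligned to the reference amplicon with a global alignment whose end
gaps are free (reads may be shorter or longer than the amplicon). Scoring is
fixed — match +2, mismatch −3, gap open −8, gap extension −1 — so results
are reproducible across runs; among co-optimal alignments the alignment
library's canonical first path is taken, which is deterministic. Both read
orientations are scored and the better one is used (forward on ties), so
quantification is invariant to whether reads arrive forward or
reverse-complemented. Reads whose identity over aligned columns falls below
0.6 are flagged unalignable and excluded; this is a degenerate-input guard,
not a biological filter.

Protospacer positions are numbered 1–20 from the PAM-distal 5′ end, with the
NGG PAM at 21–23 on the protospacer strand — the field's standard numbering.
The quantification window is the protospacer ± 5 bp. A read "spans" when its
alignment covers the whole window. Editing percentages follow the convention
of dedicated amplicon tools:

* indel % = 100 × (spanning reads with an insertion or deletion overlapping
  the window) / (all spanning reads);
* substitution percentages use only indel-free spanning reads in the
  denominator, so a converted base inside a deletion is never double-counted.

Whether indel reads belong in the substitution denominator is genuinely open;
excluding them was adopted because it keeps the two outcome classes disjoint
and matches the delegated-tool concept most users expect. For candidate
off-target sites the summary statistic is the maximum A→G % over protospacer
adenines; on a minus-strand protospacer this is computed from T→C on the
plus strand.

Group reports give the mean and the sample (n−1) standard deviation; with a
single sample the s.d. is reported as unavailable rather than zero.

## Somatic filter cascade

The cascade consumes site-level annotations (QD, MQ, FS, HaplotypeScore,
MQRankSum, ReadPosRankSum) and per-sample genotype evidence (DP, AD, GQ), not
alignments. Thresholds default to: site quality ≥ 100 (SNV) / ≥ 250 (indel);
depth ≥ 20 in clone and control; MQ ≥ 60; clone GQ ≥ 99 with control GQ ≥ 10
for SNVs and ≥ 99 for both samples for indels; clone VAF ≥ 0.2; copy-ratio
bounds 1.5 < r < 2.5 for the diploid restriction; a 100 bp exclusion radius
around control-called variants for indels; and the classic hard-filter flags
(QD < 2.0, MQ < 40.0, FS > 60.0, HaplotypeScore > 13.0, MQRankSum < −12.5,
ReadPosRankSum < −8.0, cluster of ≥ 3 SNVs within 35 bp).

Conventions that the thresholds alone do not determine:

* "No evidence in the paired control" is read strictly as zero alt-supporting
  reads at the site; a site absent from the control table is rejected under
  its own label (`control-missing`) rather than passed.
* Missing *site annotations* never fire a flag or fail the MQ ≥ 60 rule — a
  record cannot fail on absent evidence — whereas missing *genotype*
  requirements (depth, GQ) in a required sample do fail, because the rule
  demands positive evidence from that sample.
* Each rejected record is tallied under the **first** failing rule in the
  documented order, so passes plus tallied rejections always equals the input
  count. The order is a reporting convention only; the passing set is
  order-independent (a record passes iff it violates no rule).
* The cluster flag uses runs of `cluster_size` consecutive SNVs whose span is
  ≤ `cluster_window` bases (3 SNVs at positions 100/120/134 span exactly 35
  and are flagged).
* Coordinates: variants 1-based; BED regions and copy-ratio segments 0-based
  half-open; a variant at position p is inside an interval when p−1 ∈
  [start, end).
* For the indel proximity rule, any control record carrying alt evidence
  counts as a "called variant", whether or not it would itself pass filters.

Mutation burden is rescaled as raw × L_ref / L_accounted, where L_accounted
is the length of the callable-and-diploid intersection; L_ref is a required
configuration value (the simulated pipelines default it to the full toy
genome length, the analogue of the full autosomal genome).

Detection sensitivity is the fraction of germline heterozygous variants
recovered in a clone, with VAF ≥ 0.3 counting as detected (inclusive bound).
The germline-set quality criteria (quality ≥ 100, GQ = 99, depth ≥ 20
everywhere, heterozygous in all bulks) are the caller's responsibility; the
estimator itself is a per-clone detected fraction.

## 96-class profiles, the TadA signature, and spike-in

Substitutions are collapsed onto the pyrimidine strand: six types (C>A, C>G,
C>T, T>A, T>C, T>G) × 4 five-prime × 4 three-prime flanks = 96 classes, in
substitution-major order with lexicographic flanks. A>G events therefore land
in T>C, which is why the deaminase signature lives entirely on the 16 T>C
classes: the signature constructor pools its components, zeroes any mass
outside T>C (other substitutions are assumed not to contribute to deaminase
activity) and renormalizes to sum 1.

Profiles are made comparable across samples by scaling counts to a common
total of 428 SNVs (the study-scale median mutation load; counts stay
real-valued at this step). Spiking k deaminase SNVs adds
round(k · signature_i) to class i with half-away-from-zero rounding — the
everyday rounding convention, declared so tests can be exact; the realized
total may differ slightly from k (a uniform 96-class signature at k = 100
adds 96, one per cell). The adopted operation order is scale → spike →
score. Similarity is the plain cosine, scale-invariant by construction, so
scoring before or after normalization is equivalent; the scaling matters only
for the spike-in counts themselves.

The concrete TadA component spectra are data from prior deep-sequencing work
and are not shipped; the package accepts user-supplied 96-class TSVs and
provides a synthetic T>C-only stand-in (a seeded Dirichlet over the 16 T>C
cells, concentration 10 by default — concentrated enough to be non-uniform,
diffuse enough to cover all 16 contexts).

## RNA A-to-I filter

Three rules, thresholds computed once per experiment: control coverage
strictly above ("above" read literally as >) the nearest-rank 90th percentile
of treated coverages (value at rank ⌈q/100 · n⌉ of the sorted list —
nearest-rank is exact on integer coverages, making tests deterministic);
control reference fraction ≥ 0.99, using all non-reference reads in the
denominator (the stricter reading); treated depth ≥ 10. Without transcript
annotation the strand is unknown, so both A>G and T>C count as A-to-I among
passing sites.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the stages consume, at
toy scale, with every random draw controlled by one integer seed:

* **Reference genomes** are i.i.d. base sequences with adjustable GC content
  on contigs of 10⁴–10⁶ bp. The filters act per record, so small contigs
  stand in for chromosomes; "autosome" is a declared name subset.
* **Clone/bulk tables** draw each SNV's 96-class from
  background_weight · uniform + tada_weight · signature and place it at a
  genome position carrying that trinucleotide context on either strand.
  Clone alt counts are set to ⌈depth · VAF⌉ at a clonal VAF of 0.5; depths
  are negative-binomial (mean 30, dispersion 10 — the study's WGS coverage
  scale with moderate overdispersion), truncated at the 20× threshold for
  records meant to pass so that truth labels are exact rather than
  probabilistic. Site qualities are drawn from ranges that clear the
  thresholds; decoy records each violate exactly one named rule (one-violation
  design, giving per-rule test coverage). Simulated SNVs keep ≥ 35 bp
  spacing so none accidentally trips the cluster flag; consequently the
  cluster rule is exercised by dedicated unit fixtures, not by the generator.
* **Amplicon reads** are full-length copies with independent per-position
  conversion, a per-read indel probability (length uniform 1–10 bp — small
  indels dominate editing outcomes — anchored uniformly in the protospacer),
  and uniform substitution error. No PCR duplicates, no quality-score
  structure, no strand bias.
* **RNA tables** spike true A-to-I edits (treated alt fraction ~0.3) into a
  negative-binomial coverage background (mean 50, dispersion 5, a typical
  well-expressed-transcript scale) and fill the rest with one-rule decoys
  cycling the three filters. Treated depths of rule-passing sites are
  truncated at 10 for the same label-soundness reason.

Passing tests on these inputs demonstrates that the *rules are implemented
exactly as stated* and that estimators are calibrated under the declared
noise models. It does not demonstrate robustness to alignment artifacts,
mapping bias, PCR duplicates, contamination, or copy-number mis-segmentation
— none of which the generators model.

## Problem sizes and runtime

The test and reproduction runs use 1,000-record somatic tables on a 2 × 60 kb
genome, 10,000 amplicon reads, 1,000 RNA sites with 20 spiked edits, 100
replicate profiles per mixture group at 428 SNVs each, and an 86-variant
germline set — sizes at which every binomial/multinomial check has
comfortable power while the whole suite runs in well under a minute per
stage on a single CPU.

## Known limitations

* The alignment tie-break is "the library's first co-optimal path", which in
  repeat stretches may place a gap at a different (equivalent-score) offset
  than the leftmost convention of other tools; window-overlap calls are
  unaffected in practice because equivalent placements stay within the
  repeat.
* The somatic cascade assumes one clone/control pair per run; multi-clone
  designs are handled by running pairs independently.
* The RNA filter operates on site tables; it does not revisit read
  alignments, splice junctions, or expression levels.
* Group reports expose means and sample s.d. only; hypothesis testing is
  left to downstream statistical software.
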