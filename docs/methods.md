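# Methods

## Model

A signature model (DSEM) over a set of C ≥ 2 reference genomes indexes every
distinct *n*-gram of the set with a posting list of the genomes that contain
it. Per genome, `n_t` counts its *distinct* n-grams (the index is a set;
window multiplicity is discarded at model build) and `unique_count` those
with document frequency m = 1.

The weight of an n-gram with document frequency m is

    S(m, C) = [ln(C/m) / ln(C)]²

with S(1, C) = 1, S(C, C) = 0, strictly decreasing in m. The squared form is
chosen over the linear ln(C/m)/ln(C) so that weights of moderately common
n-grams decay faster than their document frequency grows; it is the unique
power form that keeps the range [0, 1] with both endpoint anchors. Weights
are recomputed from (m, C) at query time and never stored, which keeps the
model file minimal and the scoring form swappable in one function
(`model.score_ngram`).

### Encoding and orientation

n-grams are packed 2 bits/base (A=00, C=01, G=10, T=11, MSB first) into a
uint64, so n ≤ 31; the default n = 21 balances discriminatory power against
index size (unique n-grams saturate near 21 for microbial genome sets while
memory keeps growing — `ngram_size_survey` reproduces this trade-off for any
genome set). Windows containing non-ACGT characters are skipped and counted,
never encoded; lowercase is accepted.

Two orientation conventions exist because sequencing fragments originate
from either strand:

* `canonical` (default): every n-gram, on references and reads alike, is
  replaced by min(g, revcomp(g)). Matching is strand-neutral; building a
  model from reverse-complemented references yields an identical index.
* `as-is`: references are indexed on their forward strand only and mate-2
  reads are reverse-complemented to the forward direction before extraction.
  This reproduces the original construction of the method; it is lossy
  whenever a fragment's mate-1 comes from the non-indexed strand, and is
  kept for comparability rather than recommended.

### Identification

The sample's reads are reduced to their distinct n-gram set N (multiplicity
deliberately ignored — repeated common n-grams would otherwise accumulate
weight for genomes that merely share housekeeping sequence). For each genome:
S_g sums the weights of sample n-grams present in g; n_c counts them;
nFactor = n_c/n_t normalises for genome size and reference completeness;
fS = S_g·nFactor is thresholded with an inclusive ≥ comparison. fS is kept on
the natural scale of these formulas (it can exceed 1; for a fully covered,
fully unique genome fS ≈ n_t). Because cutoffs are always calibrated with
this same scorer, the absolute scale is internally consistent; no claim is
made about cutoff values published for other implementations of the scheme,
whose normalisation differs by an unstated constant.

### Cutoff calibration

Scores of a known-positive dataset (site genomes, truth restricted) sorted
descending are compared rank-by-rank with scores of a negative (off-site)
dataset — all model genomes under the negative reads, i.e. exactly the
false-positive scores the cutoff must bound — sorted ascending. The smallest
rank where the negative curve strictly exceeds the positive one is the
crossing; the cutoff is the midpoint of the two curve values at that rank
(the original description says "intersection" without defining a value;
the midpoint is symmetric and reproducible; no inter-rank interpolation is
attempted). Unequal-length curves are truncated to the shorter length, since
the comparison needs aligned ranks. If the curves never cross and are fully
separated, the midpoint of the gap is returned with `separable=True`; if
they neither cross strictly nor separate (e.g. all-tied scores, or negatives
dominating at rank 0), calibration fails with both curves attached to the
error for inspection.

In the synthetic validation, positive calibration reads are simulated at 1×
coverage over *all* model genomes — the lowest coverage the method is
validated at — so the calibrated cutoff is conservative and remains valid
for every operating coverage ≥ 1×. Negative reads come from random genomes
absent from the model, mirroring the off-site negative sets used for real
body sites.

### Quantification

Each read (mates independently; pair-level assignment is not defined by the
scheme) is assigned by a rule cascade over the predicted genomes only:

1. most unique n-grams (m = 1) of a predicted genome; ties fall through to
2. argmax of R_jg = Σ S(m, C) over shared n-grams, restricted to the tied
   genomes (or all predicted genomes when no unique n-gram matched); final
   ties break by genome_id ascending and are flagged;
3. reads sharing no n-gram with any predicted genome stay unassigned.

The cascade is implemented (and tested against a literal brute-force oracle)
as the lexicographic maximum of (unique-count, R_jg, −id-rank). Relative
abundance is the assigned-read fraction; `length_normalize=True` divides
counts by genome length first, covering the plausible alternative convention
(the equal-genome even-mix target of 1/12 ≈ 0.083 is met by read fractions,
which is why plain fractions are the default).

## Synthetic data

The simulator emulates the validation designs of the method at desk scale:

* random i.i.d. genomes (100 kb in the acceptance world) are n-gram-disjoint
  at n = 21 with overwhelming probability, optionally sharing one implanted
  block to manufacture common n-grams;
* even mocks are 12 genomes at 1/12; staggered mocks are 20 genomes on a
  geometric ladder whose raw endpoints are 0.0002 and 0.18 (ratio 900), then
  renormalised — only the range is prescribed by the ATCC staggered design,
  the ladder shape is this package's choice;
* reads are 150 bp, single or paired with a fixed 300 bp fragment (mate-2 is
  the reverse complement of the far fragment end); start positions and
  strands are uniform; errors are i.i.d. substitutions (rate ≤ 0.2). No
  quality-model, indel, or fragment-length-distribution realism is
  attempted: error-model fidelity is orthogonal to the scoring scheme under
  test. Coverage c converts to round(c·ΣL / 150 / (2 if paired)) fragments;
* subsampling draws records without replacement, keeping mate pairs
  synchronised and input order; reference degradation truncates genomes to a
  contiguous prefix (or seeded window), emulating draft assemblies.

A green synthetic test therefore establishes algorithmic correctness
(indexing, weighting, thresholding, assignment) under a stated random world;
it does not establish robustness to real error profiles, shared plasmids,
horizontally transferred regions, or the heavy inter-genome similarity of
real congeneric strains, where common-n-gram weighting and the calibrated
cutoff carry the burden.

## Numerical and format conventions

* All generators are bit-reproducible under a seed (numpy default_rng).
* Ranked outputs sort by descending fS with genome_id ascending as
  tie-break; the cutoff comparison is inclusive (fS = cutoff → predicted).
* Metrics use the model genome set as the closed universe (TN is otherwise
  uncountable); zero denominators yield `None`, never an exception.
* Model files are little-endian binary: magic `DSEM`, version u16, n u8,
  orientation u8, genome count u32, length-prefixed genome table, then
  postings sorted by n-gram (u64 key, u32 m, m delta-encoded u32 ordinals).
  Round trips are bit-exact and structurally validated on load.
* Memory is proportional to the distinct n-gram count (~16 bytes per
  posting); billion-n-gram site models need out-of-core construction, which
  is out of scope.

## Known limitations

* Identification consumes distinct n-grams only; very low-coverage samples
  of genomes whose content is mostly shared with co-site genomes can fall
  under the cutoff (sensitivity loss the original validation also notes at
  25% reference completeness for staggered mixes).
* No EM redistribution of ambiguous reads; ties are deterministic, not
  probabilistic.
* The `as-is` orientation mode discards half the strand space of unpaired
  read sets by design; use `canonical` unless reproducing the literal
  construction.
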