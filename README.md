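# strainsig

Strain-level identification and quantification of microbes in whole-genome
metagenomic sequencing data, using body-site-specific *n*-gram signature
models.

## The problem

Generic metagenomic classifiers search every read against databases spanning
all known microbes, which inflates false positives and blurs strain-level
resolution. Microbial communities are, however, strongly site-specific: the
gut, blood, or urogenital tract each host a restricted, well-characterised
set of genomes. `strainsig` exploits this by building a **DNA signature
element model (DSEM)** for one body site (or any other environment) from its
reference genomes and profiling samples against that closed universe. It is
aimed at microbiome researchers who need strain-resolved presence/absence
calls and relative abundances from shotgun reads, and who can enumerate the
candidate reference genomes of their environment.

## The method

**Model.** Every distinct *n*-gram (*k*-mer, default *n* = 21, 2-bit packed)
across the site's reference genomes is indexed with the list of genomes that
contain it. An *n*-gram present in *m* of the model's *C* genomes gets the
discriminatory weight

```
S(m, C) = [ ln(C/m) / ln(C) ]²
```

so unique *n*-grams (*m* = 1) score 1, *n*-grams present in every genome
score 0, and the squared form dampens weights rapidly as *n*-grams become
common.

**Identification.** A sample's reads are deconstructed into their distinct
*n*-gram set. For each model genome *g*,

```
S_g = Σ S(m, C)  over sample n-grams found in g
nFactor_g = n_c / n_t        (matched fraction of g's n_t distinct n-grams)
fS_g = S_g · nFactor_g
```

and genomes with `fS ≥ cutoff` are called present. The cutoff is calibrated
empirically: plot the fS scores of a known-positive dataset in descending
order against those of a negative (off-site) dataset in ascending order; the
rank where the negative curve first exceeds the positive one is the cutoff.

**Quantification.** Each read is assigned to one called genome — by its
unique *n*-grams when it has any, otherwise by the read–genome score
`R_jg = Σ S(m, C)` over shared *n*-grams — and relative abundance is the
assigned-read fraction per genome.

A bundled simulator generates random reference genomes, even (12-genome) and
staggered (20-genome, 0.0002–0.18) mock communities, error-bearing 150 bp
paired reads, coverage subsampling, and truncated "draft" references, so the
whole pipeline is testable without downloads.

## Worked example

Build a toy 5-genome model, simulate a 3-genome community at 20× coverage,
identify, and quantify (all via the `strainsig` CLI; every subcommand is also
a library call):

```
$ strainsig build --manifest refs.tsv -o gut.dsem
model: 5 genomes, 99900 distinct n-grams (99900 unique / 0 common) -> gut.dsem

$ strainsig simulate --manifest refs.tsv --composition comp.tsv --coverage 20 --seed 5 -o mock
4000 fragments (8000 records) -> mock_1.fastq, mock_2.fastq; truth -> mock_truth.tsv

$ strainsig identify --model gut.dsem --reads mock_1.fastq --reads2 mock_2.fastq \
      --cutoff 100 -o scores.tsv
3/5 genomes at cutoff 100 -> scores.tsv

$ cat scores.tsv
genome_id  S_g    n_c    n_t    nFactor   fS       predicted
g00        19971  19971  19980  0.99955   19962    1
g01        19939  19939  19980  0.997948  19898.1  1
g02        19892  19892  19980  0.995596  19804.4  1
g03        0      0      19980  0         0        0
g04        0      0      19980  0         0        0
```

At 20× almost every one of a present genome's 19 980 distinct 21-mers is
seen in the reads (`n_c ≈ n_t`, `nFactor ≈ 1`), so `fS ≈ n_t` for the three
community members and exactly 0 for the two absent genomes — any cutoff
between those bands recovers the community perfectly. Quantification then
recovers the simulated 0.6/0.3/0.1 mixture:

```
$ strainsig quantify --model gut.dsem --reads mock_1.fastq --reads2 mock_2.fastq \
      --cutoff 100 -o abundance.tsv
8000/8000 reads assigned over 3 genomes -> abundance.tsv

$ cat abundance.tsv
genome_id  assigned_reads  relative_abundance
g00        4922            0.61525
g01        2270            0.28375
g02        808             0.101
```

In real use the cutoff comes from `strainsig calibrate` with site-specific
positive/negative read sets; `strainsig survey` tabulates the unique/common
*n*-gram partition across gram sizes, `strainsig subsample` emulates lower
sequencing coverage, and `strainsig evaluate` scores predictions
(sensitivity, specificity, F1) against a truth set, optionally rolled up to
species/genus level.

## Acceptance script

`scripts/acceptance.py` rebuilds the validation world from scratch — the
scoring-function anchors; a 30-genome model containing a synthetic even
12-genome mock sequenced at 120×, identified at 30×/5×/3×/1× subsampled
coverage with a cutoff calibrated from a disjoint negative read set; and an
even-mix quantification from 120 000 error-free reads — and writes the
measured values as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`; progress is logged to stderr.

## Documentation

`docs/methods.md` describes the model, the calibration design, the
simulator's scope, numerical conventions, and known limitations.
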