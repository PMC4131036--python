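# Methods

## Quantification model

The estimand is the fraction of input DNA originating from each species in
a panel. Under shotgun sequencing, reads sample genomic positions roughly
uniformly, so the expected share of reads mapping to genome *g* equals the
species' DNA share, provided (i) the reference is complete enough that its
reads have somewhere to map and (ii) cross-species mapping is negligible at
the chosen stringency. The pipeline estimates the share as

```
p_g = f_g · (U_g + M_g) / Σ_h f_h · (U_h + M_h) ,   f_g = (n_g + c_g) / c_g
```

where `U_g` is the unique-read count, `M_g` the redistributed share of
multi-mapped reads, and `f_g` the completeness correction (`c` reference
length, `n` ambiguous positions). Genome-*size* normalization is available
behind a flag but off by default: empirically, smaller genomes co-occur
with smaller nuclei and denser cell packing, so per-gram DNA shares track
read shares well without it.

Two strategies trade specificity against quantification accuracy:
`spec` maps once at zero mismatches (strictest assignment, fewest
false-positive hits to near-relative genomes); `quant` iterates k = 0→3,
each round re-attempting only previously unmapped reads, capturing reads
with sequencing errors and maximizing the usable count. On a synthetic
near-duplicate decoy (0.5% divergence) `spec`'s false-positive share is
verifiably ≤ `quant`'s, mirroring the intended use of the two modes.

## Mapper

Ungapped Hamming-distance alignment with an exact completeness guarantee:
the read is partitioned into k+1 equal blocks; any alignment with ≤ k
mismatches leaves one block mismatch-free, so looking up the fixed-length
seed at each block start (both strands) and verifying every candidate
enumerates exactly the alignments within the allowance. Choices:

- Seed length 20 (2-bit packed into int64, sorted-array index, vectorized
  searchsorted lookups). Pigeonhole safety requires
  `seed_length ≤ read_length / (k_max + 1)`; 20 leaves margin for 50 bp
  reads at k = 1. Seeds below 10 bp are allowed (useful for toy examples)
  but warn, since random hits proliferate.
- Reference N counts as a mismatch to every base (conservative; the lost
  coverage is what the quality factor compensates). Seeds containing N are
  not indexed.
- A genome is a "hit" for a read if it has ≥ 1 alignment within the round's
  allowance — not best-stratum-only. Uniqueness is defined over genomes,
  not alignment scores; within-genome multiplicity is irrelevant
  downstream.
- Panels are capped at 62 genomes (candidate sets are stored as int64
  bitmasks); far above the intended panel sizes.
- Paired mates are mapped independently and counted as two reads; this
  leaves proportions unbiased and avoids mate-rescue effects.

External mappers can replace this stage through SAM import/export (@SQ
headers, NM tags, unmapped flag honored).

## Redistribution, correction, reporting

Multi-read redistribution pools unique counts over *all* rounds and is
applied once after the final round, renormalized within each read's
candidate set; per-round redistribution is a defensible alternative, but
pooling uses the largest (hence most stable) unique denominators. Candidate
sets with zero unique support are split evenly with a logged warning — this
is exactly what happens for a decoy genome that duplicates a panel member.
The quality factor is applied after redistribution. Reported proportions
are renormalized to sum to 100; the raw (pre-normalization) total is kept
on the report object. Relative difference is undefined for a 0% target and
rendered `n.a.`.

## Metagenomic (LCA) stage

Consumes 12-column tabular similarity output; running the search engine
itself is out of scope (intended upstream settings for short reads:
word size 11, e-value cutoff 100, best 3 hits). Filters, in order:
read complexity < 0.44 sets the read aside as low-complexity; hits with
bitscore < 75 are dropped; surviving hits within 1% of the read's best
bitscore vote; the read's taxon is their LCA. Reads per taxon must exceed
the support threshold (default 50, strict) or the taxon is folded into its
ancestors, children before parents (a discard mode exists behind a flag;
folding conserves reads). Taxa whose final count exceeds the promotion
threshold (default 1000 reads; in practice set relative to the unmapped
pool) are recommended for the mapping panel, and the pipeline's promotion
loop adds them automatically when a genome with a matching name exists in
the supplied panel library.

The complexity measure — Shannon entropy of overlapping trinucleotide
frequencies normalized by `log2(min(64, L−2))` — is this package's own
stand-in for the unpublished measure of the visualization tool that
popularized the 0.44 threshold. Under our measure a homopolymer scores 0, a
dinucleotide microsatellite 1/6 ≈ 0.17, and uniform-random 100-mers > 0.9,
so 0.44 cleanly separates microsatellite-like reads from genuine sequence;
the threshold is kept as the default.

Taxonomies are accepted as NCBI `nodes.dmp`/`names.dmp` or a 4-column TSV
(id, parent, rank, name); validation enforces a single root and rejects
cycles and dangling parents.

## Synthetic data

The generator emulates the validation design: several reference genomes
derived from a shared ancestral sequence by independent per-site
substitution (divergence *d* per genome gives pairwise difference
`1 − ((1−d)² + d²/3)`; d = 0.05 → ~9.7%, comfortably above the ~7%
floor among real food-relevant mammals), optional contiguous N-blocks
(geometric lengths, mean 1 kb, realized count trimmed to the target
exactly), and origin-tagged reads drawn uniformly from N-free windows on
either strand with a flat per-base substitution error (default 1%, no
indels — matching the validation error model). `exact_counts` (default on
for validation runs) allocates per-species reads by largest remainder so
acceptance bounds test the method rather than multinomial sampling noise.
Reads avoid reference N regions; the quality-factor effect is exercised by
mapping reads simulated from a *complete* genome against an N-masked draft
copy. Paired-end simulation draws insert sizes from a truncated normal
(min = read length). An m8-fixture generator gives every tagged read a
perfect hit to its true taxon plus optional lower-scoring confounder hits,
so the LCA stage is testable without a database.

What the simulator does **not** model: quality-dependent or
machine-specific error profiles, indels, adapter contamination, GC or
coverage bias, real repeat structure, and inter-genome homology beyond the
shared-ancestor construction. Passing tests therefore demonstrate the
correctness and statistical behavior of the *method*, not performance on
real library preparations.

## Validation problem sizes and determinism

The dataset-1 replica uses six 1 Mb genomes and one million reads (the
published dataset size) in a single one-mismatch round; the dataset-2
replica uses three mammal-like 1 Mb genomes plus a 2 Mb bacterial-like
genome with 850 K reads through the full iterative schedule. At one
mismatch, ~26.4% of 1%-error reads carry ≥2 errors and stay unmapped
(binomial tail); because this loss rate is identical across species it
cancels from the proportions, and the residual deviation is pure sampling
noise (~0.6% relative at the 1% components for 10⁶ reads). Genomes are
megabase-scale rather than gigabase-scale; divergence between synthetic
genomes is uniform rather than locally structured, which makes
multi-mapping rarer than in real mammalian panels — the redistribution
logic is therefore additionally exercised by dedicated unit tests with
constructed candidate sets.

All randomness flows through seeded `numpy` generators; identical specs and
seeds give byte-identical FASTA/FASTQ/report output. The acceptance script
derives independent 31-bit sub-seeds from its single `--seed` argument.

## Known limitations

- Ungapped alignment only; an indel-bearing read can be missed entirely
  (real runs can substitute an external gapped mapper via SAM import).
- Quantification assumes one genome copy per cell and equal DNA recovery
  per gram of tissue; matrix effects (e.g. fat vs muscle) bias real-world
  estimates and must be normalized externally.
- The LCA stage is qualitative: database representation biases make its
  counts unsuitable for quantification, which is precisely why promotion
  back into the mapping panel exists.
- Promotion matches library genomes by taxon name; no sequence-identity
  check is performed on the supplied genome.
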