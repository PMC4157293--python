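# Methods

## Model

`motifbayes` scores a read's feature vector **d** = {d_1 … d_K} — the
multiset of overlapping k-mers obtained by sliding a length-k window one
base at a time — against each reference class C_i with the naive Bayes
log-likelihood Σ_j log P(d_j | C_i), computed in double precision (the
log transform exists to avoid underflow of the product form). Class
priors are taken equal and the evidence term is constant, so both drop
out of the argmax; no class-size prior correction is applied — in
multi-profile mode the genome splitting itself is the size correction.
Every read is assigned to the top-scoring profile without a score
threshold.

Motif probabilities are Laplace-smoothed over the full motif space:
P(m | C) = (count(m) + α) / (total + α·4^k), with α = 1 by default.
Smoothing is applied at scoring time from raw stored counts, so a single
unseen motif can never produce −∞ and eliminate an otherwise good class.
At small k the smoothed probabilities are verified by enumeration to sum
to one.

## Splitting geometry

A genome of length L assigned n partitions is cut into n sub-sequences
of nominal length 2L/(n+1); adjacent sub-sequences overlap by L/(n+1),
so any read-sized window lies wholly inside at least one slice. The
stated geometry is real-valued; we fix the integer version as
start_i = ⌊i·L/(n+1)⌋, length ⌊2L/(n+1)⌋, with the final slice extended
to end exactly at L. This reproduces the exact worked example
(3 Mb → three 1.5 Mb slices, 750 kb overlaps), and a property test
verifies gap-free coverage of [0, L) for random (L, n). The default
size-group table (1/3/5/7 partitions at 2/4/6 Mb boundaries, inclusive
upper bounds) is overridable by the user; partition counts must be
non-decreasing in size and the table must cover all positive lengths.

Multi-replicon genomes (chromosome + plasmids) are concatenated in file
order for split coordinates, but motif windows never span replicon
junctions — junction k-mers are concatenation artifacts, not sequence.
Whether plasmids join their chromosome's profile is a user choice via
the record→genome manifest.

## Counting and scoring implementation

Motifs are packed two bits per base into integer codes (int32 for
k ≤ 15, int64 above); per-profile counts are stored as a sorted unique
code array with parallel counts, since dense storage at 4^15 is
infeasible. Windows containing any non-ACGT character are excluded from
both profiles and feature vectors while the characters remain in the
sequence, keeping coordinates faithful. Scoring concatenates all reads'
codes and uses one binary search per profile, recovering per-read sums
from a cumulative sum; this is exact, and a test requires agreement
within 1e-9 with a dense brute-force enumeration at k ≤ 3.

Reference profiles count the forward strand only. Reads are sequenced
from either strand, so by default each read is scored as given and as
its reverse complement and the better orientation wins; `forward_only`
restores strict as-given scoring for strand-handling experiments. Ties
are broken deterministically: forward orientation preferred, then first
profile in database order; the tie multiplicity is recorded. A read with
no valid motif in either orientation is flagged and assigned to the
first profile with score 0 rather than dropped, so the accuracy
denominator always equals the number of input reads.

## Synthetic data

The generator emulates a skewed microbial reference collection plus a
wgsim-style shotgun experiment, entirely seeded:

- **Genomes.** One order-1 Markov chain over A/C/G/T per genome. The
  chains are hierarchical: a single ancestral transition matrix is drawn
  per community (Dirichlet(10) rows — a mild shared skew) and each
  genome perturbs it log-normally, row ∝ base·exp(δ·Z) with Z ~ N(0,1).
  δ = `composition_divergence` (default 0.1) is roughly the relative
  spread of transition probabilities between genomes: 0 makes all
  genomes compositionally identical, values near 1 make them
  idiosyncratic. The default reflects that members of a real community
  share most of their base composition. The chain's inner loop is
  compiled with numba when available, with an equivalent pure-Python
  fallback.
- **Reads.** A fixed number of single-end reads per genome at uniform
  start positions and uniform strand; each base is independently
  substituted with the given probability to a uniformly random
  *different* base, applied after orientation. No indels, chimeras,
  quality model, paired ends or coverage bias. Read ids embed the truth
  label as `<genome_id>|<ordinal>|<start>|<strand>`, the single contract
  shared by the parser and the evaluator.

What this does *not* emulate — and hence what passing benchmarks do and
do not show: synthetic genomes share composition but no homologous
sequence, whereas real collections contain near-identical strains and
conserved genes. Error-free 100 bp reads at k = 12 are therefore almost
exact-substring queries and accuracy sits near the ceiling for both
modes; the large-genome bias expresses itself mainly through the
spuriously matching windows introduced by substitution errors, which is
where the multi-profile mode's advantage appears and grows with error
rate. Chance-level behavior in the no-signal limit (δ = 0) only
manifests when the motif space is saturated, i.e. at small k relative to
genome length; it is tested at k = 4. Benchmarks here characterize the
size-bias mechanism and the correctness of the machinery, not absolute
accuracy on real communities.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| k (motif length, bases) | 12 | 10–15 are the classical settings; larger k sharpens matches but sparsifies profiles |
| α (pseudocount) | 1.0 | Laplace smoothing mass per motif over the 4^k space |
| group table | 1/3/5/7 at 2/4/6 Mb | partition counts per genome-size bin |
| composition_divergence | 0.1 | relative between-genome spread of Markov transition probabilities |
| substitution_rate | 0.0 | per-base read error probability (substitutions only) |
| read_length / reads_per_genome | 100 / 100 | wgsim-style fixed-length, fixed-count sampling |

## Benchmark problem sizes

The end-to-end accuracy checks use a 20-genome community spanning
0.5–8 Mb (5/8/5/2 genomes per size group, mid-heavy as real collections
are), k = 12, 100 bp reads, 100 reads per genome, error rates
{0, 0.01, 0.02}, three seeds — about 72 Mb of reference sequence and
6,000 reads per (mode, rate) comparison. Mode comparisons are pooled
over seeds and judged within two pooled binomial standard errors; these
are the package's chosen desk-scale study conditions, small enough to
run anywhere yet large enough that every size group participates.

## Degenerate inputs and numerical choices

- Genome shorter than k: retained with an empty profile and a warning
  (the class set stays stable); such a profile scores every motif at the
  uniform smoothed floor.
- Genome shorter than n+1 bases with n > 1: splitting is a hard error
  from `split_genome`; `build_database` falls back to a single slice
  with a warning, which can only arise under user-supplied tables.
- Empty read set: classification returns an empty assignment list and
  an all-zero abundance table; accuracy on an empty set is an error
  (0/0), never reported as 0.
- Abundance ranking ties: equal counts rank alphabetically for the
  top-N cut (deterministic); Spearman's rho uses average ranks on ties
  and is an error on intersections smaller than two.
- Profile databases persist as a versioned zip container (JSON metadata
  plus raw count arrays); loads validate format, version and k against
  the request and fail with explicit incompatibility errors.

## Known limitations

Scoring is single-threaded; profile databases hold code arrays in
memory (about 16 bytes per distinct stored motif across profiles, so
multi-profile references over ~100 Mb of genome need a few hundred MB);
no LCA-style taxonomic rollup, novel-taxon rejection or probability
calibration is attempted; group boundaries and partition counts are
taken as given rather than optimized.
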