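# motifbayes

Naive Bayes taxonomic binning of metagenomic sequencing reads, with
genome-size-normalized **multi-profile** references.

The first step of most metagenome analyses is assigning each sequenced
read (DNA fragment) to the reference genome it most plausibly derives
from. Composition-based classifiers do this from motif (k-mer) occurrence
profiles of the references, without alignment. `motifbayes` is for
bioinformaticians who want such a classifier together with everything
needed to study it offline: a reference profile builder, a seeded
synthetic-community and read simulator (wgsim-style, substitution-only
errors), an evaluation/benchmark harness, and a command-line interface.

## The classifier

With genome classes C_1 … C_P and a read reduced to its feature vector
**d** = {d_1, …, d_K} of overlapping k-mers, the naive Bayes rule assigns
the read to

```
Ĉ = argmax_i  Σ_{j=1..K}  log P(d_j | C_i)
```

assuming motif independence, equal class priors and constant evidence.
P(d_j | C_i) is the Laplace-smoothed motif frequency of class i:
`(count + α) / (total + α·4^k)`.

When one profile is built per genome, large genomes are favored: they
simply contain more distinct motifs, so spurious matches accumulate in
their favor and reads from small genomes get pulled away. Microbial
genome sizes span roughly two orders of magnitude, making this bias
material. The **multi-profile** mode (`nbc-mp`) removes it by splitting
each genome of length L into n overlapping sub-sequences of length
2L/(n+1) (adjacent slices share L/(n+1) bases, so no region is lost near
a cut), profiling each slice separately, scoring reads against slices,
and folding winning slices back to their source genome. The partition
count n comes from a size-group table, by default

| genome size | ≤ 2 Mb | 2–4 Mb | 4–6 Mb | > 6 Mb |
|---|---|---|---|---|
| partitions n | 1 | 3 | 5 | 7 |

which compresses a 140 kb – 12.9 Mb collection's ~93-fold size spread to
about 23-fold. A 3 Mb genome, for example, becomes three 1.5 Mb slices
with 750 kb overlaps. The plain single-profile classifier remains
available as mode `nbc` and is exactly the n = 1 special case.

## Worked example

Four synthetic genomes spanning the size groups (1.5, 3, 5, 7 Mb), 100
reads of 100 bp from each at a 2% substitution-error rate:

```python
from motifbayes import (MotifBayesClassifier, SimulationSpec,
                        generate_genomes, simulate_reads)

spec = SimulationSpec(
    n_genomes=4,
    genome_lengths=[1_500_000, 3_000_000, 5_000_000, 7_000_000],
    read_length=100, reads_per_genome=100,
    substitution_rate=0.02, seed=42,
)
genomes = generate_genomes(spec)
reads = simulate_reads(genomes, spec)

for mode in ("nbc", "nbc-mp"):
    clf = MotifBayesClassifier(k=12, mode=mode).fit(genomes)
    assignments, abundance = clf.classify(reads)
    print(f"{mode:7s} profiles={len(clf.database_.profiles):2d} "
          f"accuracy={clf.score(reads):.3f} abundance={abundance.counts}")
```

prints

```
nbc     profiles= 4 accuracy=0.988 abundance={'G000': 95, 'G001': 100, 'G002': 101, 'G003': 104}
nbc-mp  profiles=16 accuracy=0.998 abundance={'G000': 99, 'G001': 100, 'G002': 100, 'G003': 101}
```

The single-profile classifier leaks reads from the smallest genome
(G000, 1.5 Mb: 95 of its 100 reads recovered) toward the largest (G003,
7 Mb: 104 assigned) — exactly the size bias described above. With
multiple profiles (1 + 3 + 5 + 7 = 16 of them) the abundance estimates
are nearly exact and accuracy rises from 0.988 to 0.998.

The same pipeline is scriptable from the shell:

```bash
motifbayes simulate --n-genomes 4 --lengths 1500000,3000000,5000000,7000000 \
    --read-length 100 --reads-per-genome 100 --error-rate 0.02 --seed 42 --out-dir sim/
motifbayes build sim/G*.fasta -k 12 --mode nbc-mp -o refs.db
motifbayes classify --db refs.db --reads sim/reads.fasta \
    --out assignments.tsv --abundance abundance.tsv
motifbayes evaluate --assignments assignments.tsv --out report.json
```

`motifbayes benchmark` runs full factorial grids (k × read length ×
error rate × mode × seed) from a YAML config, and
`motifbayes compare-abundance` reports the Spearman rank correlation
between two classifiers' abundance tables over their common top strains.

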