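# malespec

**Estimating the size of the male-specific region of a genome from a male
contig assembly and female short reads.**

Young or homomorphic sex chromosomes are hard to measure: the Y (or
proto-Y) carries a *male-specific region* — sequence present in males and
absent in females — that cytogenetics cannot see when the chromosomes look
alike. `malespec` implements a k-mer chromosome-scan approach to this
problem, aimed at researchers studying sex-chromosome evolution in
non-model organisms: it compares a fragmented male genome assembly against
female whole-genome short reads and turns the comparison into a
conservative, Bayesian estimate of the male-specific proportion (MSP) of
the genome and its absolute size.

## Method

1. **Female k-mer set.** Female reads are quality-masked (bases below a
   Phred threshold, default 20, become `N`), every canonical k-mer
   (default k = 15) is counted, and k-mers seen fewer than `min_count`
   times (default 5) are discarded.
2. **Chromosome scan.** Each male contig is scanned for *single-copy* (SC)
   k-mers — canonical k-mers occurring exactly once in the whole assembly,
   so that repeats carry no weight. An SC k-mer absent from the female set
   is *unmatched* (USC); one present is *matched* (MSC). Contigs at or
   near 100% USC are putatively male-specific; plotting contig size
   against %USC shows two peaks, at 0% and 100%.
3. **Beta-binomial estimate.** A contig's USC/MSC counts enter a binomial
   likelihood with a conjugate beta(a, b) prior, parameterised by a prior
   weight PW = a + b and a prior mean p0 = 2×10⁻⁴ (a = PW·p0,
   b = PW·(1−p0)). The posterior is beta(a + USC, b + MSC) with mean

   E[p | k-mers] = (a + USC) / (a + b + USC + MSC)

   With PW = 1, a 100%-USC contig with one SC k-mer has ≈50% posterior
   probability of being male-specific. Contigs below a size cutoff are
   removed; each qualifying (100%-USC) contig contributes
   posterior × length; dividing by the total length of all contigs above
   the cutoff gives the expected MSP. Read as the haploid-denominator
   quantity MSP_h = Y/(X+Y+A), halving it lower-bounds the
   diploid-denominator MSP_d = Y/(X+Y+2A), and scaling by the diploid
   genome size gives a lower bound on the absolute size of the
   male-specific region. A cutoff × prior-weight sweep probes the
   robustness of the estimate.

Because no suitable public male-assembly/female-read pair accompanies the
method at desk scale, the package ships a first-class synthetic-data
module: genomes with autosomes, an X, and a Y carrying a truly
male-specific segment; female reads with errors and quality strings; and a
fragmented male "assembly" with known per-contig origin — so every stage
is testable against exact ground truth.

## Worked example

Simulate a 500 kb genome (male-specific segment 25.2 kb ≈ 5%), scan it,
and estimate:

```python
from malespec import *
from malespec.simulate import simulate_dataset, ReadSimSpec

paths = simulate_dataset("wex", read_spec=ReadSimSpec(coverage=30, error_rate=0.003),
                         master_seed=7)
female = build_female_kmer_set(paths["female_reads"], KmerParams(k=21))
index = build_assembly_index(paths["male_contigs"], 21)
write_scan_tsv(scan_assembly(paths["male_contigs"], index, female), "wex/scan.tsv")

model = MaleSpecificProportion.from_scan_tsv("wex/scan.tsv",
                                             diploid_genome_size_bp=820_000)
print(model.fit(prior_weight=22, size_cutoff_bp=1000).summary())
```

```
Male-specific proportion estimate
=================================================
Prior weight (a+b)                             22
Prior mean p0                              0.0002
Prior a                                    0.0044
Prior b                                   21.9956
Size cutoff (bp)                             1000
%USC threshold                                100
Contigs in numerator                            9
Total length >= cutoff (bp)                494359
-------------------------------------------------
MSP (haploid reading, raw)               0.054403
MSP (raw, %)                                5.44%
MSP_d lower bound                        0.027201
MSP_d lower bound (%)                       2.72%
Absolute size lower bound (Mb)              0.022
=================================================
```

Nine contigs ≥ 1 kb were 100% USC; the raw (haploid-reading) estimate of
5.44% brackets the simulation's true haploid male-specific proportion of
5.04%, and the halved bound of 2.72% sits below the true diploid
proportion of 3.07% — the estimator is conservative by construction.
`model.sweep()` evaluates the full cutoff × prior-weight grid.

The same pipeline is available from the shell:

```bash
malespec simulate --seed 7 --coverage 30 --out-dir wex
malespec count-female-kmers wex/female_reads.fastq --k 21 --out wex/female.kmers
malespec scan wex/male_contigs.fasta wex/female.kmers --out wex/scan.tsv
malespec estimate wex/scan.tsv --prior-weight 22 --cutoff 1000 --out wex/estimate.tsv
malespec sweep wex/scan.tsv --out wex/sweep.tsv
malespec heatmap-table wex/scan.tsv --out wex/heatmap.tsv
```

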