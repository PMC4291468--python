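# Methods

## The scan statistic

The pipeline classifies contigs of a *male* assembly by comparing their
k-mers with *female* short-read data. Three filters define the statistic:

* **Canonical k-mers.** Every k-mer is represented by the lexicographic
  minimum of itself and its reverse complement. Shotgun reads are
  unstranded, so strand-collapsed matching is the only mode offered.
* **Quality masking and abundance filtering (female reads).** Bases with
  Phred score < `min_base_quality` (default 20; offsets 33 and 64
  supported) and non-ACGT bases are masked; any window covering a masked
  base is skipped. Canonical k-mers seen fewer than `min_count` times
  (default 5) are discarded, suppressing k-mers created by sequencing
  error. Defaults (k = 15, Phred 20, count 5) are the standard
  female-read filter for this kind of scan.
* **Single-copy restriction (male assembly).** Only k-mers occurring
  exactly once across the *entire* assembly are informative
  ("single copy", SC). Assembly-wide uniqueness is the default because a
  k-mer shared between contigs is repetitive and its male-specificity
  unreliable; a contig-local variant (`sc_scope="contig"`) exists for
  sensitivity analysis.

Each contig's SC k-mers split into *unmatched* (USC, absent from the
female set) and *matched* (MSC); %USC = 100·USC/(USC+MSC). Contigs with
no SC k-mers are flagged (`NO_SC_KMERS`), carry no evidence, but keep
their length in the estimator's denominator.

A consequence of the assembly-wide SC definition worth knowing: in a
genome where the Y retains a region homologous to the X but diverged from
it, that region's *undiverged* windows occur twice in the assembly (X and
Y copies) and are not single-copy, while its *diverged* windows are
single-copy and absent from females. Such a region therefore presents
100% USC k-mers — the scan reads fully differentiated (even if only
slightly diverged) Y sequence as male-specific. The estimator's
denominator still counts the whole assembly, so the effect on the
genome-wide proportion is bounded by the region's length.

## The estimator

Per qualifying contig, the probability of being truly male-specific is
modelled as a binomial on (USC, MSC) with conjugate prior beta(a, b),
a = PW·p0, b = PW·(1−p0):

* `p0` (default 2×10⁻⁴) — prior mean, i.e. a prior expected
  male-specific genome fraction of 0.02%; configurable, not a constant.
* `PW = a + b` — prior weight; the pseudo-count mass competing with the
  data. PW = 1 is weakly conservative (one SC k-mer ≈ 50% posterior);
  larger PW values (e.g. the assembly's median SC k-mer count) shrink
  small, weakly supported contigs toward the prior. The posterior is
  beta(a+USC, b+MSC); its mean (a+USC)/(a+b+USC+MSC) is used throughout.
  (Some descriptions of this posterior print a 1/B(a,b) normaliser; the
  correctly normalised density is beta(a+USC, b+MSC), whose mean is the
  expectation above, and that is what is implemented.)

Aggregation: drop contigs below `size_cutoff_bp` (closed bound,
length ≥ cutoff); qualify contigs by the %USC rule — "100% USC" is the
exact integer test USC == SC with SC > 0, generalised by
`usc_threshold_pct` (e.g. 80 for assemblies whose male-specific peak
sits below 100%); numerator = Σ posterior × length over qualifying
contigs; denominator = Σ length over *all* contigs above the cutoff.

Bounds: the raw quotient is read as the haploid-denominator proportion
MSP_h = Y/(X+Y+A) (each locus assembled once, the inbred-line case);
halving lower-bounds the diploid-denominator MSP_d = Y/(X+Y+2A) (each
locus assembled twice); multiplying MSP_d by the diploid genome size
gives the absolute lower bound. `theoretical_msp` evaluates both
boundary formulas from known chromosome sizes.

Monotonicity (used as test invariants): the posterior mean is strictly
increasing in USC, decreasing in MSC, and — whenever USC/(USC+MSC) > p0 —
decreasing in PW; hence the genome-wide estimate is non-increasing in PW.

## The synthetic-data generator

`simulate_genomes` emulates the structure the method assumes: i.i.d.
random chromosomes at a configured GC content; a Y whose distal fraction
(`male_specific_fraction_of_y`) is fresh sequence with no female
counterpart, while the proximal remainder is the X prefix substituted at
`xy_divergence` per base (a pseudo-recombining region); the female
genome is the diploid complement with two identical copies of each
autosome and the X (a fully inbred line — no heterozygosity). An
optional `repeat_fraction` overwrites windows with copies from a small
shared repeat library. Reads are single-end with i.i.d. substitution
errors and constant or linearly decaying quality strings; paired-end
structure adds nothing to k-mer counting and is not modelled. The
assembly emulator tiles each chromosome with non-overlapping contigs
(lognormal lengths by default, mean 3 kb, σ = 0.5 in log space; pieces
under `min_contig_bp` = 100 bp dropped) and labels each contig's origin,
so the true MSP of every simulated dataset is known exactly.

Default study conditions, chosen once: a 500 kb haploid male genome —
two autosomes of 160 kb, X = 152 kb, Y = 28 kb with male-specific
fraction 0.9, i.e. a 25.2 kb (≈5%) male-specific segment — with 2% X-Y
divergence and female coverage 12× (error rate 0.2%, Phred 35). This is
a 1/1000-scale stand-in for a ~500 Mb insect genome sequenced at ~12×;
verification runs raise coverage to 30× so that female k-mer dropout is
negligible and the scan's behaviour, not sampling noise, is under test.

**k at reduced scale.** Real-scale scans use k = 15. At 1/1000 genome
scale that k would *overstate* chance matching relative to the regime
the method relies on: a ~4.5×10⁵-k-mer female set in a canonical space
of 5.4×10⁸ gives ≈8×10⁻⁴ probability that a random male-specific k-mer
matches the female set by chance, enough to strip multi-kb contigs of
their 100%-USC status purely by collision. Simulation-based verification
therefore scans with k = 21 (space 2.2×10¹²), restoring negligible
chance matching; the paper-scale default k = 15 remains for real data.

What the simulator does *not* model — and hence what passing tests do
not show about real data: assembly artifacts (chimeras, collapsed
repeats, coverage-dependent fragmentation), GC bias and PCR duplicates,
indel errors, heterozygosity in the female, realistic repeat landscapes
and transposable-element families, and genome-scale k-mer-space
saturation. The conservativeness and recovery results certify the
statistical machinery, not robustness to those artifacts.

## Numerical and interface choices

* K-mers are packed two bits per base into `uint64` (k ≤ 31); packing
  preserves lexicographic order, so sorted code arrays double as sorted
  k-mer lists. Membership and multiplicity lookups are exact
  (`searchsorted` on sorted arrays); probabilistic structures are
  deliberately excluded because tests assert exact USC/MSC counts.
* All %USC computation is exact-integer; TSVs round to one decimal.
  Undefined %USC (no SC k-mers) is written as `NA`.
* The female k-mer set persists as sorted text with a header recording
  k and the filter parameters; reloading is bit-identical.
* Degenerate inputs: empty read files and empty scan tables yield empty
  sets / zero estimates with warnings, not errors; contigs shorter than
  k are flagged records; truncated FASTQ records, duplicate contig ids,
  and k mismatches between stages are hard errors.
* Every stochastic stage takes an explicit seed; a master seed derives
  per-stage seeds via `numpy.random.SeedSequence`. Outputs are
  byte-identical for a given seed.
* True simulated proportions use the whole-genome denominator
  (MSP_h = Y_ms/(X+Y+A) with Y the full Y length), the quantity the
  estimator's length denominator actually measures.
* Default sweep grids: cutoffs {0, 1000, 2000, 3000} bp and integer
  prior weights 1–70; `log_spaced_weights` provides the wide log grid
  (1–10⁴) appropriate for better-assembled genomes, where the
  qualification rule is typically relaxed to `usc_threshold_pct=80`.

## Known limitations

* Exact 100%-USC qualification is sensitive to any spurious female
  match on a contig; on low-coverage or contaminated data the 80%
  threshold variant is the practical choice, at the cost of admitting
  partially matched contigs.
* The halved bound assumes the measured quotient is the haploid-reading
  quantity; for highly fragmented, low-coverage male assemblies the
  measured value drifts toward the diploid reading and the bound becomes
  up to two-fold over-conservative.
* No credible intervals are reported for the genome-wide estimate; only
  per-contig posteriors are available (`posterior_density`).
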