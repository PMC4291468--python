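"""Synthetic genome/read/assembly generator: contracts and ground truth."""

import numpy as np
import pytest

from malespec import (
    AssemblyEmulationSpec,
    GenomeSpec,
    KmerParams,
    ReadSimSpec,
    SimulationSpecError,
    SimulationTruth,
    build_female_kmer_set,
    simulate_dataset,
    simulate_female_reads,
    simulate_genomes,
)
from malespec.simulate import derive_stage_seeds, fragment_male_assembly
from naive import naive_window_kmers

SMALL = GenomeSpec(
    n_autosomes=2, autosome_bp=4000, x_bp=3000, y_bp=1500,
    male_specific_fraction_of_y=0.8, xy_divergence=0.02, seed=5,
)


class TestSimulateGenomes:
    def test_truth_values_from_realized_sizes(self):
        male, female, truth = simulate_genomes(SMALL)
        assert truth.y_male_specific_bp == 1200
        # denominator is the whole male genome (Y-shared part included)
        assert truth.true_msp_h == pytest.approx(1200 / 12500)
        assert truth.true_msp_d == pytest.approx(1200 / 20500)
        assert len(male["Y"]) == 1500
        assert set(male) == {"A1", "A2", "X", "Y"}
        # female diploid: two identical copies of each non-Y chromosome
        assert set(female) == {
            "A1_hap1", "A1_hap2", "A2_hap1", "A2_hap2", "X_hap1", "X_hap2",
        }
        assert female["A1_hap1"] == male["A1"] == female["A1_hap2"]

    def test_no_y_means_zero_truth(self):
        spec = GenomeSpec(n_autosomes=1, autosome_bp=2000, x_bp=1000, y_bp=0,
                          male_specific_fraction_of_y=0.0, seed=1)
        male, female, truth = simulate_genomes(spec)
        assert truth.true_msp_h == 0.0
        assert truth.true_msp_d == 0.0
        assert "Y" not in male

    def test_ms_fraction_without_y_rejected(self):
        with pytest.raises(SimulationSpecError):
            GenomeSpec(y_bp=0, male_specific_fraction_of_y=0.5)

    def test_virilis_style_karyotype_anchor(self):
        spec = GenomeSpec(n_autosomes=4, autosome_bp=1000, x_bp=1000, y_bp=1000,
                          male_specific_fraction_of_y=1.0, seed=2)
        _, _, truth = simulate_genomes(spec)
        assert truth.true_msp_d == pytest.approx(0.1)
        assert truth.true_msp_h == pytest.approx(1 / 6, rel=1e-3)

    def test_seed_changes_sequence_not_truth(self):
        m1, _, t1 = simulate_genomes(SMALL)
        m2, _, t2 = simulate_genomes(
            GenomeSpec(**{**SMALL.__dict__, "seed": 99})
        )
        assert t1 == t2
        assert m1["A1"] != m2["A1"]

    def test_deterministic_given_seed(self):
        m1, f1, _ = simulate_genomes(SMALL)
        m2, f2, _ = simulate_genomes(SMALL)
        assert m1 == m2 and f1 == f2

    def test_male_specific_segment_absent_from_female(self):
        """No k-mer of the male-specific Y segment occurs in the female
        genome (divergence and repeats zero) — brute-force scan."""
        spec = GenomeSpec(n_autosomes=1, autosome_bp=3000, x_bp=2000, y_bp=1000,
                          male_specific_fraction_of_y=1.0, xy_divergence=0.0,
                          repeat_fraction=0.0, seed=3)
        male, female, truth = simulate_genomes(spec)
        k = 15
        ms_seq = male["Y"][truth.ms_start:truth.ms_end]
        female_kmers = set()
        for seq in female.values():
            female_kmers.update(naive_window_kmers(seq, k))
        ms_kmers = set(naive_window_kmers(ms_seq, k))
        assert not (ms_kmers & female_kmers)

    def test_shared_y_diverges_from_x(self):
        male, _, truth = simulate_genomes(SMALL)
        shared = male["Y"][: truth.ms_start]
        x_prefix = male["X"][: truth.ms_start]
        mismatches = sum(a != b for a, b in zip(shared, x_prefix))
        # 2% divergence on 300 bp: a handful of substitutions, not zero
        assert 0 < mismatches < 0.1 * len(shared)

    def test_repeat_fraction_plants_shared_repeats(self):
        spec = GenomeSpec(n_autosomes=1, autosome_bp=20000, x_bp=10000, y_bp=2000,
                          male_specific_fraction_of_y=1.0, repeat_fraction=0.1,
                          seed=4)
        male, _, _ = simulate_genomes(spec)
        k = 21
        counts = {}
        for seq in male.values():
            for m in naive_window_kmers(seq, k):
                counts[m] = counts.get(m, 0) + 1
        repeated = sum(1 for c in counts.values() if c > 1)
        assert repeated > 500  # repeats create many multi-copy k-mers


class TestSimulateReads:
    def test_coverage_contract(self, tmp_path):
        spec = GenomeSpec(n_autosomes=1, autosome_bp=40_000, x_bp=10_000, y_bp=0,
                          male_specific_fraction_of_y=0.0, seed=6)
        _, female, _ = simulate_genomes(spec)
        out = tmp_path / "r.fastq"
        n = simulate_female_reads(female, ReadSimSpec(coverage=20, seed=7), out)
        total_bases = n * 75
        haploid = 50_000
        assert abs(total_bases - 20 * haploid) <= 75
        assert abs(total_bases - 20 * haploid) / (20 * haploid) <= 0.01

    def test_byte_identical_given_seed(self, tmp_path):
        _, female, _ = simulate_genomes(SMALL)
        spec = ReadSimSpec(coverage=3, seed=8)
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        simulate_female_reads(female, spec, p1)
        simulate_female_reads(female, spec, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_read_longer_than_chromosome_rejected(self, tmp_path):
        _, female, _ = simulate_genomes(SMALL)
        with pytest.raises(SimulationSpecError):
            simulate_female_reads(
                female, ReadSimSpec(read_length_bp=5000, seed=0),
                tmp_path / "r.fastq",
            )

    def test_error_free_deep_coverage_recovers_genome_kmers(self, tmp_path):
        """With error-free reads, every k-mer window covered by >= 5 reads
        is in the female set at min_count=5, and no foreign k-mers appear."""
        spec = GenomeSpec(n_autosomes=1, autosome_bp=6000, x_bp=3000, y_bp=0,
                          male_specific_fraction_of_y=0.0, seed=9)
        _, female, _ = simulate_genomes(spec)
        out = tmp_path / "r.fastq"
        simulate_female_reads(
            female, ReadSimSpec(coverage=30, error_rate=0.0, seed=10), out
        )
        k = 15
        params = KmerParams(k=k, min_count=5)
        kset = set(build_female_kmer_set(out, params).members)
        genome_kmers = set()
        for seq in female.values():
            genome_kmers.update(naive_window_kmers(seq, k))
        # no false k-mers (reads are error-free)
        assert kset <= genome_kmers
        # window coverage oracle from the read names (chrom, start, strand)
        cover: dict[tuple, int] = {}
        with open(out) as fh:
            for line in fh:
                if not line.startswith("@r"):
                    continue
                _, *parts = line.strip().split("_")
                chrom, start = "_".join(parts[:-2]), int(parts[-2])
                for w in range(start, start + 75 - k + 1):
                    cover[(chrom, w)] = cover.get((chrom, w), 0) + 1
        deep = set()
        for (chrom, w), c in cover.items():
            if c >= 5:
                kmer = female[chrom][w : w + k]
                deep.add(naive_window_kmers(kmer, k)[0])
        assert deep <= kset

    def test_quality_models(self, tmp_path):
        _, female, _ = simulate_genomes(SMALL)
        p = tmp_path / "r.fastq"
        simulate_female_reads(female, ReadSimSpec(coverage=1, quality_model=30,
                                                  seed=11), p)
        qline = p.read_text().splitlines()[3]
        assert qline == chr(63) * 75
        simulate_female_reads(
            female,
            ReadSimSpec(coverage=1, quality_model=("decay", 38, 28), seed=11),
            p,
        )
        qline = p.read_text().splitlines()[3]
        assert ord(qline[0]) - 33 == 38 and ord(qline[-1]) - 33 == 28


class TestFragmenter:
    def test_fixed_length_tiling(self):
        male = {"A1": "A" * 10_000}
        contigs, origins = fragment_male_assembly(
            male, AssemblyEmulationSpec(family="fixed", mean_bp=1000, seed=0)
        )
        assert len(contigs) == 10
        assert all(len(s) == 1000 for _, s in contigs)
        assert "".join(s for _, s in contigs) == male["A1"]

    def test_lognormal_contracts(self):
        male, _, truth = simulate_genomes(SMALL)
        spec = AssemblyEmulationSpec(mean_bp=400, sigma=0.6, min_contig_bp=50,
                                     seed=12)
        contigs, origins = fragment_male_assembly(
            male, spec, ms_interval=(truth.ms_start, truth.ms_end)
        )
        assert all(len(s) >= 50 for _, s in contigs)
        by_chrom: dict[str, int] = {}
        for o, (_, s) in zip(origins, contigs):
            by_chrom[o.chromosome] = by_chrom.get(o.chromosome, 0) + len(s)
            assert s == male[o.chromosome][o.start:o.end]
        for chrom, total in by_chrom.items():
            assert total <= len(male[chrom])

    def test_origin_labels_match_interval_oracle(self):
        male, _, truth = simulate_genomes(SMALL)
        contigs, origins = fragment_male_assembly(
            male, AssemblyEmulationSpec(mean_bp=200, min_contig_bp=50, seed=13),
            ms_interval=(truth.ms_start, truth.ms_end),
        )
        for o in origins:
            if o.chromosome.startswith("A"):
                assert o.origin == "autosome"
            elif o.chromosome == "X":
                assert o.origin == "X"
            else:
                inside = o.start >= truth.ms_start and o.end <= truth.ms_end
                assert o.origin == ("Y-male-specific" if inside else "Y-shared")

    def test_heavy_truncation_warns(self):
        male = {"A1": "ACGT" * 1000}
        with pytest.warns(UserWarning, match="truncation"):
            fragment_male_assembly(
                male, AssemblyEmulationSpec(mean_bp=120, min_contig_bp=200, seed=0)
            )


class TestDatasetAndSeeds:
    def test_stage_seeds_are_deterministic_and_bounded(self):
        s1 = derive_stage_seeds(42)
        s2 = derive_stage_seeds(42)
        assert s1 == s2
        assert all(0 <= s < 2**31 for s in s1)
        assert derive_stage_seeds(43) != s1

    def test_simulate_dataset_writes_all_artifacts(self, tmp_path):
        spec = GenomeSpec(n_autosomes=1, autosome_bp=5000, x_bp=3000, y_bp=1000,
                          male_specific_fraction_of_y=0.8)
        paths = simulate_dataset(
            tmp_path / "sim",
            genome_spec=spec,
            read_spec=ReadSimSpec(coverage=2),
            assembly_spec=AssemblyEmulationSpec(mean_bp=500, min_contig_bp=50),
            master_seed=77,
        )
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
        truth = SimulationTruth.from_json(paths["truth_summary"])
        assert truth.y_male_specific_bp == 800
        header = (tmp_path / "sim" / "truth_contigs.tsv").read_text().splitlines()[0]
        assert header == "contig_id\torigin\tstart\tend\tchromosome"
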