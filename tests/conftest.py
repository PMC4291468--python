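"""Shared fixtures: simulated study replicates and small helpers.

The simulation-backed acceptance checks all run on the same study
conditions: a 500 kb haploid genome with a ~5% male-specific segment and
2% X-Y divergence, female reads at 30x coverage with 0.3% base error,
scanned with 21-mers (a k-mer length that preserves, at this reduced
genome scale, the k-mer uniqueness regime the method assumes at full
scale).  Replicates are expensive, so they are computed once per session.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # tests/naive.py

settings.register_profile(
    "malespec",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("malespec")

SIM_K = 21
N_REPLICATES = 20


def run_replicate(seed: int, coverage: float = 30.0, error_rate: float = 0.003,
                  k: int = SIM_K, tmpdir: Path | None = None):
    """One full simulate -> count -> scan run; returns (scan_df, truth)."""
    import tempfile

    from malespec import (
        AssemblyEmulationSpec,
        GenomeSpec,
        KmerParams,
        ReadSimSpec,
        build_assembly_index,
        build_female_kmer_set,
        scan_assembly,
        scan_to_frame,
        simulate_female_reads,
        simulate_genomes,
    )
    from malespec.simulate import derive_stage_seeds, fragment_male_assembly

    s_genome, s_reads, s_frag = derive_stage_seeds(seed)
    male, female, truth = simulate_genomes(GenomeSpec(seed=s_genome))
    with tempfile.TemporaryDirectory(dir=tmpdir) as td:
        fastq = Path(td) / "reads.fastq"
        simulate_female_reads(
            female,
            ReadSimSpec(coverage=coverage, error_rate=error_rate, seed=s_reads),
            fastq,
        )
        female_set = build_female_kmer_set(fastq, KmerParams(k=k))
    contigs, origins = fragment_male_assembly(
        male,
        AssemblyEmulationSpec(seed=s_frag),
        ms_interval=(truth.ms_start, truth.ms_end),
    )
    index = build_assembly_index(contigs, k)
    records = scan_assembly(contigs, index, female_set)
    df = scan_to_frame(records)
    df["origin"] = [o.origin for o in origins]
    return df, truth


@pytest.fixture(scope="session")
def study_replicates():
    """20 independent replicates of the study simulation (erroneous reads)."""
    return [run_replicate(seed) for seed in range(100, 100 + N_REPLICATES)]


@pytest.fixture(scope="session")
def error_free_replicates():
    """3 replicates with error-free reads, for recovery-accuracy checks."""
    return [run_replicate(seed, error_rate=0.0) for seed in (200, 201, 202)]


@pytest.fixture()
def write_fastq(tmp_path):
    """Write (seq, qual) pairs to a FASTQ file; returns the path."""

    def _write(reads, name="reads.fastq"):
        p = tmp_path / name
        with open(p, "w") as fh:
            for i, (seq, qual) in enumerate(reads):
                fh.write(f"@r{i}\n{seq}\n+\n{qual}\n")
        return p

    return _write


@pytest.fixture()
def write_fasta_file(tmp_path):
    def _write(records, name="contigs.fasta"):
        p = tmp_path / name
        with open(p, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return p

    return _write
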