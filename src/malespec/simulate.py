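"""Synthetic genomes, female reads, and fragmented male assemblies.

The generator emulates the data structure the male-specific-region scan
assumes, at a desk scale (default 500 kb haploid genome, a 1/1000-scale
stand-in for a ~500 Mb insect genome): a male genome of autosomes, an X,
and a Y whose distal segment is *male-specific* (absent from females);
the Y's proximal remainder is an X-derived, pseudo-recombining region
diverged from the X at a configurable per-base substitution rate.  The
female genome is the diploid complement (two identical copies of each
autosome and of the X — the sequenced line is treated as fully inbred).

From the female genome, single-end short reads with per-base substitution
errors and synthetic quality strings are drawn uniformly from both strands
of both haplotypes; from the male genome, a fragmented "assembly" is
emulated by tiling each chromosome with contigs of configurable length
distribution.  Every contig carries an origin label so the true
male-specific proportion of the simulated genome is known exactly.

All stages are deterministic given their seeds; one master seed derives
per-stage seeds via :func:`derive_stage_seeds`.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np

from .errors import SimulationSpecError
from .model import theoretical_msp

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class GenomeSpec:
    """Composition of the simulated genome.

    Defaults give a 500 kb haploid male genome emulating a three-
    chromosome-pair karyotype (two autosome pairs plus a homomorphic
    X/Y pair) whose male-specific segment is ~5% of the haploid genome.
    """

    n_autosomes: int = 2
    autosome_bp: int = 160_000
    x_bp: int = 152_000
    y_bp: int = 28_000
    male_specific_fraction_of_y: float = 0.9
    xy_divergence: float = 0.02
    repeat_fraction: float = 0.0
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_autosomes, self.autosome_bp, self.x_bp, self.y_bp) < 0:
            raise SimulationSpecError("sizes must be non-negative")
        for name in (
            "male_specific_fraction_of_y",
            "xy_divergence",
            "repeat_fraction",
            "gc_content",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationSpecError(f"{name} must be in [0, 1], got {v}")
        if self.male_specific_fraction_of_y > 0 and self.y_bp == 0:
            raise SimulationSpecError(
                "male_specific_fraction_of_y > 0 requires y_bp > 0"
            )


@dataclass(frozen=True)
class ReadSimSpec:
    """Female sequencing emulation: single-end reads, substitution errors.

    ``quality_model`` is either a constant Phred value for every base or a
    ``("decay", start, end)`` tuple for a linear per-position profile.
    Default coverage follows the ~12x female sequencing the pipeline is
    designed around; tests typically raise it.
    """

    coverage: float = 12.0
    read_length_bp: int = 75
    error_rate: float = 0.002
    quality_model: Union[int, tuple] = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise SimulationSpecError("coverage must be > 0")
        if not 0 <= self.error_rate < 1:
            raise SimulationSpecError("error_rate must be in [0, 1)")
        if self.read_length_bp < 1:
            raise SimulationSpecError("read_length_bp must be >= 1")


@dataclass(frozen=True)
class AssemblyEmulationSpec:
    """Contig-length emulation of a fragmented short-read assembly.

    ``family`` is ``"lognormal"`` (mean ``mean_bp``, log-scale ``sigma``)
    or ``"fixed"`` (every contig ``mean_bp`` long before truncation at
    chromosome ends).  Contigs shorter than ``min_contig_bp`` are dropped.
    """

    family: str = "lognormal"
    mean_bp: float = 3000.0
    sigma: float = 0.5
    min_contig_bp: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "fixed"):
            raise SimulationSpecError(f"unknown length family {self.family!r}")
        if self.mean_bp < 1:
            raise SimulationSpecError("mean_bp must be >= 1")
        if self.min_contig_bp < 1:
            raise SimulationSpecError("min_contig_bp must be >= 1")


@dataclass(frozen=True)
class ContigOrigin:
    """Ground-truth provenance of one simulated contig."""

    contig_id: str
    origin: str  # autosome | X | Y-shared | Y-male-specific
    chromosome: str
    start: int  # 0-based, half-open interval on the source chromosome
    end: int


@dataclass(frozen=True)
class SimulationTruth:
    """Realized composition of a simulated genome and its true MSP."""

    autosomes_bp: int
    x_bp: int
    y_bp: int
    y_male_specific_bp: int
    ms_start: int  # male-specific interval on Y, 0-based half-open
    ms_end: int
    true_msp_h: float
    true_msp_d: float

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SimulationTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# helpers


def derive_stage_seeds(master_seed: int, n: int = 3) -> list[int]:
    """Deterministic per-stage seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def _str_to_codes(seq: str) -> np.ndarray:
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty(a.size, dtype=np.uint8)
    for code, base in enumerate(b"ACGT"):
        out[a == base] = code
    return out


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` (never to itself)."""
    out = codes.copy()
    hit = rng.random(codes.size) < rate
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out.astype(np.uint8)


# ---------------------------------------------------------------------------
# operations


def simulate_genomes(
    spec: GenomeSpec,
) -> tuple[dict[str, str], dict[str, str], SimulationTruth]:
    """Generate the male haploid and female diploid reference genomes.

    Returns ``(male, female, truth)`` where ``male`` maps chromosome names
    (A1.., X, Y) to sequences, ``female`` maps haplotype-resolved names
    (A1_hap1.. X_hap2) to sequences, and ``truth`` records realized sizes
    and the true haploid/diploid male-specific proportions.  The female
    genome contains no copy of the Y's male-specific segment.
    """
    rng = np.random.default_rng(spec.seed)
    chroms: dict[str, np.ndarray] = {}
    for i in range(spec.n_autosomes):
        chroms[f"A{i + 1}"] = _random_codes(rng, spec.autosome_bp, spec.gc_content)
    chroms["X"] = _random_codes(rng, spec.x_bp, spec.gc_content)

    ms_len = int(round(spec.y_bp * spec.male_specific_fraction_of_y))
    shared_len = spec.y_bp - ms_len
    if shared_len > 0:
        if spec.x_bp == 0:
            raise SimulationSpecError(
                "a non-male-specific Y segment requires x_bp > 0"
            )
        reps = math.ceil(shared_len / spec.x_bp)
        template = np.tile(chroms["X"], reps)[:shared_len]
        shared = _mutate(template, spec.xy_divergence, rng)
    else:
        shared = np.empty(0, dtype=np.uint8)
    ms = _random_codes(rng, ms_len, spec.gc_content)
    if spec.y_bp > 0:
        chroms["Y"] = np.concatenate([shared, ms]).astype(np.uint8)

    if spec.repeat_fraction > 0:
        _plant_repeats(chroms, spec, rng)

    male = {name: _codes_to_str(c) for name, c in chroms.items()}
    female = {}
    for name, seq in male.items():
        if name == "Y":
            continue
        female[f"{name}_hap1"] = seq
        female[f"{name}_hap2"] = seq

    a_total = spec.n_autosomes * spec.autosome_bp
    truth = SimulationTruth(
        autosomes_bp=a_total,
        x_bp=spec.x_bp,
        y_bp=spec.y_bp,
        y_male_specific_bp=ms_len,
        ms_start=shared_len,
        ms_end=spec.y_bp,
        # the denominator counts the whole male genome, Y-shared included:
        # MSP_h = Y_ms/(X + Y + A), MSP_d = Y_ms/(X + Y + 2A)
        true_msp_h=(
            ms_len / (spec.x_bp + spec.y_bp + a_total)
            if (spec.x_bp + spec.y_bp + a_total)
            else 0.0
        ),
        true_msp_d=(
            ms_len / (spec.x_bp + spec.y_bp + 2 * a_total)
            if (spec.x_bp + spec.y_bp + a_total)
            else 0.0
        ),
    )
    return male, female, truth


def _plant_repeats(
    chroms: dict[str, np.ndarray], spec: GenomeSpec, rng: np.random.Generator
) -> None:
    """Overwrite windows with copies from a small shared repeat library."""
    elem_len = 500
    library = [_random_codes(rng, elem_len, spec.gc_content) for _ in range(5)]
    total = sum(c.size for c in chroms.values())
    n_copies = int(spec.repeat_fraction * total / elem_len)
    names = sorted(chroms)
    sizes = np.array([chroms[n].size for n in names], dtype=float)
    for _ in range(n_copies):
        name = names[rng.choice(len(names), p=sizes / sizes.sum())]
        arr = chroms[name]
        if arr.size <= elem_len:
            continue
        pos = int(rng.integers(0, arr.size - elem_len + 1))
        arr[pos : pos + elem_len] = library[int(rng.integers(0, len(library)))]


def _quality_string(model: Union[int, tuple], read_len: int) -> str:
    if isinstance(model, int):
        return chr(33 + model) * read_len
    kind, start, end = model
    if kind != "decay":
        raise SimulationSpecError(f"unknown quality model {model!r}")
    vals = np.linspace(start, end, read_len).round().astype(int)
    return "".join(chr(33 + v) for v in vals)


def simulate_female_reads(
    female_genome: dict[str, str],
    spec: ReadSimSpec,
    out_fastq: Union[str, Path],
) -> int:
    """Write single-end female reads as Phred+33 FASTQ; returns read count.

    Reads are drawn uniformly from both strands of every female sequence
    (haplotype copies included), with i.i.d. substitution errors at
    ``error_rate``.  Total bases match ``coverage x haploid genome size``
    to within one read length.  Byte-identical output for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    rl = spec.read_length_bp
    names = list(female_genome)
    shortest = min(len(s) for s in female_genome.values())
    if rl > shortest:
        raise SimulationSpecError(
            f"read_length_bp={rl} exceeds shortest chromosome ({shortest} bp)"
        )
    codes = {n: _str_to_codes(female_genome[n]) for n in names}
    haploid_size = sum(len(s) for s in female_genome.values()) / 2.0
    n_reads = int(round(spec.coverage * haploid_size / rl))

    starts_avail = np.array([codes[n].size - rl + 1 for n in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=n_reads, p=starts_avail / starts_avail.sum())
    u = rng.random(n_reads)
    rev = rng.random(n_reads) < 0.5

    mat = np.empty((n_reads, rl), dtype=np.uint8)
    starts = np.empty(n_reads, dtype=np.int64)
    window = np.arange(rl)
    for ci, name in enumerate(names):
        sel = np.flatnonzero(chrom_idx == ci)
        if sel.size == 0:
            continue
        s = np.floor(u[sel] * (codes[name].size - rl + 1)).astype(np.int64)
        starts[sel] = s
        mat[sel] = codes[name][s[:, None] + window]
    # reverse-complement the minus-strand reads
    mat[rev] = 3 - mat[rev][:, ::-1]
    if spec.error_rate > 0:
        hit = rng.random(mat.shape) < spec.error_rate
        mat[hit] = (mat[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4

    qual = _quality_string(spec.quality_model, rl)
    blob = _CODE_TO_BASE[mat].tobytes()
    with open(out_fastq, "w") as fh:
        for i in range(n_reads):
            name = names[chrom_idx[i]]
            strand = "-" if rev[i] else "+"
            fh.write(
                f"@r{i:07d}_{name}_{starts[i]}_{strand}\n"
                f"{blob[i * rl:(i + 1) * rl].decode('ascii')}\n+\n{qual}\n"
            )
    return n_reads


def fragment_male_assembly(
    male_genome: dict[str, str],
    spec: AssemblyEmulationSpec,
    ms_interval: tuple[int, int] | None = None,
) -> tuple[list[tuple[str, str]], list[ContigOrigin]]:
    """Tile each male chromosome with non-overlapping contigs.

    Contig lengths are drawn from the configured distribution, truncated
    at chromosome ends; pieces below ``min_contig_bp`` are dropped (their
    bases are lost, as in a real fragmented assembly).  Returns the contig
    list (id, sequence) and per-contig origin labels; a Y contig is
    labelled ``Y-male-specific`` exactly when its interval lies inside the
    male-specific interval ``ms_interval`` (0-based half-open on Y).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.family == "lognormal" and spec.mean_bp < spec.min_contig_bp:
        warnings.warn(
            "mean contig length below min_contig_bp: heavy truncation expected",
            stacklevel=2,
        )
    mu = math.log(spec.mean_bp) - spec.sigma**2 / 2.0

    contigs: list[tuple[str, str]] = []
    origins: list[ContigOrigin] = []
    idx = 0
    for chrom in male_genome:  # insertion order: deterministic
        seq = male_genome[chrom]
        pos = 0
        while pos < len(seq):
            if spec.family == "fixed":
                length = int(spec.mean_bp)
            else:
                length = max(1, int(round(rng.lognormal(mu, spec.sigma))))
            end = min(pos + length, len(seq))
            if end - pos >= spec.min_contig_bp:
                idx += 1
                cid = f"contig_{idx:05d}"
                contigs.append((cid, seq[pos:end]))
                origins.append(
                    ContigOrigin(cid, _origin(chrom, pos, end, ms_interval),
                                 chrom, pos, end)
                )
            pos = end
    return contigs, origins


def _origin(
    chrom: str, start: int, end: int, ms_interval: tuple[int, int] | None
) -> str:
    if chrom.startswith("A"):
        return "autosome"
    if chrom == "X":
        return "X"
    if ms_interval is not None and start >= ms_interval[0] and end <= ms_interval[1]:
        return "Y-male-specific"
    return "Y-shared"


# ---------------------------------------------------------------------------
# file output


def write_fasta(
    sequences: Union[dict[str, str], list[tuple[str, str]]],
    path: Union[str, Path],
    width: int = 80,
) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_tsv(origins: list[ContigOrigin], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\torigin\tstart\tend\tchromosome\n")
        for o in origins:
            fh.write(f"{o.contig_id}\t{o.origin}\t{o.start}\t{o.end}\t{o.chromosome}\n")


def simulate_dataset(
    out_dir: Union[str, Path],
    genome_spec: GenomeSpec = GenomeSpec(),
    read_spec: ReadSimSpec = ReadSimSpec(),
    assembly_spec: AssemblyEmulationSpec = AssemblyEmulationSpec(),
    master_seed: int | None = None,
) -> dict[str, Path]:
    """Run the full generator and write every artifact into ``out_dir``.

    When ``master_seed`` is given it overrides the per-spec seeds with
    seeds derived deterministically from it.  Returns a name -> path map
    of the written files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if master_seed is not None:
        s_genome, s_reads, s_frag = derive_stage_seeds(master_seed)
        genome_spec = replace(genome_spec, seed=s_genome)
        read_spec = replace(read_spec, seed=s_reads)
        assembly_spec = replace(assembly_spec, seed=s_frag)

    male, female, truth = simulate_genomes(genome_spec)
    paths = {
        "male_genome": out / "male_genome.fasta",
        "female_genome": out / "female_genome.fasta",
        "female_reads": out / "female_reads.fastq",
        "male_contigs": out / "male_contigs.fasta",
        "truth_contigs": out / "truth_contigs.tsv",
        "truth_summary": out / "truth_summary.json",
    }
    write_fasta(male, paths["male_genome"])
    write_fasta(female, paths["female_genome"])
    simulate_female_reads(female, read_spec, paths["female_reads"])
    contigs, origins = fragment_male_assembly(
        male, assembly_spec, ms_interval=(truth.ms_start, truth.ms_end)
    )
    write_fasta(contigs, paths["male_contigs"])
    write_truth_tsv(origins, paths["truth_contigs"])
    truth.to_json(paths["truth_summary"])
    return paths
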