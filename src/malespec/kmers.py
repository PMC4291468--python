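"""Canonical k-mer extraction, filtering and indexing.

This module replaces the external Jellyfish counting step of a YGS-style
male/female k-mer comparison with an in-package, testable implementation:

* female short reads (FASTQ) are quality-masked and counted into an exact
  :class:`KmerSet` of canonical k-mers seen at least ``min_count`` times;
* the male contig assembly (FASTA) is counted into an
  :class:`AssemblyKmerIndex` holding the multiplicity of every canonical
  k-mer across the whole contig set, from which "single copy" is defined.

K-mers are *canonical* throughout: a k-mer is represented by the
lexicographic minimum of itself and its reverse complement, collapsing the
strand ambiguity of shotgun reads.  Internally k-mers are packed two bits
per base into ``uint64`` codes (A=0, C=1, G=2, T=3), which preserves
lexicographic order; k up to 31 is supported.  Membership is exact — no
probabilistic structures — because downstream classification asserts exact
USC/MSC counts.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Union

import numpy as np

from .errors import (
    DuplicateContigError,
    InvalidSequenceError,
    MalformedRecordError,
)

logger = logging.getLogger(__name__)

MAX_K = 31

# base -> 2-bit code; lowercase accepted (soft-masked input is uppercased
# implicitly); everything else, including N, is invalid (code 255)
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _BASE_CODE[_b] = _i

_CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string (case-preserving on input)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Return the canonical form of ``kmer``.

    The canonical form is the lexicographic minimum of the (uppercased)
    k-mer and its reverse complement; the operation is idempotent.

    Raises
    ------
    InvalidSequenceError
        If the k-mer contains a character outside {A, C, G, T} (case
        insensitive).
    """
    up = kmer.upper()
    if any(c not in "ACGT" for c in up):
        raise InvalidSequenceError(f"non-ACGT character in k-mer {kmer!r}")
    rc = reverse_complement(up)
    return min(up, rc)


@dataclass(frozen=True)
class KmerParams:
    """Parameters of the female-read k-mer filter.

    Defaults follow the Jellyfish invocation the pipeline emulates:
    15-mers, bases below Phred 20 masked, Phred+33 qualities, and k-mers
    seen fewer than 5 times discarded.
    """

    k: int = 15
    min_base_quality: int = 20
    quality_offset: int = 33
    min_count: int = 5

    def __post_init__(self) -> None:
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.quality_offset not in (33, 64):
            raise ValueError("quality_offset must be 33 or 64")


def _encode_canonical(seq: Union[str, bytes], k: int) -> np.ndarray:
    """Canonical 2-bit codes of every valid k-mer window of ``seq``.

    Windows containing any non-ACGT character are dropped.  Returns a
    uint64 array in window order (duplicates retained).
    """
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    a = np.frombuffer(seq, dtype=np.uint8)
    n = a.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = _BASE_CODE[a]
    invalid = codes == 255
    c = np.where(invalid, 0, codes).astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        fwd |= c[j : j + n] << np.uint64(2 * (k - 1 - j))
        rev |= (three ^ c[j : j + n]) << np.uint64(2 * j)
    # a window is valid iff it contains no invalid base
    bad = np.cumsum(invalid)
    n_bad = bad[k - 1 :].copy()
    n_bad[1:] -= bad[: n - 1]
    canon = np.minimum(fwd, rev)
    return canon[n_bad == 0]


def _decode(codes: np.ndarray, k: int) -> list[str]:
    """Decode packed k-mer codes back to ACGT strings."""
    codes = np.asarray(codes, dtype=np.uint64)
    out = np.empty((codes.size, k), dtype=np.uint8)
    for j in range(k):
        out[:, j] = _CODE_BASE[
            ((codes >> np.uint64(2 * (k - 1 - j))) & np.uint64(3)).astype(np.uint8)
        ]
    blob = out.tobytes()
    return [blob[i * k : (i + 1) * k].decode("ascii") for i in range(codes.size)]


def mask_low_quality(read_seq: str, read_qual: str, params: KmerParams) -> str:
    """Mask low-quality and non-ACGT bases of one read with ``N``.

    Every base whose Phred score (ASCII code minus ``quality_offset``) is
    below ``min_base_quality``, and every base that is not A/C/G/T, is
    replaced by ``N`` so that any k-mer window covering it is skipped by
    the counters.  This emulates Jellyfish's min-quality behaviour of
    converting low-quality bases to N.
    """
    if len(read_seq) != len(read_qual):
        raise MalformedRecordError(
            f"sequence length {len(read_seq)} != quality length {len(read_qual)}"
        )
    s = np.frombuffer(read_seq.upper().encode("ascii"), dtype=np.uint8).copy()
    q = np.frombuffer(read_qual.encode("ascii"), dtype=np.uint8)
    bad = (q.astype(np.int16) - params.quality_offset < params.min_base_quality) | (
        _BASE_CODE[s] == 255
    )
    s[bad] = ord("N")
    return s.tobytes().decode("ascii")


class KmerSet:
    """Exact set of canonical k-mers (the female k-mer collection).

    Stores a sorted, deduplicated ``uint64`` array of packed canonical
    codes.  Exact by construction: membership queries have no false
    positives or negatives.
    """

    def __init__(self, k: int, codes: np.ndarray, params: KmerParams | None = None):
        self.k = int(k)
        codes = np.asarray(codes, dtype=np.uint64)
        self.codes = np.unique(codes)  # sorted + deduplicated
        self.params = params

    @classmethod
    def from_strings(cls, k: int, kmers: Iterable[str]) -> "KmerSet":
        codes = [_encode_canonical(canonicalize(m), k)[0] for m in kmers]
        return cls(k, np.array(codes, dtype=np.uint64))

    def __len__(self) -> int:
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            return False
        code = _encode_canonical(canonicalize(kmer), self.k)
        if code.size == 0:
            return False
        return bool(self.contains_codes(code)[0])

    def contains_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorised membership for an array of packed canonical codes."""
        codes = np.asarray(codes, dtype=np.uint64)
        idx = np.searchsorted(self.codes, codes)
        idx_c = np.minimum(idx, max(self.codes.size - 1, 0))
        if self.codes.size == 0:
            return np.zeros(codes.shape, dtype=bool)
        return self.codes[idx_c] == codes

    @property
    def members(self) -> list[str]:
        """All members as strings, in sorted (= canonical code) order."""
        return _decode(self.codes, self.k)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerSet):
            return NotImplemented
        return self.k == other.k and np.array_equal(self.codes, other.codes)

    # -- persistence: sorted text, one canonical k-mer per line -------------

    def save(self, path: Union[str, Path]) -> None:
        p = self.params or KmerParams(k=self.k)
        with open(path, "w") as fh:
            fh.write(
                "#malespec-kmerset\tk=%d\tmin_count=%d\tmin_base_quality=%d"
                "\tquality_offset=%d\n"
                % (self.k, p.min_count, p.min_base_quality, p.quality_offset)
            )
            for m in self.members:
                fh.write(m + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "KmerSet":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("#malespec-kmerset"):
                raise MalformedRecordError(f"{path}: not a malespec k-mer set file")
            kv = dict(item.split("=") for item in header.split("\t")[1:])
            params = KmerParams(
                k=int(kv["k"]),
                min_base_quality=int(kv["min_base_quality"]),
                quality_offset=int(kv["quality_offset"]),
                min_count=int(kv["min_count"]),
            )
            k = params.k
            codes = [
                _encode_canonical(line.strip(), k)[0] for line in fh if line.strip()
            ]
        return cls(k, np.array(codes, dtype=np.uint64), params=params)


@dataclass
class AssemblyKmerIndex:
    """Multiplicity of every canonical k-mer across a male contig set.

    ``codes`` is sorted; ``counts[i]`` is the number of valid windows of
    the whole assembly whose canonical form is ``codes[i]``.  A k-mer is
    *single copy* iff its count is exactly 1 (assembly-wide).
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray

    def lookup_counts(self, query: np.ndarray) -> np.ndarray:
        """Occurrence count for each packed code in ``query`` (0 if absent)."""
        query = np.asarray(query, dtype=np.uint64)
        if self.codes.size == 0:
            return np.zeros(query.shape, dtype=np.int64)
        idx = np.searchsorted(self.codes, query)
        idx_c = np.minimum(idx, self.codes.size - 1)
        hit = self.codes[idx_c] == query
        out = np.where(hit, self.counts[idx_c], 0)
        return out.astype(np.int64)

    def count(self, kmer: str) -> int:
        code = _encode_canonical(canonicalize(kmer), self.k)
        return int(self.lookup_counts(code)[0]) if code.size else 0

    @property
    def total_windows(self) -> int:
        return int(self.counts.sum())


# ---------------------------------------------------------------------------
# input iteration


def _iter_fastq(
    source: Union[str, Path, Iterable],
) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality) from a FASTQ path or an iterable.

    Iterables may contain (seq, qual) or (name, seq, qual) tuples, which is
    convenient for tests and in-memory pipelines.
    """
    if isinstance(source, (str, Path)):
        import pysam

        try:
            with pysam.FastxFile(os.fspath(source)) as fh:
                for rec in fh:
                    if rec.sequence is None or rec.quality is None:
                        raise MalformedRecordError(
                            f"truncated FASTQ record {rec.name!r}"
                        )
                    yield rec.name, rec.sequence, rec.quality
        except (OSError, ValueError) as exc:  # pysam's malformed-input errors
            raise MalformedRecordError(f"{source}: {exc}") from exc
    else:
        for i, item in enumerate(source):
            if len(item) == 2:
                seq, qual = item
                name = f"read{i}"
            else:
                name, seq, qual = item
            yield name, seq, qual


def _iter_fasta(source: Union[str, Path, Iterable]) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) from a FASTA path or an iterable of pairs."""
    if isinstance(source, (str, Path)):
        import pysam

        with pysam.FastxFile(os.fspath(source)) as fh:
            for rec in fh:
                yield rec.name, rec.sequence or ""
    else:
        for name, seq in source:
            yield name, seq


# ---------------------------------------------------------------------------
# counting


def build_female_kmer_set(
    reads: Union[str, Path, Iterable],
    params: KmerParams | None = None,
    chunk_bases: int = 8_000_000,
) -> KmerSet:
    """Count canonical k-mers of quality-masked female reads.

    Reads are quality-masked (:func:`mask_low_quality`), concatenated with
    ``N`` separators so windows never span two reads, and every valid
    canonical window counted.  K-mers observed at least ``params.min_count``
    times are retained.  Deterministic for a given input.
    """
    params = params or KmerParams()
    k = params.k
    minq_char_threshold = params.quality_offset + params.min_base_quality

    chunks: list[np.ndarray] = []
    seqs: list[str] = []
    quals: list[str] = []
    pending = 0
    n_reads = 0

    def flush() -> None:
        nonlocal pending
        if not seqs:
            return
        blob = np.frombuffer(
            "N".join(seqs).upper().encode("ascii"), dtype=np.uint8
        ).copy()
        qblob = np.frombuffer("\x00".join(quals).encode("ascii"), dtype=np.uint8)
        blob[qblob < minq_char_threshold] = ord("N")
        chunks.append(_encode_canonical(blob.tobytes(), k))
        seqs.clear()
        quals.clear()
        pending = 0

    for name, seq, qual in _iter_fastq(reads):
        if len(seq) != len(qual):
            raise MalformedRecordError(
                f"record {name!r}: sequence length {len(seq)} != "
                f"quality length {len(qual)}"
            )
        n_reads += 1
        seqs.append(seq)
        quals.append(qual)
        pending += len(seq)
        if pending >= chunk_bases:
            flush()
    flush()

    if n_reads == 0:
        logger.warning("no reads in input; female k-mer set is empty")
        return KmerSet(k, np.empty(0, dtype=np.uint64), params=params)

    all_codes = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    uniq, counts = np.unique(all_codes, return_counts=True)
    return KmerSet(k, uniq[counts >= params.min_count], params=params)


def count_reads_kmers(
    reads: Union[str, Path, Iterable], params: KmerParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Unfiltered (codes, counts) of the quality-masked reads — no
    min-count threshold.  Exposed for diagnostics and tests."""
    params = params or KmerParams()
    chunks = [
        _encode_canonical(mask_low_quality(seq, qual, params), params.k)
        for _, seq, qual in _iter_fastq(reads)
    ]
    all_codes = (
        np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    )
    return np.unique(all_codes, return_counts=True)


def build_assembly_index(
    contigs: Union[str, Path, Iterable], k: int
) -> AssemblyKmerIndex:
    """Count every valid canonical k-mer window across all contigs.

    Raises
    ------
    DuplicateContigError
        If two contigs share an identifier (downstream tables key on it).
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    seen: set[str] = set()
    chunks: list[np.ndarray] = []
    for name, seq in _iter_fasta(contigs):
        if name in seen:
            raise DuplicateContigError(f"duplicate contig identifier {name!r}")
        seen.add(name)
        chunks.append(_encode_canonical(seq.upper(), k))
    all_codes = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    codes, counts = np.unique(all_codes, return_counts=True)
    return AssemblyKmerIndex(k=k, codes=codes, counts=counts.astype(np.int64))
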