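"""Independent brute-force oracles for k-mer counting and classification.

Deliberately naive (string-based, O(L*k)) and implemented without any of
the package's encoding machinery, so they can serve as an independent
reference on small inputs.
"""

from __future__ import annotations

_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_revcomp(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s))


def naive_canonical(kmer: str) -> str:
    rc = naive_revcomp(kmer)
    return kmer if kmer <= rc else rc


def naive_window_kmers(seq: str, k: int) -> list[str]:
    """Canonical k-mers of every valid window (non-ACGT windows skipped)."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(c in "ACGT" for c in w):
            out.append(naive_canonical(w))
    return out

def naive_counts(seqs: list[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        for m in naive_window_kmers(seq, k):
            counts[m] = counts.get(m, 0) + 1
    return counts


def naive_mask(seq: str, qual: str, min_q: int, offset: int) -> str:
    out = []
    for c, q in zip(seq.upper(), qual):
        ok = c in "ACGT" and (ord(q) - offset) >= min_q
        out.append(c if ok else "N")
    return "".join(out)


def naive_female_set(
    reads: list[tuple[str, str]], k: int, min_q: int, offset: int, min_count: int
) -> set[str]:
    masked = [naive_mask(s, q, min_q, offset) for s, q in reads]
    counts = naive_counts(masked, k)
    return {m for m, c in counts.items() if c >= min_count}


def naive_classify(
    contig: str, assembly_counts: dict[str, int], female: set[str], k: int
) -> tuple[int, int, int]:
    """(sc, usc, msc) for one contig under assembly-wide single-copy."""
    sc = usc = msc = 0
    for m in naive_window_kmers(contig, k):
        if assembly_counts[m] == 1:
            sc += 1
            if m in female:
                msc += 1
            else:
                usc += 1
    return sc, usc, msc
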