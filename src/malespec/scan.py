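"""Per-contig single-copy k-mer classification against the female set.

This is the chromosome-scan stage: every valid k-mer window of a male
contig is looked up in the assembly-wide index; windows occurring exactly
once in the whole assembly are *single copy* (SC).  Each SC k-mer is then
matched against the female k-mer set: absent k-mers are *unmatched single
copy* (USC, evidence of male-specificity), present ones *matched single
copy* (MSC).  A contig's %USC = 100·USC/(USC+MSC) is the scan statistic:
~100% suggests a male-specific contig, ~0% an autosomal or X contig.

"Single copy" is assembly-wide by default (a k-mer shared between two
contigs is repetitive and uninformative); a contig-local variant is
available via ``sc_scope="contig"`` for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .errors import ConfigError
from .kmers import AssemblyKmerIndex, KmerSet, _encode_canonical

FLAG_OK = "OK"
FLAG_NO_SC = "NO_SC_KMERS"

SCAN_COLUMNS = [
    "contig_id",
    "length_bp",
    "sc_kmers",
    "usc_kmers",
    "msc_kmers",
    "pct_usc",
    "flag",
]


@dataclass(frozen=True)
class ContigClassification:
    """Scan record for one contig.

    ``pct_usc`` is NaN (and ``flag`` is ``NO_SC_KMERS``) when the contig
    has no single-copy k-mers; otherwise usc + msc == sc holds exactly.
    """

    contig_id: str
    length_bp: int
    sc_kmers: int
    usc_kmers: int
    msc_kmers: int
    pct_usc: float
    flag: str = FLAG_OK


def classify_contig(
    contig_seq: str,
    contig_id: str,
    index: AssemblyKmerIndex,
    female: KmerSet,
    sc_scope: str = "assembly",
) -> ContigClassification:
    """Classify one contig's single-copy k-mers as USC vs MSC.

    Parameters
    ----------
    sc_scope
        ``"assembly"`` (default): a k-mer is single copy iff it occurs
        exactly once across the entire assembly.  ``"contig"``: iff it
        occurs exactly once within this contig (its multiplicity elsewhere
        is ignored).
    """
    if index.k != female.k:
        raise ConfigError(
            f"k mismatch: assembly index built with k={index.k}, "
            f"female k-mer set with k={female.k}"
        )
    if sc_scope not in ("assembly", "contig"):
        raise ValueError(f"sc_scope must be 'assembly' or 'contig', got {sc_scope!r}")

    codes = _encode_canonical(contig_seq.upper(), index.k)
    if sc_scope == "assembly":
        counts = index.lookup_counts(codes)
        sc_codes = codes[counts == 1]
    else:
        uniq, local = np.unique(codes, return_counts=True)
        sc_codes = uniq[local == 1]

    sc = int(sc_codes.size)
    if sc == 0:
        return ContigClassification(
            contig_id, len(contig_seq), 0, 0, 0, math.nan, FLAG_NO_SC
        )
    msc = int(female.contains_codes(sc_codes).sum())
    usc = sc - msc
    return ContigClassification(
        contig_id, len(contig_seq), sc, usc, msc, 100.0 * usc / sc, FLAG_OK
    )


def scan_assembly(
    contigs: Union[str, Path, Iterable],
    index: AssemblyKmerIndex,
    female: KmerSet,
    sc_scope: str = "assembly",
) -> list[ContigClassification]:
    """Classify every contig of the assembly, in input order.

    Contigs shorter than k are emitted with ``sc_kmers == 0`` and the
    ``NO_SC_KMERS`` flag, not treated as errors: their length still counts
    in the estimator's denominator.
    """
    from .kmers import _iter_fasta

    return [
        classify_contig(seq, name, index, female, sc_scope=sc_scope)
        for name, seq in _iter_fasta(contigs)
    ]


def scan_to_frame(records: Iterable[ContigClassification]) -> pd.DataFrame:
    """Scan records as a DataFrame with the canonical column order."""
    return pd.DataFrame([r.__dict__ for r in records], columns=SCAN_COLUMNS)


def write_scan_tsv(
    records: Iterable[ContigClassification], path: Union[str, Path]
) -> None:
    """Write the scan table (TSV, %USC to one decimal, NA when undefined)."""
    df = scan_to_frame(records).copy()
    df["pct_usc"] = df["pct_usc"].map(
        lambda v: "NA" if pd.isna(v) else f"{v:.1f}"
    )
    df.to_csv(path, sep="\t", index=False)


def read_scan_tsv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a scan TSV back into a DataFrame (pct_usc as float, NaN for NA)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(SCAN_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: scan table missing columns {sorted(missing)}")
    return df[SCAN_COLUMNS]
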