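"""Report tables derived from a contig scan.

Currently one artifact: the 2D histogram of log10(contig size) vs %USC
that visualises the two-peak structure (male-specific contigs near 100%
USC, autosomal/X contigs near 0%).  Tables, not plots, are the contract;
the TSV can be rendered with any plotting tool.
"""

from __future__ import annotations

from typing import Iterable, Union

import numpy as np
import pandas as pd

from .scan import ContigClassification, scan_to_frame

HEATMAP_COLUMNS = [
    "log10_size_lo",
    "log10_size_hi",
    "pct_usc_lo",
    "pct_usc_hi",
    "count",
]


def heatmap_table(
    records: Union[pd.DataFrame, Iterable[ContigClassification]],
    n_size_bins: int = 30,
    n_pct_bins: int = 20,
) -> pd.DataFrame:
    """2D histogram of log10(length) x %USC over classifiable contigs.

    Contigs without single-copy k-mers (undefined %USC) are excluded; the
    counts of the returned table therefore sum to the number of
    classifiable contigs.  %USC bins span [0, 100] with the last bin
    closed; size bins span the observed log10-length range.
    """
    df = records if isinstance(records, pd.DataFrame) else scan_to_frame(list(records))
    usable = df[df["sc_kmers"] > 0]
    if usable.empty:
        raise ValueError("no classifiable contigs (all lack single-copy k-mers)")
    logsize = np.log10(usable["length_bp"].to_numpy(dtype=float))
    pct = usable["pct_usc"].to_numpy(dtype=float)
    lo, hi = logsize.min(), logsize.max()
    if lo == hi:
        hi = lo + 1e-9
    counts, size_edges, pct_edges = np.histogram2d(
        logsize, pct, bins=[n_size_bins, n_pct_bins], range=[[lo, hi], [0.0, 100.0]]
    )
    rows = []
    for i in range(n_size_bins):
        for j in range(n_pct_bins):
            rows.append(
                {
                    "log10_size_lo": size_edges[i],
                    "log10_size_hi": size_edges[i + 1],
                    "pct_usc_lo": pct_edges[j],
                    "pct_usc_hi": pct_edges[j + 1],
                    "count": int(counts[i, j]),
                }
            )
    return pd.DataFrame(rows, columns=HEATMAP_COLUMNS)
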