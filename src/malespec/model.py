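"""Beta-binomial estimator of the male-specific proportion (MSP) of a genome.

Model
-----
For each putatively male-specific contig (all of its single-copy k-mers
unmatched in the female set, or above a configurable %USC threshold), the
probability that the contig is truly male-specific is modelled with a
binomial likelihood on its USC/MSC k-mer counts under a conjugate
beta(a, b) prior.  The prior is parameterised by a *prior weight*
PW = a + b and a prior mean p0 (default 2x10^-4, i.e. a prior expected
male-specific genome fraction of 0.02%):

    a = PW * p0,    b = PW * (1 - p0)

The posterior is beta(a + USC, b + MSC) with mean

    E[p | k-mers] = (a + USC) / (a + b + USC + MSC)

so with PW = 1 a 100%-USC contig carrying a single single-copy k-mer has
posterior probability ~50% of being male-specific, and with PW = 22 the
same holds at 22 single-copy k-mers.

The genome-wide estimate length-weights these posteriors: contigs below a
size cutoff are removed; each qualifying contig contributes posterior x
length to the numerator; the denominator is the total length of *all*
contigs above the cutoff.  The quotient is the expected male-specific
proportion.  Treated conservatively as the haploid-denominator quantity
MSP_h = Y/(X+Y+A), halving it lower-bounds the diploid-denominator
MSP_d = Y/(X+Y+2A); multiplying by the diploid genome size gives a lower
bound on the absolute male-specific genome size.

The public surface is both functional (:func:`prior_from_weight`,
:func:`posterior_expectation`, :func:`estimate_msp`, :func:`msp_bounds`,
:func:`theoretical_msp`, :func:`sweep`) and object-oriented: build a
:class:`MaleSpecificProportion` model from a scan table and call
``fit()`` / ``sweep()`` on it; ``fit()`` returns :class:`MSPResults` with
a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .scan import SCAN_COLUMNS, ContigClassification, read_scan_tsv, scan_to_frame

logger = logging.getLogger(__name__)

DEFAULT_P0 = 2e-4
DEFAULT_CUTOFFS = (0, 1000, 2000, 3000)
DEFAULT_PRIOR_WEIGHTS = tuple(range(1, 71))

SWEEP_COLUMNS = [
    "cutoff_bp",
    "prior_weight",
    "a",
    "b",
    "n_contigs_used",
    "total_length_bp",
    "msp_raw",
    "msp_raw_pct",
    "msp_d_lower_pct",
    "absolute_lower_Mb",
]


@dataclass(frozen=True)
class PriorSpec:
    """Beta prior beta(a, b) with a + b = prior_weight and mean p0."""

    prior_weight: float
    p0: float = DEFAULT_P0
    a: float = field(init=False)
    b: float = field(init=False)

    def __post_init__(self) -> None:
        if self.prior_weight <= 0:
            raise ValueError(f"prior_weight must be > 0, got {self.prior_weight}")
        if not 0 < self.p0 < 1:
            raise ValueError(f"p0 must be in (0, 1), got {self.p0}")
        object.__setattr__(self, "a", self.prior_weight * self.p0)
        object.__setattr__(self, "b", self.prior_weight * (1.0 - self.p0))


def prior_from_weight(prior_weight: float, p0: float = DEFAULT_P0) -> PriorSpec:
    """Solve a + b = PW, a/(a+b) = p0 for the beta prior parameters."""
    return PriorSpec(prior_weight=prior_weight, p0=p0)


@dataclass(frozen=True)
class EstimatorConfig:
    """Aggregation settings: size cutoff, %USC qualification rule, prior."""

    prior: PriorSpec
    size_cutoff_bp: int = 0
    usc_threshold_pct: float = 100.0

    def __post_init__(self) -> None:
        if self.size_cutoff_bp < 0:
            raise ValueError("size_cutoff_bp must be >= 0")
        if not 0 < self.usc_threshold_pct <= 100:
            raise ValueError("usc_threshold_pct must be in (0, 100]")


def posterior_expectation(prior: PriorSpec, usc: int, msc: int) -> float:
    """Posterior mean probability that a contig is male-specific.

    (a + USC) / (a + b + USC + MSC); strictly inside (0, 1).
    """
    if usc < 0 or msc < 0:
        raise ValueError("usc and msc must be non-negative")
    return (prior.a + usc) / (prior.a + prior.b + usc + msc)


def posterior_density(prior: PriorSpec, usc: int, msc: int, x) -> float:
    """Density of the beta(a + USC, b + MSC) posterior at ``x`` in (0, 1)."""
    x_arr = np.asarray(x, dtype=float)
    if np.any((x_arr <= 0) | (x_arr >= 1)):
        raise ValueError("x must lie strictly inside (0, 1)")
    d = stats.beta.pdf(x_arr, prior.a + usc, prior.b + msc)
    return float(d) if np.isscalar(x) or x_arr.ndim == 0 else d


@dataclass(frozen=True)
class RawEstimate:
    """The length-weighted quotient before the haploid/diploid bounds."""

    msp_raw: float
    n_contigs_used: int
    total_length_bp: int


@dataclass(frozen=True)
class MSPResults:
    """Male-specific proportion estimate with conservative bounds.

    ``msp_raw`` is the length-weighted posterior quotient (read as the
    haploid-denominator proportion), ``msp_d_lower = msp_raw / 2`` the
    lower bound on the diploid-denominator proportion, and
    ``absolute_size_lower_bp`` that bound scaled by the diploid genome
    size (None when no genome size was supplied).
    """

    msp_raw: float
    msp_d_lower: float
    diploid_genome_size_bp: int | None = None
    absolute_size_lower_bp: float | None = None
    n_contigs_used: int = 0
    total_length_bp: int = 0
    prior: PriorSpec | None = None
    config: EstimatorConfig | None = None

    @property
    def absolute_size_lower_mb(self) -> float | None:
        if self.absolute_size_lower_bp is None:
            return None
        return self.absolute_size_lower_bp / 1e6

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Male-specific proportion estimate",
            "=" * 49,
        ]
        if self.prior is not None:
            lines += [
                f"{'Prior weight (a+b)':<34}{self.prior.prior_weight:>15g}",
                f"{'Prior mean p0':<34}{self.prior.p0:>15g}",
                f"{'Prior a':<34}{self.prior.a:>15.6g}",
                f"{'Prior b':<34}{self.prior.b:>15.6g}",
            ]
        if self.config is not None:
            lines += [
                f"{'Size cutoff (bp)':<34}{self.config.size_cutoff_bp:>15d}",
                f"{'%USC threshold':<34}{self.config.usc_threshold_pct:>15g}",
            ]
        lines += [
            f"{'Contigs in numerator':<34}{self.n_contigs_used:>15d}",
            f"{'Total length >= cutoff (bp)':<34}{self.total_length_bp:>15d}",
            "-" * 49,
            f"{'MSP (haploid reading, raw)':<34}{self.msp_raw:>15.6f}",
            f"{'MSP (raw, %)':<34}{100 * self.msp_raw:>14.2f}%",
            f"{'MSP_d lower bound':<34}{self.msp_d_lower:>15.6f}",
            f"{'MSP_d lower bound (%)':<34}{100 * self.msp_d_lower:>14.2f}%",
        ]
        if self.absolute_size_lower_bp is not None:
            lines.append(
                f"{'Absolute size lower bound (Mb)':<34}"
                f"{self.absolute_size_lower_mb:>15.3f}"
            )
        lines.append("=" * 49)
        return "\n".join(lines)


def _as_frame(
    records: Union[pd.DataFrame, Iterable[ContigClassification]],
) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return scan_to_frame(list(records))


def estimate_msp(
    records: Union[pd.DataFrame, Iterable[ContigClassification]],
    config: EstimatorConfig,
) -> RawEstimate:
    """Length-weighted posterior estimate of the male-specific proportion.

    Numerator: sum over contigs with length >= cutoff, at least one
    single-copy k-mer, and %USC >= threshold of posterior x length.
    Denominator: total length of *all* contigs with length >= cutoff
    (contigs without single-copy k-mers included).  Returns 0 with a
    warning when the denominator is empty.
    """
    df = _as_frame(records)
    if df.empty:
        logger.warning("empty scan table; msp_raw = 0")
        return RawEstimate(0.0, 0, 0)

    above = df[df["length_bp"] >= config.size_cutoff_bp]
    total_length = int(above["length_bp"].sum())
    if total_length == 0:
        logger.warning("no contigs at or above the size cutoff; msp_raw = 0")
        return RawEstimate(0.0, 0, 0)

    sc = above["sc_kmers"].to_numpy()
    usc = above["usc_kmers"].to_numpy()
    # exact-integer qualification: usc/sc*100 >= threshold, robust at 100
    qualifies = (sc > 0) & (100 * usc >= config.usc_threshold_pct * sc)
    q = above[qualifies]
    post = (config.prior.a + q["usc_kmers"].to_numpy()) / (
        config.prior.a
        + config.prior.b
        + q["usc_kmers"].to_numpy()
        + q["msc_kmers"].to_numpy()
    )
    numerator = float((post * q["length_bp"].to_numpy()).sum())
    return RawEstimate(numerator / total_length, int(qualifies.sum()), total_length)


def msp_bounds(
    msp_raw: float,
    diploid_genome_size_bp: int | None,
    *,
    n_contigs_used: int = 0,
    total_length_bp: int = 0,
    prior: PriorSpec | None = None,
    config: EstimatorConfig | None = None,
) -> MSPResults:
    """Conservative bounds: read the raw quotient as the haploid-denominator
    proportion, halve it to lower-bound the diploid-denominator proportion,
    and scale by the diploid genome size for an absolute lower bound."""
    if not 0 <= msp_raw <= 1:
        raise ValueError(f"msp_raw must be in [0, 1], got {msp_raw}")
    msp_d_lower = msp_raw / 2.0
    absolute = None
    if diploid_genome_size_bp is not None:
        if diploid_genome_size_bp <= 0:
            raise ValueError("diploid_genome_size_bp must be > 0")
        absolute = msp_d_lower * diploid_genome_size_bp
    return MSPResults(
        msp_raw=msp_raw,
        msp_d_lower=msp_d_lower,
        diploid_genome_size_bp=diploid_genome_size_bp,
        absolute_size_lower_bp=absolute,
        n_contigs_used=n_contigs_used,
        total_length_bp=total_length_bp,
        prior=prior,
        config=config,
    )


def theoretical_msp(
    y_bp: float, x_bp: float, autosomes_bp: float, mode: str = "haploid"
) -> float:
    """Expected male-specific proportion from known chromosome sizes.

    haploid: Y/(X+Y+A); diploid: Y/(X+Y+2A), A = total autosomal bases.
    """
    if min(y_bp, x_bp, autosomes_bp) < 0:
        raise ValueError("chromosome sizes must be non-negative")
    if mode == "haploid":
        denom = x_bp + y_bp + autosomes_bp
    elif mode == "diploid":
        denom = x_bp + y_bp + 2 * autosomes_bp
    else:
        raise ValueError(f"mode must be 'haploid' or 'diploid', got {mode!r}")
    if denom == 0:
        raise ValueError("zero denominator: all sizes are zero")
    return y_bp / denom


def sweep(
    records: Union[pd.DataFrame, Iterable[ContigClassification]],
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
    prior_weights: Sequence[float] = DEFAULT_PRIOR_WEIGHTS,
    usc_threshold_pct: float = 100.0,
    p0: float = DEFAULT_P0,
    diploid_genome_size_bp: int | None = None,
) -> pd.DataFrame:
    """Estimate over the cutoff x prior-weight grid; one row per point."""
    if len(cutoffs) == 0 or len(prior_weights) == 0:
        raise ValueError("cutoff and prior-weight grids must be non-empty")
    df = _as_frame(records)
    rows = []
    for cutoff in cutoffs:
        for pw in prior_weights:
            prior = prior_from_weight(pw, p0)
            cfg = EstimatorConfig(
                prior=prior,
                size_cutoff_bp=int(cutoff),
                usc_threshold_pct=usc_threshold_pct,
            )
            raw = estimate_msp(df, cfg)
            res = msp_bounds(
                raw.msp_raw,
                diploid_genome_size_bp,
                n_contigs_used=raw.n_contigs_used,
                total_length_bp=raw.total_length_bp,
                prior=prior,
                config=cfg,
            )
            rows.append(
                {
                    "cutoff_bp": int(cutoff),
                    "prior_weight": float(pw),
                    "a": prior.a,
                    "b": prior.b,
                    "n_contigs_used": raw.n_contigs_used,
                    "total_length_bp": raw.total_length_bp,
                    "msp_raw": raw.msp_raw,
                    "msp_raw_pct": 100 * raw.msp_raw,
                    "msp_d_lower_pct": 100 * res.msp_d_lower,
                    "absolute_lower_Mb": res.absolute_size_lower_mb,
                }
            )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def log_spaced_weights(
    low: float = 1.0, high: float = 10_000.0, n: int = 25
) -> list[float]:
    """Log-spaced prior-weight grid for wide sensitivity sweeps."""
    return list(np.geomspace(low, high, n))


class MaleSpecificProportion:
    """Length-weighted beta-binomial model of male-specific genome content.

    Parameters
    ----------
    scan
        Per-contig scan records (a DataFrame with the scan-table columns
        or an iterable of :class:`ContigClassification`).
    diploid_genome_size_bp
        Diploid genome size used to convert proportions to absolute sizes;
        optional.

    Examples
    --------
    >>> model = MaleSpecificProportion.from_scan_tsv("scan.tsv",
    ...                                              diploid_genome_size_bp=10**9)
    >>> res = model.fit(prior_weight=22, size_cutoff_bp=1000)
    >>> print(res.summary())
    """

    def __init__(
        self,
        scan: Union[pd.DataFrame, Iterable[ContigClassification]],
        diploid_genome_size_bp: int | None = None,
    ):
        self.scan = _as_frame(scan)
        missing = set(SCAN_COLUMNS) - set(self.scan.columns)
        if missing:
            raise ValueError(f"scan table missing columns {sorted(missing)}")
        self.diploid_genome_size_bp = diploid_genome_size_bp

    @classmethod
    def from_scan_tsv(
        cls, path: Union[str, Path], diploid_genome_size_bp: int | None = None
    ) -> "MaleSpecificProportion":
        return cls(read_scan_tsv(path), diploid_genome_size_bp)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, diploid_genome_size_bp: int | None = None
    ) -> "MaleSpecificProportion":
        return cls(df, diploid_genome_size_bp)

    def fit(
        self,
        prior_weight: float = 1.0,
        p0: float = DEFAULT_P0,
        size_cutoff_bp: int = 0,
        usc_threshold_pct: float = 100.0,
    ) -> MSPResults:
        """Estimate the male-specific proportion at one parameter point."""
        prior = prior_from_weight(prior_weight, p0)
        cfg = EstimatorConfig(
            prior=prior,
            size_cutoff_bp=size_cutoff_bp,
            usc_threshold_pct=usc_threshold_pct,
        )
        raw = estimate_msp(self.scan, cfg)
        return msp_bounds(
            raw.msp_raw,
            self.diploid_genome_size_bp,
            n_contigs_used=raw.n_contigs_used,
            total_length_bp=raw.total_length_bp,
            prior=prior,
            config=cfg,
        )

    def sweep(
        self,
        cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
        prior_weights: Sequence[float] = DEFAULT_PRIOR_WEIGHTS,
        usc_threshold_pct: float = 100.0,
        p0: float = DEFAULT_P0,
    ) -> pd.DataFrame:
        """Estimate over the full cutoff x prior-weight grid."""
        return sweep(
            self.scan,
            cutoffs=cutoffs,
            prior_weights=prior_weights,
            usc_threshold_pct=usc_threshold_pct,
            p0=p0,
            diploid_genome_size_bp=self.diploid_genome_size_bp,
        )
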