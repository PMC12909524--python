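"""Per-marker genetic diversity statistics.

Implements the classical single-locus summaries used to characterise a SNP
marker panel: allele frequencies, gene diversity (expected heterozygosity),
Botstein's polymorphism information content (PIC), observed heterozygosity
and missing rate, plus a panel-level summary with an arithmetic Mean row.

For a biallelic locus with allele frequencies p and q = 1 - p:

    gene diversity  D   = 1 - p^2 - q^2 = 2pq
    PIC                 = D - 2 p^2 q^2
    MAF                 = min(p, q)

Frequencies are estimated from called genotypes only; each called diploid
contributes two allele observations. Gene diversity is reported without the
small-sample n/(n-1) correction by default (the convention of PowerMarker's
printed tables); the corrected variant is available via ``unbiased=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import UndefinedStatisticError
from .genotypes import GenotypeMatrix


@dataclass
class MarkerDiversity:
    """Diversity summary for one marker (one row of a panel table)."""

    marker_id: str
    maf: float
    gene_diversity: float
    heterozygosity: float
    pic: float
    missing_rate: float
    n_called: int


@dataclass
class PanelSummary:
    """Per-marker diversity rows plus their arithmetic means."""

    per_marker: list[MarkerDiversity]
    means: MarkerDiversity

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        """Table-shaped DataFrame; missing rate as a percentage.

        With ``rounded`` the fractions are printed half-up at 3 decimals and
        the missing-rate percentage at 2, as diversity tables are published;
        internal values stay full precision.
        """
        rows = self.per_marker + [self.means]
        df = pd.DataFrame(
            {
                "Marker": [r.marker_id for r in rows],
                "MAF": [r.maf for r in rows],
                "Gene diversity": [r.gene_diversity for r in rows],
                "Heterozygosity": [r.heterozygosity for r in rows],
                "PIC": [r.pic for r in rows],
                "Missing rate (%)": [100.0 * r.missing_rate for r in rows],
            }
        ).set_index("Marker")
        if rounded:
            for col in ("MAF", "Gene diversity", "Heterozygosity", "PIC"):
                df[col] = df[col].map(lambda v: round_half_up(v, 3))
            df["Missing rate (%)"] = df["Missing rate (%)"].map(
                lambda v: round_half_up(v, 2)
            )
        return df


def allele_frequencies(calls: pd.Series | list) -> pd.Series:
    """Allele frequencies of one genotype column, missing calls excluded.

    Returns a Series indexed by allele, sorted by descending frequency then
    allele name; sums to 1.
    """
    counts: dict[str, int] = {}
    n_called = 0
    for g in calls:
        if g is None or (isinstance(g, float) and np.isnan(g)):
            continue
        n_called += 1
        for a in g:
            counts[a] = counts.get(a, 0) + 1
    if n_called == 0:
        raise UndefinedStatisticError("no called genotypes in column")
    total = 2 * n_called
    freqs = pd.Series({a: c / total for a, c in counts.items()}, dtype=float)
    return freqs.sort_index().sort_values(ascending=False, kind="stable")


def minor_allele_frequency(freqs: pd.Series | np.ndarray | list) -> float:
    """Frequency of the rarest allele; 0.0 for a monomorphic locus."""
    arr = np.asarray(freqs, dtype=float)
    if arr.size == 1:
        return 0.0
    return float(arr.min())


def gene_diversity(freqs, unbiased: bool = False, n: int | None = None) -> float:
    """Expected heterozygosity 1 - sum(p_i^2).

    ``unbiased`` applies the n/(n-1) small-sample correction where n is the
    number of sampled alleles (2 x called individuals).
    """
    p = np.asarray(freqs, dtype=float)
    d = 1.0 - float(np.sum(p * p))
    if unbiased:
        if not n or n < 2:
            raise UndefinedStatisticError("unbiased gene diversity needs n >= 2 alleles")
        d *= n / (n - 1)
    return d


def pic(freqs) -> float:
    """Botstein's polymorphism information content.

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2; for a biallelic locus this
    reduces to 2pq - 2 p^2 q^2 and is bounded by 0.375.
    """
    p = np.asarray(freqs, dtype=float)
    sq = p * p
    cross = (float(np.sum(sq)) ** 2 - float(np.sum(sq * sq))) / 2.0
    return 1.0 - float(np.sum(sq)) - 2.0 * cross


def observed_heterozygosity(calls) -> float:
    """Fraction of called individuals that are heterozygous."""
    n_called = 0
    n_het = 0
    for g in calls:
        if g is None or (isinstance(g, float) and np.isnan(g)):
            continue
        n_called += 1
        if g[0] != g[1]:
            n_het += 1
    if n_called == 0:
        raise UndefinedStatisticError("no called genotypes in column")
    return n_het / n_called


def missing_rate(calls, n_total: int | None = None) -> float:
    """Fraction of missing calls out of ``n_total`` samples (default: column length)."""
    calls = list(calls)
    if n_total is None:
        n_total = len(calls)
    n_called = sum(
        1
        for g in calls
        if not (g is None or (isinstance(g, float) and np.isnan(g)))
    )
    if n_total == 0:
        raise UndefinedStatisticError("n_total is zero")
    if n_total < n_called:
        raise ValueError("n_total smaller than number of called genotypes")
    return (n_total - n_called) / n_total


def marker_diversity(
    marker_id: str, calls, n_total: int | None = None, unbiased: bool = False
) -> MarkerDiversity:
    """All per-marker statistics for one genotype column."""
    calls = list(calls)
    if n_total is None:
        n_total = len(calls)
    try:
        freqs = allele_frequencies(calls)
    except UndefinedStatisticError:
        return MarkerDiversity(marker_id, np.nan, np.nan, np.nan, np.nan, 1.0, 0)
    n_called = sum(
        1
        for g in calls
        if not (g is None or (isinstance(g, float) and np.isnan(g)))
    )
    return MarkerDiversity(
        marker_id=marker_id,
        maf=minor_allele_frequency(freqs),
        gene_diversity=gene_diversity(
            freqs, unbiased=unbiased, n=2 * n_called if unbiased else None
        ),
        heterozygosity=observed_heterozygosity(calls),
        pic=pic(freqs),
        missing_rate=missing_rate(calls, n_total),
        n_called=n_called,
    )


def summarize_markers(
    gm: GenotypeMatrix, n_total: int | None = None, unbiased: bool = False
) -> PanelSummary:
    """Per-marker diversity for a whole panel plus the arithmetic Mean row.

    Columns with zero called genotypes yield NaN statistics without aborting
    the panel; means are taken over the defined values.
    """
    rows = [
        marker_diversity(m, gm.column(m), n_total=n_total, unbiased=unbiased)
        for m in gm.markers
    ]
    means = MarkerDiversity(
        marker_id="Mean",
        maf=float(np.nanmean([r.maf for r in rows])),
        gene_diversity=float(np.nanmean([r.gene_diversity for r in rows])),
        heterozygosity=float(np.nanmean([r.heterozygosity for r in rows])),
        pic=float(np.nanmean([r.pic for r in rows])),
        missing_rate=float(np.mean([r.missing_rate for r in rows])),
        n_called=int(round(np.mean([r.n_called for r in rows]))),
    )
    return PanelSummary(per_marker=rows, means=means)
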