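"""Genotype matrix container.

The central in-memory object of the pipeline: accessions x markers, each cell
an unordered allele pair ("AA", "AG", ...) or missing. Backed by a pandas
DataFrame with accession ids as the index and marker ids as columns; cells are
canonicalised (alphabetically sorted) two-letter strings or None.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import MISSING_TOKEN, normalize_genotype
from .errors import UndefinedStatisticError, UnsupportedMarkerError


class GenotypeMatrix:
    """Accessions x markers matrix of unordered biallelic genotype calls.

    Parameters
    ----------
    data
        DataFrame (accessions as index, markers as columns) whose cells are
        two-letter genotype strings in any allele order, or missing
        (None/NaN/"NA").
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise ValueError("duplicate accession ids")
        if data.columns.has_duplicates:
            raise ValueError("duplicate marker ids")
        df = data.copy()
        for col in df.columns:
            df[col] = [normalize_genotype(v) for v in df[col]]
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        self.df = df

    # -- construction ------------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.fillna(MISSING_TOKEN).to_csv(path)

    # -- basic views -------------------------------------------------------

    @property
    def accessions(self) -> list[str]:
        return list(self.df.index)

    @property
    def markers(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def column(self, marker: str) -> pd.Series:
        return self.df[marker]

    def subset_markers(self, markers: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.df[list(markers)])

    def alleles(self, marker: str) -> list[str]:
        """Sorted distinct alleles observed at a marker (missing excluded)."""
        seen: set[str] = set()
        for g in self.df[marker]:
            if g is not None:
                seen.update(g)
        return sorted(seen)

    # -- numeric codings ---------------------------------------------------

    def minor_allele(self, marker: str) -> str:
        """Least frequent allele at a biallelic marker (tie -> alphabetical)."""
        counts: dict[str, int] = {}
        for g in self.df[marker]:
            if g is not None:
                for a in g:
                    counts[a] = counts.get(a, 0) + 1
        if not counts:
            raise UndefinedStatisticError(f"no called genotypes at {marker}")
        if len(counts) > 2:
            raise UnsupportedMarkerError(f"{marker} has >2 alleles: {sorted(counts)}")
        return min(counts, key=lambda a: (counts[a], a))

    def dosage(self, counted: dict[str, str] | None = None) -> np.ndarray:
        """Accessions x markers array of counted-allele dosages (0/1/2, NaN missing).

        By default the counted allele at each marker is its minor allele.
        """
        n, m = self.df.shape
        out = np.full((n, m), np.nan)
        for j, marker in enumerate(self.df.columns):
            allele = (counted or {}).get(marker) or self.minor_allele(marker)
            col = self.df[marker]
            for i, g in enumerate(col):
                if g is not None:
                    out[i, j] = g.count(allele)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.df.shape
        return f"GenotypeMatrix({n} accessions x {m} markers)"


def genotype_from_dosage(d: int, ref: str, alt: str) -> str:
    """Map an alt-allele count to a sorted genotype string."""
    if d == 0:
        return ref + ref
    if d == 1:
        return "".join(sorted(ref + alt))
    if d == 2:
        return alt + alt
    raise ValueError(f"dosage must be 0, 1 or 2, got {d}")


def column_alleles(calls: Iterable[str | None]) -> list[str]:
    """Sorted distinct alleles in a single genotype column."""
    seen: set[str] = set()
    for g in calls:
        if g is not None:
            seen.update(g)
    return sorted(seen)
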