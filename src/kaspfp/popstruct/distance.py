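"""Pairwise genetic distances between accessions.

The default distance is the allele-sharing p-distance: one minus the
proportion of shared alleles over loci where both accessions are called. At
a biallelic locus the shared-allele count between two unordered pairs equals
``2 - |dosage_i - dosage_j|`` (0, 1 or 2), so identical genotypes share 2,
opposite homozygotes share 0, and a homozygote/heterozygote pair shares 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..errors import UndefinedStatisticError
from ..genotypes import GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric accession distance matrix with per-pair locus counts."""

    labels: list[str]
    d: np.ndarray
    n_loci_compared: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")

    @property
    def n(self) -> int:
        return len(self.labels)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if np.isnan(self.d[i, j]):
                    out.append((self.labels[i], self.labels[j]))
        return out

    def mean_offdiag(self) -> float:
        iu = np.triu_indices(self.n, k=1)
        return float(np.nanmean(self.d[iu]))


def allele_sharing_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing p-distance over pairwise-complete loci.

    d(i, j) = 1 - (shared alleles) / (2 * loci compared). Pairs with no
    mutually called locus get NaN and are reported by ``undefined_pairs``.
    Accessions with zero called loci are excluded with a warning.
    """
    dos = gm.dosage()
    labels = gm.accessions
    called = ~np.isnan(dos)
    keep = called.sum(axis=1) > 0
    if not np.all(keep):
        dropped = [l for l, k in zip(labels, keep) if not k]
        warnings.warn(f"excluding accessions with zero called loci: {dropped}")
        dos = dos[keep]
        called = called[keep]
        labels = [l for l, k in zip(labels, keep) if k]
    n = len(labels)
    if n < 2:
        raise UndefinedStatisticError("need at least two accessions with calls")
    d = np.zeros((n, n))
    n_loci = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            m = int(both.sum())
            n_loci[i, j] = n_loci[j, i] = m
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                continue
            shared = np.sum(2.0 - np.abs(dos[i, both] - dos[j, both]))
            dij = 1.0 - shared / (2.0 * m)
            d[i, j] = d[j, i] = dij
    np.fill_diagonal(n_loci, called.sum(axis=1))
    return DistanceMatrix(labels=labels, d=d, n_loci_compared=n_loci)


def nei_standard_distance(freqs_a: np.ndarray, freqs_b: np.ndarray) -> float:
    """Nei's (1972) standard distance between two groups' allele frequencies.

    ``freqs_a``/``freqs_b`` are per-locus frequencies of the same counted
    allele in the two groups; the complementary allele is implied. Provided
    as an option for between-group comparisons; the per-accession default is
    the allele-sharing distance.
    """
    pa = np.asarray(freqs_a, dtype=float)
    pb = np.asarray(freqs_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("frequency vectors must align on loci")
    jxy = np.sum(pa * pb + (1 - pa) * (1 - pb))
    jx = np.sum(pa**2 + (1 - pa) ** 2)
    jy = np.sum(pb**2 + (1 - pb) ** 2)
    return float(-np.log(jxy / np.sqrt(jx * jy)))
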