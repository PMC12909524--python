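"""Variant records shared between the simulator and the screening stage."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class VariantRecord:
    """One biallelic SNP with per-accession genotype calls.

    ``sample_genotypes`` maps accession id to a sorted two-letter genotype
    string built from ``ref``/``alt``, or None for a missing call. Coordinates
    are 1-based, VCF style.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_genotypes: dict[str, str | None] = field(default_factory=dict)
    id: str | None = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.chrom}:{self.pos}: only single-base SNPs supported")
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def called(self) -> list[str]:
        return [g for g in self.sample_genotypes.values() if g is not None]
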