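"""SNP screening and KASP assay assembly.

Candidate loci for KASP conversion pass a four-round specificity cascade,
applied in this order:

1. minor allele frequency strictly greater than ``maf_min`` (default 0.05);
2. missing rate at most ``missing_max`` (default 0.2; loci with a greater
   rate are removed);
3. polymorphism information content strictly greater than ``pic_min``
   (default 0.3);
4. no other input variant within ``flank_bp`` (default 100) on either side
   on the same chromosome — measured against the *full* input list, since a
   neighbouring variant disturbs allele-specific priming whether or not it
   passed the statistical rounds itself.

Survivors are thinned to an even chromosomal spread, their flanking sequence
is pulled from a reference FASTA, and a tailed-primer assay record is
assembled: two allele-specific forward primers carrying the universal FAM
and HEX tail sequences, plus a fixed-placement common reverse primer. Primer
thermodynamics are deliberately out of scope; the assay record captures the
sequence logic of the chemistry, not an optimised design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .diversity import allele_frequencies, minor_allele_frequency, missing_rate, pic
from .errors import (
    InsufficientContextError,
    ReferenceLookupError,
    ReferenceMismatchError,
    VcfFormatError,
    VcfParseError,
)
from .genotypes import GenotypeMatrix
from .variants import VariantRecord

logger = logging.getLogger(__name__)

FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
HEX_TAIL = "GAAGGTCGGAGTCAACGGATT"
ARM_LENGTH = 20
REVERSE_OFFSET = 30  # bases downstream of the SNP where the reverse window starts
REVERSE_LENGTH = 20

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class FilterThresholds:
    """Thresholds of the four screening rounds."""

    maf_min: float = 0.05  # exclusive
    missing_max: float = 0.2  # inclusive
    pic_min: float = 0.3  # exclusive
    flank_bp: int = 100

    def validate(self) -> None:
        for name in ("maf_min", "missing_max", "pic_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


@dataclass
class StageCounts:
    """Survivor counts after each screening round."""

    input: int = 0
    after_maf: int = 0
    after_missing: int = 0
    after_pic: int = 0
    after_flank: int = 0


@dataclass
class FlankContext:
    """Reference sequence window centred on a SNP."""

    chrom: str
    pos: int
    seq: str
    center_index: int  # 0-based index of the SNP base within seq
    truncated: bool


@dataclass
class KaspAssay:
    """Minimal tailed-primer record for one SNP assay."""

    marker_id: str
    fam_primer: str  # FAM tail + allele-specific arm ending in ref
    hex_primer: str  # HEX tail + arm ending in alt
    common_reverse: str
    context: str
    ref: str = ""
    alt: str = ""


def parse_vcf(path: str | Path) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read biallelic SNP records and their genotype matrix from a VCF.

    Multi-allelic and non-SNP records are skipped with a logged count.
    Missing genotypes (./.) become missing calls.
    """
    try:
        from cyvcf2 import VCF

        vcf = VCF(str(path))
    except Exception as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if samples and "GT" not in (v.FORMAT or []):
            raise VcfFormatError(f"record {v.CHROM}:{v.POS} has no GT field")
        geno: dict[str, str | None] = {}
        for s, g in zip(samples, v.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                geno[s] = None
            else:
                alleles = sorted(v.REF if idx == 0 else v.ALT[0] for idx in (a, b))
                geno[s] = "".join(alleles)
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                id=None if v.ID in (None, ".") else v.ID,
                sample_genotypes=geno,
            )
        )
    if n_skipped:
        logger.info("skipped %d multi-allelic or non-SNP records", n_skipped)
    cells = {}
    for i, r in enumerate(records):
        mid = r.id or f"{r.chrom}:{r.pos}"
        cells[mid] = [r.sample_genotypes.get(s) for s in samples]
    gm = GenotypeMatrix(pd.DataFrame(cells, index=samples, dtype=object))
    return records, gm


def _variant_stats(r: VariantRecord) -> tuple[float, float, float]:
    """(maf, missing_rate, pic) of one record over its samples."""
    calls = list(r.sample_genotypes.values())
    miss = missing_rate(calls)
    called = [g for g in calls if g is not None]
    if not called:
        return 0.0, miss, 0.0
    freqs = allele_frequencies(called)
    return minor_allele_frequency(freqs), miss, pic(freqs)


def filter_cascade(
    variants: list[VariantRecord],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantRecord], StageCounts]:
    """Apply the four screening rounds in order; report per-stage survivors.

    The flanking round (4) tests each survivor of rounds 1–3 against every
    *input* variant on the same chromosome within ``flank_bp`` of it
    (absolute position difference, both sides, inclusive).
    """
    t = thresholds or FilterThresholds()
    t.validate()
    counts = StageCounts(input=len(variants))

    stage1 = [r for r in variants if _variant_stats(r)[0] > t.maf_min]
    counts.after_maf = len(stage1)
    stage2 = [r for r in stage1 if _variant_stats(r)[1] <= t.missing_max]
    counts.after_missing = len(stage2)
    stage3 = [r for r in stage2 if _variant_stats(r)[2] > t.pic_min]
    counts.after_pic = len(stage3)

    by_chrom: dict[str, list[int]] = {}
    for r in variants:
        by_chrom.setdefault(r.chrom, []).append(r.pos)
    for c in by_chrom:
        by_chrom[c].sort()
    stage4 = [r for r in stage3 if _isolated(r, by_chrom, t.flank_bp)]
    counts.after_flank = len(stage4)
    return stage4, counts


def _isolated(r: VariantRecord, by_chrom: dict[str, list[int]], flank_bp: int) -> bool:
    import bisect

    positions = by_chrom.get(r.chrom, [])
    lo = bisect.bisect_left(positions, r.pos - flank_bp)
    hi = bisect.bisect_right(positions, r.pos + flank_bp)
    # the window contains r itself exactly once; any other hit is a neighbour
    return (hi - lo) <= 1


def select_spaced_markers(
    retained: list[VariantRecord],
    per_chrom_quota: int,
    min_gap_bp: int,
) -> list[VariantRecord]:
    """Greedy per-chromosome selection of spaced, high-PIC loci.

    On each chromosome, loci are taken in decreasing PIC (ties broken by
    (chrom, pos)); a locus is accepted only if it lies at least ``min_gap_bp``
    from every locus already selected on that chromosome, until the quota is
    filled or candidates are exhausted. Input order does not matter.
    """
    if per_chrom_quota <= 0:
        return []
    chosen: list[VariantRecord] = []
    by_chrom: dict[str, list[VariantRecord]] = {}
    for r in sorted(retained, key=lambda r: (r.chrom, r.pos)):
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        ranked = sorted(
            by_chrom[chrom],
            key=lambda r: (-_variant_stats(r)[2], r.chrom, r.pos),
        )
        picked: list[VariantRecord] = []
        for r in ranked:
            if len(picked) >= per_chrom_quota:
                break
            if all(abs(r.pos - p.pos) >= min_gap_bp for p in picked):
                picked.append(r)
        chosen.extend(sorted(picked, key=lambda r: r.pos))
    return chosen


def extract_flanks(
    reference,
    chrom: str,
    pos: int,
    flank_bp: int = 100,
    expect_base: str | None = None,
) -> FlankContext:
    """Reference window [pos - flank_bp, pos + flank_bp] (1-based inclusive).

    ``reference`` is a FASTA path or a pyfaidx.Fasta. The window is truncated
    (and flagged) at contig ends. With ``expect_base`` the centre base must
    equal it, else a reference-mismatch error: the assay is designed against
    the variant's REF allele.
    """
    import pyfaidx

    fa = reference if isinstance(reference, pyfaidx.Fasta) else pyfaidx.Fasta(str(reference))
    if chrom not in fa:
        raise ReferenceLookupError(f"chromosome {chrom!r} not in reference")
    contig = fa[chrom]
    if not (1 <= pos <= len(contig)):
        raise ReferenceLookupError(f"position {pos} outside {chrom} (length {len(contig)})")
    start = max(1, pos - flank_bp)
    end = min(len(contig), pos + flank_bp)
    seq = str(contig[start - 1 : end]).upper()
    ctx = FlankContext(
        chrom=chrom,
        pos=pos,
        seq=seq,
        center_index=pos - start,
        truncated=(start > pos - flank_bp) or (end < pos + flank_bp),
    )
    if expect_base is not None and seq[ctx.center_index] != expect_base.upper():
        raise ReferenceMismatchError(
            f"{chrom}:{pos}: reference base {seq[ctx.center_index]} != expected {expect_base}"
        )
    return ctx


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def build_kasp_assay(variant: VariantRecord, context: FlankContext) -> KaspAssay:
    """Assemble a tailed two-forward/one-reverse assay record.

    The allele-specific arm is the ARM_LENGTH reference bases ending at the
    SNP, with the 3' terminal base set to the targeted allele; the FAM primer
    targets REF and the HEX primer targets ALT. The common reverse primer is
    the reverse complement of a fixed window starting REVERSE_OFFSET bases
    downstream — a placeholder for thermodynamic design, which is out of
    scope here.
    """
    c = context.center_index
    if c < ARM_LENGTH - 1:
        raise InsufficientContextError(
            f"need {ARM_LENGTH - 1} bases upstream of the SNP, have {c}"
        )
    if len(context.seq) < c + 1 + REVERSE_OFFSET + REVERSE_LENGTH:
        raise InsufficientContextError(
            "context too short for the reverse-primer window"
        )
    arm_stub = context.seq[c - ARM_LENGTH + 1 : c]
    fwd_window = context.seq[c + 1 + REVERSE_OFFSET : c + 1 + REVERSE_OFFSET + REVERSE_LENGTH]
    return KaspAssay(
        marker_id=variant.id or f"{variant.chrom}:{variant.pos}",
        fam_primer=FAM_TAIL + arm_stub + variant.ref,
        hex_primer=HEX_TAIL + arm_stub + variant.alt,
        common_reverse=reverse_complement(fwd_window),
        context=context.seq,
        ref=variant.ref,
        alt=variant.alt,
    )
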