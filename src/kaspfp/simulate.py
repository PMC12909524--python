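"""Synthetic populations, fluorescence plates and toy VCFs with known truth.

The generator emulates the data a KASP fingerprinting study works from:

* an admixed population of diploid accessions genotyped at biallelic SNPs —
  subpopulation allele frequencies follow the Balding–Nichols model around a
  shared ancestral frequency with differentiation F (an FST analogue),
  individual ancestry proportions are Dirichlet, genotypes are binomial in
  the individual-specific allele frequency, and missingness is applied
  completely at random;
* endpoint-fluorescence plates — each genotype class sits on a canonical
  angle in the FAM/HEX plane (FAM-homozygote 0°, heterozygote 45°,
  HEX-homozygote 90°) at a common amplitude, with isotropic Gaussian noise;
  no-template controls and amplification dropouts sit near the origin.

Every operation takes an explicit seed and is bit-for-bit reproducible, and
returns the underlying truth so downstream callers can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import normalize_genotype, spawn_rng
from .errors import ConfigurationError, UnsupportedMarkerError
from .genotypes import GenotypeMatrix, genotype_from_dosage
from .variants import VariantRecord

_BASES = "ACGT"


@dataclass
class PopulationSimConfig:
    """Parameters of the admixed-population generator.

    Defaults mirror the study design this package targets: 105 accessions,
    31 markers, three subpopulations, and a low per-cell missing rate
    (observed per-marker missing rates in such panels run 0–5%).
    """

    n_accessions: int = 105
    n_markers: int = 31
    n_subpops: int = 3
    fst: float = 0.15
    dirichlet_alpha: float = 0.2
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_accessions < 1:
            raise ConfigurationError("n_accessions must be >= 1")
        if self.n_markers < 1:
            raise ConfigurationError("n_markers must be >= 1")
        if self.n_subpops < 1:
            raise ConfigurationError("n_subpops must be >= 1")
        if not (0.0 <= self.fst < 1.0):
            raise ConfigurationError("fst must lie in [0, 1)")
        if self.dirichlet_alpha <= 0:
            raise ConfigurationError("dirichlet_alpha must be positive")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("ancestral_maf_range must sit within (0, 0.5]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated genotype matrix."""

    ancestral_freqs: np.ndarray  # (L,) frequency of the alt allele
    subpop_freqs: np.ndarray  # (K, L)
    admixture_Q: np.ndarray  # (n, K), rows sum to 1
    true_genotypes: GenotypeMatrix  # before missingness
    marker_alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def dominant_ancestry(self) -> np.ndarray:
        """Per-accession index of the largest ancestry component."""
        return np.argmax(self.admixture_Q, axis=1)


def simulate_population(
    config: PopulationSimConfig | None = None, **overrides
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw an admixed diploid population with known truth.

    Ancestral alt-allele frequency p_l ~ Uniform(ancestral_maf_range). With
    differentiation F > 0, subpopulation frequencies follow Balding–Nichols,
    Beta(p(1-F)/F, (1-p)(1-F)/F); with F = 0 they equal p exactly. Ancestry
    rows Q_i ~ Dirichlet(alpha * 1_K); the individual allele frequency is
    q_il = sum_k Q_ik P_kl and the genotype is Binomial(2, q_il) mapped to an
    allele pair. Missingness is applied MCAR per cell after genotypes are
    drawn; the returned truth holds the pre-missingness matrix.
    """
    if config is None:
        config = PopulationSimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    config.validate()
    rng = spawn_rng(config.seed)
    n, L, K = config.n_accessions, config.n_markers, config.n_subpops

    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=L)
    if config.fst > 0:
        F = config.fst
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        subpop = rng.beta(a, b, size=(K, L))
    else:
        subpop = np.tile(p_anc, (K, 1))
    Q = rng.dirichlet(np.full(K, config.dirichlet_alpha), size=n)
    q_il = Q @ subpop  # (n, L) individual alt-allele frequencies
    dosages = rng.binomial(2, q_il)

    markers = [f"M{j + 1:03d}" for j in range(L)]
    accessions = [f"acc{i + 1:03d}" for i in range(n)]
    alleles: dict[str, tuple[str, str]] = {}
    cells = {}
    for j, m in enumerate(markers):
        ref, alt = rng.choice(list(_BASES), size=2, replace=False)
        alleles[m] = (str(ref), str(alt))
        cells[m] = [
            genotype_from_dosage(int(d), str(ref), str(alt)) for d in dosages[:, j]
        ]
    full = pd.DataFrame(cells, index=accessions)
    truth = SimulationTruth(
        ancestral_freqs=p_anc,
        subpop_freqs=subpop,
        admixture_Q=Q,
        true_genotypes=GenotypeMatrix(full),
        marker_alleles=alleles,
    )

    observed = full.copy()
    if config.missing_rate > 0:
        mask = rng.random(size=(n, L)) < config.missing_rate
        observed = observed.mask(pd.DataFrame(mask, index=full.index, columns=full.columns))
    return GenotypeMatrix(observed), truth


@dataclass
class PlateSimConfig:
    """Geometry of a simulated endpoint-fluorescence plate.

    Centroid angles are in degrees for the FAM-homozygote, heterozygote and
    HEX-homozygote clusters; wells are placed at
    ``signal_amplitude * (cos a, sin a)`` plus isotropic Gaussian noise.
    """

    centroid_angles: tuple[float, float, float] = (0.0, 45.0, 90.0)
    signal_amplitude: float = 1.0
    noise_sd: float = 0.05
    n_ntc: int = 2
    dropout_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        a, b, c = self.centroid_angles
        if not (0.0 <= a < b < c <= 90.0):
            raise ConfigurationError(
                "centroid_angles must be strictly increasing within [0, 90]"
            )
        if self.signal_amplitude <= 0:
            raise ConfigurationError("signal_amplitude must be positive")
        if self.noise_sd < 0 or self.noise_sd >= self.signal_amplitude:
            raise ConfigurationError("noise_sd must satisfy 0 <= noise_sd < amplitude")
        if self.n_ntc < 0:
            raise ConfigurationError("n_ntc must be >= 0")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ConfigurationError("dropout_rate must lie in [0, 1]")


def simulate_plate(
    calls: pd.Series,
    config: PlateSimConfig | None = None,
    marker_id: str = "marker",
    **overrides,
):
    """Simulate a FAM/HEX endpoint plate for one biallelic marker.

    ``calls`` maps sample id to genotype string (or None). Samples with a
    genotype land on their class centroid; missing calls and randomly chosen
    dropout wells behave as no-amplification points near the origin, as do
    the appended no-template controls. Negative fluorescence after noise is
    clipped at zero (detectors do not report negative intensity).

    Returns ``(FluorescencePlate, truth)`` where truth maps well id to the
    generating label: a genotype string, "dropout" or "ntc".
    """
    from .calling import FluorescencePlate  # local import to avoid a cycle

    if config is None:
        config = PlateSimConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    config.validate()
    rng = spawn_rng(config.seed)

    calls = pd.Series(calls).map(normalize_genotype)
    alleles = sorted({a for g in calls if g is not None for a in g})
    if len(alleles) > 2:
        raise UnsupportedMarkerError(f"more than two alleles in calls: {alleles}")
    while len(alleles) < 2:  # monomorphic or empty column still defines an assay
        alleles.append(next(b for b in _BASES if b not in alleles))
    allele_x, allele_y = alleles
    angle_of = {
        allele_x + allele_x: config.centroid_angles[0],
        "".join(sorted(allele_x + allele_y)): config.centroid_angles[1],
        allele_y + allele_y: config.centroid_angles[2],
    }

    rows = []
    truth: dict[str, str] = {}
    for i, (sample, g) in enumerate(calls.items()):
        well = f"W{i + 1:03d}"
        dropped = g is None or rng.random() < config.dropout_rate
        if dropped:
            x, y = 0.0, 0.0
            truth[well] = "dropout"
        else:
            theta = np.deg2rad(angle_of[g])
            x = config.signal_amplitude * np.cos(theta)
            y = config.signal_amplitude * np.sin(theta)
            truth[well] = g
        noise = rng.normal(0.0, config.noise_sd, size=2) if config.noise_sd else (0.0, 0.0)
        rows.append(
            {
                "well": well,
                "sample": str(sample),
                "fam": max(0.0, x + noise[0]),
                "hex": max(0.0, y + noise[1]),
                "is_ntc": False,
            }
        )
    for k in range(config.n_ntc):
        well = f"NTC{k + 1}"
        noise = rng.normal(0.0, config.noise_sd, size=2) if config.noise_sd else (0.0, 0.0)
        rows.append(
            {
                "well": well,
                "sample": "NTC",
                "fam": max(0.0, noise[0]),
                "hex": max(0.0, noise[1]),
                "is_ntc": True,
            }
        )
        truth[well] = "ntc"
    plate = FluorescencePlate(
        wells=pd.DataFrame(rows),
        marker_id=marker_id,
        allele_x=allele_x,
        allele_y=allele_y,
    )
    return plate, truth


def write_toy_vcf(records: list[VariantRecord], path) -> None:
    """Write variant records as a minimal VCF v4.2 text file.

    Records must be sorted by (chrom, pos); all records must carry the same
    sample ids. Supports fixtures with neighbouring variants at chosen
    offsets to exercise flanking-distance filters.
    """
    keys = [r.key for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chrom, pos)")
    samples: list[str] = list(records[0].sample_genotypes) if records else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dict.fromkeys(r.chrom for r in records)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if samples:
            header += ["FORMAT"] + samples
        fh.write("\t".join(header) + "\n")
        for r in records:
            fields = [
                r.chrom,
                str(r.pos),
                r.id or ".",
                r.ref,
                r.alt,
                ".",
                "PASS",
                ".",
            ]
            if samples:
                fields.append("GT")
                for s in samples:
                    g = r.sample_genotypes.get(s)
                    if g is None:
                        fields.append("./.")
                    else:
                        fields.append(f"{_gt_code(g[0], r)}/{_gt_code(g[1], r)}")
            fh.write("\t".join(fields) + "\n")


def _gt_code(allele: str, r: VariantRecord) -> str:
    if allele == r.ref:
        return "0"
    if allele == r.alt:
        return "1"
    raise ValueError(f"allele {allele} matches neither ref nor alt at {r.chrom}:{r.pos}")


def simulate_variant_panel(
    n_loci: int,
    n_accessions: int = 50,
    n_chroms: int = 5,
    chrom_length: int = 1_000_000,
    seed: int = 0,
    **pop_kwargs,
) -> list[VariantRecord]:
    """Simulated sorted variant records with genomic positions.

    A convenience wrapper for exercising the screening cascade: genotypes come
    from :func:`simulate_population` and each marker is assigned a distinct
    (chrom, pos). Positions are uniform per chromosome, so some loci fall
    within flanking distance of a neighbour by chance.
    """
    rng = spawn_rng(seed)
    pop_kwargs.setdefault("missing_rate", 0.05)
    pop_kwargs.setdefault("ancestral_maf_range", (0.01, 0.5))
    gm, truth = simulate_population(
        PopulationSimConfig(
            n_accessions=n_accessions,
            n_markers=n_loci,
            seed=int(rng.integers(2**31)),
            **pop_kwargs,
        )
    )
    chroms = rng.integers(n_chroms, size=n_loci)
    positions = rng.integers(1, chrom_length + 1, size=n_loci)
    order = np.lexsort((positions, chroms))
    records = []
    used: set[tuple[str, int]] = set()
    for j in order:
        marker = gm.markers[j]
        ref, alt = truth.marker_alleles[marker]
        key = (f"chr{chroms[j] + 1}", int(positions[j]))
        if key in used:  # collisions are astronomically rare; just skip
            continue
        used.add(key)
        records.append(
            VariantRecord(
                chrom=key[0],
                pos=key[1],
                ref=ref,
                alt=alt,
                id=marker,
                sample_genotypes=dict(gm.column(marker)),
            )
        )
    return records
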