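"""Endpoint-fluorescence genotype calling for KASP assays.

A finished KASP plate yields one (FAM, HEX) intensity pair per well. Wells
carrying an amplified template separate into up to three clusters along the
angle theta = atan2(hex, fam): FAM-homozygotes near 0, heterozygotes near
45 degrees, HEX-homozygotes near 90 degrees. No-template controls (NTCs) and
failed amplifications stay near the origin.

The caller here mirrors that geometry:

1. subtract the mean NTC intensity per channel (baseline normalisation);
2. gate on signal magnitude — wells within ``min_magnitude_sds`` NTC standard
   deviations of the NTC magnitude are no-calls;
3. cluster the remaining wells on angle with deterministic 1-D k-means
   initialised at the canonical cluster angles, choosing k in {1, 2, 3} by a
   silhouette criterion;
4. map clusters to genotypes by angle via an optimal assignment to the
   canonical angles (lowest -> FAM-homozygote, highest -> HEX-homozygote,
   middle -> heterozygote).

Angle-space clustering is robust to well-to-well amplitude variation, which
dominates plate noise in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ArityError, GatingError
from .genotypes import genotype_from_dosage

CANONICAL_ANGLES_DEG = (0.0, 45.0, 90.0)
# silhouette floor under which a multi-cluster split is rejected in favour of
# a single cluster; tight single clusters split by k-means score well below
# this, clean genotype clusters well above
_SILHOUETTE_FLOOR = 0.6


@dataclass
class FluorescencePlate:
    """One marker's endpoint plate: per-well FAM/HEX intensities.

    ``wells`` columns: well, sample, fam, hex, is_ntc. ``allele_x`` is the
    FAM-linked allele, ``allele_y`` the HEX-linked allele.
    """

    wells: pd.DataFrame
    marker_id: str = "marker"
    allele_x: str = "A"
    allele_y: str = "B"
    ntc_stats: dict | None = None  # set by normalize_plate

    def __post_init__(self) -> None:
        required = {"well", "sample", "fam", "hex", "is_ntc"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate is missing columns: {sorted(missing)}")
        vals = self.wells[["fam", "hex"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("intensities must be finite and non-negative")

    @classmethod
    def from_csv(
        cls, path: str | Path, marker_id: str = "marker", allele_x: str = "A", allele_y: str = "B"
    ) -> "FluorescencePlate":
        df = pd.read_csv(path)
        df["is_ntc"] = df["is_ntc"].astype(bool)
        return cls(wells=df, marker_id=marker_id, allele_x=allele_x, allele_y=allele_y)

    def to_csv(self, path: str | Path) -> None:
        self.wells.to_csv(path, index=False)

    @property
    def ntc(self) -> pd.DataFrame:
        return self.wells[self.wells["is_ntc"]]

    @property
    def samples(self) -> pd.DataFrame:
        return self.wells[~self.wells["is_ntc"]]


@dataclass
class GenotypeCallSet:
    """Calls for one plate: per-sample genotype (or None) and diagnostics."""

    marker_id: str
    calls: dict[str, str | None]
    cluster_assignments: dict[str, int | None]
    cluster_angles_deg: list[float]
    quality: dict = field(default_factory=dict)

    @property
    def n_called(self) -> int:
        return sum(1 for g in self.calls.values() if g is not None)

    @property
    def nocall_fraction(self) -> float:
        if not self.calls:
            return 1.0
        return 1.0 - self.n_called / len(self.calls)

    def genotype_classes(self) -> set[str]:
        return {g for g in self.calls.values() if g is not None}


@dataclass
class AssayTriage:
    """Keep/drop decision for one assay."""

    status: str  # "core" | "indistinct_or_failed" | "monomorphic"
    reasons: list[str]


def normalize_plate(plate: FluorescencePlate) -> FluorescencePlate:
    """Subtract the per-channel mean NTC intensity; clip negatives to zero.

    Idempotent when the NTC mean is already zero. Records the NTC spread
    (per-channel sd and magnitude statistics) on the returned plate for the
    no-call gate.
    """
    ntc = plate.ntc
    if len(ntc) == 0:
        raise GatingError("cannot normalize a plate with no NTC wells")
    baseline = ntc[["fam", "hex"]].mean()
    wells = plate.wells.copy()
    wells["fam"] = (wells["fam"] - baseline["fam"]).clip(lower=0.0)
    wells["hex"] = (wells["hex"] - baseline["hex"]).clip(lower=0.0)
    ntc_after = wells[wells["is_ntc"]]
    mags = np.hypot(ntc_after["fam"], ntc_after["hex"])
    stats = {
        "fam_sd": float(ntc["fam"].std(ddof=0)),
        "hex_sd": float(ntc["hex"].std(ddof=0)),
        "mag_mean": float(mags.mean()),
        "mag_sd": float(mags.std(ddof=0)),
        "n_ntc": int(len(ntc)),
    }
    return FluorescencePlate(
        wells=wells,
        marker_id=plate.marker_id,
        allele_x=plate.allele_x,
        allele_y=plate.allele_y,
        ntc_stats=stats,
    )


def _kmeans_1d(x: np.ndarray, centers: np.ndarray, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic Lloyd iterations in one dimension; empty clusters dropped."""
    centers = np.asarray(centers, dtype=float).copy()
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        labels = np.argmin(d, axis=1)
        new = centers.copy()
        for k in range(len(centers)):
            pts = x[labels == k]
            if len(pts):
                new[k] = pts.mean()
        if np.allclose(new, centers):
            break
        centers = new
    keep = np.array([np.any(labels == k) for k in range(len(centers))])
    centers = centers[keep]
    remap = {old: new for new, old in enumerate(np.flatnonzero(keep))}
    labels = np.array([remap[l] for l in labels])
    return labels, centers


def _silhouette(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette for 1-D data.

    Matches the classical definition except that a point alone in its
    cluster scores 1 (perfectly separated) rather than being refused:
    plates with few wells legitimately produce singleton genotype clusters.
    """
    ks = sorted(set(labels))
    if len(ks) < 2:
        return -1.0
    d = np.abs(x[:, None] - x[None, :])
    scores = np.empty(len(x))
    for i in range(len(x)):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            scores[i] = 1.0
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, labels == k].mean() for k in ks if k != labels[i])
        scores[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(scores.mean())


def call_genotypes(
    plate: FluorescencePlate,
    min_magnitude_sds: float = 6.0,
    k_max: int = 3,
) -> GenotypeCallSet:
    """Call genotypes from a normalized plate.

    Wells whose signal magnitude does not exceed
    ``NTC magnitude mean + min_magnitude_sds * NTC magnitude sd`` are
    no-calls. The rest are clustered on angle; the cluster count k <= 3 is
    chosen by silhouette (k = 1 when every multi-way split scores below the
    acceptance floor). Clusters are mapped to genotypes through a
    minimum-cost assignment of cluster mean angles to the canonical angles.
    """
    if plate.ntc_stats is None:
        plate = normalize_plate(plate)
    stats = plate.ntc_stats
    samples = plate.samples
    fam = samples["fam"].to_numpy(dtype=float)
    hx = samples["hex"].to_numpy(dtype=float)
    ids = samples["sample"].astype(str).tolist()
    mag = np.hypot(fam, hx)
    gate = stats["mag_mean"] + min_magnitude_sds * stats["mag_sd"]
    callable_mask = mag > gate

    calls: dict[str, str | None] = {s: None for s in ids}
    clusters: dict[str, int | None] = {s: None for s in ids}
    angles = np.degrees(np.arctan2(hx[callable_mask], fam[callable_mask]))
    quality = {
        "n_wells": len(ids),
        "nocall_fraction": 1.0 - (callable_mask.sum() / len(ids) if len(ids) else 0.0),
        "cluster_count": 0,
        "min_gap_deg": np.nan,
        "gate_magnitude": gate,
    }
    if callable_mask.sum() == 0:
        return GenotypeCallSet(plate.marker_id, calls, clusters, [], quality)

    canon = np.array(CANONICAL_ANGLES_DEG)
    candidates: list[tuple[float, int, np.ndarray, np.ndarray]] = []
    # k = 1 is the fallback with a fixed pseudo-score at the acceptance floor
    labels1 = np.zeros(len(angles), dtype=int)
    candidates.append((_SILHOUETTE_FLOOR, 1, labels1, np.array([angles.mean()])))
    ks = [k for k in (2, 3) if k <= k_max and k <= len(angles)]
    for k in ks:
        best = None
        inits = [canon] if k == 3 else [canon[[0, 1]], canon[[0, 2]], canon[[1, 2]]]
        for init in inits:
            labels, centers = _kmeans_1d(angles, init)
            inertia = float(np.sum((angles - centers[labels]) ** 2))
            if best is None or inertia < best[0] - 1e-12:
                best = (inertia, labels, centers)
        _, labels, centers = best
        if len(centers) < 2:
            continue
        candidates.append((_silhouette(angles, labels), len(centers), labels, centers))
    # highest silhouette wins; ties go to the smaller k
    score, k, labels, centers = max(candidates, key=lambda c: (c[0], -c[1]))

    order = np.argsort(centers)
    centers_sorted = centers[order]
    rank_of = {int(old): i for i, old in enumerate(order)}
    # optimal injective assignment of cluster angles to canonical genotype angles
    cost = np.abs(centers_sorted[:, None] - canon[None, :])
    rows, cols = linear_sum_assignment(cost)
    dosage_of_rank = {int(r): int(cols[i]) for i, r in enumerate(rows)}

    called_ids = [s for s, ok in zip(ids, callable_mask) if ok]
    for s, lab in zip(called_ids, labels):
        rank = rank_of[int(lab)]
        d = dosage_of_rank[rank]  # 0 -> X/X, 1 -> het, 2 -> Y/Y
        calls[s] = genotype_from_dosage(d, plate.allele_x, plate.allele_y)
        clusters[s] = rank
    quality["cluster_count"] = len(centers_sorted)
    quality["silhouette"] = score
    sds = np.array(
        [float(np.std(angles[labels == old])) for old in order], dtype=float
    )
    quality["cluster_sds_deg"] = sds.tolist()
    quality["angular_spread_deg"] = float(np.std(angles))
    if len(centers_sorted) >= 2:
        center_gaps = np.diff(centers_sorted)
        quality["min_center_gap_deg"] = float(np.min(center_gaps))
        # separation between cluster *edges*: the centre gap minus two
        # angular sds per flank; overlapping clusters go negative
        eff = center_gaps - 2.0 * (sds[:-1] + sds[1:])
        quality["min_gap_deg"] = float(np.min(eff))
    return GenotypeCallSet(
        plate.marker_id, calls, clusters, [float(c) for c in centers_sorted], quality
    )


def triage_assay(
    callset: GenotypeCallSet,
    min_gap_deg: float = 15.0,
    max_nocall: float = 0.2,
) -> AssayTriage:
    """Classify an assay as core, monomorphic, or indistinct/failed.

    An assay fails when too many wells are no-calls, when adjacent clusters
    are separated by less than ``min_gap_deg`` of clear angle (edge-to-edge:
    centre gap minus two angular sds per flank), or when a single called
    cluster is too diffuse to be one genotype; it is monomorphic when
    exactly one genotype class was called cleanly; otherwise it is a core
    candidate.
    """
    reasons: list[str] = []
    nocall = callset.nocall_fraction
    if callset.n_called == 0:
        return AssayTriage("indistinct_or_failed", ["no wells produced a call"])
    if nocall > max_nocall:
        reasons.append(f"no-call fraction {nocall:.2f} > {max_nocall}")
    gap = callset.quality.get("min_gap_deg", np.nan)
    n_clusters = callset.quality.get("cluster_count", 0)
    if n_clusters >= 2 and gap < min_gap_deg:
        reasons.append(f"minimal cluster gap {gap:.1f} deg < {min_gap_deg}")
    spread = callset.quality.get("angular_spread_deg", 0.0)
    if n_clusters == 1 and spread > min_gap_deg:
        reasons.append(
            f"single cluster too diffuse ({spread:.1f} deg angular sd)"
        )
    if reasons:
        return AssayTriage("indistinct_or_failed", reasons)
    if len(callset.genotype_classes()) == 1:
        return AssayTriage("monomorphic", ["single genotype class called"])
    return AssayTriage("core", [])


def replicate_concordance(
    callsets: list[GenotypeCallSet],
    nocall_as_discordant: bool = False,
    denominator: str = "samples",
) -> dict:
    """Consistency of replicate runs of the same assay.

    Default semantics: samples with any no-call across replicates are
    excluded; concordance is the fraction of the remaining samples with
    identical genotypes in every replicate, and error rate its complement.
    ``nocall_as_discordant`` instead keeps those samples and counts them as
    discordant. ``denominator="pairs"`` scores all replicate pairs per sample
    instead of the all-identical criterion.
    """
    if len(callsets) < 2:
        raise ArityError("need at least two replicate call sets")
    common = set(callsets[0].calls)
    for cs in callsets[1:]:
        common &= set(cs.calls)
    if not common:
        raise ArityError("replicates share no sample ids")
    fully_called = []
    discordant_nocall = 0
    for s in sorted(common):
        gs = [cs.calls[s] for cs in callsets]
        if any(g is None for g in gs):
            if nocall_as_discordant:
                discordant_nocall += 1
            continue
        fully_called.append(gs)

    if denominator == "samples":
        n_eval = len(fully_called) + discordant_nocall
        if n_eval == 0:
            raise ArityError("no sample is fully called in all replicates")
        n_ok = sum(1 for gs in fully_called if len(set(gs)) == 1)
        concordance = n_ok / n_eval
    elif denominator == "pairs":
        n_pairs = 0
        n_ok_pairs = 0
        for gs in fully_called:
            for i in range(len(gs)):
                for j in range(i + 1, len(gs)):
                    n_pairs += 1
                    n_ok_pairs += gs[i] == gs[j]
        r = len(callsets)
        n_pairs += discordant_nocall * r * (r - 1) // 2
        if n_pairs == 0:
            raise ArityError("no comparable replicate pairs")
        concordance = n_ok_pairs / n_pairs
    else:
        raise ValueError("denominator must be 'samples' or 'pairs'")
    return {
        "concordance": concordance,
        "error_rate": 1.0 - concordance,
        "n_samples": len(common),
        "n_fully_called": len(fully_called),
    }
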