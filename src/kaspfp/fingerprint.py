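"""DNA fingerprint databases, core-marker selection and query matching.

A fingerprint is an accession's ordered multilocus genotype profile. The
database stores profiles verbatim (missing calls included, never imputed)
and supports:

* near-duplicate detection (pairs differing at few mutually called loci);
* greedy selection of a minimal discriminating marker subset, with the
  identification-efficiency curve (distinct profiles and separated pairs
  after each added marker);
* matching an unknown profile against the database — an exact match means
  zero mismatches over sufficiently many mutually called loci;
* export of the colour-coded fingerprint matrix (homozygous AA yellow,
  GG orange, CC blue, TT purple; heterozygotes green; missing grey).

Two accessions are *separated* by a marker only where both are called and
differ there; a missing call is conservative evidence of nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import allele_frequencies, pic
from .errors import UndefinedStatisticError
from .genotypes import GenotypeMatrix

COLOR_LEGEND = {
    "AA": "yellow",
    "GG": "orange",
    "CC": "blue",
    "TT": "purple",
    "heterozygote": "green",
    "missing": "grey",
}


def genotype_color(g: str | None) -> str:
    """Fingerprint heatmap colour of one genotype cell."""
    if g is None:
        return COLOR_LEGEND["missing"]
    if g[0] != g[1]:
        return COLOR_LEGEND["heterozygote"]
    return COLOR_LEGEND.get(g, "grey")


@dataclass
class FingerprintDB:
    """Ordered marker list plus per-accession genotype profiles."""

    genotypes: GenotypeMatrix
    provenance: str = ""

    @property
    def marker_order(self) -> list[str]:
        return self.genotypes.markers

    @property
    def accessions(self) -> list[str]:
        return self.genotypes.accessions

    def profile(self, accession: str) -> pd.Series:
        return self.genotypes.df.loc[accession]

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str = "") -> "FingerprintDB":
        return cls(GenotypeMatrix.from_csv(path), provenance=provenance)

    def to_csv(self, path: str | Path) -> None:
        self.genotypes.to_csv(path)


@dataclass
class MatchReport:
    """Comparison of one query profile against every database entry."""

    query_id: str
    verdict: str  # matched accession id | "no match" | "insufficient data"
    nearest: pd.DataFrame  # index accession; columns mismatches, loci_compared


@dataclass
class EfficiencyCurve:
    """Identification efficiency as markers are added greedily."""

    steps: pd.DataFrame  # columns: marker, n_distinct, pairs_separated_fraction
    unseparated_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.unseparated_pairs


def build_fingerprint_db(gm: GenotypeMatrix, provenance: str = "") -> FingerprintDB:
    """Wrap a genotype matrix as a fingerprint database (calls verbatim)."""
    return FingerprintDB(genotypes=gm, provenance=provenance)


def _mismatches(a: pd.Series, b: pd.Series) -> tuple[int, int]:
    """(mismatch count, loci compared) over mutually called loci."""
    mism = 0
    compared = 0
    for x, y in zip(a, b):
        if x is None or y is None:
            continue
        compared += 1
        mism += x != y
    return mism, compared


def find_duplicates(db: FingerprintDB, max_mismatch: int = 1) -> pd.DataFrame:
    """All unordered accession pairs with <= ``max_mismatch`` differences.

    Differences are counted over mutually called loci; the returned frame
    carries (accession_a, accession_b, mismatches, loci_compared).
    """
    rows = []
    acc = db.accessions
    for i in range(len(acc)):
        for j in range(i + 1, len(acc)):
            m, c = _mismatches(db.profile(acc[i]), db.profile(acc[j]))
            if m <= max_mismatch:
                rows.append(
                    {
                        "accession_a": acc[i],
                        "accession_b": acc[j],
                        "mismatches": m,
                        "loci_compared": c,
                    }
                )
    return pd.DataFrame(rows, columns=["accession_a", "accession_b", "mismatches", "loci_compared"])


def discrimination_count(db: FingerprintDB, markers: Sequence[str]) -> int:
    """Distinct profiles when restricted to a marker subset.

    Missing compares equal to missing and unequal to every call, so two
    profiles are counted distinct only if they differ at some subset marker
    as stored. The empty subset collapses everything to one profile.
    """
    unknown = [m for m in markers if m not in db.marker_order]
    if unknown:
        raise KeyError(f"unknown marker ids: {unknown}")
    if not markers:
        return 1 if db.accessions else 0
    sub = db.genotypes.df[list(markers)]
    return len({tuple(row) for row in sub.itertuples(index=False)})


def _marker_pic(db: FingerprintDB, marker: str) -> float:
    try:
        return pic(allele_frequencies(db.genotypes.column(marker)))
    except UndefinedStatisticError:
        return 0.0


def greedy_core_markers(db: FingerprintDB) -> tuple[list[str], EfficiencyCurve]:
    """Greedy minimal discriminating marker subset + efficiency curve.

    At each step the marker separating the most not-yet-separated accession
    pairs is added (a pair is separated by a marker where both are called
    and differ); ties go to the higher-PIC marker, then to database marker
    order. Stops when every pair is separated or no marker separates any
    remaining pair. The greedy subset is small but not certified minimal.
    """
    acc = db.accessions
    n = len(acc)
    markers = db.marker_order
    pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
    total_pairs = len(pair_idx)
    pics = {m: _marker_pic(db, m) for m in markers}
    order_idx = {m: i for i, m in enumerate(markers)}

    # separates[p, m]: pair p has both members called and different at marker m
    df = db.genotypes.df
    separates = np.zeros((total_pairs, len(markers)), dtype=bool)
    for mj, m in enumerate(markers):
        col = list(df[m])
        for p, (i, j) in enumerate(pair_idx):
            gi, gj = col[i], col[j]
            separates[p, mj] = gi is not None and gj is not None and gi != gj

    unsep = np.ones(total_pairs, dtype=bool)
    chosen: list[str] = []
    steps = []
    while unsep.any():
        best = None
        for m in markers:
            if m in chosen:
                continue
            gain = int(np.sum(separates[unsep, order_idx[m]]))
            cand = (gain, pics[m], -order_idx[m], m)
            if best is None or cand[:3] > best[:3]:
                best = cand
        if best is None or best[0] == 0:
            break
        m = best[3]
        chosen.append(m)
        unsep &= ~separates[:, order_idx[m]]
        steps.append(
            {
                "marker": m,
                "n_distinct": discrimination_count(db, chosen),
                "pairs_separated_fraction": (
                    1.0 - unsep.sum() / total_pairs if total_pairs else 1.0
                ),
            }
        )

    unseparated = sorted(
        (acc[pair_idx[p][0]], acc[pair_idx[p][1]]) for p in np.flatnonzero(unsep)
    )
    curve = EfficiencyCurve(
        steps=pd.DataFrame(
            steps, columns=["marker", "n_distinct", "pairs_separated_fraction"]
        ),
        unseparated_pairs=unseparated,
    )
    return chosen, curve


def match_query(
    db: FingerprintDB,
    profile: pd.Series | dict,
    query_id: str = "query",
    min_overlap: int = 20,
) -> MatchReport:
    """Compare an unknown profile against every database entry.

    Mismatches are counted over mutually called loci. Verdict: the matched
    accession id when some entry shows zero mismatches with at least
    ``min_overlap`` loci compared; "insufficient data" when no entry reaches
    the overlap; otherwise "no match". Nearest entries are ranked by
    (mismatches, more loci compared first).
    """
    from ._util import normalize_genotype

    q = pd.Series(profile).reindex(db.marker_order).map(normalize_genotype)
    rows = []
    for a in db.accessions:
        m, c = _mismatches(q, db.profile(a))
        rows.append({"accession": a, "mismatches": m, "loci_compared": c})
    nearest = (
        pd.DataFrame(rows)
        .sort_values(["mismatches", "loci_compared"], ascending=[True, False], kind="stable")
        .set_index("accession")
    )
    enough = nearest["loci_compared"] >= min_overlap
    if not enough.any():
        verdict = "insufficient data"
    else:
        hits = nearest[enough & (nearest["mismatches"] == 0)]
        verdict = hits.index[0] if len(hits) else "no match"
    return MatchReport(query_id=query_id, verdict=verdict, nearest=nearest)


def export_fingerprint_matrix(
    db: FingerprintDB, path: str | Path, render_image: str | Path | None = None
) -> None:
    """Write the genotype matrix CSV plus a colour-legend sidecar.

    The legend file (``<path>.legend.csv``) maps genotype classes to the
    conventional fingerprint colours. With ``render_image`` a heatmap is
    drawn to the given file via matplotlib.
    """
    path = Path(path)
    db.to_csv(path)
    legend = pd.DataFrame(
        [{"genotype": k, "color": v} for k, v in COLOR_LEGEND.items()]
    )
    legend.to_csv(path.with_suffix(path.suffix + ".legend.csv"), index=False)
    if render_image is not None:
        _render_heatmap(db, render_image)


def _render_heatmap(db: FingerprintDB, out: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    palette = ["yellow", "orange", "blue", "purple", "green", "grey"]
    index_of = {"AA": 0, "GG": 1, "CC": 2, "TT": 3}
    df = db.genotypes.df
    mat = np.full(df.shape, 5)
    for i, acc in enumerate(df.index):
        for j, m in enumerate(df.columns):
            g = df.iat[i, j]
            if g is None:
                mat[i, j] = 5
            elif g[0] != g[1]:
                mat[i, j] = 4
            else:
                mat[i, j] = index_of.get(g, 5)
    fig, ax = plt.subplots(figsize=(max(4, df.shape[1] * 0.3), max(4, df.shape[0] * 0.15)))
    ax.imshow(mat.T, aspect="auto", cmap=ListedColormap(palette), vmin=0, vmax=5)
    ax.set_yticks(range(df.shape[1]), df.columns, fontsize=6)
    ax.set_xticks(range(df.shape[0]), df.index, rotation=90, fontsize=5)
    ax.set_xlabel("accession")
    ax.set_ylabel("marker")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
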