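"""Evanno's Delta-K for choosing the number of ancestral clusters.

Structure-style admixture runs are replicated at each candidate K and their
final log-likelihoods lnP(D) tabulated. With L(K) the replicate mean and
s(K) the replicate sample standard deviation:

    L'(K)    = L(K) - L(K-1)
    |L''(K)| = |L'(K+1) - L'(K)|
    DeltaK   = |L''(K)| / s(K)

DeltaK is defined for interior K only and is undefined where s(K) = 0
(identical replicates); the supported K is the argmax of the defined DeltaK
values. This is the per-K form plotted by the standard Evanno tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EvannoTable:
    """Per-K summary of replicate log-likelihoods and derived Delta-K."""

    table: pd.DataFrame  # index K; columns: n_runs, mean_lnP, sd_lnP, Lprime, Lsecond_abs, deltaK
    best_k: int | None  # argmax of defined deltaK values

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def evanno_delta_k(runs: pd.DataFrame | dict) -> EvannoTable:
    """Compute the Evanno table from replicate run likelihoods.

    ``runs`` is either a mapping {K: [lnP values]} or a long DataFrame with
    columns (K, lnP). Requires at least three consecutive K values and at
    least two replicates per K.
    """
    if isinstance(runs, dict):
        long = pd.DataFrame(
            [(int(k), float(v)) for k, vals in runs.items() for v in vals],
            columns=["K", "lnP"],
        )
    else:
        long = runs.rename(columns={c: c.strip() for c in runs.columns})[["K", "lnP"]]
    grouped = long.groupby("K")["lnP"]
    ks = sorted(grouped.groups)
    if len(ks) < 3:
        raise ValueError("need at least three K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    if (grouped.count() < 2).any():
        raise ValueError("need at least two replicates per K")

    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    tbl = pd.DataFrame(
        {
            "n_runs": grouped.count(),
            "mean_lnP": mean,
            "sd_lnP": sd,
            "Lprime": mean.diff(),
            "Lsecond_abs": np.nan,
            "deltaK": np.nan,
        }
    )
    for k in ks[1:-1]:
        lpp = abs(tbl.loc[k + 1, "Lprime"] - tbl.loc[k, "Lprime"])
        tbl.loc[k, "Lsecond_abs"] = lpp
        if sd[k] > 0:
            tbl.loc[k, "deltaK"] = lpp / sd[k]
    defined = tbl["deltaK"].dropna()
    best_k = int(defined.idxmax()) if len(defined) else None
    return EvannoTable(table=tbl, best_k=best_k)
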