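"""Maximum-likelihood admixture model fitted by EM.

Model
-----
Each accession i carries ancestry proportions Q_i (a point on the K-simplex)
and each source population k has an allele frequency P_kl at locus l. The
counted-allele dosage is

    g_il ~ Binomial(2, q_il),   q_il = sum_k Q_ik P_kl,

so the log-likelihood (up to a constant) is
``sum_il g_il ln q_il + (2 - g_il) ln(1 - q_il)`` over called cells.

This is the likelihood maximised by Structure-style admixture programs; here
it is fitted by the standard multiplicative EM updates (as in FRAPPE /
ADMIXTURE's EM mode), which ascend the likelihood monotonically. Several
seeded random restarts guard against local optima; the best final
log-likelihood wins.

The interface follows the statsmodels convention: construct an
:class:`AdmixtureModel` from data, call :meth:`~AdmixtureModel.fit`, and read
estimates off the returned :class:`AdmixtureResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._util import spawn_rng
from ..errors import ConfigurationError
from ..genotypes import GenotypeMatrix

_EPS = 1e-6


class AdmixtureModel:
    """Admixture likelihood for a genotype matrix at a fixed K.

    Parameters
    ----------
    data
        GenotypeMatrix, or an (n, L) dosage array with values in {0, 1, 2}
        and NaN for missing.
    K
        Number of ancestral populations (1 <= K <= n).
    """

    def __init__(self, data: GenotypeMatrix | np.ndarray, K: int):
        if isinstance(data, GenotypeMatrix):
            self.dosage = data.dosage()
            self.accessions = data.accessions
            self.markers = data.markers
        else:
            self.dosage = np.asarray(data, dtype=float)
            self.accessions = [f"acc{i + 1}" for i in range(self.dosage.shape[0])]
            self.markers = [f"M{j + 1}" for j in range(self.dosage.shape[1])]
        n, L = self.dosage.shape
        if not (1 <= K <= n):
            raise ConfigurationError(f"K must lie in [1, {n}], got {K}")
        self.K = K
        self.mask = ~np.isnan(self.dosage)
        self.g = np.nan_to_num(self.dosage, nan=0.0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, K: int) -> "AdmixtureModel":
        """Build from a DataFrame of genotype strings (accessions x markers)."""
        return cls(GenotypeMatrix(df), K)

    # -- likelihood --------------------------------------------------------

    def loglik(self, Q: np.ndarray, P: np.ndarray) -> float:
        q = np.clip(Q @ P, _EPS, 1 - _EPS)
        ll = self.g * np.log(q) + (2 - self.g) * np.log(1 - q)
        return float(np.sum(ll[self.mask]))

    def _em_run(self, seed: int, tol: float, max_iter: int):
        rng = spawn_rng(seed)
        n, L, K = *self.dosage.shape, self.K
        Q = rng.dirichlet(np.ones(K), size=n)
        P = rng.uniform(0.05, 0.95, size=(K, L))
        g = self.g
        m = self.mask.astype(float)
        two_Li = 2.0 * self.mask.sum(axis=1, keepdims=True)  # callable alleles per accession
        trace = [self.loglik(Q, P)]
        converged = False
        for _ in range(max_iter):
            q = np.clip(Q @ P, _EPS, 1 - _EPS)
            # posterior responsibilities for the counted / complementary allele
            A = (g * m) / q  # (n, L)
            B = ((2 - g) * m) / (1 - q)
            # a_ilk = Q_ik P_kl A_il ; b_ilk = Q_ik (1-P_kl) B_il, summed over l / i
            QA = Q * (A @ P.T)  # (n, K): sum_l a_ilk
            QB = Q * (B @ (1 - P).T)  # (n, K): sum_l b_ilk
            Q_new = (QA + QB) / two_Li
            Q_new /= Q_new.sum(axis=1, keepdims=True)
            num = Q.T @ A * P  # (K, L): sum_i a_ilk
            den = num + (Q.T @ B) * (1 - P)
            P_new = np.clip(num / np.maximum(den, _EPS), _EPS, 1 - _EPS)
            Q, P = Q_new, P_new
            trace.append(self.loglik(Q, P))
            if abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
        return Q, P, trace, converged

    def fit(
        self,
        seed: int = 0,
        tol: float = 1e-6,
        max_iter: int = 2000,
        n_restarts: int = 5,
    ) -> "AdmixtureResults":
        """Fit by EM from ``n_restarts`` seeded random initialisations."""
        rng = spawn_rng(seed)
        best = None
        for _ in range(max(1, n_restarts)):
            run_seed = int(rng.integers(2**31))
            Q, P, trace, converged = self._em_run(run_seed, tol, max_iter)
            if best is None or trace[-1] > best[2][-1]:
                best = (Q, P, trace, converged)
        Q, P, trace, converged = best
        return AdmixtureResults(
            model=self, Q=Q, P=P, loglik_trace=np.array(trace), converged=converged
        )


@dataclass
class AdmixtureResults:
    """Fitted ancestry proportions and source allele frequencies."""

    model: AdmixtureModel
    Q: np.ndarray  # (n, K), rows sum to 1
    P: np.ndarray  # (K, L), entries in [eps, 1 - eps]
    loglik_trace: np.ndarray
    converged: bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Q,
            index=self.model.accessions,
            columns=[f"K{k + 1}" for k in range(self.model.K)],
        )

    def dominant_ancestry(self) -> np.ndarray:
        return np.argmax(self.Q, axis=1)

    def aligned_Q(self, reference_Q: np.ndarray) -> np.ndarray:
        """Q with columns permuted to best match a reference (label switching).

        Uses a minimum-cost (Hungarian) assignment on mean absolute column
        differences — ancestry components are only identified up to
        permutation.
        """
        from scipy.optimize import linear_sum_assignment

        ref = np.asarray(reference_Q, dtype=float)
        if ref.shape != self.Q.shape:
            raise ValueError("reference Q shape mismatch")
        K = self.model.K
        cost = np.zeros((K, K))
        for a in range(K):
            for b in range(K):
                cost[a, b] = np.mean(np.abs(self.Q[:, a] - ref[:, b]))
        rows, cols = linear_sum_assignment(cost)
        perm = np.empty(K, dtype=int)
        perm[cols] = rows
        return self.Q[:, perm]

    def summary(self) -> str:
        n, K = self.Q.shape
        mean_q = self.Q.mean(axis=0)
        lines = [
            "Admixture model (EM)",
            "=" * 40,
            f"accessions:        {n}",
            f"markers:           {self.P.shape[1]}",
            f"K:                 {K}",
            f"log-likelihood:    {self.loglik:.3f}",
            f"EM iterations:     {len(self.loglik_trace) - 1}",
            f"converged:         {self.converged}",
            "mean ancestry by component:",
        ]
        for k in range(K):
            lines.append(f"  K{k + 1}: {mean_q[k]:.3f}")
        return "\n".join(lines)


def admixture_em(
    gm: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 5,
) -> AdmixtureResults:
    """Functional facade over :class:`AdmixtureModel` + ``fit``."""
    return AdmixtureModel(gm, K).fit(
        seed=seed, tol=tol, max_iter=max_iter, n_restarts=n_restarts
    )
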