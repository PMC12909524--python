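"""Genotype principal component analysis.

Genotypes are coded as minor-allele dosage (0/1/2), missing cells are
mean-imputed per marker, columns are centred, and the covariance is
eigendecomposed (via SVD). The leading components separate ancestry groups
when population structure is present.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import DegenerateInputError
from ..genotypes import GenotypeMatrix


def genotype_pca(
    gm: GenotypeMatrix, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Top principal components of the dosage matrix.

    Returns (coordinates, variance_explained): a DataFrame of accession
    scores on PC1..PCk and the fraction of total variance carried by each
    component (non-increasing, summing to <= 1).
    """
    from sklearn.decomposition import PCA

    if len(gm.accessions) < 2 or len(gm.markers) < 2:
        raise DegenerateInputError("PCA needs at least 2 accessions and 2 markers")
    X = gm.dosage()
    col_means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_means[nan_c]
    if np.allclose(X.var(axis=0), 0.0):
        raise DegenerateInputError("genotype matrix carries no variation")
    n_components = min(n_components, min(X.shape) - 1) or 1
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    coords = pd.DataFrame(
        scores,
        index=gm.accessions,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return coords, pca.explained_variance_ratio_
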