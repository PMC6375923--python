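"""Correlation structure and PCA over the 8-category composition matrix."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # categories x components, orthonormal
    explained_variance_ratio: np.ndarray
    preprocessing: str

    def cumulative_variance(self, n: int) -> float:
        return float(self.explained_variance_ratio[:n].sum())


def correlation_matrix(m: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between categories over samples.

    Zero-variance categories yield NaN rows/columns (their correlation is
    undefined) with a warning.
    """
    df = pd.DataFrame(m)
    if len(df) < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    zero_var = df.columns[df.std(ddof=1) == 0]
    if len(zero_var):
        warnings.warn(
            f"zero-variance categories {list(zero_var)}: correlations undefined",
            stacklevel=2,
        )
    corr = df.corr(method="pearson")
    # pandas leaves the unit diagonal in place for constant columns; blank it
    for c in zero_var:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    return corr


def pca(
    m: pd.DataFrame,
    scaling: str = "unit-variance",
    n_components: int | None = None,
) -> PCAResult:
    """Centered (optionally standardized) PCA by singular value decomposition.

    Sign convention: within each loading vector the entry of largest
    magnitude is made positive, so scores and loadings are reproducible
    across linear-algebra backends.
    """
    df = pd.DataFrame(m).astype(float)
    n, p = df.shape
    if n < 2:
        raise ValueError("PCA needs more than one sample")
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    elif n_components > max_comp:
        warnings.warn(
            f"requested {n_components} components; only {max_comp} identifiable",
            stacklevel=2,
        )
        n_components = max_comp

    X = df.to_numpy() - df.to_numpy().mean(axis=0)
    if scaling == "unit-variance":
        sd = df.std(ddof=1).to_numpy()
        keep = sd > 0
        if not np.all(keep):
            warnings.warn("dropping zero-variance columns before scaling",
                          stacklevel=2)
        X = X[:, keep] / sd[keep]
        cols = df.columns[keep]
    elif scaling == "none":
        cols = df.columns
    else:
        raise ValueError("scaling must be 'unit-variance' or 'none'")

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic signs: largest |loading| entry positive per component
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    var = S ** 2
    ratio = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (U[:, :n_components] * S[:n_components]), index=df.index, columns=comp_names
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=cols, columns=comp_names)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=ratio[:n_components],
        preprocessing=f"centered, scaling={scaling}",
    )
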