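"""Sample-structure diagnostics: log transform, PCA, loading orders, correlation.

PCA is run on the log-transformed gene x sample matrix with gene-wise mean
centering and no variance scaling. Eigenvector signs follow a deterministic
convention (the largest-magnitude loading of each component is positive) so
score plots and loading orders are reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from surfdbm.expression import ExpressionMatrix


def log_transform(
    matrix: ExpressionMatrix, pseudocount: float = 1.0, base: float = 2.0
) -> ExpressionMatrix:
    """Entry-wise log(value + pseudocount); strictly monotone in the input."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    if base <= 1:
        raise ValueError(f"log base must be > 1, got {base}")
    arr = matrix.values.to_numpy(dtype=float)
    if arr.size and (arr < 0).any():
        raise ValueError("matrix entries must be non-negative")
    out = np.log(arr + pseudocount) / np.log(base)
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    unit = f"log{base:g}({matrix.unit}+{pseudocount:g})"
    return matrix.with_values(df, unit=unit)


@dataclass
class PCAResult:
    """Principal components of the sample cloud in gene space.

    ``scores`` is sample x component, ``loadings`` gene x component with
    orthonormal columns; components are labelled PC1..PCk.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    pseudocount: float | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(
    matrix: ExpressionMatrix, n_components: int | None = None, pseudocount: float | None = None
) -> PCAResult:
    """PCA of samples over genes: gene-wise centering, SVD, deterministic signs.

    ``n_components`` defaults to min(n_genes, n_samples - 1). The all-identical
    degenerate case yields zero scores and zero explained variance rather than
    an error.
    """
    X = matrix.values.to_numpy(dtype=float).T  # samples x genes
    n_samples, n_genes = X.shape
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    max_k = min(n_genes, n_samples - 1)
    k = max_k if n_components is None else int(n_components)
    if not 1 <= k <= max_k:
        raise ValueError(f"n_components must be in [1, {max_k}], got {k}")
    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = float((Xc**2).sum())
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:k].T  # genes x k
    # sign convention: largest-|loading| entry of each component is positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = Xc @ loadings
    if total_var > 0:
        evr = (S[:k] ** 2) / total_var
    else:
        evr = np.zeros(k)
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.values.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.values.index, columns=comp_names),
        explained_variance_ratio=evr,
        pseudocount=pseudocount,
    )


def sorted_loadings(pca: PCAResult, component: int) -> pd.DataFrame:
    """Genes sorted ascending by their weight in one component (1-based index).

    Ties on weight break lexicographically by gene_id.
    """
    if not 1 <= component <= pca.n_components:
        raise ValueError(f"component must be in [1, {pca.n_components}], got {component}")
    col = f"PC{component}"
    df = pd.DataFrame(
        {"gene_id": pca.loadings.index.to_numpy(), "weight": pca.loadings[col].to_numpy()}
    )
    return df.sort_values(["weight", "gene_id"], kind="mergesort").reset_index(drop=True)


def loading_concentration(pca: PCAResult, component: int, genes: Sequence[str]) -> float:
    """Fraction of a component's total |weight| mass carried by the given genes."""
    if not 1 <= component <= pca.n_components:
        raise ValueError(f"component must be in [1, {pca.n_components}], got {component}")
    w = pca.loadings[f"PC{component}"].abs()
    total = float(w.sum())
    if total == 0:
        return 0.0
    keep = [g for g in genes if g in w.index]
    return float(w.loc[keep].sum()) / total


def component_separation(pca: PCAResult, labels: Sequence[str]) -> np.ndarray:
    """Silhouette of the given sample grouping along each component's 1-D score axis.

    Returns one value per component; use it to identify which component, if
    any, separates a factor such as stage or genotype.
    """
    labels = list(labels)
    if len(labels) != pca.scores.shape[0]:
        raise ValueError("one label per sample required")
    if len(set(labels)) < 2:
        raise ValueError("at least two distinct labels required")
    out = np.empty(pca.n_components)
    for j in range(pca.n_components):
        axis = pca.scores.iloc[:, [j]].to_numpy()
        if np.allclose(axis, axis[0]):
            out[j] = 0.0
        else:
            out[j] = silhouette_score(axis, labels)
    return out


@dataclass
class CorrelationMatrix:
    """Sample x sample correlation with a method tag.

    Zero-variance samples yield undefined (NaN) correlations and are listed
    in ``degenerate``.
    """

    values: pd.DataFrame
    method: str
    degenerate: list[str]


def sample_correlation(matrix: ExpressionMatrix, method: str = "pearson") -> CorrelationMatrix:
    """Pairwise correlation between sample columns (Pearson default, Spearman optional)."""
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    if matrix.n_samples < 2:
        raise ValueError("correlation requires at least 2 samples")
    if matrix.n_genes < 2:
        raise ValueError("correlation requires at least 2 genes")
    stds = matrix.values.std(axis=0)
    degenerate = stds.index[stds == 0].tolist()
    arr = matrix.values.corr(method=method).to_numpy()
    np.fill_diagonal(arr, 1.0)
    corr = pd.DataFrame(arr, index=matrix.values.columns, columns=matrix.values.columns)
    for sid in degenerate:
        corr.loc[sid, :] = np.nan
        corr.loc[:, sid] = np.nan
        corr.loc[sid, sid] = np.nan
    return CorrelationMatrix(values=corr, method=method, degenerate=degenerate)
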