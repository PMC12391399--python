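"""Unsupervised ordination (PCA) of normalized proteome samples.

Samples are the observations, proteins the features. Features are
mean-centred and the decomposition runs through SVD, with a
deterministic sign convention (each component's largest-magnitude
loading is made positive) so scores are reproducible across runs and
platforms. Variance explained is reported as the fraction of total
(centred) variance per component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix

__all__ = ["OrdinationResult", "pca", "condition_silhouette"]


@dataclass(frozen=True)
class OrdinationResult:
    scores: pd.DataFrame        # sample × component
    loadings: pd.DataFrame      # protein × component
    variance_explained: np.ndarray  # fraction per returned component

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(
    m: NormalizedMatrix | pd.DataFrame,
    n_components: int = 2,
    center_features: bool = True,
) -> OrdinationResult:
    """PCA of a complete (imputed) protein × sample matrix.

    Proteins are features; no per-feature unit-variance scaling is
    applied by default because upstream sample-level normalization
    already equalizes dynamic range.
    """
    values = m.values if isinstance(m, NormalizedMatrix) else m
    if values.isna().to_numpy().any():
        raise ValueError("matrix has missing cells; impute before ordination")
    X = values.to_numpy(dtype=float).T  # samples × proteins
    n_samples, n_features = X.shape
    max_rank = min(n_samples - 1 if center_features else n_samples, n_features)
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds rank bound {max_rank}"
        )
    if center_features:
        X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for j in range(Vt.shape[0]):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    total_var = float((s ** 2).sum())
    frac = (s ** 2) / total_var if total_var > 0 else np.zeros_like(s)
    comps = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        U[:, :n_components] * s[:n_components], index=values.columns, columns=comps
    )
    loadings = pd.DataFrame(Vt[:n_components].T, index=values.index, columns=comps)
    return OrdinationResult(
        scores=scores, loadings=loadings,
        variance_explained=frac[:n_components].copy(),
    )


def condition_silhouette(result: OrdinationResult, design, component: str = "PC1") -> float:
    """Silhouette of control vs treated groups along one component.

    Positive values mean the two conditions separate along that axis —
    the qualitative ordination signature of a strong treatment effect.
    """
    from sklearn.metrics import silhouette_score

    labels = design.table.set_index("sample_id").loc[
        result.scores.index, "treatment"
    ]
    x = result.scores[[component]].to_numpy()
    return float(silhouette_score(x, labels.to_numpy()))
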