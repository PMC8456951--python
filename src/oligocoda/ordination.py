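"""Compositional covariance biplot via SVD of the centred clr matrix.

The data matrix is perturbation-centred (each row ⊖ the dataset center),
clr-transformed, and decomposed as Z = U S Vᵀ.  In the covariance scaling
the part rays are columns of V S / sqrt(n−1) and sample scores columns of
U sqrt(n−1); squared distances between ray endpoints then approximate the
corresponding variation-matrix entries (exactly so when Z has rank ≤ 2),
and nearly coincident rays flag parts with nearly constant ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CompositionMatrix, center, clr

__all__ = ["BiplotResult", "centred_clr_matrix", "covariance_biplot"]


def centred_clr_matrix(X: CompositionMatrix) -> pd.DataFrame:
    """Z = clr(X ⊖ cen(X)): rows sum to 0 and column means are 0."""
    if X.n < 2:
        raise ValueError("need at least 2 samples")
    cen = center(X).parts
    Z = clr(X.values / cen[None, :])
    return pd.DataFrame(Z, index=X.data.index, columns=list(X.labels))


@dataclass
class BiplotResult:
    """Two-dimensional biplot coordinates and the full singular spectrum."""

    ray_coords: pd.DataFrame  # D × 2
    sample_scores: pd.DataFrame  # n × 2
    singular_values: np.ndarray  # non-increasing
    variance_explained: np.ndarray  # proportions for the two shown axes
    scaling: str


def covariance_biplot(
    Z: pd.DataFrame, n_samples: int | None = None, scaling: str = "covariance"
) -> BiplotResult:
    """Biplot of a centred clr matrix.

    scaling="covariance" (default): rays V·S / sqrt(n−1), scores
    U·sqrt(n−1), so squared inter-ray links live on the scale of
    log-ratio variance.  scaling="form" puts the singular values on the
    samples instead (rays V, scores U·S).

    Sign indeterminacy of the SVD is resolved by flipping each component
    so that its largest-magnitude part loading is positive.
    """
    Zv = np.asarray(Z, dtype=float)
    n = n_samples if n_samples is not None else Zv.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    U, s, Vt = np.linalg.svd(Zv, full_matrices=False)
    if not np.isfinite(s[0]) or s[0] < np.abs(Zv).shape[0] * 1e-12:
        raise ValueError("no variation in the data matrix")
    V = Vt.T
    for k in range(2):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    if scaling == "covariance":
        rays = V[:, :2] * s[:2] / np.sqrt(n - 1)
        scores = U[:, :2] * np.sqrt(n - 1)
    elif scaling == "form":
        rays = V[:, :2]
        scores = U[:, :2] * s[:2]
    else:
        raise ValueError("scaling must be 'covariance' or 'form'")
    tot = float((s**2).sum())
    return BiplotResult(
        ray_coords=pd.DataFrame(rays, index=Z.columns, columns=["axis1", "axis2"]),
        sample_scores=pd.DataFrame(scores, index=Z.index, columns=["axis1", "axis2"]),
        singular_values=s,
        variance_explained=s[:2] ** 2 / tot,
        scaling=scaling,
    )


def plot_biplot(result: BiplotResult, yearday: pd.Series | None = None, path=None):
    """Optional figure writer (requires matplotlib); colors samples by year day."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(
        result.sample_scores["axis1"],
        result.sample_scores["axis2"],
        c=None if yearday is None else yearday.reindex(result.sample_scores.index),
        cmap="twilight",
        s=18,
    )
    if yearday is not None:
        fig.colorbar(sc, ax=ax, label="year day")
    for lab, (x1, x2) in result.ray_coords.iterrows():
        ax.annotate(lab, (x1, x2))
        ax.plot([0, x1], [0, x2], color="k", lw=1)
    v1, v2 = result.variance_explained
    ax.set_xlabel(f"axis 1 ({100 * v1:.1f}%)")
    ax.set_ylabel(f"axis 2 ({100 * v2:.1f}%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
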