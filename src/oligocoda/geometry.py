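"""Aitchison geometry on the simplex.

Relative-abundance data live on the simplex S^D: vectors of D strictly
positive parts constrained to sum to one.  The meaningful information in
such data is carried by ratios of parts, and the natural geometry is the
Aitchison geometry, in which perturbation (closed elementwise product)
plays the role of addition and all metric quantities are built from log
ratios.  This module implements the primitives: closure, perturbation,
inner product / norm / distance, the evenness index AI2, the dataset
center, the variation matrix, and the centred log-ratio (clr) transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Composition",
    "CompositionMatrix",
    "VariationMatrix",
    "AitchisonIndex",
    "closure",
    "perturb",
    "perturb_diff",
    "inverse",
    "aitchison_inner",
    "aitchison_norm",
    "aitchison_distance",
    "aitchison_index",
    "ai2_series",
    "center",
    "variation_matrix",
    "total_variance",
    "clr",
    "clr_inv",
    "pairwise_distance_matrix",
]

_SUM_TOL = 1e-9


def closure(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Normalize a non-negative vector (or rows of a matrix) to unit sum.

    Closure is scale-invariant: ``closure(lam * c) == closure(c)`` for any
    positive scalar ``lam``.  The result is a plain array of proportions;
    promotion to :class:`Composition` additionally requires strict
    positivity (zeros must be imputed first).
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("negative entry in composition vector")
    s = v.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("empty composition: all entries are zero")
    return v / s


def _parts(x: "Composition | np.ndarray | Sequence[float]") -> np.ndarray:
    if isinstance(x, Composition):
        return x.parts
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class Composition:
    """A point of the simplex S^D: D strictly positive parts summing to 1."""

    parts: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.parts, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ValueError("a composition needs at least two parts")
        if np.any(p <= 0) or not np.all(np.isfinite(p)):
            raise ValueError(
                "composition parts must be strictly positive and finite; "
                "impute zeros before constructing a Composition"
            )
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValueError("composition parts must sum to 1 (apply closure first)")
        p = p.copy()
        p.flags.writeable = False
        object.__setattr__(self, "parts", p)
        if self.labels is not None:
            labels = tuple(str(l) for l in self.labels)
            if len(labels) != p.size:
                raise ValueError("labels length does not match number of parts")
            object.__setattr__(self, "labels", labels)

    @classmethod
    def from_counts(
        cls, counts: Sequence[float], labels: Sequence[str] | None = None
    ) -> "Composition":
        """Closure of a strictly positive count/abundance vector."""
        return cls(closure(counts), tuple(labels) if labels is not None else None)

    @classmethod
    def uniform(cls, D: int, labels: Sequence[str] | None = None) -> "Composition":
        return cls(np.full(D, 1.0 / D), tuple(labels) if labels is not None else None)

    @property
    def D(self) -> int:
        return self.parts.size

    def as_series(self) -> pd.Series:
        return pd.Series(self.parts, index=list(self.labels) if self.labels else None)

    def __len__(self) -> int:
        return self.parts.size

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.parts, dtype=dtype)


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xv, yv = _parts(x), _parts(y)
    if xv.shape != yv.shape:
        raise ValueError(f"composition length mismatch: {xv.shape} vs {yv.shape}")
    if (
        isinstance(x, Composition)
        and isinstance(y, Composition)
        and x.labels is not None
        and y.labels is not None
        and x.labels != y.labels
    ):
        raise ValueError("composition labels do not match")
    return xv, yv


def _labels_of(x, y=None) -> tuple[str, ...] | None:
    for c in (x, y):
        if isinstance(c, Composition) and c.labels is not None:
            return c.labels
    return None


def perturb(x, y) -> Composition:
    """Perturbation x ⊕ y: closure of the elementwise product."""
    xv, yv = _check_pair(x, y)
    return Composition(closure(xv * yv), _labels_of(x, y))


def inverse(x) -> Composition:
    """Perturbation inverse: closure of elementwise reciprocals."""
    xv = _parts(x)
    return Composition(closure(1.0 / xv), _labels_of(x))


def perturb_diff(x, y) -> Composition:
    """Perturbation difference x ⊖ y = x ⊕ y⁻¹."""
    xv, yv = _check_pair(x, y)
    return Composition(closure(xv / yv), _labels_of(x, y))


def clr(x) -> np.ndarray:
    """Centred log-ratio transform: ln(parts / geometric mean).

    Works on a single composition (returns a D-vector summing to 0) or on
    an (n, D) matrix row-wise.
    """
    v = _parts(x) if not isinstance(x, CompositionMatrix) else x.values
    logv = np.log(v)
    return logv - logv.mean(axis=-1, keepdims=True)


def clr_inv(v: np.ndarray, labels: Sequence[str] | None = None) -> Composition | np.ndarray:
    """Inverse clr: closure of exp.  1-D input yields a Composition."""
    v = np.asarray(v, dtype=float)
    out = closure(np.exp(v))
    if v.ndim == 1:
        return Composition(out, tuple(labels) if labels is not None else None)
    return out


def aitchison_inner(x, y) -> float:
    """Aitchison inner product ⟨x, y⟩_a = clr(x) · clr(y)."""
    xv, yv = _check_pair(x, y)
    return float(np.dot(clr(xv), clr(yv)))


def aitchison_norm(x) -> float:
    """Aitchison norm ‖x‖_a = sqrt(⟨x, x⟩_a); 0 iff x is uniform."""
    c = clr(_parts(x))
    return float(np.sqrt(np.dot(c, c)))


def aitchison_distance(x, y) -> float:
    """Aitchison distance d_a(x, y) = ‖x ⊖ y‖_a (a metric on S^D)."""
    xv, yv = _check_pair(x, y)
    diff = clr(xv) - clr(yv)
    return float(np.sqrt(np.dot(diff, diff)))


@dataclass(frozen=True)
class AitchisonIndex:
    """Evenness of a composition: AI2 = ‖x‖²_a / D, plus the [0,1) scaling."""

    ai2: float
    scaled: float


def aitchison_index(x) -> AitchisonIndex:
    """Aitchison evenness index AI2 = ‖x‖²_a / D and scaled = 1 − exp(−AI2).

    AI2 is 0 exactly for the uniform composition and grows without bound
    as one part dominates; scaled AI2 maps this to [0, 1), with values
    near 1 indicating that only one or two parts dominate.
    """
    v = _parts(x)
    ai2 = aitchison_norm(v) ** 2 / v.size
    return AitchisonIndex(ai2=ai2, scaled=float(1.0 - np.exp(-ai2)))


@dataclass
class CompositionMatrix:
    """n dated samples × D parts, every row a valid composition.

    ``data`` is a DataFrame indexed by sample id with part labels as
    columns; ``dates`` is a datetime Series aligned to the same index.
    """

    data: pd.DataFrame
    dates: pd.Series

    def __post_init__(self) -> None:
        if self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise ValueError("composition matrix needs >=1 sample and >=2 parts")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
            raise ValueError("composition matrix entries must be strictly positive")
        if np.any(np.abs(vals.sum(axis=1) - 1.0) > _SUM_TOL):
            raise ValueError("composition matrix rows must sum to 1")
        self.dates = pd.Series(pd.to_datetime(self.dates), index=self.data.index)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")

    @classmethod
    def from_rows(
        cls,
        rows: Iterable[Composition],
        sample_ids: Sequence[str],
        sample_dates: Sequence,
    ) -> "CompositionMatrix":
        rows = list(rows)
        labels = rows[0].labels or [f"p{j+1}" for j in range(rows[0].D)]
        for r in rows:
            if r.labels != rows[0].labels or r.D != rows[0].D:
                raise ValueError("all rows must share labels and dimension")
        df = pd.DataFrame(
            np.vstack([r.parts for r in rows]), index=list(sample_ids), columns=list(labels)
        )
        return cls(df, pd.Series(pd.to_datetime(sample_dates), index=df.index))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def D(self) -> int:
        return self.data.shape[1]

    def row(self, sample_id) -> Composition:
        return Composition(self.data.loc[sample_id].to_numpy(), self.labels)


@dataclass(frozen=True)
class VariationMatrix:
    """Aitchison variation matrix: t_kj = var(ln(x_k / x_j)) across samples.

    Symmetric, zero diagonal, entries >= 0; t_kj == 0 exactly when the
    ratio x_k/x_j is constant, so small entries flag proportional parts.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValueError("variation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("variation matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("variation matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("variation matrix entries must be non-negative")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def D(self) -> int:
        return self.values.shape[0]


def center(X: CompositionMatrix) -> Composition:
    """Center of a dataset: closure of per-part geometric means."""
    g = np.exp(np.log(X.values).mean(axis=0))
    return Composition(closure(g), X.labels)


def variation_matrix(X: CompositionMatrix) -> VariationMatrix:
    """Pairwise log-ratio variances (sample variance, divisor n − 1)."""
    if X.n < 2:
        raise ValueError("variation matrix requires at least 2 samples")
    L = np.log(X.values)
    D = X.D
    t = np.zeros((D, D))
    for k in range(D):
        diff = L[:, k][:, None] - L  # ln(x_k / x_j) per sample
        t[k, :] = diff.var(axis=0, ddof=1)
    t = np.maximum((t + t.T) / 2.0, 0.0)
    np.fill_diagonal(t, 0.0)
    return VariationMatrix(pd.DataFrame(t, index=list(X.labels), columns=list(X.labels)))


def total_variance(X: CompositionMatrix) -> float:
    """Total (metric) variance: sum of per-part clr variances.

    Equals (1/(2D)) * sum of all variation-matrix entries.
    """
    Z = clr(X.values)
    return float(Z.var(axis=0, ddof=1).sum())


def ai2_series(X: CompositionMatrix) -> pd.DataFrame:
    """AI2 and scaled AI2 per sample (the evenness time series)."""
    out = [aitchison_index(row) for row in X.values]
    return pd.DataFrame(
        {"ai2": [a.ai2 for a in out], "scaled_ai2": [a.scaled for a in out]},
        index=X.data.index,
    )


def pairwise_distance_matrix(
    X: CompositionMatrix, seasons: pd.Series | None = None
) -> pd.DataFrame:
    """All pairwise Aitchison distances, as a labelled symmetric matrix.

    With ``seasons`` given (sample id -> season label), rows and columns
    are ordered by season group and, within season, by day of year — the
    layout that makes within-season similarity blocks visible.
    """
    if X.n < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    Z = clr(X.values)
    dm = squareform(pdist(Z, metric="euclidean"))
    df = pd.DataFrame(dm, index=X.data.index, columns=X.data.index)
    if seasons is not None:
        season_rank = {"winter_spring": 0, "summer": 1, "fall": 2}
        yearday = X.dates.dt.dayofyear
        order = sorted(
            X.sample_ids,
            key=lambda s: (season_rank.get(seasons.loc[s], 99), int(yearday.loc[s])),
        )
        df = df.loc[order, order]
    return df
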