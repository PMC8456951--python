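"""Sequential binary partitions, balances and the ilr transform.

An SBP splits the D parts of a composition into nested binary groups; each
split defines a *balance*, a weighted log ratio of the geometric means of
its two groups.  Stacking the D−1 balancing-element vectors gives the
contrast matrix B, whose rows are an orthonormal basis of clr space; the
isometric log-ratio (ilr) transform is the projection of a composition on
the corresponding simplex basis.  ilr coordinates are real, unbounded, and
distance-preserving, which is what lets standard multivariate statistics
run on relative-abundance data.

The built-in ``mvco_sbp()`` encodes the partition used for the six
dominant MVCO *Synechococcus* oligotypes O1–O6: first split O2 against the
rest, then the spring group {O1, O3, O6} against the fall group {O4, O5},
then O4|O5, {O1, O3}|O6 and O1|O3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .geometry import Composition, CompositionMatrix, VariationMatrix, clr, closure

__all__ = [
    "SBP",
    "ContrastMatrix",
    "mvco_sbp",
    "balancing_element",
    "contrast_matrix",
    "basis_from_contrast",
    "balance_names",
    "ilr",
    "ilr_inverse",
    "sbp_from_variation",
]


@dataclass(frozen=True)
class SBP:
    """A sequential binary partition of D parts as a signed (D−1)×D table.

    Row k carries +1 for parts in the numerator (r) group, −1 for the
    denominator (s) group and 0 for parts not in the partition.  Rows are
    ordered root-first: the support of each row must be a block produced
    by the splits above it.
    """

    signs: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        s = np.asarray(self.signs, dtype=int)
        if not np.all(np.isin(s, (-1, 0, 1))):
            raise ValueError("SBP entries must be -1, 0 or +1")
        D = len(self.labels)
        if s.shape != (D - 1, D):
            raise ValueError(f"SBP must be (D-1)xD = {(D-1, D)}, got {s.shape}")
        blocks = {frozenset(range(D))}
        for k, row in enumerate(s):
            r = frozenset(np.flatnonzero(row > 0))
            sg = frozenset(np.flatnonzero(row < 0))
            if not r or not sg:
                raise ValueError(f"SBP row {k + 1} lacks a +1 or a -1 group")
            support = r | sg
            if support not in blocks:
                raise ValueError(
                    f"SBP row {k + 1} does not split a block produced by earlier rows"
                )
            blocks.remove(support)
            blocks.update(b for b in (r, sg) if len(b) > 1)
        s = s.copy()
        s.flags.writeable = False
        object.__setattr__(self, "signs", s)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))

    @property
    def D(self) -> int:
        return len(self.labels)

    def row_groups(self, k: int) -> tuple[list[str], list[str]]:
        """(r-group labels, s-group labels) of partition k (0-based)."""
        row = self.signs[k]
        lab = np.asarray(self.labels)
        return list(lab[row > 0]), list(lab[row < 0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.signs,
            index=[f"k{k + 1}" for k in range(self.D - 1)],
            columns=list(self.labels),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="partition")

    @classmethod
    def from_tsv(cls, path) -> "SBP":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=int), tuple(df.columns))


def mvco_sbp() -> SBP:
    """The built-in partition for oligotypes O1–O6 (see module docstring)."""
    signs = np.array(
        [
            [1, -1, 1, 1, 1, 1],   # O2 vs the rest
            [1, 0, 1, -1, -1, 1],  # spring group vs fall group
            [0, 0, 0, 1, -1, 0],   # O4 vs O5
            [1, 0, 1, 0, 0, -1],   # {O1,O3} vs O6
            [1, 0, -1, 0, 0, 0],   # O1 vs O3
        ]
    )
    return SBP(signs, ("O1", "O2", "O3", "O4", "O5", "O6"))


def balancing_element(sbp_row: Sequence[int]) -> np.ndarray:
    """Balancing element of one partition row.

    With R parts in the r-group and S in the s-group, r-parts receive
    +sqrt(S / (R (R+S))), s-parts −sqrt(R / (S (R+S))), absent parts 0;
    the vector sums to zero and has unit Euclidean norm.
    """
    row = np.asarray(sbp_row, dtype=int)
    R = int((row > 0).sum())
    S = int((row < 0).sum())
    if R == 0 or S == 0:
        raise ValueError("partition row must have both an r-group and an s-group")
    b = np.zeros(row.size)
    b[row > 0] = np.sqrt(S / (R * (R + S)))
    b[row < 0] = -np.sqrt(R / (S * (R + S)))
    return b


@dataclass(frozen=True)
class ContrastMatrix:
    """(D−1)×D matrix of balancing elements: orthonormal rows summing to 0."""

    B: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=float)
        if np.any(np.abs(B.sum(axis=1)) > 1e-12):
            raise ValueError("contrast-matrix rows must sum to 0")
        if not np.allclose(B @ B.T, np.eye(B.shape[0]), atol=1e-10):
            raise ValueError("contrast-matrix rows must be orthonormal")
        B = B.copy()
        B.flags.writeable = False
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "labels", tuple(self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.B,
            index=[f"b{k + 1}" for k in range(self.B.shape[0])],
            columns=list(self.labels),
        )


def contrast_matrix(sbp: SBP) -> ContrastMatrix:
    """Stack the balancing elements of an SBP into the contrast matrix B."""
    B = np.vstack([balancing_element(row) for row in sbp.signs])
    return ContrastMatrix(B, sbp.labels)


def basis_from_contrast(cm: ContrastMatrix) -> list[Composition]:
    """Orthonormal simplex basis e_k = closure(exp(b_k))."""
    return [Composition(closure(np.exp(b)), cm.labels) for b in cm.B]


def balance_names(sbp: SBP) -> list[str]:
    """Readable coordinate names, e.g. ``O1.O3.O6_vs_O4.O5``."""
    names = []
    for k in range(sbp.D - 1):
        r, s = sbp.row_groups(k)
        names.append(".".join(r) + "_vs_" + ".".join(s))
    return names


def _ilr_rows(V: np.ndarray, sbp: SBP) -> np.ndarray:
    """Direct SBP expression: sqrt(RS/(R+S)) * ln(gmean(r) / gmean(s))."""
    logv = np.log(V)
    out = np.empty((V.shape[0], sbp.D - 1))
    for k, row in enumerate(sbp.signs):
        r = row > 0
        s = row < 0
        R, S = int(r.sum()), int(s.sum())
        coef = np.sqrt(R * S / (R + S))
        out[:, k] = coef * (logv[:, r].mean(axis=1) - logv[:, s].mean(axis=1))
    return out


def ilr(x, sbp: SBP):
    """ilr coordinates of a composition (or matrix of compositions).

    Computed by the direct SBP log-contrast expression; identical to the
    projection ⟨x, e_k⟩_a on the basis compositions and to clr(x) · Bᵀ.
    Returns a (D−1)-vector for a single composition, a DataFrame of shape
    (n, D−1) with named balance columns for a CompositionMatrix, and a
    plain (n, D−1) array for a raw 2-D array.
    """
    if isinstance(x, CompositionMatrix):
        if tuple(x.labels) != sbp.labels:
            raise ValueError("composition labels do not match the SBP labels")
        coords = _ilr_rows(x.values, sbp)
        return pd.DataFrame(coords, index=x.data.index, columns=balance_names(sbp))
    if isinstance(x, Composition):
        if x.labels is not None and x.labels != sbp.labels:
            raise ValueError("composition labels do not match the SBP labels")
        v = x.parts[None, :]
        return _ilr_rows(v, sbp)[0]
    v = np.asarray(x, dtype=float)
    if np.any(v <= 0):
        raise ValueError("zero or negative part: impute first")
    if v.ndim == 1:
        return _ilr_rows(v[None, :], sbp)[0]
    return _ilr_rows(v, sbp)


def ilr_inverse(y, sbp: SBP):
    """Inverse ilr: closure(exp(y · B)).

    A zero coordinate vector maps to the uniform composition; for 2-D
    input the rows are inverted independently and a DataFrame of part
    proportions is returned when the input is a DataFrame.
    """
    B = contrast_matrix(sbp).B
    arr = np.asarray(y, dtype=float)
    if arr.shape[-1] != sbp.D - 1:
        raise ValueError(f"expected {sbp.D - 1} ilr coordinates, got {arr.shape[-1]}")
    comp = closure(np.exp(arr @ B))
    if arr.ndim == 1:
        return Composition(comp, sbp.labels)
    if isinstance(y, pd.DataFrame):
        return pd.DataFrame(comp, index=y.index, columns=list(sbp.labels))
    return comp


def sbp_from_variation(T: VariationMatrix, linkage: str = "ward") -> SBP:
    """Data-driven SBP from hierarchical clustering of the variation matrix.

    Parts whose log ratios are nearly constant (small t_kj) merge first;
    each merge node of the dendrogram, read root-first, becomes one
    partition row.  sqrt(t_kj) is used as the pairwise distance.  The
    r-group of each row is the block containing the lowest part index,
    which makes the output deterministic.

    This is exploratory support for choosing a basis; a curated SBP (such
    as the built-in ``mvco_sbp``) should be preferred for final analyses.
    """
    if linkage not in ("ward", "complete"):
        raise ValueError("linkage must be 'ward' or 'complete'")
    D = T.D
    if D < 2:
        raise ValueError("need at least 2 parts")
    dist = squareform(np.sqrt(T.values.to_numpy()), checks=False)
    Z = _scipy_linkage(dist, method=linkage)
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(D)}
    for m, (a, b, *_rest) in enumerate(Z):
        members[D + m] = members[int(a)] | members[int(b)]
    rows = []
    for m in range(D - 2, -1, -1):  # last merge = root, first row
        a, b = int(Z[m, 0]), int(Z[m, 1])
        ga, gb = members[a], members[b]
        if min(ga) > min(gb):
            ga, gb = gb, ga
        row = np.zeros(D, dtype=int)
        row[list(ga)] = 1
        row[list(gb)] = -1
        rows.append(row)
    return SBP(np.vstack(rows), T.labels)
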