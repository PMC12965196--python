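"""Spatial eigenvectors and (distance-based) RDA variance partitioning.

PCNM/MEM eigenvectors: the pairwise distance matrix is truncated at the
longest minimum-spanning-tree edge (entries beyond it replaced by four
times the threshold), double-centred and eigendecomposed; eigenvectors
with positive eigenvalues describe spatial structure from broad to fine
scales and serve as predictors.

Redundancy analysis (RDA) here is used only through its coefficient of
determination: with a centred multivariate response Y and predictor block
X, R^2 = ||P_X Y||^2_F / ||Y||^2_F and
R^2_adj = 1 - (1 - R^2)(n - 1)/(n - m - 1) (Ezekiel adjustment, m = rank
of X).  Variance partitioning solves the inclusion-exclusion system over
all non-empty subsets of up to four predictor sets for unique and shared
adjusted fractions.  Distance-based RDA replaces Y by the positive-
eigenvalue principal coordinates of a Gower-centred distance matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from landgen.core import PairwiseMatrix

__all__ = [
    "SpatialEigenvectors",
    "pcnm_eigenvectors",
    "rda_adjusted_r2",
    "VarPartResult",
    "varpart",
    "dbrda_varpart",
    "pcoa_coordinates",
    "family_indicators",
]


@dataclass
class SpatialEigenvectors:
    vectors: np.ndarray  # n_samples x k, duplicated rows for co-located samples
    eigenvalues: np.ndarray  # descending, > 0
    truncation: float  # MST-edge threshold used
    ids: list[str]

    @property
    def k(self) -> int:
        return self.vectors.shape[1]


def pcnm_eigenvectors(D: PairwiseMatrix, tol: float = 1e-8) -> SpatialEigenvectors:
    """PCNM spatial eigenvectors from a pairwise geographic distance matrix.

    Samples at duplicate locations (zero mutual distance) are collapsed to
    unique locations first and the resulting eigenvector rows propagated
    back to every sample.  Requires >= 3 unique locations.
    """
    vals = D.values
    n = D.n
    # group samples by zero-distance equivalence (duplicate coordinates)
    rep = np.arange(n)
    for i in range(n):
        if rep[i] != i:
            continue
        dup = np.flatnonzero((vals[i] <= tol) & (np.arange(n) > i))
        rep[dup] = i
    uniq = np.flatnonzero(rep == np.arange(n))
    if uniq.size < 3:
        raise ValueError("need at least 3 unique locations for PCNM")
    Du = vals[np.ix_(uniq, uniq)]

    mst = minimum_spanning_tree(Du)
    t = float(mst.data.max())
    Dt = np.where(Du > t, 4.0 * t, Du)
    np.fill_diagonal(Dt, 0.0)
    A = -0.5 * Dt**2
    J = np.eye(uniq.size) - np.ones((uniq.size, uniq.size)) / uniq.size
    B = J @ A @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > max(tol, tol * abs(eigval[0]))
    eigval, eigvec = eigval[keep], eigvec[:, keep]

    # rep points at a member of uniq for every sample
    back = np.array([np.flatnonzero(uniq == rep[i])[0] for i in range(n)])
    return SpatialEigenvectors(eigvec[back], eigval, t, list(D.ids))


def _prune_collinear(X: np.ndarray, tol: float = 1e-9):
    """Drop collinear columns (after centring) via pivoted QR; warn."""
    Xc = X - X.mean(axis=0)
    if Xc.shape[1] == 0:
        return Xc
    from scipy.linalg import qr

    _, R, piv = qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * max(diag[0], 1e-300)).sum()) if diag.size else 0
    if rank < Xc.shape[1]:
        warnings.warn(
            f"dropping {Xc.shape[1] - rank} collinear predictor column(s)",
            stacklevel=3,
        )
    return Xc[:, np.sort(piv[:rank])]


def rda_adjusted_r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """RDA R^2 and Ezekiel-adjusted R^2 of multivariate Y on block X.

    Y is centred column-wise; X is centred and collinear columns dropped.
    Requires n > m + 1 for the adjustment to be defined.
    """
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean(axis=0)
    total = float((Yc**2).sum())
    if total == 0:
        raise ValueError("response has no variance")
    Xc = _prune_collinear(np.asarray(X, dtype=float))
    n, m = Y.shape[0], Xc.shape[1]
    if m == 0:
        return 0.0, 0.0
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 (n={n}, m={m})")
    Q, _ = np.linalg.qr(Xc)
    fitted = Q @ (Q.T @ Yc)
    r2 = float((fitted**2).sum() / total)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    return r2, r2_adj


@dataclass
class VarPartResult:
    """Inclusion-exclusion decomposition of adjusted R^2 over predictor sets.

    ``subset_r2`` holds (R^2, R^2_adj) for every non-empty union of sets;
    ``fractions`` holds one component per non-empty subset T of set names:
    the variation explained jointly (and only) by the sets in T.  Unique
    fractions are the singleton keys.  Components can be slightly negative
    (adjusted-R^2 property).  Fractions sum to the full-model R^2_adj.
    """

    set_names: list[str]
    subset_r2: dict[frozenset, tuple[float, float]]
    fractions: dict[frozenset, float]
    residual: float
    meta: dict = field(default_factory=dict)

    @property
    def full_r2_adj(self) -> float:
        return self.subset_r2[frozenset(self.set_names)][1]

    def fraction(self, *names) -> float:
        return self.fractions[frozenset(names)]

    def unique(self, name) -> float:
        return self.fractions[frozenset([name])]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": "&".join(sorted(k)), "fraction": v}
            for k, v in self.fractions.items()
        ]
        rows.append({"component": "residual", "fraction": self.residual})
        return pd.DataFrame(rows)


def varpart(Y: np.ndarray, sets: dict[str, np.ndarray]) -> VarPartResult:
    """Variance partitioning of a multivariate response over 2-4 sets.

    ``sets`` maps a set name to its predictor matrix (n x m_k).  All
    2^k - 1 subset unions are fitted with :func:`rda_adjusted_r2`; the
    fraction components are solved from R_adj(S) = sum of components whose
    set combination intersects S.  A set whose matrix has no usable
    columns yields NaN for every fraction that involves it.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("varpart supports 2 to 4 predictor sets")
    n = np.asarray(Y).shape[0]
    mats = {}
    empty = []
    for k, v in sets.items():
        v = np.asarray(v, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.shape[0] != n:
            raise ValueError(f"set {k!r} has {v.shape[0]} rows, expected {n}")
        pruned = _prune_collinear(v)
        if pruned.shape[1] == 0:
            empty.append(k)
        mats[k] = pruned
    active = [k for k in names if k not in empty]
    if empty:
        warnings.warn(f"set(s) with no usable columns: {empty}", stacklevel=2)
    if len(active) < 2:
        raise ValueError("fewer than two non-empty predictor sets")

    subsets = []
    for r in range(1, len(active) + 1):
        subsets.extend(frozenset(c) for c in itertools.combinations(active, r))
    subset_r2 = {}
    for S in subsets:
        X = np.column_stack([mats[k] for k in names if k in S])
        subset_r2[S] = rda_adjusted_r2(Y, X)

    # solve fractions: R_adj(S) = sum over components T with T & S != {}
    comp_keys = subsets
    Amat = np.zeros((len(subsets), len(comp_keys)))
    bvec = np.zeros(len(subsets))
    for i, S in enumerate(subsets):
        bvec[i] = subset_r2[S][1]
        for j, T in enumerate(comp_keys):
            if T & S:
                Amat[i, j] = 1.0
    sol = np.linalg.solve(Amat, bvec)
    fractions = {T: float(v) for T, v in zip(comp_keys, sol)}
    # components involving an empty set are undefined
    for k in empty:
        for r in range(1, len(names) + 1):
            for c in itertools.combinations(names, r):
                if k in c:
                    fractions[frozenset(c)] = float("nan")
    full = subset_r2[frozenset(active)][1]
    return VarPartResult(
        set_names=names,
        subset_r2=subset_r2,
        fractions=fractions,
        residual=float(1.0 - full),
        meta={"n": n, "empty_sets": empty},
    )


def pcoa_coordinates(D: PairwiseMatrix, tol: float = 1e-9):
    """Principal coordinates of a distance matrix (Gower centring).

    Negative eigenvalues are dropped (their total magnitude returned for
    logging); coordinates are U * sqrt(lambda) over positive axes.
    """
    vals = D.values
    if np.ptp(vals) == 0:
        raise ValueError("constant distance matrix has no principal coordinates")
    n = D.n
    A = -0.5 * vals**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(tol, tol * abs(eigval[0]))
    neg_magnitude = float(-eigval[eigval < 0].sum())
    Y = eigvec[:, pos] * np.sqrt(eigval[pos])
    return Y, eigval[pos], neg_magnitude


def dbrda_varpart(
    Dresp: PairwiseMatrix, sets: dict[str, np.ndarray]
) -> VarPartResult:
    """Distance-based RDA variance partitioning.

    The response distance matrix (e.g. the 1/(1+x) IBD transform) is
    converted to principal coordinates; the positive-eigenvalue coordinate
    matrix then plays the role of Y in :func:`varpart`.
    """
    Y, _, neg = pcoa_coordinates(Dresp)
    if neg > 0:
        warnings.warn(
            f"dropped negative PCoA eigenvalues (total magnitude {neg:.3g})",
            stacklevel=2,
        )
    res = varpart(Y, sets)
    res.meta["pcoa_negative_magnitude"] = neg
    return res


def family_indicators(families) -> tuple[np.ndarray, list[str]]:
    """Dummy-code a family label vector, dropping the first level."""
    s = pd.Series(list(families), dtype="object")
    dummies = pd.get_dummies(s, drop_first=True).astype(float)
    return dummies.to_numpy(), list(dummies.columns)
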