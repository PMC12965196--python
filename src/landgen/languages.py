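"""Linguistic grouping of samples and (hierarchical) F-statistics.

Samples are assigned to the geographically closest language point of a
georeferenced catalogue (glottolog-like: language, family, lon, lat).
Population structure over the resulting nested grouping
(family > language > individual > allele) is quantified with
moment-estimated variance components from the unbalanced nested ANOVA on
allele indicators, combined across loci as ratios of summed components
(the multi-locus Weir-Cockerham convention).  Slightly negative component
estimates are kept un-truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from landgen.genotypes import MISSING, GenotypeMatrix
from landgen.geodesy import vincenty_km

__all__ = [
    "LanguageCatalog",
    "assign_language",
    "filter_families",
    "HierFResult",
    "hierarchical_f",
    "fst_wc",
    "nested_varcomp",
]


@dataclass
class LanguageCatalog:
    """Georeferenced language points with family labels."""

    table: pd.DataFrame  # columns: language, family, lon, lat

    def __post_init__(self) -> None:
        req = {"language", "family", "lon", "lat"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"catalog needs columns {sorted(req)}")
        if self.table["language"].duplicated().any():
            raise ValueError("language names must be unique within the catalog")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LanguageCatalog":
        return cls(pd.read_csv(path))


def assign_language(samples: pd.DataFrame, catalog: LanguageCatalog) -> pd.DataFrame:
    """Assign each sample to its geodesically nearest language.

    Returns a frame (id, language, family, distance_km, tie); exact
    distance ties are broken by catalog order and flagged.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    lon_s = samples["lon"].to_numpy(dtype=float)[:, None]
    lat_s = samples["lat"].to_numpy(dtype=float)[:, None]
    lon_l = catalog.table["lon"].to_numpy(dtype=float)[None, :]
    lat_l = catalog.table["lat"].to_numpy(dtype=float)[None, :]
    D = vincenty_km(lon_s, lat_s, lon_l, lat_l)
    D = np.atleast_2d(D)
    best = D.argmin(axis=1)
    dmin = D[np.arange(D.shape[0]), best]
    tie = (np.abs(D - dmin[:, None]) < 1e-9).sum(axis=1) > 1
    return pd.DataFrame(
        {
            "id": samples["id"].astype(str).to_numpy(),
            "language": catalog.table["language"].to_numpy()[best],
            "family": catalog.table["family"].to_numpy()[best],
            "distance_km": dmin,
            "tie": tie,
        }
    )


def filter_families(
    assignment: pd.DataFrame, min_languages: int = 5, strict: bool = True
) -> pd.DataFrame:
    """Keep samples whose family has more than ``min_languages`` distinct
    assigned languages (``strict=False`` relaxes to >=)."""
    counts = assignment.groupby("family")["language"].nunique()
    if strict:
        keep = counts.index[counts > min_languages]
    else:
        keep = counts.index[counts >= min_languages]
    return assignment[assignment["family"].isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Nested allele-level ANOVA


def _group_codes(labels) -> np.ndarray:
    _, codes = np.unique(np.asarray(labels), return_inverse=True)
    return codes


def nested_varcomp(G: GenotypeMatrix, levels: list[np.ndarray]):
    """Variance components of the nested allele ANOVA, per grouping level.

    ``levels`` are label arrays over samples ordered top (coarsest) to
    bottom; an individual level and the within-individual (allele) error
    level are appended automatically.  Returns ``(components, names,
    degenerate)`` where components are summed over loci and degenerate
    levels (no replication: as many groups as parent groups) get NaN.

    Method of moments: per locus, sums of squares between successive
    nesting levels are equated to their expectations under random effects;
    group sizes are allele counts of non-missing individuals, so
    missingness is handled per locus.  Estimates may be negative and are
    not truncated.
    """
    n = G.n_samples
    # enforce nesting by combining labels downward, then add individuals
    combined = []
    running = np.zeros(n, dtype=np.int64)
    for lab in levels:
        codes = _group_codes(lab)
        running = running * (codes.max() + 1) + codes
        running = _group_codes(running)
        combined.append(running.copy())
    combined.append(np.arange(n))  # individual level

    # structural degeneracy: a level with as many groups as its parent has
    # no replication (SS identically zero); drop it from the solved system
    n_groups_all = [1] + [lev.max() + 1 for lev in combined]
    keep_levels = [
        i for i in range(len(combined))
        if n_groups_all[i + 1] > n_groups_all[i]
    ]
    dropped = [i for i in range(len(combined)) if i not in keep_levels]
    combined = [combined[i] for i in keep_levels]
    n_levels = len(combined)  # grouping levels incl. individual
    n_comp = n_levels + 1  # + within-individual (allele) error

    D = np.where(G.dosage != MISSING, G.dosage, 0).astype(np.float64)
    M = (G.dosage != MISSING).astype(np.float64)
    L = G.n_snps

    # per-level per-locus group allele counts and dosage sums
    sizes, sums, aggs = [], [], []
    for lev in combined:
        Gn = lev.max() + 1
        I = np.zeros((Gn, n))
        I[lev, np.arange(n)] = 1.0
        sizes.append(2.0 * (I @ M))  # (Gn, L)
        sums.append(I @ D)
        aggs.append(I)
    N_tot = 2.0 * M.sum(axis=0)  # (L,)
    S_tot = D.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        T = []  # T[i] for i = 0 (overall) .. n_levels, plus observations
        T.append(np.where(N_tot > 0, S_tot**2 / N_tot, 0.0))
        for nz, sm in zip(sizes, sums):
            T.append(np.where(nz > 0, sm**2 / nz, 0.0).sum(axis=0))
        T_obs = D.sum(axis=0)  # sum over alleles of y^2 (y in {0,1})
        T.append(T_obs)

        # K[i][j]: coefficient of sigma2_j in E[T_i], per locus
        # K[i][j] = N for j <= i; for deeper j: sum_g (sum_{h in g} n_h^2)/n_g
        # error component: number of non-empty groups at level i
        def K(i, j):
            if j <= i:
                return N_tot
            if j == n_comp:  # error/allele component
                if i == 0:
                    return np.ones(L)
                return (sizes[i - 1] > 0).sum(axis=0).astype(float)
            nj2 = sizes[j - 1] ** 2  # (G_j, L)
            if i == 0:
                return np.where(N_tot > 0, nj2.sum(axis=0) / N_tot, 0.0)
            # aggregate level-j group sizes^2 up to level-i groups
            up = _ancestor_map(combined[i - 1], combined[j - 1])
            agg = np.zeros_like(sizes[i - 1])
            np.add.at(agg, up, nj2)
            return np.where(sizes[i - 1] > 0, agg / sizes[i - 1], 0.0).sum(axis=0)

        # rows: SS_i = T_i - T_{i-1} for i = 1..n_comp; unknowns sigma2_1..n_comp
        C = np.zeros((L, n_comp, n_comp))
        SS = np.zeros((L, n_comp))
        Kcache = {}
        for i in range(n_comp + 1):
            for j in range(1, n_comp + 1):
                Kcache[(i, j)] = K(i, j) if j > i else N_tot
        Kcache[(n_comp, n_comp)] = N_tot  # observations level: every j <= i
        for i in range(1, n_comp + 1):
            Ti = T[i]
            SS[:, i - 1] = Ti - T[i - 1]
            for j in range(1, n_comp + 1):
                hi = N_tot if j <= i else Kcache[(i, j)]
                lo = N_tot if j <= i - 1 else Kcache[(i - 1, j)]
                C[:, i - 1, j - 1] = hi - lo

    solved = np.einsum("lij,lj->li", np.linalg.pinv(C), SS).sum(axis=0)

    # re-insert NaN at the positions of the dropped degenerate levels;
    # the individual and allele (error) components always exist
    total_levels = len(levels) + 1  # grouping levels incl. individual
    comps = np.full(total_levels + 1, np.nan)
    for out_pos, lev_idx in enumerate(keep_levels):
        comps[lev_idx] = solved[out_pos]
    comps[total_levels] = solved[-1]
    degenerate = np.zeros(total_levels + 1, dtype=bool)
    degenerate[dropped] = True
    names = [f"level_{i}" for i in range(len(levels))] + ["individual", "allele"]
    return comps, names, degenerate


def _ancestor_map(parent_codes: np.ndarray, child_codes: np.ndarray) -> np.ndarray:
    """For each child group, the code of its (unique) parent group."""
    out = np.zeros(child_codes.max() + 1, dtype=np.int64)
    out[child_codes] = parent_codes
    return out


@dataclass
class HierFResult:
    """Hierarchical F-statistics over family > language nesting."""

    comp_family: float
    comp_language: float
    comp_individual: float
    comp_allele: float
    f_family_total: float
    f_language_total: float
    f_language_family: float
    meta: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        parts = [
            self.comp_family,
            self.comp_language,
            self.comp_individual,
            self.comp_allele,
        ]
        return float(np.nansum(parts))


def hierarchical_f(
    G: GenotypeMatrix, assignment: pd.DataFrame
) -> HierFResult:
    """Hierarchical F-statistics for family > language > individual nesting.

    ``assignment`` maps every sample id in ``G`` to (language, family).
    Returns summed variance components and the ratios
    F(family/total) = s2_F / s2_T,
    F(language/total) = (s2_F + s2_L) / s2_T and
    F(language/family) = s2_L / (s2_T - s2_F).
    Degenerate levels (e.g. one language per family) are reported NaN.
    """
    amap = assignment.set_index("id")
    fam = amap.loc[G.sample_ids, "family"].to_numpy()
    lang = amap.loc[G.sample_ids, "language"].to_numpy()
    comps, _, _ = nested_varcomp(G, [fam, lang])
    c_f, c_l, c_i, c_a = comps
    total = np.nansum(comps)
    with np.errstate(invalid="ignore"):
        f_ft = c_f / total if np.isfinite(c_f) else np.nan
        f_lt = (c_f + c_l) / total if np.isfinite(c_l) and np.isfinite(c_f) else np.nan
        f_lf = (
            c_l / (total - c_f)
            if np.isfinite(c_l) and np.isfinite(c_f)
            else np.nan
        )
    return HierFResult(
        comp_family=float(c_f),
        comp_language=float(c_l),
        comp_individual=float(c_i),
        comp_allele=float(c_a),
        f_family_total=float(f_ft),
        f_language_total=float(f_lt),
        f_language_family=float(f_lf),
        meta={"n_samples": G.n_samples, "n_snps": G.n_snps},
    )


def fst_wc(G: GenotypeMatrix, grouping) -> float:
    """Multi-locus Weir-Cockerham theta for one grouping level.

    Ratio of summed variance components (among-group over total) from the
    group > individual > allele ANOVA.  Returns NaN for monomorphic-only
    data.
    """
    grouping = np.asarray(grouping)
    if grouping.shape[0] != G.n_samples:
        raise ValueError("grouping length must match sample count")
    if len(np.unique(grouping)) < 2:
        raise ValueError("need at least two groups")
    comps, _, _ = nested_varcomp(G, [grouping])
    total = np.nansum(comps)
    if total == 0 or not np.isfinite(total):
        warnings.warn("no allelic variance; theta undefined", stacklevel=2)
        return float("nan")
    return float(comps[0] / total)
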