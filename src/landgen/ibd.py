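"""Identity-by-descent segment sharing and its decay over distance.

Segments shared between phased haplotypes (Refined-IBD text output:
sample1, hap1, sample2, hap2, chromosome, start bp, end bp, LOD, cM) are
binned by genetic length (1-3, 3-5, > 5 cM; longer segments = more recent
common ancestry), turned into per-pair mean counts per
haplotype-pair-chromosome unit (4 haplotype pairs x chromosomes), and
regressed on geographic distance with a weighted Poisson model allowing a
region-specific decay rate; a likelihood-ratio test compares against a
common-slope model.  For ordination, sharing x is mapped to the distance
1/(1 + x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from landgen.core import PairwiseMatrix

__all__ = [
    "IBD_COLUMNS",
    "DEFAULT_BIN_EDGES",
    "read_refined_ibd",
    "write_refined_ibd",
    "bin_segments",
    "bin_label",
    "sharing_matrix",
    "PoissonDecayFit",
    "poisson_decay_fit",
    "ibd_to_distance",
]

IBD_COLUMNS = [
    "sample1",
    "hap1",
    "sample2",
    "hap2",
    "chrom",
    "start",
    "end",
    "lod",
    "cm",
]

DEFAULT_BIN_EDGES = (1.0, 3.0, 5.0, np.inf)


def read_refined_ibd(path) -> pd.DataFrame:
    """Parse whitespace-delimited Refined-IBD output (9 columns)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(IBD_COLUMNS):
                raise ValueError(
                    f"{path}: line {ln} has {len(parts)} fields, expected 9"
                )
            try:
                rec = dict(
                    sample1=parts[0],
                    hap1=int(parts[1]),
                    sample2=parts[2],
                    hap2=int(parts[3]),
                    chrom=parts[4],
                    start=int(parts[5]),
                    end=int(parts[6]),
                    lod=float(parts[7]),
                    cm=float(parts[8]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: malformed record at line {ln}: {exc}")
            if rec["end"] <= rec["start"]:
                raise ValueError(
                    f"{path}: line {ln}: segment end <= start"
                )
            if rec["cm"] <= 0:
                raise ValueError(f"{path}: line {ln}: non-positive cM length")
            rows.append(rec)
    return pd.DataFrame(rows, columns=IBD_COLUMNS)


def write_refined_ibd(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", header=False, index=False, columns=IBD_COLUMNS)


def bin_label(edges, k) -> str:
    lo, hi = edges[k], edges[k + 1]
    if np.isinf(hi):
        return f">{lo:g}"
    return f"{lo:g}-{hi:g}"


def bin_segments(
    table: pd.DataFrame, edges=DEFAULT_BIN_EDGES
) -> dict[str, pd.DataFrame]:
    """Split segments into half-open cM length bins [e0,e1), [e1,e2), ...

    Segments shorter than the first edge are discarded; total counts are
    conserved across bins for lengths at or above it.
    """
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly ascending")
    out = {}
    for k in range(len(edges) - 1):
        sel = (table["cm"] >= edges[k]) & (table["cm"] < edges[k + 1])
        out[bin_label(edges, k)] = table[sel].reset_index(drop=True)
    return out


def sharing_matrix(
    table: pd.DataFrame, sample_ids, n_chromosomes: int
) -> PairwiseMatrix:
    """Mean IBD segment count per haplotype-pair-chromosome unit.

    x_ij = (#segments between i and j) / (4 * n_chromosomes): two diploid
    samples have 2 x 2 haplotype pairs, and chromosomes are treated
    separately.  Diagonal is zero by convention.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    ids = [str(s) for s in sample_ids]
    pos = {s: k for k, s in enumerate(ids)}
    n = len(ids)
    counts = np.zeros((n, n))
    for s1, s2 in zip(table["sample1"], table["sample2"]):
        try:
            i, j = pos[str(s1)], pos[str(s2)]
        except KeyError as exc:
            raise ValueError(f"IBD segment names unknown sample {exc}")
        counts[i, j] += 1
        counts[j, i] += 1
    np.fill_diagonal(counts, 0.0)
    return PairwiseMatrix(
        counts / (4.0 * n_chromosomes), ids, "segments per haplotype-pair-chromosome"
    )


@dataclass
class PoissonDecayFit:
    """Weighted Poisson regression of IBD sharing on distance by region."""

    params: pd.Series  # interaction-model coefficients
    aic_interaction: float
    aic_common: float
    lrt_stat: float
    lrt_df: int
    lrt_pvalue: float
    slopes: dict[str, float]  # per-region distance-decay slope (1/km)
    slopes_se: dict[str, float]
    intercepts: dict[str, float]
    n_pairs: int
    meta: dict = field(default_factory=dict)


def poisson_decay_fit(
    sharing: PairwiseMatrix,
    distance: PairwiseMatrix,
    regions,
    weights: str = "region_size",
) -> PoissonDecayFit:
    """Fit log E[x_ij] = a_r + b_r d_ij over within-region pairs.

    ``regions`` maps each sample id to a region label; only pairs whose two
    members share a region enter.  Prior weights are the region's sample
    size (``weights="region_size"``) or 1 (``"none"``).  The mean counts
    are continuous, so the Poisson family is used in the quasi-likelihood
    sense (IRLS accepts a continuous response).  Returns the region-slope
    model, the common-slope model AIC, and their likelihood-ratio test.
    """
    if distance.ids != sharing.ids:
        distance = distance.align_to(sharing.ids)
    reg = pd.Series(regions)
    labels = reg.loc[sharing.ids].to_numpy()
    n = sharing.n
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    region_pair = labels[iu][same]
    x = sharing.values[iu, ju][same]
    d = distance.values[iu, ju][same]
    ok = np.isfinite(x) & np.isfinite(d)
    region_pair, x, d = region_pair[ok], x[ok], d[ok]

    counts = pd.Series(region_pair).value_counts()
    small = counts.index[counts < 3]
    if len(small):
        warnings.warn(
            f"excluding region(s) with <3 within-region pairs: {list(small)}",
            stacklevel=2,
        )
        keep = ~np.isin(region_pair, small)
        region_pair, x, d = region_pair[keep], x[keep], d[keep]
    if len(np.unique(region_pair)) < 1 or x.size < 4:
        raise ValueError("not enough within-region pairs to fit")

    region_sizes = pd.Series(labels).value_counts()
    if weights == "region_size":
        w = region_sizes.loc[region_pair].to_numpy(dtype=float)
    elif weights == "none":
        w = np.ones_like(x)
    elif np.isscalar(weights):
        # e.g. 4 * n_chromosomes: the exact precision of a mean count
        w = float(weights) * np.ones_like(x)
    else:
        raise ValueError("weights must be 'region_size', 'none' or a scalar")

    df = pd.DataFrame({"x": x, "d": d, "region": region_pair})
    dummies = pd.get_dummies(df["region"], prefix="", prefix_sep="").astype(float)
    regions_u = list(dummies.columns)
    # interaction model: region-specific intercept and slope
    X1 = pd.concat(
        [dummies, dummies.mul(df["d"], axis=0).add_suffix(":d")], axis=1
    )
    # common-slope model
    X0 = pd.concat([dummies, df["d"].rename("d")], axis=1)
    fam = sm.families.Poisson()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer counts are intended
        fit1 = sm.GLM(df["x"], X1, family=fam, var_weights=w).fit()
        fit0 = sm.GLM(df["x"], X0, family=fam, var_weights=w).fit()
    lrt = 2.0 * (fit1.llf - fit0.llf)
    dfree = len(regions_u) - 1
    from scipy.stats import chi2

    pval = float(chi2.sf(lrt, dfree)) if dfree > 0 else float("nan")
    slopes = {r: float(fit1.params[f"{r}:d"]) for r in regions_u}
    slopes_se = {r: float(fit1.bse[f"{r}:d"]) for r in regions_u}
    intercepts = {r: float(fit1.params[r]) for r in regions_u}
    return PoissonDecayFit(
        params=fit1.params,
        aic_interaction=float(fit1.aic),
        aic_common=float(fit0.aic),
        lrt_stat=float(lrt),
        lrt_df=dfree,
        lrt_pvalue=pval,
        slopes=slopes,
        slopes_se=slopes_se,
        intercepts=intercepts,
        n_pairs=int(x.size),
        meta={"weights": weights, "regions": regions_u},
    )


def ibd_to_distance(sharing: PairwiseMatrix) -> PairwiseMatrix:
    """Map sharing x >= 0 to the genetic distance 1/(1 + x).

    This is the sqrt((1/(1+x))^2) skew-reducing transformation; it sends
    [0, inf) monotonically onto (0, 1].  The diagonal is set to 0
    (self-distance).
    """
    x = sharing.values
    off = ~np.eye(sharing.n, dtype=bool)
    if (x[off] < 0).any():
        raise ValueError("sharing values must be non-negative")
    vals = 1.0 / (1.0 + x)
    np.fill_diagonal(vals, 0.0)
    return PairwiseMatrix(vals, sharing.ids, "ibd distance")
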