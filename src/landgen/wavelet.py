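"""Scale-specific wavelet dissimilarity of genotypes across a landscape.

For each focal location a and spatial scale s (km), a band-pass kernel
over sample locations is built as the difference of two distance-weighted
Gaussians with bandwidths s and 2s (Ricker-like, zero-sum after each is
normalised to unit mass).  The wavelet coefficient of locus l is the
kernel-weighted sum of centred dosages; the dissimilarity at (a, s) is
the Euclidean norm of coefficients across loci divided by the kernel's
root-sum-of-squares.  Large values mean strong genetic turnover at that
scale around that location.  Significance comes from permuting the
sample-to-location mapping (a panmixia null): the global curve is
compared with an empirical envelope, and each location can be flagged
low / non-significant / high against its local permutation distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from landgen.genotypes import MISSING, GenotypeMatrix
from landgen.geodesy import pairwise_distance_km

__all__ = [
    "WaveletResult",
    "wavelet_dissimilarity",
    "permutation_null",
    "local_significance_map",
]


@dataclass
class WaveletResult:
    scales_km: np.ndarray
    ids: list[str]
    local: np.ndarray  # n_locations x n_scales observed dissimilarity
    global_curve: np.ndarray  # mean over focal locations, per scale
    null_lo: np.ndarray | None = None  # 2.5% envelope per scale
    null_hi: np.ndarray | None = None  # 97.5%
    null_global: np.ndarray | None = None  # n_perm x n_scales
    null_local: np.ndarray | None = None  # n_perm x n_locations x n_scales
    meta: dict = field(default_factory=dict)


def _centred_dosage(G: GenotypeMatrix) -> np.ndarray:
    """Mean-impute missing dosages per locus, then centre per locus."""
    d = G.dosage.astype(float)
    miss = G.dosage == MISSING
    with np.errstate(invalid="ignore"):
        mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(miss, 0, d).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
            0.0,
        )
    d = np.where(miss, mean[None, :], d)
    return d - d.mean(axis=0)


def _kernels(Dkm: np.ndarray, scale: float) -> np.ndarray:
    """Difference-of-Gaussians kernel rows (one per focal location)."""
    g1 = np.exp(-(Dkm**2) / (2.0 * scale**2))
    g2 = np.exp(-(Dkm**2) / (2.0 * (2.0 * scale) ** 2))
    g1 = g1 / g1.sum(axis=1, keepdims=True)
    g2 = g2 / g2.sum(axis=1, keepdims=True)
    return g1 - g2  # zero row-sum by construction


def _dissimilarity(K: np.ndarray, Xc: np.ndarray) -> np.ndarray:
    coeff = K @ Xc
    norm = np.sqrt((K**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(
            norm > 0, np.sqrt((coeff**2).sum(axis=1)) / norm, 0.0
        )


def wavelet_dissimilarity(
    G: GenotypeMatrix, samples, scales_km
) -> WaveletResult:
    """Observed wavelet dissimilarity at every sample location and scale.

    ``samples`` is a frame with id/lon/lat matching ``G.sample_ids``;
    focal locations are the sample locations themselves.  Scales larger
    than the domain extent return NaN with a warning.
    """
    scales_km = np.asarray(scales_km, dtype=float)
    if (scales_km <= 0).any():
        raise ValueError("scales must be positive")
    if G.n_samples < 10:
        raise ValueError("need at least 10 samples")
    samples = samples.set_index(samples["id"].astype(str)).loc[G.sample_ids]
    Dkm = pairwise_distance_km(
        samples["lon"].to_numpy(dtype=float), samples["lat"].to_numpy(dtype=float)
    )
    extent = float(Dkm.max())
    Xc = _centred_dosage(G)
    n = G.n_samples
    local = np.full((n, scales_km.size), np.nan)
    for k, s in enumerate(scales_km):
        if s > extent:
            warnings.warn(
                f"scale {s} km exceeds the domain extent ({extent:.0f} km); NaN",
                stacklevel=2,
            )
            continue
        local[:, k] = _dissimilarity(_kernels(Dkm, s), Xc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN scale columns
        global_curve = np.nanmean(local, axis=0)
    return WaveletResult(
        scales_km=scales_km,
        ids=list(G.sample_ids),
        local=local,
        global_curve=global_curve,
        meta={"extent_km": extent, "distance_matrix": Dkm},
    )


def permutation_null(
    G: GenotypeMatrix,
    samples,
    scales_km,
    n_perm: int = 199,
    rng=None,
) -> WaveletResult:
    """Observed dissimilarity plus a panmixia permutation envelope.

    Each permutation shuffles the sample-to-location mapping (equivalent
    to permuting kernel columns) and recomputes every local and global
    curve.  The envelope is the empirical 2.5%/97.5% quantile of the
    global curve per scale; with n_perm = 19 these are the min/max.
    """
    if n_perm < 19:
        raise ValueError("need at least 19 permutations")
    rng = np.random.default_rng(rng)
    res = wavelet_dissimilarity(G, samples, scales_km)
    Dkm = res.meta["distance_matrix"]
    Xc = _centred_dosage(G)
    n = G.n_samples
    scales_km = res.scales_km
    null_local = np.full((n_perm, n, scales_km.size), np.nan)
    extent = res.meta["extent_km"]
    kernels = [
        _kernels(Dkm, s) if s <= extent else None for s in scales_km
    ]
    for p in range(n_perm):
        perm = rng.permutation(n)
        Xp = Xc[perm]
        for k, K in enumerate(kernels):
            if K is None:
                continue
            null_local[p, :, k] = _dissimilarity(K, Xp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN scale columns
        null_global = np.nanmean(null_local, axis=1)
        # conservative order statistics: with 19 draws these are min/max
        res.null_lo = np.nanquantile(null_global, 0.025, axis=0, method="lower")
        res.null_hi = np.nanquantile(null_global, 0.975, axis=0, method="higher")
    res.null_local = null_local
    res.null_global = null_global
    res.meta["n_perm"] = n_perm
    return res


def local_significance_map(
    result: WaveletResult, scale_km: float, alpha: float = 0.05
) -> np.ndarray:
    """Per-location flags at one scale: -1 low, 0 ns, +1 high.

    Each location's observed dissimilarity is compared with its own
    permutation distribution at two-sided level ``alpha``.  Deterministic
    given the stored permutation draws.
    """
    if result.null_local is None:
        raise ValueError("run permutation_null first")
    k = int(np.argmin(np.abs(result.scales_km - scale_km)))
    if not np.isclose(result.scales_km[k], scale_km):
        raise ValueError(f"scale {scale_km} km was not evaluated")
    obs = result.local[:, k]
    null = result.null_local[:, :, k]  # n_perm x n_locations
    lo = np.nanquantile(null, alpha / 2, axis=0, method="lower")
    hi = np.nanquantile(null, 1 - alpha / 2, axis=0, method="higher")
    flags = np.zeros(obs.size, dtype=int)
    flags[obs < lo] = -1
    flags[obs > hi] = 1
    return flags
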