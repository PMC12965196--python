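"""Comparing predictors of pairwise genetic distance.

The workhorse is the MLPE mixed model (maximum-likelihood population
effects): for the distance between samples i and j,

    y_ij = b0 + b1 x_ij + a_i + a_j + e_ij,   a ~ N(0, s2_a), e ~ N(0, s2_e)

where the per-individual random effect a_i absorbs the non-independence of
the n(n-1)/2 pairs each sample participates in.  Models for different
predictors (geographic km vs travel hours) are compared by ML-based AIC.
A Spearman Mantel permutation test and a descriptive OLS R-squared over
pairs round out the module.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, sparse, stats

from landgen.core import PairwiseMatrix

__all__ = ["MLPEFit", "fit_mlpe", "compare_aic", "mantel_test", "linear_r2"]


@dataclass
class MLPEFit:
    intercept: float
    slope: float
    slope_se: float
    sigma2_a: float
    sigma2_a_se: float
    sigma2_e: float
    loglik: float
    aic: float
    n_pairs: int
    n_individuals: int
    boundary_sigma_a: bool
    pair_key: tuple  # identifies (response values, retained pairs) for AIC comparability
    predictor: str = ""


def _pair_design(y: PairwiseMatrix, x: PairwiseMatrix):
    if y.ids != x.ids:
        x = x.align_to(y.ids)
    n = y.n
    iu, ju = np.triu_indices(n, k=1)
    yv = y.values[iu, ju]
    xv = x.values[iu, ju]
    ok = np.isfinite(yv) & np.isfinite(xv)
    dropped = int((~ok).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} non-finite pair(s)", stacklevel=3)
    return yv[ok], xv[ok], iu[ok], ju[ok], n


def _mlpe_loglik(theta, yv, X, Z, ZtZ):
    """Profile log-likelihood of (log s2_a, log s2_e); beta profiled out.

    Uses the Woodbury identity: V = s2_e I + s2_a Z Z', so solves involve
    only the n x n matrix  A = (s2_e / s2_a) I + Z'Z.
    """
    s2a, s2e = np.exp(theta)
    m = yv.size
    A = (s2e / s2a) * np.eye(ZtZ.shape[0]) + ZtZ
    cA, low = None, None
    try:
        cA = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        return np.inf, None
    # V^{-1} u = (u - Z A^{-1} Z'u) / s2e
    def vinv(u):
        Ztu = Z.T @ u
        sol = np.linalg.solve(A, Ztu)
        return (u - Z @ sol) / s2e

    Xv = vinv(X)
    XtVX = X.T @ Xv
    XtVy = Xv.T @ yv
    beta = np.linalg.solve(XtVX, XtVy)
    resid = yv - X @ beta
    quad = resid @ vinv(resid)
    # log|V| = m log s2_e + log|A| + n log(s2_a / s2_e) ... from det lemma:
    # |V| = s2_e^m |I + (s2a/s2e) Z'Z| = s2_e^m |A| (s2a/s2e)^n
    nre = ZtZ.shape[0]
    logdetV = (
        m * np.log(s2e)
        + 2 * np.sum(np.log(np.diag(cA)))
        + nre * (np.log(s2a) - np.log(s2e))
    )
    ll = -0.5 * (m * np.log(2 * np.pi) + logdetV + quad)
    return -ll, (beta, XtVX)


def fit_mlpe(
    y: PairwiseMatrix, x: PairwiseMatrix, predictor_name: str = ""
) -> MLPEFit:
    """Fit the MLPE mixed model by maximum likelihood.

    Non-finite pairs (e.g. unreachable travel times) are dropped pairwise.
    Variance components are optimised on the log scale; a s2_a estimate
    collapsing to ~0 is flagged (``boundary_sigma_a``) but kept.
    """
    yv, xv, iu, ju, n = _pair_design(y, x)
    m = yv.size
    if m < 3:
        raise ValueError("need at least 3 usable pairs")
    X = np.column_stack([np.ones(m), xv])
    rows = np.repeat(np.arange(m), 2)
    cols = np.concatenate([np.stack([iu, ju], axis=1).ravel()])
    Z = sparse.coo_matrix((np.ones(2 * m), (rows, cols)), shape=(m, n)).toarray()
    used = Z.sum(axis=0) > 0
    Z = Z[:, used]
    ZtZ = Z.T @ Z

    var_y = max(yv.var(), 1e-12)
    best = None
    for frac in (0.5, 0.1):
        start = np.log([max(var_y * frac, 1e-10), max(var_y * (1 - frac), 1e-10)])
        res = optimize.minimize(
            lambda th: _mlpe_loglik(th, yv, X, Z, ZtZ)[0],
            start,
            method="Nelder-Mead",
            options=dict(xatol=1e-8, fatol=1e-10, maxiter=2000),
        )
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(f"MLPE likelihood did not converge: {best}")
    nll, aux = _mlpe_loglik(best.x, yv, X, Z, ZtZ)
    beta, XtVX = aux
    s2a, s2e = np.exp(best.x)
    cov_beta = np.linalg.inv(XtVX)
    ll = -nll
    k = 4  # intercept, slope, s2_a, s2_e
    boundary = s2a < 1e-8 * (s2a + s2e)
    if boundary:
        warnings.warn("sigma2_a estimate is on the zero boundary", stacklevel=2)
    # delta-method SE of s2_a from the numerical Hessian of the profile
    # negative log-likelihood in (log s2_a, log s2_e)
    s2a_se = float("nan")
    if not boundary:
        h = 1e-4
        H = np.zeros((2, 2))
        f0 = best.fun

        def f(th):
            return _mlpe_loglik(th, yv, X, Z, ZtZ)[0]

        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h
                ej = np.eye(2)[j] * h
                if i == j:
                    H[i, i] = (f(best.x + ei) - 2 * f0 + f(best.x - ei)) / h**2
                else:
                    H[i, j] = H[j, i] = (
                        f(best.x + ei + ej)
                        - f(best.x + ei - ej)
                        - f(best.x - ei + ej)
                        + f(best.x - ei - ej)
                    ) / (4 * h**2)
        try:
            var_log = np.linalg.inv(H)[0, 0]
            if var_log > 0:
                s2a_se = float(s2a * np.sqrt(var_log))
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
    key = (
        int(m),
        round(float(yv.sum()), 10),
        round(float((yv**2).sum()), 10),
        tuple(iu[:20]),
        tuple(ju[:20]),
    )
    return MLPEFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        slope_se=float(np.sqrt(cov_beta[1, 1])),
        sigma2_a=float(s2a),
        sigma2_a_se=s2a_se,
        sigma2_e=float(s2e),
        loglik=float(ll),
        aic=float(2 * k - 2 * ll),
        n_pairs=m,
        n_individuals=n,
        boundary_sigma_a=bool(boundary),
        pair_key=key,
        predictor=predictor_name,
    )


def compare_aic(fits: list[MLPEFit]):
    """Rank MLPE fits of the *same response/pairs* by AIC (ascending).

    Returns a list of (fit, delta_aic); raises if the fits were computed on
    different responses or pair subsets (their AICs are not comparable).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    keys = {f.pair_key for f in fits}
    if len(keys) != 1:
        raise ValueError(
            "fits use different responses or retained pair sets; AIC not comparable"
        )
    ranked = sorted(fits, key=lambda f: f.aic)
    return [(f, f.aic - ranked[0].aic) for f in ranked]


def mantel_test(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    n_perm: int = 9999,
    method: str = "spearman",
    alternative: str = "greater",
    exhaustive: bool = False,
    rng=None,
):
    """Mantel permutation test of association between two distance matrices.

    The statistic is the Spearman (or Pearson) correlation of the two
    condensed upper triangles; the null is generated by jointly permuting
    rows and columns of B.  p = (#{r_perm >= r_obs} + 1) / (n_perm + 1)
    for the one-sided "greater" alternative, giving the 1/(n_perm+1)
    p-value floor.  ``exhaustive=True`` enumerates all n! permutations
    (small n only).
    """
    if B.ids != A.ids:
        B = B.align_to(A.ids)
    n = A.n
    iu = np.triu_indices(n, k=1)
    av = A.values[iu]
    bv = B.values[iu]
    if not (np.isfinite(av).all() and np.isfinite(bv).all()):
        raise ValueError("Mantel test requires finite matrices")
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("Mantel statistic undefined for a constant matrix")
    if method == "spearman":
        ra = stats.rankdata(av)
    elif method == "pearson":
        ra = av.astype(float)
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    ra = (ra - ra.mean()) / ra.std()

    def corr(bmat):
        v = bmat[iu]
        rv = stats.rankdata(v) if method == "spearman" else v.astype(float)
        rv = (rv - rv.mean()) / rv.std()
        return float(ra @ rv / ra.size)

    r_obs = corr(B.values)
    if exhaustive:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        r_null = np.array([corr(B.values[np.ix_(p, p)]) for p in perms])
        n_perm = len(perms) - 1  # identity included below via >= on full set
        count = _tail_count(r_null, r_obs, alternative)
        p = count / len(perms)
    else:
        rng = np.random.default_rng(rng)
        r_null = np.empty(n_perm)
        for k in range(n_perm):
            p_idx = rng.permutation(n)
            r_null[k] = corr(B.values[np.ix_(p_idx, p_idx)])
        count = _tail_count(r_null, r_obs, alternative)
        p = (count + 1) / (n_perm + 1)
    return r_obs, float(p)


def _tail_count(r_null, r_obs, alternative):
    tol = 1e-12
    if alternative == "greater":
        return int((r_null >= r_obs - tol).sum())
    if alternative == "less":
        return int((r_null <= r_obs + tol).sum())
    if alternative == "two-sided":
        return int((np.abs(r_null) >= abs(r_obs) - tol).sum())
    raise ValueError(f"unknown alternative: {alternative}")


def linear_r2(y: PairwiseMatrix, x: PairwiseMatrix):
    """Descriptive OLS R-squared of y on x over all finite pairs.

    Pairs are not independent, so this is a descriptive summary (the
    metadata notes this), matching scatterplot-style fits.
    """
    yv, xv, *_ = _pair_design(y, x)
    if yv.size < 3:
        raise ValueError("need at least 3 finite pairs for OLS")
    res = stats.linregress(xv, yv)
    return {
        "r2": float(res.rvalue**2),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "n_pairs": int(yv.size),
        "note": "pairs are non-independent; descriptive only",
    }
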