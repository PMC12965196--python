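"""Geodesic distances on the WGS-84 ellipsoid.

Vincenty's inverse formula, vectorised over arrays of point pairs.  The
rare antipodal pairs where Vincenty's iteration fails to converge fall
back to the great-circle distance on a sphere of authalic radius and are
flagged via a warning.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["vincenty_km", "pairwise_distance_km"]

_WGS84_A = 6378137.0  # semi-major axis, m
_WGS84_F = 1.0 / 298.257223563  # flattening
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)
_AUTHALIC_R = 6371007.2  # m, for the non-convergent fallback


def vincenty_km(lon1, lat1, lon2, lat2, max_iter: int = 200, tol: float = 1e-12):
    """Vincenty inverse geodesic distance in km (vectorised, broadcasting).

    Coordinates in decimal degrees.  Coincident points return 0.  Pairs for
    which the lambda-iteration does not converge (nearly antipodal points)
    use a spherical great-circle fallback and trigger a single warning.
    """
    lon1, lat1, lon2, lat2 = np.broadcast_arrays(
        *[np.asarray(x, dtype=float) for x in (lon1, lat1, lon2, lat2)]
    )
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1 - _WGS84_F) * np.tan(phi1))
    U2 = np.arctan((1 - _WGS84_F) * np.tan(phi2))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    active = np.ones(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.zeros_like(lam)
    for _ in range(max_iter):
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        t1 = cosU2 * sin_lam
        t2 = cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        sin_sigma_new = np.hypot(t1, t2)
        cos_sigma_new = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma_new = np.arctan2(sin_sigma_new, cos_sigma_new)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(
                sin_sigma_new > 0, cosU1 * cosU2 * sin_lam / sin_sigma_new, 0.0
            )
        cos_sq_alpha_new = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            cos2sm_new = np.where(
                cos_sq_alpha_new > 0,
                cos_sigma_new - 2 * sinU1 * sinU2 / np.where(
                    cos_sq_alpha_new > 0, cos_sq_alpha_new, 1.0
                ),
                0.0,  # equatorial line
            )
        C = _WGS84_F / 16 * cos_sq_alpha_new * (
            4 + _WGS84_F * (4 - 3 * cos_sq_alpha_new)
        )
        lam_new = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma_new
            + C * sin_sigma_new * (cos2sm_new + C * cos_sigma_new * (-1 + 2 * cos2sm_new**2))
        )
        upd = active
        sin_sigma = np.where(upd, sin_sigma_new, sin_sigma)
        cos_sigma = np.where(upd, cos_sigma_new, cos_sigma)
        sigma = np.where(upd, sigma_new, sigma)
        cos_sq_alpha = np.where(upd, cos_sq_alpha_new, cos_sq_alpha)
        cos2sm = np.where(upd, cos2sm_new, cos2sm)
        converged = np.abs(lam_new - lam) < tol
        lam = np.where(upd, lam_new, lam)
        active = active & ~converged
        if not active.any():
            break

    u_sq = cos_sq_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1 + u_sq / 16384 * (4096 + u_sq * (-768 + u_sq * (320 - 175 * u_sq)))
    B = u_sq / 1024 * (256 + u_sq * (-128 + u_sq * (74 - 47 * u_sq)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos2sm
            + B
            / 4
            * (
                cos_sigma * (-1 + 2 * cos2sm**2)
                - B
                / 6
                * cos2sm
                * (-3 + 4 * sin_sigma**2)
                * (-3 + 4 * cos2sm**2)
            )
        )
    )
    dist = _WGS84_B * A * (sigma - delta_sigma) / 1000.0

    coincident = (lon1 == lon2) & (lat1 == lat2)
    dist = np.where(coincident, 0.0, dist)
    failed = active & ~coincident
    if failed.any():
        warnings.warn(
            f"Vincenty failed to converge for {int(failed.sum())} "
            "near-antipodal pair(s); using great-circle fallback",
            stacklevel=2,
        )
        gc = _great_circle_km(lon1, lat1, lon2, lat2)
        dist = np.where(failed, gc, dist)
    return dist if dist.shape else float(dist)


def _great_circle_km(lon1, lat1, lon2, lat2):
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return 2 * _AUTHALIC_R * np.arcsin(np.sqrt(np.clip(a, 0, 1))) / 1000.0


def pairwise_distance_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Full symmetric matrix of Vincenty distances for n points, in km."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = lon.size
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vincenty_km(lon[iu[0]], lat[iu[0]], lon[iu[1]], lat[iu[1]])
    out += out.T
    return out
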