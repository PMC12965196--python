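"""Synthetic landscape-genomic datasets with known, recoverable structure.

Generates every input the analysis pipeline consumes — a smooth elevation
raster with a contiguous sea, a clustered language catalogue, climate
fields, georeferenced samples with a biallelic SNP matrix, and an IBD
segment table — so each downstream stage can be tested end to end with no
download and full determinism under a fixed seed.

The genotype model: per locus, the alternate-allele frequency follows a
latent Gaussian field on the logit scale with exponential spatial
covariance exp(-d / migration_scale) (isolation by distance); a fraction
``language_effect`` of loci add family-specific frequency shifts and a
fraction ``climate_effect`` add clines along one climate variable.
Genotypes are drawn with inbreeding calibrated so the expected
heterozygote fraction is ``het_rate`` (high-selfing crop), then thinned
by ``missing_rate``.  IBD segments are simulated directly at the segment
level: per haplotype pair, chromosome and length bin, counts are Poisson
with log-mean log(rate_bin) - distance / decay_km_bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, label
from scipy.special import expit, logit

from landgen.genotypes import (
    MOISTURE_VARS,
    TEMPERATURE_VARS,
    GenotypeMatrix,
    write_ped,
    write_vcf,
)
from landgen.geodesy import pairwise_distance_km
from landgen.grid import LandscapeGrid
from landgen.ibd import IBD_COLUMNS, write_refined_ibd
from landgen.languages import LanguageCatalog, assign_language

__all__ = [
    "SimParams",
    "SimulatedData",
    "generate_landscape",
    "generate_language_catalog",
    "generate_climate",
    "generate_samples_genotypes",
    "generate_genetic_map",
    "generate_ibd_segments",
    "simulate_dataset",
    "write_dataset",
]

CLIMATE_VARS = TEMPERATURE_VARS + MOISTURE_VARS


@dataclass
class SimParams:
    """Knobs of the generator; defaults emulate the study's structure at
    desk scale (a few hundred samples on a few-thousand-km domain)."""

    n_samples: int = 150
    n_snps: int = 800
    n_regions: int = 4
    n_families: int = 6
    languages_per_family: int = 8
    migration_scale: float = 500.0  # km; distance-decay of freq correlation
    spatial_sigma: float = 1.5  # sd of the latent logit field
    language_effect: float = 0.15  # fraction of loci with family shifts
    language_sigma: float = 0.8  # sd of family shifts on the logit scale
    climate_effect: float = 0.10  # fraction of loci with climate clines
    climate_beta: float = 0.8  # logit slope per sd of climate
    het_rate: float = 0.05  # expected heterozygote fraction (selfing crop)
    missing_rate: float = 0.02
    # expected IBD segments per haplotype pair per chromosome at distance 0
    ibd_rate_per_bin: dict = field(
        default_factory=lambda: {"1-3": 0.05, "3-5": 0.02, ">5": 0.01}
    )
    # e-folding distance of the decay, km (recent bins decay faster)
    ibd_decay_km: dict = field(
        default_factory=lambda: {"1-3": 1500.0, "3-5": 900.0, ">5": 600.0}
    )
    n_chromosomes: int = 10
    chrom_length_cm: float = 100.0
    # landscape
    n_rows: int = 30
    n_cols: int = 40
    cell_size: float = 1.0  # degrees
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    sea_fraction: float = 0.2
    smooth_cells: float = 5.0  # elevation autocorrelation length, cells
    max_elevation: float = 2500.0  # metres
    language_cluster_sd: float = 2.0  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("language_effect", "climate_effect", "het_rate",
                     "missing_rate", "sea_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.migration_scale <= 0:
            raise ValueError("migration_scale must be positive")
        if any(v <= 0 for v in self.ibd_decay_km.values()):
            raise ValueError("ibd_decay_km values must be positive")
        if self.n_rows * self.n_cols < 4:
            raise ValueError("grid must have at least 4 cells")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")


def _rng(params: SimParams, rng, salt: int):
    """Independent deterministic stream per generator stage."""
    if rng is not None:
        return rng
    return np.random.default_rng(np.random.SeedSequence([params.seed, salt]))


def generate_landscape(params: SimParams, rng=None) -> LandscapeGrid:
    """Smooth (spatially autocorrelated) elevation with a contiguous sea.

    White noise is Gaussian-filtered at ``smooth_cells``; the lowest
    ``sea_fraction`` of the field seeds the sea, of which the largest
    connected component is kept (guaranteeing contiguity)."""
    rng = _rng(params, rng, 1)
    noise = rng.standard_normal((params.n_rows, params.n_cols))
    smooth = gaussian_filter(noise, sigma=params.smooth_cells, mode="reflect")
    smooth = (smooth - smooth.min()) / max(np.ptp(smooth), 1e-12)
    if params.sea_fraction > 0:
        thr = np.quantile(smooth, params.sea_fraction)
        low = smooth <= thr
        lab, nlab = label(low)
        if nlab > 0:
            sizes = np.bincount(lab.ravel())[1:]
            sea = lab == (np.argmax(sizes) + 1)
        else:  # pragma: no cover
            sea = low
    else:
        sea = np.zeros_like(smooth, dtype=bool)
    elev = smooth * params.max_elevation
    elev[sea] = 0.0
    return LandscapeGrid(
        elevation=elev,
        sea_mask=sea,
        xllcorner=params.origin_lon,
        yllcorner=params.origin_lat,
        cell_size=params.cell_size,
    )


def generate_language_catalog(
    grid: LandscapeGrid, params: SimParams, rng=None
) -> LanguageCatalog:
    """Languages placed as one spatial cluster per family.

    Family centres are spread over land by greedy max-min selection, so
    language (and family) identity is spatially autocorrelated; each
    language gets a unique name."""
    if params.n_families < 1:
        raise ValueError("need at least one family")
    rng = _rng(params, rng, 2)
    land = np.argwhere(~grid.sea_mask)
    cand = land[rng.choice(len(land), size=min(len(land), 200), replace=False)]
    lon_c, lat_c = grid.cell_center(cand[:, 0], cand[:, 1])
    pts = np.column_stack([lon_c, lat_c])
    chosen = [int(rng.integers(len(pts)))]
    while len(chosen) < params.n_families:
        d = np.min(
            np.linalg.norm(pts[:, None, :] - pts[chosen][None, :, :], axis=2),
            axis=1,
        )
        chosen.append(int(np.argmax(d)))
    centres = pts[chosen]
    rows = []
    for f, (clon, clat) in enumerate(centres):
        for k in range(params.languages_per_family):
            rows.append(
                dict(
                    language=f"fam{f}_lang{k}",
                    family=f"family{f}",
                    lon=float(clon + rng.normal(0, params.language_cluster_sd)),
                    lat=float(clat + rng.normal(0, params.language_cluster_sd)),
                )
            )
    return LanguageCatalog(pd.DataFrame(rows))


def generate_climate(grid: LandscapeGrid, params: SimParams, rng=None):
    """Per-cell climate fields for the eight temperature/moisture variables.

    Temperature variables follow latitude and elevation lapse plus smooth
    noise; precipitation variables are smooth non-negative fields, with
    precipitation of the driest month strongly right-skewed (zeros occur,
    as in arid sites)."""
    rng = _rng(params, rng, 3)
    nr, nc = grid.n_rows, grid.n_cols
    lat = grid.cell_center(
        np.arange(nr)[:, None].repeat(nc, 1), np.arange(nc)[None, :].repeat(nr, 0)
    )[1]

    def smooth_field(scale=1.0):
        return scale * gaussian_filter(
            rng.standard_normal((nr, nc)), sigma=4.0, mode="reflect"
        ) / 0.1  # rescale filtered-noise sd to O(scale)

    elev_km = grid.elevation / 1000.0
    fields = {
        "temperature_seasonality": 200.0 + 30.0 * np.abs(lat) + smooth_field(2.0),
        "max_temp_warmest_month": 38.0 - 0.3 * np.abs(lat) - 6.0 * elev_km
        + smooth_field(0.4),
        "min_temp_coldest_month": 18.0 - 0.5 * np.abs(lat) - 6.5 * elev_km
        + smooth_field(0.4),
        "mean_temp_driest_quarter": 28.0 - 0.35 * np.abs(lat) - 6.0 * elev_km
        + smooth_field(0.4),
        "annual_precip": np.maximum(
            900.0 - 20.0 * np.abs(lat) + smooth_field(60.0), 0.0
        ),
        "precip_driest_month": np.maximum(smooth_field(8.0) - 4.0, 0.0),
        "precip_seasonality": np.maximum(70.0 + smooth_field(6.0), 1.0),
        "precip_warmest_quarter": np.maximum(
            300.0 - 5.0 * np.abs(lat) + smooth_field(30.0), 0.0
        ),
    }
    return fields


def generate_samples_genotypes(
    grid: LandscapeGrid,
    catalog: LanguageCatalog,
    climate: dict[str, np.ndarray],
    params: SimParams,
    rng=None,
):
    """Place samples on land and draw their genotypes.

    Returns (samples frame, GenotypeMatrix).  The frame carries id, lon,
    lat, region (longitude-quantile blocks), continent, the assigned
    language/family used in generation, and the eight climate variables
    read off the cell fields."""
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    rng = _rng(params, rng, 4)
    land = np.argwhere(~grid.sea_mask)
    if params.n_samples > len(land):
        raise ValueError(
            f"{params.n_samples} samples but only {len(land)} land cells"
        )
    pick = land[rng.choice(len(land), size=params.n_samples, replace=False)]
    lon_c, lat_c = grid.cell_center(pick[:, 0], pick[:, 1])
    jitter = (rng.random((2, params.n_samples)) - 0.5) * grid.cell_size * 0.9
    lon = lon_c + jitter[0]
    lat = lat_c + jitter[1]
    ids = [f"s{i:04d}" for i in range(params.n_samples)]

    samples = pd.DataFrame({"id": ids, "lon": lon, "lat": lat})
    # regions: longitude-quantile blocks (contiguous east-west strata)
    qs = np.quantile(lon, np.linspace(0, 1, params.n_regions + 1)[1:-1])
    samples["region"] = [f"region{k}" for k in np.searchsorted(qs, lon)]
    samples["continent"] = "A"
    for var in CLIMATE_VARS:
        samples[var] = climate[var][pick[:, 0], pick[:, 1]]

    assign = assign_language(samples, catalog)
    samples["language"] = assign["language"].to_numpy()
    samples["family"] = assign["family"].to_numpy()

    # latent spatially correlated allele-frequency fields
    n, L = params.n_samples, params.n_snps
    D = pairwise_distance_km(lon, lat)
    if np.isfinite(params.migration_scale):
        cov = np.exp(-D / params.migration_scale)
    else:
        cov = np.ones_like(D)
    chol = np.linalg.cholesky(cov + 1e-6 * np.eye(n))
    z = chol @ rng.standard_normal((n, L))

    p0 = rng.uniform(0.15, 0.85, L)
    eta = logit(p0)[None, :] + params.spatial_sigma * z

    n_lang = int(round(params.language_effect * L))
    if n_lang and len(catalog.table["family"].unique()) > 1:
        lang_loci = rng.choice(L, size=n_lang, replace=False)
        fams = pd.Categorical(samples["family"]).codes
        shifts = rng.normal(
            0, params.language_sigma, (fams.max() + 1, n_lang)
        )
        eta[:, lang_loci] += shifts[fams]
    n_clim = int(round(params.climate_effect * L))
    if n_clim:
        clim_loci = rng.choice(L, size=n_clim, replace=False)
        var_pick = rng.integers(0, len(CLIMATE_VARS), n_clim)
        zclim = np.column_stack(
            [
                (samples[v] - samples[v].mean()) / max(samples[v].std(), 1e-9)
                for v in CLIMATE_VARS
            ]
        )
        betas = rng.choice([-1.0, 1.0], n_clim) * params.climate_beta
        eta[:, clim_loci] += zclim[:, var_pick] * betas[None, :]

    p = expit(eta)
    # inbreeding: both alleles identical-by-state with probability F so the
    # expected heterozygote fraction is ~het_rate
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.clip(1.0 - params.het_rate / (2.0 * p * (1.0 - p)), 0.0, 1.0)
    ibd_draw = rng.random((n, L)) < F
    hom = 2 * (rng.random((n, L)) < p).astype(np.int8)
    out = rng.binomial(2, p).astype(np.int8)
    dosage = np.where(ibd_draw, hom, out).astype(np.int8)
    if params.missing_rate > 0:
        dosage[rng.random((n, L)) < params.missing_rate] = -1

    variants = pd.DataFrame(
        {
            "chrom": (rng.integers(1, params.n_chromosomes + 1, L)).astype(str),
            "pos": np.arange(1, L + 1) * 1000,
            "id": [f"snp{j:05d}" for j in range(L)],
            "ref": "A",
            "alt": "T",
        }
    )
    variants = variants.sort_values(["chrom", "pos"], key=lambda s: (
        s.astype(int) if s.name == "chrom" else s
    )).reset_index(drop=True)
    order = variants.index.to_numpy()
    G = GenotypeMatrix(dosage[:, order], ids, variants.reset_index(drop=True))
    return samples, G


def generate_genetic_map(params: SimParams) -> pd.DataFrame:
    """Linear genetic map: 1 cM per Mbp, anchors every 10 cM per chromosome."""
    rows = []
    for c in range(1, params.n_chromosomes + 1):
        for cm in np.arange(0, params.chrom_length_cm + 1e-9, 10.0):
            rows.append(dict(chrom=str(c), bp=int(cm * 1e6) + 1, cm=float(cm)))
    return pd.DataFrame(rows)


def generate_ibd_segments(
    samples: pd.DataFrame, gmap: pd.DataFrame, params: SimParams, rng=None
) -> pd.DataFrame:
    """Poisson segment counts per haplotype pair/chromosome/length bin.

    log E[count] = log(rate_bin) - d_ij / decay_km_bin; segment lengths are
    drawn inside the bin's cM range (the open-ended bin uses a shifted
    exponential), positions uniformly along the chromosome, and cM is
    converted to bp through the genetic map."""
    if gmap.empty:
        raise ValueError("genetic map is empty")
    rng = _rng(params, rng, 5)
    ids = samples["id"].astype(str).to_numpy()
    n = len(ids)
    D = pairwise_distance_km(
        samples["lon"].to_numpy(dtype=float), samples["lat"].to_numpy(dtype=float)
    )
    chroms = sorted(gmap["chrom"].unique(), key=lambda c: int(c))
    cm_max = {c: gmap.loc[gmap["chrom"] == c, "cm"].max() for c in chroms}
    edges = {"1-3": (1.0, 3.0), "3-5": (3.0, 5.0), ">5": (5.0, np.inf)}
    rows = []
    iu, ju = np.triu_indices(n, k=1)
    for b, rate in params.ibd_rate_per_bin.items():
        if rate == 0:
            continue
        decay = params.ibd_decay_km[b]
        lam = rate * np.exp(-D[iu, ju] / decay)
        # counts per pair aggregated over 4 haplotype pairs x chromosomes
        counts = rng.poisson(lam * 4 * params.n_chromosomes)
        lo, hi = edges[b]
        for pair_idx in np.flatnonzero(counts):
            i, j = iu[pair_idx], ju[pair_idx]
            for _ in range(counts[pair_idx]):
                c = chroms[rng.integers(len(chroms))]
                if np.isinf(hi):
                    length = lo + rng.exponential(2.0)
                else:
                    length = rng.uniform(lo, hi)
                length = min(length, cm_max[c])
                start_cm = rng.uniform(0, cm_max[c] - length)
                sub = gmap[gmap["chrom"] == c]
                start_bp = int(np.interp(start_cm, sub["cm"], sub["bp"]))
                end_bp = int(np.interp(start_cm + length, sub["cm"], sub["bp"]))
                rows.append(
                    dict(
                        sample1=ids[i],
                        hap1=int(rng.integers(1, 3)),
                        sample2=ids[j],
                        hap2=int(rng.integers(1, 3)),
                        chrom=c,
                        start=start_bp,
                        end=max(end_bp, start_bp + 1),
                        lod=float(np.round(rng.uniform(3, 15), 2)),
                        cm=float(np.round(length, 3)),
                    )
                )
    return pd.DataFrame(rows, columns=IBD_COLUMNS)


@dataclass
class SimulatedData:
    params: SimParams
    grid: LandscapeGrid
    catalog: LanguageCatalog
    climate: dict[str, np.ndarray]
    samples: pd.DataFrame
    genotypes: GenotypeMatrix
    genetic_map: pd.DataFrame
    ibd: pd.DataFrame


def simulate_dataset(params: SimParams) -> SimulatedData:
    """Run every generator in a fixed order; reproducible from params.seed."""
    grid = generate_landscape(params)
    catalog = generate_language_catalog(grid, params)
    climate = generate_climate(grid, params)
    samples, G = generate_samples_genotypes(grid, catalog, climate, params)
    gmap = generate_genetic_map(params)
    ibd = generate_ibd_segments(samples, gmap, params)
    return SimulatedData(params, grid, catalog, climate, samples, G, gmap, ibd)


def write_dataset(data: SimulatedData, outdir) -> dict[str, Path]:
    """Write every artefact in its interchange format; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "ped": outdir / "genotypes",
        "samples": outdir / "samples.csv",
        "languages": outdir / "languages.csv",
        "gmap": outdir / "genetic_map.tsv",
        "ibd": outdir / "segments.ibd",
    }
    write_vcf(data.genotypes, paths["vcf"])
    write_ped(data.genotypes, paths["ped"])
    data.samples.to_csv(paths["samples"], index=False)
    data.catalog.to_csv(paths["languages"])
    data.genetic_map.to_csv(paths["gmap"], sep="\t", index=False)
    write_refined_ibd(data.ibd, paths["ibd"])
    data.grid.write(outdir)
    paths["elevation"] = outdir / "landscape_elevation.asc"
    paths["seamask"] = outdir / "landscape_seamask.asc"
    return paths
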