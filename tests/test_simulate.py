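import numpy as np
import pandas as pd
import pytest

from landgen.core import PairwiseMatrix
from landgen.genotypes import genetic_distance
from landgen.geodesy import pairwise_distance_km
from landgen.grid import LandscapeGrid
from landgen.ibd import bin_segments, poisson_decay_fit, sharing_matrix
from landgen.languages import filter_families, fst_wc
from landgen.pairwise import mantel_test
from landgen.simulate import (
    SimParams,
    generate_genetic_map,
    generate_ibd_segments,
    generate_landscape,
    generate_language_catalog,
    simulate_dataset,
    write_dataset,
)


def small_params(**kw):
    base = dict(n_samples=60, n_snps=200, seed=5, n_rows=20, n_cols=25)
    base.update(kw)
    return SimParams(**base)


# ---------------------------------------------------------------------------
# Determinism & landscape


def test_full_dataset_deterministic_under_seed():
    a = simulate_dataset(small_params())
    b = simulate_dataset(small_params())
    np.testing.assert_array_equal(a.grid.elevation, b.grid.elevation)
    np.testing.assert_array_equal(a.genotypes.dosage, b.genotypes.dosage)
    pd.testing.assert_frame_equal(a.samples, b.samples)
    pd.testing.assert_frame_equal(a.ibd, b.ibd)


def test_different_seed_changes_draws():
    a = simulate_dataset(small_params())
    b = simulate_dataset(small_params(seed=6))
    assert not np.array_equal(a.genotypes.dosage, b.genotypes.dosage)


def test_zero_sea_fraction_gives_all_land():
    grid = generate_landscape(small_params(sea_fraction=0.0))
    assert not grid.sea_mask.any()


def test_sea_region_contiguous():
    from scipy.ndimage import label

    grid = generate_landscape(small_params(sea_fraction=0.3))
    _, n_comp = label(grid.sea_mask)
    assert n_comp == 1


def test_elevation_autocorrelated_lag1_exceeds_lag10():
    grid = generate_landscape(small_params(smooth_cells=5.0, sea_fraction=0.0))
    e = grid.elevation - grid.elevation.mean()

    def moran_lag(e, lag):
        num = (e[:, :-lag] * e[:, lag:]).mean() + (e[:-lag, :] * e[lag:, :]).mean()
        return num / (2 * e.var())

    assert moran_lag(e, 1) > moran_lag(e, 10)


def test_invalid_dimensions_rejected():
    with pytest.raises(ValueError):
        SimParams(n_rows=1, n_cols=2)
    with pytest.raises(ValueError):
        SimParams(n_rows=-3, n_cols=10)


def test_landscape_ascii_roundtrip(tmp_path):
    grid = generate_landscape(small_params())
    grid.write(tmp_path)
    back = LandscapeGrid.read(
        tmp_path / "landscape_elevation.asc", tmp_path / "landscape_seamask.asc"
    )
    land = ~grid.sea_mask
    np.testing.assert_allclose(back.elevation[land], grid.elevation[land])
    np.testing.assert_array_equal(back.sea_mask, grid.sea_mask)


# ---------------------------------------------------------------------------
# Genotype structure


def genetic_geo(data):
    gen = genetic_distance(data.genotypes, "hamming")
    geo = PairwiseMatrix(
        pairwise_distance_km(
            data.samples["lon"].to_numpy(), data.samples["lat"].to_numpy()
        ),
        gen.ids,
        "km",
    )
    return gen, geo


def test_panmixia_limit_gives_no_isolation_by_distance():
    params = SimParams(
        n_samples=200, n_snps=150, seed=21, migration_scale=np.inf,
        language_effect=0.0, climate_effect=0.0,
    )
    data = simulate_dataset(params)
    gen, geo = genetic_geo(data)
    r, _ = mantel_test(gen, geo, n_perm=0, rng=0)
    assert abs(r) < 0.05


def test_short_migration_scale_gives_strong_isolation_by_distance():
    # correlation length well below the ~2700 km domain extent
    params = small_params(migration_scale=300.0, seed=22)
    data = simulate_dataset(params)
    gen, geo = genetic_geo(data)
    r, p = mantel_test(gen, geo, n_perm=99, rng=0)
    assert r > 0.3
    assert p == pytest.approx(1 / 100)


def test_language_effect_creates_family_fst():
    params = SimParams(
        n_samples=80, n_snps=300, seed=23, n_families=2,
        languages_per_family=4, language_effect=0.3,
    )
    data = simulate_dataset(params)
    theta = fst_wc(data.genotypes, data.samples["family"].to_numpy())
    assert theta > 0.02


def test_heterozygosity_near_target():
    data = simulate_dataset(small_params(het_rate=0.05, missing_rate=0.0))
    obs = (data.genotypes.dosage == 1).mean()
    assert obs == pytest.approx(0.05, abs=0.015)


def test_missingness_near_target():
    data = simulate_dataset(small_params(missing_rate=0.1))
    assert (data.genotypes.dosage == -1).mean() == pytest.approx(0.1, abs=0.02)


def test_more_samples_than_land_cells_rejected():
    with pytest.raises(ValueError, match="land cells"):
        simulate_dataset(SimParams(n_samples=100, n_snps=10, n_rows=6,
                                   n_cols=6, sea_fraction=0.5))


# ---------------------------------------------------------------------------
# Built-in effects recoverable & monotone


def test_isolation_by_distance_slope_monotone_in_migration_scale():
    """Shorter allele-frequency correlation length = steeper distance decay.

    The slope of genetic on geographic distance is the recoverable
    statistic; Spearman Mantel r saturates once the correlation length
    drops far below the domain extent, so the slope is compared instead.
    """
    from landgen.pairwise import linear_r2

    slopes = []
    for scale in (600.0, 3000.0, 1e7):
        data = simulate_dataset(small_params(migration_scale=scale, seed=31))
        gen, geo = genetic_geo(data)
        slopes.append(linear_r2(gen, geo)["slope"])
    assert slopes[0] > slopes[1] > slopes[2]


def test_family_fst_monotone_in_language_effect():
    thetas = []
    for eff in (0.0, 0.15, 0.4):
        data = simulate_dataset(
            SimParams(n_samples=70, n_snps=250, seed=32, n_families=3,
                      language_effect=eff)
        )
        thetas.append(fst_wc(data.genotypes, data.samples["family"].to_numpy()))
    assert thetas[0] < thetas[1] < thetas[2]


def test_ibd_decay_rate_monotone_in_decay_parameter():
    slopes = []
    for decay in (300.0, 1000.0, 5000.0):
        params = SimParams(
            n_samples=90, n_snps=10, seed=33, n_regions=1,
            ibd_rate_per_bin={"1-3": 0.05},
            ibd_decay_km={"1-3": decay},
        )
        data = simulate_dataset(params)
        share = sharing_matrix(
            bin_segments(data.ibd)["1-3"], data.samples["id"], params.n_chromosomes
        )
        geo = PairwiseMatrix(
            pairwise_distance_km(
                data.samples["lon"].to_numpy(), data.samples["lat"].to_numpy()
            ),
            share.ids,
            "km",
        )
        regions = dict(zip(data.samples["id"].astype(str), data.samples["region"]))
        slopes.append(poisson_decay_fit(share, geo, regions).slopes["region0"])
    assert slopes[0] < slopes[1] < slopes[2] < 0.01


def test_infinite_decay_slope_ci_covers_zero():
    params = SimParams(
        n_samples=90, n_snps=10, seed=34, n_regions=1,
        ibd_rate_per_bin={"1-3": 0.05}, ibd_decay_km={"1-3": 1e12},
    )
    data = simulate_dataset(params)
    share = sharing_matrix(
        bin_segments(data.ibd)["1-3"], data.samples["id"], params.n_chromosomes
    )
    geo = PairwiseMatrix(
        pairwise_distance_km(
            data.samples["lon"].to_numpy(), data.samples["lat"].to_numpy()
        ),
        share.ids,
        "km",
    )
    regions = dict(zip(data.samples["id"].astype(str), data.samples["region"]))
    # weight = number of aggregated haplotype-pair-chromosome units, the
    # exact precision of a mean count, so the slope CI is calibrated
    fit = poisson_decay_fit(share, geo, regions,
                            weights=4 * params.n_chromosomes)
    s, se = fit.slopes["region0"], fit.slopes_se["region0"]
    assert abs(s) < 2 * se


# ---------------------------------------------------------------------------
# Language catalog generator


def test_single_language_catalog_catches_all_samples():
    params = small_params(n_families=1, languages_per_family=1)
    data = simulate_dataset(params)
    assert (data.samples["language"] == data.catalog.table.loc[0, "language"]).all()


def test_many_families_survive_family_filter():
    params = SimParams(
        n_samples=100, n_snps=10, seed=36, n_families=8,
        languages_per_family=7, n_rows=30, n_cols=40,
    )
    data = simulate_dataset(params)
    catalog_families = set(data.catalog.table["family"])
    assert len(catalog_families) == 8
    # language clusters are spatial, so each catalogued family has >5
    # languages available; the filter keeps every family that reached >5
    # *assigned* languages
    assign = data.samples.rename(columns={"id": "id"})[["id", "language", "family"]]
    kept = filter_families(assign, min_languages=5)
    retained = set(kept["family"])
    counts = assign.groupby("family")["language"].nunique()
    assert retained == set(counts.index[counts > 5])


def test_catalog_names_unique_and_clustered():
    params = small_params(n_families=4, languages_per_family=6)
    grid = generate_landscape(params)
    cat = generate_language_catalog(grid, params)
    assert cat.table["language"].is_unique
    # within-family spread well below between-family centre spread
    spread = cat.table.groupby("family")[["lon", "lat"]].std().mean().mean()
    centres = cat.table.groupby("family")[["lon", "lat"]].mean()
    centre_spread = centres.std().mean()
    assert spread < centre_spread


# ---------------------------------------------------------------------------
# Dataset writer


def test_write_dataset_emits_all_text_artefacts(tmp_path):
    data = simulate_dataset(SimParams(n_samples=12, n_snps=20, seed=37))
    paths = write_dataset(data, tmp_path)
    for p in paths.values():
        if str(p).endswith("genotypes"):  # ped/map prefix
            assert (tmp_path / "genotypes.ped").exists()
            assert (tmp_path / "genotypes.map").exists()
        else:
            assert p.exists()


def test_empty_ibd_map_rejected():
    params = small_params()
    data = simulate_dataset(params)
    with pytest.raises(ValueError, match="map is empty"):
        generate_ibd_segments(data.samples, generate_genetic_map(params).iloc[0:0],
                              params)
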