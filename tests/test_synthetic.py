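"""Generator behaviour: gradients, layers, pool composition, sampling, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from floragap.grid import assign_cells
from floragap.projection import SOUTH_AMERICA_LCC
from floragap.synthetic import (
    ConfigurationError,
    EffortSurface,
    LandscapeConfig,
    SamplingError,
    build_name_table,
    generate_climate,
    generate_layers,
    generate_species_pool,
    sample_occurrences,
    simulate_dataset,
)


class TestClimate:
    def test_degenerate_range_gives_constant_surface(self):
        cfg = LandscapeConfig(width_cells=8, height_cells=8,
                              temp_range=(10.0, 10.0), temp_noise_sd=0.0, seed=0)
        anmt, _ = generate_climate(cfg)
        assert np.all(anmt.values == 10.0)

    def test_same_seed_bit_identical(self):
        a1, p1 = generate_climate(LandscapeConfig(seed=5))
        a2, p2 = generate_climate(LandscapeConfig(seed=5))
        np.testing.assert_array_equal(a1.values, a2.values)
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_noiseless_gradients_strictly_monotone(self):
        cfg = LandscapeConfig(width_cells=20, height_cells=20,
                              temp_noise_sd=0.0, precip_noise_sd=0.0, seed=0)
        anmt, anp = generate_climate(cfg)
        col_means = anmt.values.mean(axis=0)
        row_means = anp.values.mean(axis=1)
        # direct scan: each successive mean strictly larger
        for i in range(len(col_means) - 1):
            assert col_means[i] < col_means[i + 1]
        for i in range(len(row_means) - 1):
            assert row_means[i] < row_means[i + 1]

    def test_invalid_range_rejected(self):
        with pytest.raises(ConfigurationError):
            LandscapeConfig(temp_range=(20.0, 10.0))


class TestLayers:
    def test_zero_transformed_fraction_all_false(self):
        cfg = LandscapeConfig(width_cells=10, height_cells=10,
                              transformed_fraction=0.0, seed=1)
        anmt, anp = generate_climate(cfg)
        _, _, mask = generate_layers(cfg, anmt, anp)
        assert not mask.values.any()

    def test_single_region_is_constant(self):
        cfg = LandscapeConfig(width_cells=10, height_cells=10, n_regions=1, seed=1)
        anmt, anp = generate_climate(cfg)
        _, region, _ = generate_layers(cfg, anmt, anp)
        assert set(np.unique(region.values)) == {1}

    def test_realized_transformed_fraction_close_to_target(self):
        cfg = LandscapeConfig(width_cells=50, height_cells=50,
                              transformed_fraction=0.1, seed=3)
        anmt, anp = generate_climate(cfg)
        _, region, mask = generate_layers(cfg, anmt, anp)
        # direct tally, overall and per region
        frac = mask.values.sum() / mask.values.size
        assert 0.08 <= frac <= 0.12
        for rid in np.unique(region.values):
            sel = region.values == rid
            f = mask.values[sel].sum() / sel.sum()
            assert 0.08 <= f <= 0.12

    def test_too_many_classes_rejected(self):
        cfg = LandscapeConfig(width_cells=2, height_cells=2, seed=0)
        anmt, anp = generate_climate(cfg)
        with pytest.raises(ConfigurationError):
            generate_layers(
                LandscapeConfig(width_cells=2, height_cells=2, n_biomes=5, seed=0),
                anmt, anp,
            )


class TestSpeciesPool:
    def test_zero_useful_fraction_means_no_uses(self, small_config):
        pool = generate_species_pool(small_config, n_species=50, useful_fraction=0.0)
        assert all(not sp.is_useful and not sp.uses for sp in pool)

    def test_all_one_marginals_give_all_categories(self, small_config):
        from floragap.occurrences import USE_CATEGORIES

        pool = generate_species_pool(
            small_config, n_species=30, useful_fraction=1.0,
            use_marginals={c: 1.0 for c in USE_CATEGORIES},
        )
        assert all(sp.uses == frozenset(USE_CATEGORIES) for sp in pool)

    def test_medicines_marginal_recovered_within_3_sd(self, small_config):
        from floragap.synthetic import DEFAULT_USE_MARGINALS

        p = DEFAULT_USE_MARGINALS["MEDICINES"]  # 0.763
        pool = generate_species_pool(
            small_config, n_species=2000, useful_fraction=1.0,
        )
        realized = np.mean([("MEDICINES" in sp.uses) for sp in pool])
        # redrawing empty use sets conditions every marginal on "at least one
        # category", so the exact expectation is p / (1 - prod(1 - p_c))
        p_empty = np.prod([1 - q for q in DEFAULT_USE_MARGINALS.values()])
        expected = p / (1 - p_empty)
        sd = np.sqrt(expected * (1 - expected) / len(pool))
        assert abs(realized - expected) < 3 * sd


class TestSampling:
    def test_zero_records_empty_table(self, small_config, small_dataset):
        recs, truth = sample_occurrences(
            small_dataset.pool, small_dataset.anmt, small_dataset.anp,
            EffortSurface.uniform(small_config), 0, small_config.seed,
        )
        assert len(recs) == 0 and truth["n_records"] == 0

    def test_single_flat_species_forced_composition(self, small_config):
        anmt, anp = generate_climate(small_config)
        pool = generate_species_pool(small_config, n_species=1, useful_fraction=0.0,
                                     endemic_fraction=0.0)
        sp = pool[0]
        # widen the niche and range so the species is suitable everywhere
        sp.niche_breadth = (1e6, 1e9)
        sp.range_radius_m = 1e12
        sp.is_point_endemic = False
        recs, _ = sample_occurrences(
            pool, anmt, anp, EffortSurface.uniform(small_config), 100, 0
        )
        assert len(recs) == 100
        assert set(recs["verbatim_name"]) == {sp.accepted_name}

    def test_uniform_effort_cell_counts_multinomial(self, ):
        cfg = LandscapeConfig(width_cells=30, height_cells=30, seed=9)
        anmt, anp = generate_climate(cfg)
        pool = generate_species_pool(cfg, n_species=1, useful_fraction=0.0,
                                     endemic_fraction=0.0)
        pool[0].niche_breadth = (1e6, 1e9)
        pool[0].range_radius_m = 1e12
        _, truth = sample_occurrences(
            pool, anmt, anp, EffortSurface.uniform(cfg), 5000, cfg.seed
        )
        counts = np.bincount(truth["cell_index"], minlength=cfg.n_cells)
        chi2 = ((counts - 5000 / cfg.n_cells) ** 2 / (5000 / cfg.n_cells)).sum()
        crit = stats.chi2.ppf(1 - 0.001, df=cfg.n_cells - 1)
        assert chi2 < crit

    def test_all_zero_suitability_raises(self, small_config):
        anmt, anp = generate_climate(small_config)
        pool = generate_species_pool(small_config, n_species=1, endemic_fraction=0.0,
                                     useful_fraction=0.0)
        pool[0].range_radius_m = 0.0  # suitable nowhere
        with pytest.raises(SamplingError):
            sample_occurrences(pool, anmt, anp,
                               EffortSurface.uniform(small_config), 10, 0)


class TestDatasetInvariants:
    def test_same_seed_bit_identical_dataset(self, small_config):
        d1 = simulate_dataset(small_config, n_species=60, n_records=500)
        d2 = simulate_dataset(small_config, n_species=60, n_records=500)
        pd.testing.assert_frame_equal(d1.records, d2.records)
        np.testing.assert_array_equal(d1.biome.values, d2.biome.values)
        assert [s.accepted_name for s in d1.pool] == [s.accepted_name for s in d2.pool]

    def test_effort_weights_normalized(self, small_config):
        for eff in (EffortSurface.uniform(small_config),
                    EffortSurface.access_biased(small_config)):
            assert abs(eff.weights.sum() - 1.0) <= 1e-9
            assert (eff.weights >= 0).all()

    def test_uncorrupted_records_inside_bounding_box(self, small_config, small_dataset):
        from floragap.synthetic import CorruptionRates

        recs, _ = sample_occurrences(
            small_dataset.pool, small_dataset.anmt, small_dataset.anp,
            EffortSurface.uniform(small_config), 800, 11,
            rates=CorruptionRates(0, 0, 0, 0, 0, 0),
        )
        x, y = SOUTH_AMERICA_LCC.forward(recs["lon"].to_numpy(), recs["lat"].to_numpy())
        idx = assign_cells(x, y, small_dataset.anmt)
        assert (idx >= 0).all()

    def test_point_endemics_have_one_locality(self, small_dataset):
        endemics = {s.accepted_name for s in small_dataset.pool if s.is_point_endemic}
        truth_names = pd.Series(small_dataset.truth["true_accepted_name"])
        recs = small_dataset.records.assign(true_name=truth_names)
        for name, grp in recs.groupby("true_name"):
            if name in endemics:
                assert grp[["lat", "lon"]].drop_duplicates().shape[0] == 1

    def test_name_table_round_trips_corruption(self, small_dataset):
        """Every corrupted verbatim name resolves back to a real species or is
        an intentionally unresolvable junk name."""
        lut = small_dataset.name_table.table
        resolvable = set(lut.loc[lut["status"].isin(
            ["accepted", "synonym", "misspelling"]), "verbatim_name"])
        junk = set(lut.loc[lut["status"] == "unresolved", "verbatim_name"])
        for v in small_dataset.records["verbatim_name"]:
            assert v in resolvable or v in junk
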