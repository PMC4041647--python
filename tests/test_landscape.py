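"""Synthetic floodplain generator: determinism, rule-consistency of the
productivity labels, exact distance transforms, parcel constraints and
lossless text round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from palmland.landscape import (
    LandscapeParams,
    LandscapeStack,
    ParcelParams,
    distance_to_river,
    flood_prone_fraction,
    generate_landscape,
    generate_parcels,
    read_stack,
    sample_suitability_points,
    write_stack,
)
from palmland.raster import RasterGrid, read_ascii_grid, write_ascii_grid
from palmland.suitability import classify_raster, reference_ruleset


def brute_force_distance(mask: np.ndarray, cell_size: float) -> np.ndarray:
    """O(N*R) oracle: min Euclidean cell-center distance to any river cell."""
    rows, cols = mask.shape
    rr, cc = np.nonzero(mask)
    out = np.empty(mask.shape)
    for i in range(rows):
        for j in range(cols):
            out[i, j] = np.sqrt(((rr - i) ** 2 + (cc - j) ** 2).min()) * cell_size
    return out


class TestDistanceToRiver:
    def test_river_cells_are_zero(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, :] = True
        d = distance_to_river(mask, cell_size=100.0)
        assert np.all(d.values[10, :] == 0.0)
        assert np.all(d.values >= 0.0)

    def test_three_cells_away_is_300m(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:, 5] = True
        d = distance_to_river(mask, cell_size=100.0)
        assert d.values[7, 8] == pytest.approx(300.0)

    def test_3_4_5_triangle(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2, 2] = True
        d = distance_to_river(mask, cell_size=100.0)
        assert d.values[5, 6] == pytest.approx(500.0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no river cell"):
            distance_to_river(np.zeros((20, 20), dtype=bool))

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_exactly(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(5, 30)), int(rng.integers(5, 30)))
        mask = rng.random(shape) < 0.08
        if not mask.any():
            mask[0, 0] = True
        d = distance_to_river(mask, cell_size=100.0)
        np.testing.assert_allclose(d.values, brute_force_distance(mask, 100.0),
                                   rtol=0, atol=1e-9)


class TestGenerateLandscape:
    def test_same_seed_bit_identical(self):
        a = generate_landscape((40, 40), LandscapeParams(), seed=9)
        b = generate_landscape((40, 40), LandscapeParams(), seed=9)
        for name in LandscapeStack.LAYERS:
            la, lb = getattr(a, name), getattr(b, name)
            if la is None:
                continue
            assert np.array_equal(la.values, lb.values), name

    def test_different_seed_differs(self):
        a = generate_landscape((40, 40), LandscapeParams(), seed=1)
        b = generate_landscape((40, 40), LandscapeParams(), seed=2)
        assert not np.array_equal(a.elevation.values, b.elevation.values)

    def test_layers_aligned_and_categorical_codes_valid(self, small_stack):
        ref = small_stack.elevation
        for name in ("dist_river", "soil", "forest_system", "productivity", "titles"):
            layer = getattr(small_stack, name)
            assert ref.aligned_with(layer)
        assert set(np.unique(small_stack.soil.values)) <= {1, 2, 3, 4}
        assert set(np.unique(small_stack.productivity.values)) <= {0, 1}

    def test_zero_noise_productivity_equals_rule_labels(self, small_stack):
        ruled = classify_raster(small_stack, reference_ruleset())
        assert np.array_equal(ruled.values, small_stack.productivity.values)

    def test_label_noise_flips_expected_fraction(self):
        clean = generate_landscape((100, 100), LandscapeParams(), seed=3)
        noisy = generate_landscape((100, 100), LandscapeParams(label_noise=0.1), seed=3)
        frac = float(
            (clean.productivity.values != noisy.productivity.values).mean()
        )
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_elevation_rises_with_distance_in_expectation(self, small_stack):
        d = small_stack.dist_river.values.ravel()
        e = small_stack.elevation.values.ravel()
        qs = np.quantile(d, np.linspace(0, 1, 7)[1:-1])
        bins = np.digitize(d, qs)
        means = [e[bins == b].mean() for b in range(6)]
        assert all(m2 > m1 for m1, m2 in zip(means, means[1:]))

    def test_flood_prone_fraction_monotone_in_flood_extent(self):
        fracs = []
        for fe in (0.3, 0.5, 1.0, 2.0, 4.0):
            s = generate_landscape((60, 60), LandscapeParams(flood_extent=fe), seed=3)
            fracs.append(flood_prone_fraction(s))
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] > fracs[0]

    @pytest.mark.parametrize("shape", [(10, 40), (40, 10)])
    def test_too_small_grid_rejected(self, shape):
        with pytest.raises(ValueError, match="20x20"):
            generate_landscape(shape, LandscapeParams(), seed=0)

    @pytest.mark.parametrize("eps", [-0.1, 1.0, 1.5])
    def test_invalid_label_noise_rejected(self, eps):
        with pytest.raises(ValueError, match="label_noise"):
            LandscapeParams(label_noise=eps)


class TestParcels:
    def test_native_title_parcels_under_40ha(self):
        for seed in (0, 1, 2):
            pm = generate_parcels((80, 80), ParcelParams(), seed=seed)
            nt = [p for p in pm.parcels if p.title_type == "NT"]
            assert nt, "no NT parcels placed"
            assert max(p.area_ha for p in nt) < 40.0

    def test_nt_size_request_at_or_above_40ha_rejected(self):
        with pytest.raises(ValueError, match="40 ha"):
            ParcelParams(nt_size_ha=(2.0, 40.0))

    def test_parcels_do_not_overlap_and_fit_grid(self):
        pm = generate_parcels((80, 80), ParcelParams(), seed=7)
        occupancy = np.zeros((80, 80), dtype=int)
        for p in pm.parcels:
            occupancy[p.cell_slice()] += 1
        assert occupancy.max() <= 1
        total_area = sum(p.area_ha for p in pm.parcels)
        assert total_area <= 80 * 80 * 1.0
        assert len({p.id for p in pm.parcels}) == len(pm.parcels)

    def test_same_seed_identical_parcels(self):
        a = generate_parcels((50, 50), ParcelParams(), seed=3)
        b = generate_parcels((50, 50), ParcelParams(), seed=3)
        assert [vars(p) for p in a.parcels] == [vars(p) for p in b.parcels]


class TestStackIO:
    def test_round_trip_preserves_every_layer(self, small_stack, tmp_path):
        write_stack(small_stack, tmp_path)
        back = read_stack(tmp_path)
        for name in LandscapeStack.LAYERS:
            orig = getattr(small_stack, name)
            rt = getattr(back, name)
            if orig is None:
                assert rt is None
                continue
            np.testing.assert_array_equal(orig.values, rt.values, err_msg=name)
            assert orig.cell_size == rt.cell_size
            assert orig.origin == rt.origin

    def test_round_trip_preserves_parcels(self, small_stack, tmp_path):
        write_stack(small_stack, tmp_path)
        back = read_stack(tmp_path)
        assert [vars(p) for p in back.parcels.parcels] == [
            vars(p) for p in small_stack.parcels.parcels
        ]

    def test_nodata_cells_survive_round_trip(self, tmp_path):
        vals = np.arange(12, dtype=np.int64).reshape(3, 4)
        vals[1, 2] = -9999
        grid = RasterGrid(vals, cell_size=100.0, nodata=-9999)
        write_ascii_grid(grid, tmp_path / "g.asc")
        back = read_ascii_grid(tmp_path / "g.asc")
        np.testing.assert_array_equal(back.values, vals)
        assert back.nodata == -9999

    def test_float_layer_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(5, 7)) * 13.7
        grid = RasterGrid(vals, cell_size=50.0, origin=(10.0, 20.0), nodata=-9999.0)
        write_ascii_grid(grid, tmp_path / "f.asc")
        back = read_ascii_grid(tmp_path / "f.asc")
        np.testing.assert_array_equal(back.values, vals)


class TestTrainingSampler:
    def test_deterministic(self):
        a = sample_suitability_points(500, seed=4)
        b = sample_suitability_points(500, seed=4)
        assert a.equals(b)

    def test_noise_free_labels_match_rules(self):
        df = sample_suitability_points(2000, seed=1, noise_rate=0.0)
        rules = reference_ruleset()
        labels = rules.classify(
            dist_river=df["dist_river"].to_numpy(),
            elevation=df["elevation"].to_numpy(),
            soil=df["soil"].to_numpy(),
        )
        assert (labels == df["label"].to_numpy()).all()

    def test_noise_rate_flips_expected_fraction(self):
        clean = sample_suitability_points(10_000, seed=2, noise_rate=0.0)
        noisy = sample_suitability_points(10_000, seed=2, noise_rate=0.1)
        frac = float((clean["label"] != noisy["label"]).mean())
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_both_classes_present_and_ranges_respected(self):
        df = sample_suitability_points(1000, seed=3)
        assert set(df["label"]) == {"full_stand", "redundant"}
        assert df["dist_river"].between(0, 5000).all()
        assert df["elevation"].between(0, 40.01).all()
        assert set(df["soil"]) <= {1.0, 2.0, 3.0, 4.0}
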