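"""Tessellation, edge-quantity QC, Macenko normalization, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lauren_mil.preprocess import (
    EmptySlideError,
    InsufficientTissueError,
    SlideImage,
    StainReference,
    TileRecord,
    augment,
    default_reference,
    edge_quantity,
    macenko_fit,
    macenko_normalize,
    qc_filter,
    tessellate,
)
from lauren_mil.synthetic import SyntheticSlideConfig, generate_slide


def flat_slide(width_um, height_um, mpp, value=128):
    w, h = int(round(width_um / mpp)), int(round(height_um / mpp))
    return SlideImage(np.full((h, w, 3), value, dtype=np.uint8), mpp, "flat")


def beer_lambert_tile(stain_matrix, rng, n=224, max_conc=(1.2, 0.9)):
    """Independent forward model: known stain vectors -> RGB tile.

    Includes near-pure hematoxylin and eosin patches so the extreme angular
    percentiles of the OD cloud correspond to the true stain directions.
    """
    c = np.empty((n * n, 2))
    c[:, 0] = rng.uniform(0.1, max_conc[0], n * n)
    c[:, 1] = rng.uniform(0.1, max_conc[1], n * n)
    third = n * n // 3
    c[:third, 1] = rng.uniform(0.0, 0.02, third)       # pure hematoxylin
    c[third:2 * third, 0] = rng.uniform(0.0, 0.02, third)  # pure eosin
    od = c @ stain_matrix.T
    rgb = np.clip(np.round(255.0 * 10.0 ** (-od)), 0, 255).astype(np.uint8)
    return rgb.reshape(n, n, 3), c


def angular_error_deg(a, b):
    return np.degrees(np.arccos(np.clip(abs(a @ b), -1, 1)))


class TestTessellate:
    def test_effective_resolution_matches_published_setup(self):
        slide = flat_slide(1024, 1024, 1.0)
        ts = tessellate(slide, tile_um=256, tile_px=224)
        assert round(ts.effective_mpp, 2) == 1.14

    def test_grid_from_physical_size(self):
        ts = tessellate(flat_slide(512, 512, 2.0), tile_um=256)
        assert len(ts) == 4
        assert ts.grid_shape == (2, 2)

    def test_partial_edge_tiles_dropped(self):
        ts = tessellate(flat_slide(448, 448, 2.0), tile_um=256)
        assert len(ts) == 1

    def test_slide_smaller_than_tile_warns_and_is_empty(self):
        with pytest.warns(UserWarning):
            ts = tessellate(flat_slide(100, 100, 1.0), tile_um=256)
        assert len(ts) == 0

    def test_tiles_have_exact_pixel_size_and_unique_grid_positions(self):
        ts = tessellate(flat_slide(900, 700, 1.3), tile_um=256, tile_px=224)
        coords = {(t.grid_row, t.grid_col) for t in ts.tiles}
        assert len(coords) == len(ts)
        for t in ts.tiles:
            assert t.pixels.shape == (224, 224, 3)

    @settings(max_examples=25, deadline=None)
    @given(
        w=st.floats(min_value=256, max_value=1500),
        h=st.floats(min_value=256, max_value=1500),
        mpp=st.floats(min_value=0.5, max_value=4.0),
    )
    def test_footprints_partition_interior(self, w, h, mpp):
        """Tile footprints are disjoint, lie inside the slide, and their
        count is the floor of each materialized physical dimension (the
        pixel grid quantizes the requested size) over the tile size."""
        slide = flat_slide(w, h, mpp)
        real_w, real_h = slide.width_um, slide.height_um
        ts = tessellate(slide, tile_um=256)
        n_expected = int(real_w / 256 + 1e-9) * int(real_h / 256 + 1e-9)
        assert len(ts) == n_expected
        seen = set()
        for t in ts.tiles:
            x0, y0 = t.origin_um
            assert x0 + 256 <= real_w + 1e-6 and y0 + 256 <= real_h + 1e-6
            assert (t.grid_row, t.grid_col) not in seen
            seen.add((t.grid_row, t.grid_col))


class TestEdgeQuantity:
    def test_constant_tile_scores_zero(self):
        tile = np.full((224, 224, 3), 77, dtype=np.uint8)
        assert edge_quantity(tile) == 0.0

    def test_fine_checkerboard_scores_high(self):
        idx = (np.indices((224, 224)).sum(axis=0) // 2) % 2
        tile = (idx * 255).astype(np.uint8)[..., None].repeat(3, axis=2)
        assert edge_quantity(tile) >= 0.5

    def test_blur_strictly_lowers_edge_quantity(self):
        from scipy.ndimage import gaussian_filter

        slide = generate_slide(SyntheticSlideConfig(seed=4))
        tile = slide.image[:224, :224]
        blurred = np.stack(
            [gaussian_filter(tile[..., c].astype(float), 4) for c in range(3)],
            axis=-1,
        ).astype(np.uint8)
        assert edge_quantity(blurred) < edge_quantity(tile)


class TestQCFilter:
    def _tileset(self):
        cfg = SyntheticSlideConfig(
            background_fraction=0.3, blur_fraction=0.0, mucin_fraction=0.0,
            seed=6,
        )
        return tessellate(generate_slide(cfg).to_slide_image())

    def test_zero_threshold_is_identity(self):
        ts = self._tileset()
        assert len(qc_filter(ts, threshold=0.0)) == len(ts)

    def test_threshold_separates_blank_from_textured(self):
        ts = self._tileset()
        kept = qc_filter(ts, threshold=0.02)
        scores = sorted(t.edge_quantity for t in ts.tiles)
        assert max(s for s in scores if s < 0.02) < 0.02 <= min(
            t.edge_quantity for t in kept.tiles
        )

    def test_retained_fraction_tracks_tissue_fraction(self):
        """A slide with 30% background keeps about 70% of its tiles."""
        ts = self._tileset()
        kept = qc_filter(ts, threshold=0.02)
        assert abs(len(kept) / len(ts) - 0.70) <= 0.10

    def test_idempotence(self):
        ts = self._tileset()
        once = qc_filter(ts, threshold=0.02)
        twice = qc_filter(once, threshold=0.02)
        assert [id(t) for t in twice.tiles] == [id(t) for t in once.tiles]

    def test_everything_removed_names_the_slide(self):
        blank = tessellate(flat_slide(512, 512, 2.0))
        with pytest.raises(EmptySlideError, match="flat"):
            qc_filter(blank, threshold=0.5)


class TestMacenko:
    TRUE = np.array([[0.55, 0.10], [0.72, 0.95], [0.42, 0.29]])
    TRUE /= np.linalg.norm(TRUE, axis=0)

    def test_stain_vectors_recovered_from_forward_model(self, rng):
        tile, _ = beer_lambert_tile(self.TRUE, rng)
        ref = macenko_fit(tile)
        for j in range(2):
            err = angular_error_deg(ref.stain_matrix[:, j], self.TRUE[:, j])
            assert err < 5.0

    def test_white_tile_raises_insufficient_tissue(self):
        white = np.full((64, 64, 3), 255, dtype=np.uint8)
        with pytest.raises(InsufficientTissueError):
            macenko_fit(white)

    def test_pixel_duplication_leaves_fit_unchanged(self, rng):
        tile, _ = beer_lambert_tile(self.TRUE, rng, n=100)
        flat = tile.reshape(-1, 3)
        doubled = np.concatenate([flat, flat]).reshape(2, -1, 3)
        a, b = macenko_fit(tile), macenko_fit(doubled)
        assert np.allclose(a.stain_matrix, b.stain_matrix, atol=1e-3)
        assert np.allclose(a.max_concentrations, b.max_concentrations,
                           rtol=1e-2)

    def test_normalize_to_own_reference_is_identity(self, rng):
        tile, _ = beer_lambert_tile(self.TRUE, rng)
        ref = macenko_fit(tile)
        out = macenko_normalize(tile, ref, ref)
        assert np.max(np.abs(out.astype(int) - tile.astype(int))) <= 2

    def test_normalization_idempotent_under_target(self, rng):
        tile, _ = beer_lambert_tile(self.TRUE, rng)
        target = default_reference()
        once = macenko_normalize(tile, macenko_fit(tile), target)
        twice = macenko_normalize(once, macenko_fit(once), target)
        assert np.mean(np.abs(twice.astype(int) - once.astype(int))) < 2.0

    def test_normalization_shrinks_stain_intensity_differences(self, rng):
        """Two renderings of the same tissue under different stain strengths
        land closer together after normalization to a common reference."""
        _, conc = beer_lambert_tile(self.TRUE, rng)
        target = default_reference()
        tiles = []
        for scale in (0.7, 1.3):
            od = (conc * scale) @ self.TRUE.T
            t = np.clip(np.round(255 * 10.0 ** (-od)), 0, 255).astype(np.uint8)
            tiles.append(t.reshape(224, 224, 3))
        before = np.abs(
            tiles[0].mean(axis=(0, 1)) - tiles[1].mean(axis=(0, 1))
        ).mean()
        normed = [macenko_normalize(t, macenko_fit(t), target) for t in tiles]
        after = np.abs(
            normed[0].mean(axis=(0, 1)) - normed[1].mean(axis=(0, 1))
        ).mean()
        assert after < before

    def test_singular_source_matrix_rejected(self, rng):
        v = np.array([0.6, 0.7, 0.39])
        v /= np.linalg.norm(v)
        with pytest.raises(ValueError, match="unit-norm|singular"):
            bad = StainReference(np.column_stack([v, v]), np.array([1.0, 1.0]))
            tile, _ = beer_lambert_tile(self.TRUE, rng, n=32)
            macenko_normalize(tile, bad)


class TestAugment:
    def _tile(self, rng):
        return rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)

    def test_seeded_draw_is_deterministic(self, rng):
        tile = self._tile(rng)
        assert np.array_equal(augment(tile, seed=5), augment(tile, seed=5))

    def test_zero_rotation_no_flip_is_identity(self, rng):
        tile = self._tile(rng)
        assert np.array_equal(augment(tile, angle=0.0, flip=False), tile)

    def test_four_quarter_turns_are_identity(self, rng):
        tile = self._tile(rng)
        out = tile
        for _ in range(4):
            out = augment(out, angle=90.0, flip=False)
        assert np.array_equal(out, tile)

    def test_double_vertical_flip_is_identity(self, rng):
        tile = self._tile(rng)
        out = augment(augment(tile, angle=0.0, flip=True), angle=0.0, flip=True)
        assert np.array_equal(out, tile)
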