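import numpy as np
import pandas as pd
import pytest
import imageio.v3 as iio

from ccpipe.color_features import (
    FEATURE_COLUMNS,
    ChannelCountError,
    RGBImage,
    compute_product_vi,
    compute_vi,
    extract_pixel_features,
    load_image,
    to_color_planes,
)


def _img(arr):
    return RGBImage(pixels=np.asarray(arr, dtype=float))


class TestLoadImage:
    def test_8bit_png_rescaled_by_255(self, tmp_path):
        raw = np.zeros((4, 5, 3), dtype=np.uint8)
        raw[0, 0] = (204, 128, 26)
        path = tmp_path / "a.png"
        iio.imwrite(path, raw)
        img = load_image(path)
        assert np.allclose(img.pixels[0, 0], np.array([204, 128, 26]) / 255.0)
        assert img.pixels.min() >= 0 and img.pixels.max() <= 1

    def test_16bit_tiff_rescaled_by_65535(self, tmp_path):
        raw = ((np.arange(60).reshape(4, 5, 3) * 1000) % 65536).astype(np.uint16)
        path = tmp_path / "a.tiff"
        iio.imwrite(path, raw.astype(np.uint16))
        img = load_image(path)
        assert np.allclose(img.pixels, raw / 65535.0)
        assert img.pixels.max() <= 1.0

    def test_truncated_file_raises_io_error(self, tmp_path):
        raw = np.zeros((16, 16, 3), dtype=np.uint8)
        path = tmp_path / "a.png"
        iio.imwrite(path, raw)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(OSError):
            load_image(path)

    def test_grayscale_rejected(self, tmp_path):
        path = tmp_path / "g.png"
        iio.imwrite(path, np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ChannelCountError):
            load_image(path)

    def test_alpha_requires_explicit_flag(self, tmp_path):
        path = tmp_path / "rgba.png"
        iio.imwrite(path, np.zeros((8, 8, 4), dtype=np.uint8))
        with pytest.raises(ChannelCountError):
            load_image(path)
        img = load_image(path, drop_alpha=True)
        assert img.pixels.shape == (8, 8, 3)

    def test_metadata_carried(self, tmp_path):
        path = tmp_path / "m.png"
        iio.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint8))
        img = load_image(path, plot_id="p1", date="2014-11-07")
        assert img.plot_id == "p1"
        assert img.date.isoformat() == "2014-11-07"


class TestColorPlanes:
    def test_achromatic_gray_pixel(self):
        planes = to_color_planes(_img([[[0.5, 0.5, 0.5]]]))
        assert abs(planes.S[0, 0]) < 1e-9
        # sRGB/D65 whitepoint rounding leaves a sub-2e-3 chroma residual
        assert abs(planes.a[0, 0]) < 5e-3
        assert abs(planes.b[0, 0]) < 5e-3

    def test_pure_red_pixel(self):
        planes = to_color_planes(_img([[[1.0, 0.0, 0.0]]]))
        assert planes.H[0, 0] == 0.0
        assert planes.S[0, 0] == 1.0
        assert planes.V[0, 0] == 1.0

    def test_value_plane_is_channel_maximum(self, rng):
        px = rng.uniform(0, 1, (12, 9, 3))
        planes = to_color_planes(RGBImage(pixels=px))
        assert np.allclose(planes.V, px.max(axis=2))


class TestComputeVI:
    @pytest.mark.parametrize(
        "pixel, vi_name, expected",
        [
            ((0.5, 0.7, 0.0), "ExR", 1.4 * 0.5 - 0.7),  # exactly 0
            ((0.3, 0.3, 0.3), "NDI3", 0.0),
            ((0.8, 0.5, 0.1), "NDI3", (0.8 + 0.5 - 0.2) / (0.8 + 0.5 + 0.2)),
            ((0.2, 0.6, 0.4), "ExB", 1.4 * 0.4 - 0.6),
            ((0.6, 0.1, 0.2), "NDI2", (0.6 - 0.2) / (0.6 + 0.2)),
            ((0.6, 0.3, 0.2), "ExR_minus_ExB", 1.4 * 0.6 - 1.4 * 0.2),
        ],
    )
    def test_pointwise_formulas(self, pixel, vi_name, expected):
        vi = compute_vi(_img([[pixel]]), vi_name)
        assert vi.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_maps_to_zero(self):
        vi2 = compute_vi(_img([[[0.0, 0.0, 0.0]]]), "NDI2")
        vi3 = compute_vi(_img([[[0.0, 0.0, 0.0]]]), "NDI3")
        assert vi2.values[0, 0] == 0.0
        assert vi3.values[0, 0] == 0.0

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            compute_vi(_img([[[0.1, 0.2, 0.3]]]), "NDVI")

    def test_ndi_bounded_on_channel_grid(self):
        levels = np.arange(0.0, 1.0001, 0.05)
        R, G, B = np.meshgrid(levels, levels, levels, indexing="ij")
        px = np.stack([R.ravel(), G.ravel(), B.ravel()], axis=-1)[None, :, :]
        img = RGBImage(pixels=px)
        for name in ("NDI2", "NDI3"):
            vals = compute_vi(img, name).values
            assert vals.min() >= -1.0 - 1e-12
            assert vals.max() <= 1.0 + 1e-12

    def test_pointwise_operator_commutes_with_permutation(self, rng):
        px = rng.uniform(0, 1, (6, 7, 3))
        perm = rng.permutation(42)
        img = RGBImage(pixels=px)
        img_p = RGBImage(pixels=px.reshape(42, 3)[perm].reshape(6, 7, 3))
        for name in ("ExR", "NDI2", "NDI3"):
            direct = compute_vi(img, name).values.ravel()[perm]
            permuted = compute_vi(img_p, name).values.ravel()
            assert np.allclose(direct, permuted)


class TestProductVI:
    def test_zero_ndi3_forces_zero_product(self):
        # R=G=B makes NDI3 = 0 regardless of brightness (V)
        vi = compute_product_vi(_img([[[0.9, 0.9, 0.9], [0.2, 0.2, 0.2]]]), "NDI3V")
        assert np.all(vi.values == 0.0)

    def test_unit_value_plane_is_identity(self, rng):
        # channel 0 pinned at 1 so V = max(R,G,B) = 1 everywhere
        px = rng.uniform(0, 1, (5, 5, 3))
        px[:, :, 0] = 1.0
        img = RGBImage(pixels=px)
        ndi3v = compute_product_vi(img, "NDI3V")
        ndi3 = compute_vi(img, "NDI3")
        assert np.allclose(ndi3v.values, ndi3.values)

    def test_product_equals_elementwise_plane_product(self, rng):
        px = rng.uniform(0.05, 1, (8, 8, 3))
        img = RGBImage(pixels=px)
        planes = to_color_planes(img)
        ndi3v = compute_product_vi(img, "NDI3V")
        assert np.allclose(ndi3v.values, compute_vi(img, "NDI3").values * planes.V)
        a01 = (planes.a - planes.a.min()) / (planes.a.max() - planes.a.min())
        ndi2a = compute_product_vi(img, "NDI2a")
        assert np.allclose(ndi2a.values, compute_vi(img, "NDI2").values * a01)

    def test_constant_a_plane_warns_and_maps_to_half(self):
        img = _img([[[0.5, 0.5, 0.5], [0.5, 0.5, 0.5]]])  # a constant (= 0)
        with pytest.warns(RuntimeWarning, match="constant a-plane"):
            vi = compute_product_vi(img, "NDI3a")
        assert np.all(vi.values == 0.0)  # NDI3 = 0 here; a-plane was 0.5

    def test_unknown_product_rejected(self):
        with pytest.raises(ValueError):
            compute_product_vi(_img([[[0.1, 0.2, 0.3]]]), "NDI3L")


class TestExtractPixelFeatures:
    def test_canonical_ten_columns_in_order(self, rng):
        img = RGBImage(pixels=rng.uniform(0, 1, (3, 4, 3)))
        table = extract_pixel_features(img)
        assert list(table.columns) == list(FEATURE_COLUMNS)
        assert len(FEATURE_COLUMNS) == 10

    def test_one_row_per_pixel(self, rng):
        img = RGBImage(pixels=rng.uniform(0, 1, (2, 2, 3)))
        assert len(extract_pixel_features(img)) == 4

    def test_subset_rows_match_source_pixels(self, rng):
        px = rng.uniform(0, 1, (20, 30, 3))
        img = RGBImage(pixels=px)
        idx = rng.choice(20 * 30, size=100, replace=False)
        table = extract_pixel_features(img, sample=idx)
        assert len(table) == 100
        flat = px.reshape(-1, 3)
        assert np.allclose(table[["R", "G", "B"]].to_numpy(), flat[idx])

    def test_out_of_bounds_sample_rejected(self, rng):
        img = RGBImage(pixels=rng.uniform(0, 1, (4, 4, 3)))
        with pytest.raises(IndexError):
            extract_pixel_features(img, sample=np.array([0, 16]))

    def test_label_mask_subset(self, rng):
        px = rng.uniform(0, 1, (6, 6, 3))
        labels = rng.integers(0, 2, (6, 6))
        idx = np.array([0, 7, 35])
        table = extract_pixel_features(RGBImage(pixels=px), sample=idx, labels=labels)
        assert list(table["label"]) == list(labels.ravel()[idx])
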