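import logging

import numpy as np
import pandas as pd
import pytest

from ccpipe.color_features import FEATURE_COLUMNS, RGBImage, extract_pixel_features
from ccpipe.quality import evaluate_segmentation
from ccpipe.segmentation import (
    DegenerateClusteringError,
    ModelBank,
    SegModel,
    load_training_table,
    route_scenario,
    segment_kmeans,
    segment_supervised,
    train_pixel_model,
)
from ccpipe.synthetic import PLANT_COLOR, SOIL_COLOR, generate_field_image


def _two_color_image(rng, n_plant=60, n_soil=60, noise=0.01):
    """Checkerboard-free two-population image with an exact label mask."""
    h = 10
    w = (n_plant + n_soil) // h
    labels = np.zeros((h, w), dtype=np.uint8)
    labels.ravel()[: n_plant] = 1
    px = np.where(labels[..., None] == 1, PLANT_COLOR, SOIL_COLOR)
    px = np.clip(px + rng.normal(0, noise, px.shape), 0, 1)
    return RGBImage(pixels=px), labels


@pytest.fixture(scope="module")
def separable_table():
    rng = np.random.default_rng(12)
    img, labels = _two_color_image(rng, n_plant=5000, n_soil=5000)
    return extract_pixel_features(img, labels=labels)


class TestTrainPixelModel:
    @pytest.mark.parametrize("algorithm", ["DT", "SVM"])
    def test_separable_table_learned(self, separable_table, algorithm):
        # single-feature oracle first: NDI3V alone separates the classes
        ndi3v = separable_table["NDI3V"].to_numpy()
        labels = separable_table["label"].to_numpy()
        oracle_acc = ((ndi3v > 0.25).astype(int) == labels).mean()
        assert oracle_acc >= 0.99

        model = train_pixel_model(separable_table, algorithm, "ALC", seed=0)
        assert model.summary["training_accuracy"] >= 0.99

    def test_deterministic_for_fixed_seed(self, separable_table, rng):
        m1 = train_pixel_model(separable_table, "DT", "ALC", seed=4)
        m2 = train_pixel_model(separable_table, "DT", "ALC", seed=4)
        probe = rng.uniform(0, 1, (50, 10))
        assert np.array_equal(m1.estimator.predict(probe), m2.estimator.predict(probe))

    def test_single_class_rejected(self, separable_table):
        plant_only = separable_table[separable_table["label"] == 1]
        with pytest.raises(ValueError, match="single class"):
            train_pixel_model(plant_only, "DT", "ALC")

    def test_schema_mismatch_rejected(self, separable_table):
        with pytest.raises(ValueError, match="feature columns"):
            train_pixel_model(separable_table.drop(columns=["H"]), "DT", "ALC")

    def test_subsampling_respects_budget(self, separable_table):
        model = train_pixel_model(separable_table, "DT", "ALC", seed=0, max_pixels=1000)
        assert sum(model.summary["n_per_class"].values()) <= 1100

    def test_unknown_algorithm_or_scenario(self, separable_table):
        with pytest.raises(ValueError):
            train_pixel_model(separable_table, "RF", "ALC")
        with pytest.raises(ValueError):
            train_pixel_model(separable_table, "DT", "XYZ")


@pytest.fixture(scope="module")
def model(separable_table):
    return train_pixel_model(separable_table, "DT", "ALC", seed=0)


class TestSegmentSupervised:

    def test_uniform_plant_image_all_one(self, model):
        img = RGBImage(pixels=np.tile(PLANT_COLOR, (6, 6, 1)))
        assert segment_supervised(model, img).all()

    def test_uniform_soil_image_all_zero(self, model):
        img = RGBImage(pixels=np.tile(SOIL_COLOR, (6, 6, 1)))
        assert not segment_supervised(model, img).any()

    def test_equals_rowwise_feature_prediction(self, model, rng):
        img = RGBImage(pixels=rng.uniform(0, 1, (9, 11, 3)))
        mask = segment_supervised(model, img)
        feats = extract_pixel_features(img)
        manual = model.estimator.predict(feats[list(FEATURE_COLUMNS)].to_numpy())
        assert np.array_equal(mask.ravel(), manual.astype(np.uint8))

    def test_untrained_model_refuses(self, llc_scene):
        with pytest.raises(RuntimeError):
            segment_supervised(SegModel(algorithm="DT", scenario="ALC"), llc_scene.image)

    def test_llc_scene_segmented_accurately(self, llc_scene):
        rng = np.random.default_rng(77)
        tables = []
        for seed in (501, 502):
            sc = generate_field_image("LLC", 8, float(rng.uniform(0.2, 0.5)), seed=seed)
            tables.append(extract_pixel_features(sc.image, labels=sc.truth))
        model = train_pixel_model(pd.concat(tables, ignore_index=True), "DT", "LLC", seed=0)
        q = evaluate_segmentation(segment_supervised(model, llc_scene.image), llc_scene.truth)
        assert q.qseg >= 0.9


class TestRouting:
    def _bank(self, separable_table, scenarios):
        bank = ModelBank()
        for s in scenarios:
            bank.add(train_pixel_model(separable_table, "DT", s, seed=0, max_pixels=500))
        return bank

    def test_class_one_routes_to_llc(self, separable_table):
        bank = self._bank(separable_table, ["ALC", "HLC", "LLC"])
        assert route_scenario(bank, 1).scenario == "LLC"
        assert route_scenario(bank, 2).scenario == "HLC"

    def test_missing_scenario_falls_back_to_alc(self, separable_table, caplog):
        bank = self._bank(separable_table, ["ALC"])
        with caplog.at_level(logging.WARNING, logger="ccpipe.segmentation"):
            model = route_scenario(bank, 2)
        assert model.scenario == "ALC"
        assert "falling back" in caplog.text

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            route_scenario(ModelBank(), 1)

    def test_bank_roundtrip(self, separable_table, tmp_path):
        bank = self._bank(separable_table, ["ALC", "LLC"])
        bank.save(tmp_path)
        loaded = ModelBank.load(tmp_path)
        assert set(loaded.models) == {"ALC", "LLC"}


class TestKMeans:
    def _three_population_image(self, rng, noise=0.01):
        # plant / dry soil / wet soil, separated in Lab (a, b); plant has top NDI3
        colors = {
            1: np.array([0.75, 0.50, 0.15]),  # plant, NDI3 ~ 0.61
            0: np.array([0.55, 0.45, 0.30]),  # dry soil, NDI3 = 0.25
            2: np.array([0.25, 0.27, 0.40]),  # wet soil, NDI3 < 0
        }
        labels = rng.integers(0, 3, (40, 40))
        px = np.zeros((40, 40, 3))
        for k, c in colors.items():
            px[labels == k] = c
        px = np.clip(px + rng.normal(0, noise, px.shape), 0, 1)
        return RGBImage(pixels=px), (labels == 1)

    def test_recovers_plant_population(self, rng):
        img, truth = self._three_population_image(rng)
        mask = segment_kmeans(img, seed=0)
        recovered = (mask.astype(bool) & truth).sum() / truth.sum()
        assert recovered >= 0.99
        false_rate = (mask.astype(bool) & ~truth).sum() / (~truth).sum()
        assert false_rate <= 0.01

    def test_two_distinct_colors_rejected(self):
        px = np.zeros((10, 10, 3))
        px[:5] = [0.8, 0.2, 0.1]
        with pytest.raises(DegenerateClusteringError):
            segment_kmeans(RGBImage(pixels=px), seed=0)

    def test_deterministic(self, rng):
        img, _ = self._three_population_image(rng)
        assert np.array_equal(segment_kmeans(img, seed=3), segment_kmeans(img, seed=3))


class TestTrainingTableIO:
    def test_csv_roundtrip(self, separable_table, tmp_path):
        path = tmp_path / "train.csv"
        separable_table.head(50).to_csv(path, index=False)
        loaded = load_training_table(path)
        assert list(loaded.columns[:10]) == list(FEATURE_COLUMNS)
        assert "label" in loaded.columns

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"R": [0.1], "label": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            load_training_table(path)
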