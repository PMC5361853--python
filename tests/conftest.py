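import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ccpipe.synthetic import SeriesSpec, generate_field_image, generate_series, save_scene


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def llc_scene():
    return generate_field_image("LLC", row_count=8, cc_target=0.35, seed=7)


@pytest.fixture(scope="session")
def hlc_scene():
    return generate_field_image("HLC", row_count=8, cc_target=0.35, seed=7)


def stripe_vi(rows, shape=(120, 220), plant=0.7, soil=0.1, noise_sd=0.02, seed=None,
              fill=1.0):
    """Analytic vertical-stripe VI image with a known row count.

    ``fill`` < 1 leaves within-row soil gaps (as real crop rows have), which
    pulls the column-mean profile peaks below the plant pixel level.
    """
    h, w = shape
    gen = np.random.default_rng(seed if seed is not None else 0)
    vi = np.full((h, w), soil)
    spacing = w / rows
    cols = np.arange(w)
    for r in range(rows):
        center = (r + 0.5) * spacing
        stripe = np.abs(cols - center) < 0.25 * spacing
        block = np.where(
            gen.uniform(size=(h, int(stripe.sum()))) < fill, plant, soil
        )
        vi[:, stripe] = block
    if noise_sd and seed is not None:
        vi += gen.normal(0, noise_sd, vi.shape)
    return vi


@pytest.fixture(scope="session")
def series_dates():
    return [dt.date(2014, 11, 7) + dt.timedelta(days=7 * i) for i in range(6)]


@pytest.fixture(scope="session")
def llc_series(series_dates, tmp_path_factory):
    """An all-LLC campaign (8 plots x 6 dates) written to disk.

    Returns (manifest DataFrame, truth table, scenes, directory).
    """
    out = tmp_path_factory.mktemp("llc_series")
    scenes, truth = generate_series(SeriesSpec(n_plots=8, dates=series_dates, seed=5))
    rows = [
        save_scene(s, out, f"{s.image.plot_id}_{s.image.date.isoformat()}") for s in scenes
    ]
    return pd.DataFrame(rows), truth, scenes, out
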