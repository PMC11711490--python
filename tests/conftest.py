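import warnings

import numpy as np
import pandas as pd
import pytest

import ctdetect as ct


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """The default seeded on-disk synthetic study (generated once)."""
    out = tmp_path_factory.mktemp("fixture")
    return ct.generate_fixture(out, seed=1)


@pytest.fixture(scope="session")
def fixture_analysis(fixture_dataset):
    """Full multimodal pipeline run on the default fixture."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result, runs = ct.analyze_sample(fixture_dataset)
    return result, runs


@pytest.fixture(scope="session")
def templates():
    return ct.make_synthetic_templates(seed=11)


@pytest.fixture()
def simple_track():
    """Unmasked single-chromosome coverage track builder."""

    def make(y, chrom="chr1", masked=None):
        y = np.asarray(y, dtype=float)
        n = len(y)
        bins = pd.DataFrame(
            {
                "chrom": chrom,
                "start": np.arange(n) * 1000,
                "end": (np.arange(n) + 1) * 1000,
                "raw_count": 0,
                "gc": np.nan,
                "mappability": np.nan,
                "masked": np.zeros(n, bool) if masked is None else np.asarray(masked, bool),
            }
        )
        yy = y.copy()
        if masked is not None:
            yy = np.where(np.asarray(masked, bool), np.nan, yy)
        return ct.CoverageTrack(bins=bins, y=yy, stage="smoothed")

    return make
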