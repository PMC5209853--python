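import numpy as np
import pandas as pd
import pytest

from relic import ControlPairTable, IntensitySet


def make_intensity_set(meth, unmeth, assay_types, channels, sample_ids=None):
    """Build an IntensitySet from plain arrays and per-probe metadata."""
    meth = np.atleast_2d(np.asarray(meth, dtype=float))
    unmeth = np.atleast_2d(np.asarray(unmeth, dtype=float))
    n_probes, n_samples = meth.shape
    probe_ids = [f"cg{i:05d}" for i in range(n_probes)]
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    ann = pd.DataFrame(
        {"assay_type": assay_types, "channel": channels},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return IntensitySet(
        meth=pd.DataFrame(meth, index=ann.index, columns=sample_ids),
        unmeth=pd.DataFrame(unmeth, index=ann.index, columns=sample_ids),
        annotations=ann,
    )


def make_controls(red, green, sample_ids=None):
    """Build a ControlPairTable from (pair x sample) arrays."""
    red = np.atleast_2d(np.asarray(red, dtype=float))
    green = np.atleast_2d(np.asarray(green, dtype=float))
    n_pairs, n_samples = red.shape
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(n_samples)]
    index = pd.Index([f"pair_{k + 1:03d}" for k in range(n_pairs)], name="pair_id")
    return ControlPairTable(
        red=pd.DataFrame(red, index=index, columns=sample_ids),
        green=pd.DataFrame(green, index=index, columns=sample_ids),
        red_probe_ids=pd.Series([f"NORM_A.{k + 1}" for k in range(n_pairs)], index=index),
        green_probe_ids=pd.Series([f"NORM_G.{k + 1}" for k in range(n_pairs)], index=index),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def tiny_set():
    """3 probes (one of each design flavor) x 2 samples."""
    return make_intensity_set(
        meth=[[1000.0, 1100.0], [2000.0, 2100.0], [3000.0, 3100.0]],
        unmeth=[[500.0, 550.0], [600.0, 650.0], [700.0, 750.0]],
        assay_types=["II", "I", "I"],
        channels=[None, "Red", "Grn"],
    )


@pytest.fixture
def tiny_controls():
    red = np.array([[100.0, 110.0], [200.0, 210.0], [400.0, 420.0]])
    return make_controls(red=red, green=red / 2.0)
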