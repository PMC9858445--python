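import numpy as np
import pytest

from connsiam._rng import substream
from connsiam.io import ASD, NC, ROITimeSeries
from connsiam.model import EncoderSpec, SiameseNet
from connsiam.training import SiteDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model():
    """Small seeded twin network on 12-dimensional inputs."""
    spec = EncoderSpec(
        input_dim=12,
        encoder_widths=(8, 6),
        head_widths=(5,),
        embedding_dim=4,
        activation="relu",
    )
    model = SiameseNet(spec)
    model.init_params(substream(7, "init"))
    return model


def make_site(site_id, n_per_class, n_features, rng, offset=0.0):
    """Random labelled site; ASD rows shifted by ``offset`` on all features."""
    feats, labels, ids = [], [], []
    for klass, shift in ((NC, 0.0), (ASD, offset)):
        for i in range(n_per_class):
            feats.append(rng.normal(size=n_features) + shift)
            labels.append(klass)
            ids.append(f"{site_id}_{klass}_{i}")
    return SiteDataset(site_id, np.array(feats), tuple(labels), tuple(ids))


@pytest.fixture
def toy_sites(rng):
    sites = [make_site(f"S{i}", 6, 12, rng, offset=1.0) for i in range(2)]
    baseline = make_site("BASE", 5, 12, rng, offset=1.0)
    return sites, baseline


def random_timeseries(rng, n_timepoints=40, n_regions=5, **meta):
    data = rng.normal(size=(n_timepoints, n_regions))
    meta.setdefault("subject_id", "subj")
    meta.setdefault("site_id", "S0")
    meta.setdefault("label", NC)
    return ROITimeSeries(data=data, **meta)
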