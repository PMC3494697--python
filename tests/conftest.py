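import numpy as np
import pytest

from pdmri.discriminate import FeatureBundle
from pdmri.synthetic_cohort import make_atlas


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_atlas():
    """8 octant regions on a 12^3 grid with generic labels."""
    return make_atlas((12, 12, 12), 8)


def make_feature_bundles(n_cases, n_controls, n_regions, rng,
                         effects=None, metrics=("ReHo", "ALFF", "RFCS",
                                                "GM", "WM", "CSF")):
    """Feature-space cohort: standard-normal features with optional
    (metric, region-index, shift-in-SD) implants in the case group."""
    effects = effects or []
    bundles = []
    for i in range(n_cases + n_controls):
        group = "case" if i < n_cases else "control"
        feats = {}
        for m in metrics:
            v = rng.normal(size=n_regions)
            if group == "case":
                for metric, j, d in effects:
                    if metric == m:
                        v[j] += d
            feats[m] = v
        bundles.append(FeatureBundle(f"s{i:02d}", group, feats))
    return bundles


@pytest.fixture
def bundle_factory():
    return make_feature_bundles
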