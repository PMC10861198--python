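import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk as draw_disk

from histoquant.morphometrics import FEATURE_CATALOG, FeatureTable
from histoquant.segmentation import records_from_labels
from histoquant.synthetic import PopulationParams, generate_nuclei_scene


@pytest.fixture(scope="session")
def default_params():
    return PopulationParams()


@pytest.fixture(scope="session")
def small_scene(default_params):
    """100 well-separated nuclei at the default SNR of 10."""
    return generate_nuclei_scene(
        default_params, default_params, n_per_pop=50, dispersion=60.0,
        image_size=512, pixel_size=0.5, seed=7,
    )


@pytest.fixture(scope="session")
def disk_case():
    """A bright disk (radius 10 px, intensity 1000) on a zero background."""
    image = np.zeros((64, 64))
    rr, cc = draw_disk((32, 32), 10.0)
    image[rr, cc] = 1000.0
    labels = np.zeros((64, 64), dtype=np.int32)
    labels[rr, cc] = 1
    return image, labels


@pytest.fixture(scope="session")
def disk_records(disk_case):
    image, labels = disk_case
    return records_from_labels(labels, image, pixel_size=0.5)


def make_feature_table(X: np.ndarray, labels, feature_names=None, groups=None) -> FeatureTable:
    """Fabricate a FeatureTable from a plain matrix (for scoring tests)."""
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]
    if groups is None:
        groups = ["texture"] * p
    data = pd.DataFrame(X, columns=pd.MultiIndex.from_arrays([groups, feature_names],
                                                             names=["group", "feature"]))
    idx = data.index
    return FeatureTable(
        data=data,
        condition=pd.Series(list(labels), index=idx),
        image_id=pd.Series([""] * n, index=idx),
        degenerate=pd.Series([False] * n, index=idx),
    )
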