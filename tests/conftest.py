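import numpy as np
import pandas as pd
import pytest

from periwound.io_config import AnnotationTable, RunConfig
from periwound.synthetic import SceneParams, scaled_scene_params

#: per-rater marginal counts of the published four-clinician annotation
#: distribution over the six raw categories (1860 images in total)
CLINICIAN_MARGINALS = {
    "e1": {
        "indistinct": 57,
        "attached": 718,
        "not_attached": 523,
        "rolled_under": 83,
        "hyperkeratotic": 255,
        "fibrotic": 224,
    },
    "e2": {
        "indistinct": 115,
        "attached": 612,
        "not_attached": 788,
        "rolled_under": 207,
        "hyperkeratotic": 72,
        "fibrotic": 66,
    },
    "e3": {
        "indistinct": 84,
        "attached": 981,
        "not_attached": 231,
        "rolled_under": 82,
        "hyperkeratotic": 400,
        "fibrotic": 82,
    },
    "e4": {
        "indistinct": 67,
        "attached": 893,
        "not_attached": 634,
        "rolled_under": 90,
        "hyperkeratotic": 149,
        "fibrotic": 27,
    },
}


def table_from_marginals(marginals: dict[str, dict[str, int]]) -> AnnotationTable:
    """Annotation table whose per-rater label counts equal given marginals."""
    totals = {sum(c.values()) for c in marginals.values()}
    assert len(totals) == 1, "raters must label the same number of images"
    n = totals.pop()
    data = {}
    for rater, counts in marginals.items():
        col = []
        for cat, k in counts.items():
            col.extend([cat] * k)
        data[rater] = col
    ids = [f"img_{i:05d}" for i in range(n)]
    return AnnotationTable(pd.DataFrame(data, index=pd.Index(ids, name="image_id")))


@pytest.fixture(scope="session")
def clinician_table() -> AnnotationTable:
    return table_from_marginals(CLINICIAN_MARGINALS)


@pytest.fixture(scope="session")
def disk_mask() -> np.ndarray:
    yy, xx = np.mgrid[0:201, 0:201]
    return (xx - 100) ** 2 + (yy - 100) ** 2 <= 50**2


@pytest.fixture(scope="session")
def small_params() -> SceneParams:
    """Half-scale scene geometry used by fast pipeline tests."""
    return scaled_scene_params(0.5)


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return RunConfig(d_in=10, d_out=10, contour_points=180)
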