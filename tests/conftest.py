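import numpy as np
import pytest

from pdl1bench import AnnotationSet, CellClass, CellPoint


def make_set(coords, labels=None, roi_id="roi", source_id="S", **geom):
    """Build an AnnotationSet from raw coordinates (labels default NEG_TUMOR)."""
    if labels is None:
        labels = [CellClass.NEG_TUMOR] * len(coords)
    pts = [CellPoint(float(x), float(y), lab, source=source_id) for (x, y), lab in zip(coords, labels)]
    return AnnotationSet(roi_id=roi_id, source_id=source_id, points=pts, **geom)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_instance_factory():
    """Random matching instances: coordinates in a 50x50 um box."""

    def factory(seed, max_points=10, box=50.0):
        r = np.random.default_rng(seed)
        n_ref = int(r.integers(0, max_points + 1))
        n_pred = int(r.integers(0, max_points + 1))
        ref = r.uniform(0, box, size=(n_ref, 2))
        pred = r.uniform(0, box, size=(n_pred, 2))
        return ref, pred

    return factory
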