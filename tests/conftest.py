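import matplotlib

matplotlib.use("Agg", force=True)

import math

import numpy as np
import pytest


@pytest.fixture
def symmetric_refs():
    """Reference points on the axes, equidistant from the origin.

    Anterior +x, posterior -x, dorsal +y, ventral -y (the generator's
    map-frame convention).
    """
    return {
        "posterior": (-2000.0, 0.0),
        "anterior": (2000.0, 0.0),
        "dorsal": (0.0, 2000.0),
        "ventral": (0.0, -2000.0),
    }


@pytest.fixture
def symmetric_partition(symmetric_refs):
    from dendrorient.sectors import build_partition

    return build_partition((0.0, 0.0), symmetric_refs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def cloud_from_alphas(alphas, partition, radius=50.0):
    """Build a SegmentCloud whose points sit at relative angles ``alphas``.

    alpha is measured counterclockwise from the posterior ray, so the
    absolute bearing is alpha + bearing(posterior axis).
    """
    from dendrorient.io import SegmentCloud

    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    base = math.atan2(partition.posterior_axis[1], partition.posterior_axis[0])
    theta = base + alphas
    r = np.full(alphas.shape, float(radius))
    soma = np.asarray(partition.soma)
    pts = soma + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    return SegmentCloud(points=pts, soma=soma, step=0.5)
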