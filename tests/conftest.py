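import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def phantom_suite():
    """The default named phantom suite with oracle truths (built once)."""
    from plaqueindex import default_phantom_suite

    return default_phantom_suite()


@pytest.fixture(scope="session")
def segmented_suite(phantom_suite):
    """Suite phantoms run through the full contour/grow/volumetry chain."""
    from plaqueindex import (
        auto_keyframe_contours,
        compute_api,
        generate_phantom,
        interpolate_contours,
        segment_aorta_plaque,
    )

    out = []
    for spec, truth in phantom_suite:
        vol, _ = generate_phantom(spec, supersample_truth=4)
        tube = interpolate_contours(auto_keyframe_contours(vol), vol.shape, vol.spacing)
        seg = segment_aorta_plaque(vol, tube)
        out.append((spec, truth, seg, compute_api(seg)))
    return out


def bfs_flood_fill(voxels, seeds, hu_lo, hu_hi, constraint, connectivity=6):
    """Independent brute-force breadth-first flood fill oracle."""
    from collections import deque

    shape = voxels.shape
    if connectivity == 6:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offs = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    ok = lambda k, j, i: (
        0 <= k < shape[0]
        and 0 <= j < shape[1]
        and 0 <= i < shape[2]
        and constraint[k, j, i]
        and hu_lo <= voxels[k, j, i] < hu_hi
    )
    out = np.zeros(shape, dtype=bool)
    q = deque()
    for s in seeds:
        if ok(*s) and not out[s]:
            out[s] = True
            q.append(s)
    while q:
        k, j, i = q.popleft()
        for dz, dy, dx in offs:
            n = (k + dz, j + dy, i + dx)
            if ok(*n) and not out[n]:
                out[n] = True
                q.append(n)
    return out
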