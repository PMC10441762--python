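import numpy as np
import pytest
from scipy.ndimage import convolve

from organoquant.imaging import ChannelImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """Small random nonnegative intensity field."""
    return ChannelImage(rng.uniform(0, 255, size=(32, 32)), channel="GENERIC")


def make_disk_mask(shape, disks):
    """Boolean mask with filled disks given as (row, col, radius)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for r, c, rad in disks:
        mask |= (yy - r) ** 2 + (xx - c) ** 2 <= rad * rad
    return mask


def exhaustive_circle_oracle(mask, radii):
    """Best-IoU circle over all integer centers and the given radii.

    Independent brute-force reference for the Hough detector: for every
    integer radius the disk template is correlated with the mask at every
    center and the (row, col, radius) maximising intersection-over-union
    is returned.
    """
    m = mask.astype(float)
    msum = mask.sum()
    best_iou, best = -1.0, None
    for r in radii:
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        disk = ((yy**2 + xx**2) <= r * r).astype(float)
        inter = convolve(m, disk, mode="constant")
        union = disk.sum() + msum - inter
        iou = inter / union
        idx = np.unravel_index(iou.argmax(), iou.shape)
        if iou[idx] > best_iou:
            best_iou, best = iou[idx], (idx[0], idx[1], r)
    return best
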