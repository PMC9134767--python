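import numpy as np
import pytest

from chromasym.imgio import ImageStack, RegionOfInterest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_stack(rng):
    """Two-channel 16-bit stack with random content."""
    shape = (4, 24, 32)
    channels = {
        "old": rng.integers(0, 60000, size=shape).astype(np.uint16),
        "new": rng.integers(0, 60000, size=shape).astype(np.uint16),
    }
    return ImageStack(channels, voxel_size=(0.5, 0.1, 0.1), bit_depth=16)


@pytest.fixture
def circle_roi():
    return RegionOfInterest("cell", "circle", center=(12.0, 16.0), radius=6.0)


# --- independent oracles (deliberately naive implementations) ---------------


def loop_raw_sum(image, mask):
    """Brute-force double/triple loop pixel sum."""
    image = np.asarray(image)
    total = 0
    if image.ndim == 2:
        for y in range(image.shape[0]):
            for x in range(image.shape[1]):
                if mask[y, x]:
                    total += int(image[y, x])
    else:
        for z in range(image.shape[0]):
            for y in range(image.shape[1]):
                for x in range(image.shape[2]):
                    if mask[y, x]:
                        total += int(image[z, y, x])
    return total


def exhaustive_largest_square(mask):
    """Enumerate every (top, left, side); first max in lexicographic order."""
    mask = np.asarray(mask, dtype=bool)
    ny, nx = mask.shape
    best = (0, 0, 0)
    for side in range(min(ny, nx), 0, -1):
        hits = []
        for top in range(ny - side + 1):
            for left in range(nx - side + 1):
                if mask[top : top + side, left : left + side].all():
                    hits.append((top, left))
        if hits:
            top, left = sorted(hits)[0]
            best = (top, left, side)
            break
    return best


def spearman_formula(a, b):
    """1 - 6 sum(d^2) / (n (n^2 - 1)); valid only without ties."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ra = np.empty(len(a))
    ra[np.argsort(a)] = np.arange(1, len(a) + 1)
    rb = np.empty(len(b))
    rb[np.argsort(b)] = np.arange(1, len(b) + 1)
    d2 = ((ra - rb) ** 2).sum()
    n = len(a)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def exact_mannwhitney(a, b):
    """Exhaustive permutation null for the Mann-Whitney U (no ties)."""
    import itertools

    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n_a = len(a)

    def u_min(sample_a, sample_b):
        u = sum(1 for x in sample_a for y in sample_b if x > y)
        return min(u, len(sample_a) * len(sample_b) - u)

    observed = u_min(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_min(ga, gb) <= observed:
            count += 1
    return observed, count / total


def point_in_polygon(y, x, vertices):
    """Ray-casting test, independent of shapely."""
    inside = False
    n = len(vertices)
    for i in range(n):
        y1, x1 = vertices[i]
        y2, x2 = vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside
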