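import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_convex_polygon(rng, n_max=30, scale=100.0):
    """Convex hull of random points, as an ordered (N, 2) contour."""
    from scipy.spatial import ConvexHull

    while True:
        n = rng.integers(4, n_max + 1)
        pts = rng.uniform(10, 10 + scale, size=(n, 2))
        try:
            hull = ConvexHull(pts)
        except Exception:
            continue
        return pts[hull.vertices]


def sweep_min_rect(points, step_deg=0.5):
    """Exhaustive-orientation oracle for the minimum-area rectangle.

    Scans a ``step_deg`` grid of orientations plus every polygon edge
    direction (the minimum-area rectangle provably has a side collinear
    with one hull edge, so including the edge directions makes the
    candidate set exact; the grid alone can land on a different
    near-minimum whose sides differ wildly on near-square shapes).

    Returns the list of (long, short) side pairs of every candidate whose
    area ties the minimum (the minimum-area rectangle need not be unique;
    distinct orientations can enclose the same minimal area)."""
    pts = np.asarray(points, float)
    edges = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    edge_angles = np.degrees(np.arctan2(edges[:, 1], edges[:, 0])) % 90.0
    angles = np.concatenate([np.arange(0.0, 90.0, step_deg), edge_angles])
    sides = []
    for deg in angles:
        th = np.radians(deg)
        rot = pts @ np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]]).T
        w = rot[:, 0].max() - rot[:, 0].min()
        h = rot[:, 1].max() - rot[:, 1].min()
        sides.append((w * h, max(w, h), min(w, h)))
    min_area = min(a for a, _, _ in sides)
    return [(lo, sh) for a, lo, sh in sides if a <= min_area * (1 + 1e-9)]


def disk_mask(shape, center, radius):
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    return (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius**2
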