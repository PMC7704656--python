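"""Named study fixtures: forcing layouts, initial densities, test images.

The shipped forcing layouts emulate the standard benchmark settings of
routing-optimization studies on the unit square: pairs of rectangles, a
central sink fed by four corner sources, and a central disk source
surrounded by an annular sink (the configuration used for the vein-length
analysis: f⁺ = 1 on (x−0.5)² + (y−0.5)² ≤ 0.01 and f⁻ = −1 on
0.01 < (x−0.5)² + (y−0.5)² ≤ 0.45).  Initial transport densities come in
three families — uniform, a parabola-like central bump, and a delta-like
concentrated peak.  ``synthetic-skeleton`` renders a small loopy network
image for the image-input pipeline; it is generated programmatically and
deterministically from the seed.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError
from .forcing import Annulus, Disk, ForcingSpec, Rectangle
from .mesh import TriangularMesh

__all__ = [
    "FIXTURE_NAMES",
    "forcing_fixture",
    "mu0_fixture",
    "random_rectangles",
    "synthetic_skeleton_image",
    "generate_fixture",
]

FORCING_FIXTURES = ("two-rectangles", "four-sources", "disk-annulus")
MU0_FIXTURES = ("uniform-mu0", "parabola-mu0", "delta-mu0")
FIXTURE_NAMES = FORCING_FIXTURES + MU0_FIXTURES + (
    "random-rectangles",
    "synthetic-skeleton",
)


def forcing_fixture(name: str) -> ForcingSpec:
    """A named source/sink layout on the unit square."""
    if name == "two-rectangles":
        return ForcingSpec(
            [
                Rectangle(0.05, 0.40, 0.15, 0.60, sign=+1),
                Rectangle(0.85, 0.40, 0.95, 0.60, sign=-1),
            ]
        )
    if name == "four-sources":
        # four corner sources feeding one central sink
        s = 0.12
        corners = [(0.08, 0.08), (0.80, 0.08), (0.08, 0.80), (0.80, 0.80)]
        regions = [Rectangle(x, y, x + s, y + s, sign=+1) for x, y in corners]
        regions.append(Rectangle(0.42, 0.42, 0.58, 0.58, sign=-1))
        return ForcingSpec(regions)
    if name == "disk-annulus":
        return ForcingSpec(
            [
                Disk(0.5, 0.5, 0.1, sign=+1),
                Annulus(0.5, 0.5, 0.1, float(np.sqrt(0.45)), sign=-1),
            ]
        )
    raise InvalidParameterError(
        f"unknown forcing fixture {name!r}; available: {FORCING_FIXTURES}"
    )


def mu0_fixture(name: str, mesh: TriangularMesh) -> np.ndarray:
    """A named initial transport density evaluated at the barycenters."""
    b = mesh.barycenters
    d2 = (b[:, 0] - 0.5) ** 2 + (b[:, 1] - 0.5) ** 2
    if name == "uniform-mu0":
        return np.ones(mesh.n_triangles)
    if name == "parabola-mu0":
        # parabola-like bump centred in the domain, floored to stay positive
        return np.maximum(1.0 - 2.0 * d2, 0.0) + 0.01
    if name == "delta-mu0":
        # delta-like concentrated peak at the centre
        return 0.01 + 10.0 * np.exp(-d2 / (2 * 0.1**2))
    raise InvalidParameterError(
        f"unknown mu0 fixture {name!r}; available: {MU0_FIXTURES}"
    )


def random_rectangles(seed: int, n_sources: int = 2, n_sinks: int = 2) -> ForcingSpec:
    """A randomized rectangle source/sink placement (seeded, side 0.1–0.2).

    Placements are rejection-sampled so that no two rectangles overlap:
    the model assumes disjoint source and sink supports.
    """
    rng = np.random.default_rng(seed)
    regions: list[Rectangle] = []
    for sign, count in ((+1, n_sources), (-1, n_sinks)):
        for _ in range(count):
            for _attempt in range(200):
                w, h = rng.uniform(0.1, 0.2, size=2)
                x = rng.uniform(0.0, 1.0 - w)
                y = rng.uniform(0.0, 1.0 - h)
                cand = Rectangle(x, y, x + w, y + h, sign=sign)
                overlap = any(
                    cand.xmin < r.xmax and r.xmin < cand.xmax
                    and cand.ymin < r.ymax and r.ymin < cand.ymax
                    for r in regions
                )
                if not overlap:
                    regions.append(cand)
                    break
            else:  # pragma: no cover - 200 draws always suffice at these sizes
                raise RuntimeError("could not place disjoint rectangles")
    return ForcingSpec(regions)


def synthetic_skeleton_image(seed: int = 0, size: int = 64) -> np.ndarray:
    """Render a deterministic loopy skeleton as an 8-bit greyscale image.

    The drawing is a rectangle-shaped loop with two branches hanging off
    it; positions are jittered from the seed so distinct seeds give
    distinct but reproducible images.
    """
    from skimage.draw import line

    rng = np.random.default_rng(seed)
    img = np.zeros((size, size), dtype=np.uint8)
    j = lambda v: int(np.clip(v + rng.integers(-2, 3), 1, size - 2))
    x0, x1 = j(size // 4), j(3 * size // 4)
    y0, y1 = j(size // 4), j(3 * size // 4)
    loop = [(y0, x0), (y0, x1), (y1, x1), (y1, x0), (y0, x0)]
    for (ra, ca), (rb, cb) in zip(loop[:-1], loop[1:]):
        rr, cc = line(ra, ca, rb, cb)
        img[rr, cc] = 255
    # two dangling branches
    rr, cc = line(y0, x0, j(2), j(2))
    img[rr, cc] = 255
    rr, cc = line(y1, x1, j(size - 3), j(size - 3))
    img[rr, cc] = 255
    return img


def generate_fixture(name: str, seed: int = 0):
    """Return the named fixture object (spec, density factory, or image).

    Unknown names raise an error listing the available fixtures.
    """
    if name in FORCING_FIXTURES:
        return forcing_fixture(name)
    if name in MU0_FIXTURES:
        return lambda mesh: mu0_fixture(name, mesh)
    if name == "random-rectangles":
        return random_rectangles(seed)
    if name == "synthetic-skeleton":
        return synthetic_skeleton_image(seed)
    raise InvalidParameterError(
        f"unknown fixture {name!r}; available fixtures: {', '.join(FIXTURE_NAMES)}"
    )
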