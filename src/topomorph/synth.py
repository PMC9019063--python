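"""Ground-truth phantoms and noise models for denoising experiments.

Phantoms are binary images assembled from axis-aligned black rectangles
with rectangular white holes, so the Betti pair (number of components,
number of holes) is known by construction.  The default two-scale phantom
mimics the experimental ground truths used to benchmark the denoiser: a
190 x 190 image with 6 components and 5 holes whose feature scales all
exceed 13 px and whose pairwise separations exceed the diameter of the
largest default structuring element, so small-scale noise and true
structure are separated in scale.

Two contamination models are provided: classic salt-and-pepper noise (each
pixel independently flips to the extreme low/high value with probability
d/2 each) and its larger-spatial-scale variant that stamps random black or
white squares of sides 1, 2, 4, and 8 px.  All generators are pure
functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import as_image, is_binary

__all__ = [
    "PhantomSpec",
    "make_phantom",
    "default_phantom_spec",
    "salt_pepper",
    "large_salt_pepper",
    "make_grayscale_phantom",
    "make_rgb_phantom",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom: black rectangles with white rectangular holes.

    ``components`` and ``holes`` are (x, y, w, h) boxes, x = column of the
    left edge, y = row of the top edge.  Every hole must lie strictly
    inside some component with at least ``separation`` pixels of black
    margin, and distinct components (and distinct holes) must be at least
    ``separation`` pixels apart, so each feature is an isolated topological
    feature of its own spatial scale.  ``separation`` should exceed the
    diameter of the largest structuring element an experiment will apply
    plus the largest noise feature scale, so that noise attached to one
    feature can never let an operator bridge to another.
    """

    size: tuple = (190, 190)  # (height, width)
    components: tuple = ()
    holes: tuple = ()
    separation: int = 8

    @property
    def betti(self) -> tuple:
        """Ground-truth (beta_0, beta_1) implied by the construction."""
        return len(self.components), len(self.holes)


def _boxes_apart(a, b, gap: int) -> bool:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    return (
        ax + aw + gap <= bx
        or bx + bw + gap <= ax
        or ay + ah + gap <= by
        or by + bh + gap <= ay
    )


def _box_inside(inner, outer, margin: int) -> bool:
    ix, iy, iw, ih = inner
    ox, oy, ow, oh = outer
    return (
        ix >= ox + margin
        and iy >= oy + margin
        and ix + iw + margin <= ox + ow
        and iy + ih + margin <= oy + oh
    )


def make_phantom(spec: PhantomSpec) -> tuple:
    """Render a phantom; returns (binary image, (beta_0, beta_1)).

    Raises when boxes overlap, crowd each other, or leave the domain.
    """
    h, w = spec.size
    img = np.ones((h, w), dtype=np.uint8)  # all white
    sep = spec.separation
    comps = [tuple(map(int, c)) for c in spec.components]
    holes = [tuple(map(int, c)) for c in spec.holes]
    for x, y, bw, bh in comps:
        if x < 0 or y < 0 or x + bw > w or y + bh > h or bw < 1 or bh < 1:
            raise ValueError(f"component ({x},{y},{bw},{bh}) leaves the domain")
    for i, a in enumerate(comps):
        for b in comps[i + 1 :]:
            if not _boxes_apart(a, b, sep):
                raise ValueError(f"components {a} and {b} are not separated")
    for hole in holes:
        if not any(_box_inside(hole, c, sep) for c in comps):
            raise ValueError(f"hole {hole} is not strictly inside a component")
    for i, a in enumerate(holes):
        for b in holes[i + 1 :]:
            if not _boxes_apart(a, b, sep):
                raise ValueError(f"holes {a} and {b} are not separated")
    for x, y, bw, bh in comps:
        img[y : y + bh, x : x + bw] = 0
    for x, y, bw, bh in holes:
        img[y : y + bh, x : x + bw] = 1
    return img, spec.betti


def default_phantom_spec(size: int = 190) -> PhantomSpec:
    """The standard two-scale phantom: 6 components and 5 holes on a
    190 x 190 canvas.

    Every feature scale (hole side, component thickness, hole margin,
    feature separation, border margin) is at least 17-18 px.  The layout is
    dimensioned for experiments whose noise features reach 8 px and whose
    largest applied structuring element is the 9 x 9 square: a noise stamp
    attached to a feature shifts its effective boundary by up to 8 px, and
    17 = 8 + 9 is the smallest clearance that still leaves room for a full
    9 x 9 window, so no admissible opening or closing can bridge, sever, or
    fill a true feature.
    """
    if size != 190:
        raise ValueError("the default layout is designed for 190 x 190")
    components = (
        (17, 17, 52, 87),  # two holes, stacked
        (86, 17, 52, 87),  # two holes, stacked
        (86, 121, 52, 52),
        (17, 121, 52, 52),  # one hole
        (155, 17, 18, 87),  # thin bar
        (155, 121, 18, 52),  # short bar
    )
    holes = (
        (34, 34, 18, 18),
        (34, 69, 18, 18),
        (103, 34, 18, 18),
        (103, 69, 18, 18),
        (34, 138, 18, 18),
    )
    return PhantomSpec(
        size=(size, size), components=components, holes=holes, separation=17
    )


def salt_pepper(g, density: float, seed) -> np.ndarray:
    """Classic salt-and-pepper contamination at a given density.

    Each pixel independently becomes the minimum representable value
    (pepper) with probability density/2, the maximum with probability
    density/2, and is unchanged otherwise.  For binary images the extremes
    are 0/1; otherwise 0/255.
    """
    g = as_image(g)
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    lo, hi = (0, 1) if is_binary(g) else (0, 255)
    rng = np.random.default_rng(seed)
    u = rng.random(g.shape)
    out = g.copy()
    out[u < density / 2] = lo
    out[(u >= density / 2) & (u < density)] = hi
    return out


def large_salt_pepper(g, counts: dict, seed) -> np.ndarray:
    """Stamp random black/white squares onto a binary image.

    ``counts`` maps square side (e.g. {1: 200, 2: 50, 4: 20, 8: 8}) to the
    number of stamps of that side; each stamp is white or black with equal
    probability and its top-left corner is uniform over valid positions.
    Stamps may overlap each other and true features.
    """
    g = as_image(g)
    if not is_binary(g):
        raise ValueError("large_salt_pepper expects a binary image")
    h, w = g.shape
    rng = np.random.default_rng(seed)
    out = g.copy()
    for side in sorted(counts):
        c = counts[side]
        if c < 0:
            raise ValueError("counts must be >= 0")
        if side > min(h, w):
            raise ValueError(f"square of side {side} does not fit the image")
        for _ in range(int(c)):
            y = int(rng.integers(0, h - side + 1))
            x = int(rng.integers(0, w - side + 1))
            color = int(rng.integers(0, 2))
            out[y : y + side, x : x + side] = color
    return out


def make_grayscale_phantom(
    spec: PhantomSpec = None,
    levels: tuple = (64, 160, 224),
) -> np.ndarray:
    """Piecewise-constant 8-bit phantom with known sublevel-set topology.

    The binary phantom's black components are painted with the darkest
    level, the holes with the middle level, and the background with the
    lightest, so every global threshold yields a binary image whose
    topology follows from the construction.
    """
    if spec is None:
        spec = default_phantom_spec()
    dark, mid, light = sorted(int(v) for v in levels)
    if not 0 <= dark < mid < light <= 255:
        raise ValueError("levels must be three distinct values in 0..255")
    h, w = spec.size
    img = np.full((h, w), light, dtype=np.uint8)
    for x, y, bw, bh in spec.components:
        img[y : y + bh, x : x + bw] = dark
    for x, y, bw, bh in spec.holes:
        img[y : y + bh, x : x + bw] = mid
    return img


def make_rgb_phantom(spec: PhantomSpec = None, seed=0) -> np.ndarray:
    """Three independently-shaded grayscale phantoms stacked as RGB."""
    rng = np.random.default_rng(seed)
    chans = []
    for _ in range(3):
        dark = int(rng.integers(16, 96))
        mid = int(rng.integers(112, 176))
        light = int(rng.integers(192, 256))
        chans.append(make_grayscale_phantom(spec, levels=(dark, mid, light)))
    return np.stack(chans, axis=2)
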