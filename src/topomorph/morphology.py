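"""Flat mathematical morphology on rectangular pixel grids.

Images are 2-D numpy arrays of non-negative values on the domain
``P = {0..width-1} x {0..height-1}``; arrays are indexed ``[row, col]`` and
offsets are ``(dx, dy)`` pairs with ``x`` the column and ``y`` the row,
0-based, origin at the top-left.  Binary images take values in ``{0, 1}``
with 0 = black, 1 = white.

All operators clip their window to the image domain: the value at ``x`` is
the min/max over ``(x + B) n P`` (erosion) or ``(x - B) n P`` (dilation).
No padding value is ever invented, which differs from the constant/reflect
border modes common in image libraries.  Because every structuring element
contains the origin, the clipped window is never empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StructuringElement",
    "SESequence",
    "square_se_sequence",
    "as_image",
    "is_binary",
    "erode",
    "dilate",
    "opening",
    "closing",
    "top_hats",
    "threshold",
]


def as_image(g) -> np.ndarray:
    """Validate and return ``g`` as a 2-D array of non-negative values."""
    arr = np.asarray(g)
    if arr.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {arr.shape}")
    if arr.size and arr.min() < 0:
        raise ValueError("image values must be non-negative")
    return arr


def is_binary(g) -> bool:
    """True when the value set of ``g`` is contained in {0, 1}."""
    arr = np.asarray(g)
    return bool(np.isin(arr, (0, 1)).all())


def _require_binary(g) -> np.ndarray:
    arr = as_image(g)
    if not is_binary(arr):
        raise ValueError("expected a binary image with values in {0, 1}")
    return arr


@dataclass(frozen=True)
class StructuringElement:
    """A finite set of integer offsets containing the origin.

    Parameters
    ----------
    offsets : iterable of (dx, dy)
        The flat structuring element B as a subset of Z^2.  ``(0, 0)`` must
        be a member, which guarantees non-empty clipped windows.
    """

    offsets: frozenset = field()

    def __init__(self, offsets):
        offs = frozenset((int(dx), int(dy)) for dx, dy in offsets)
        if (0, 0) not in offs:
            raise ValueError("structuring element must contain the origin (0, 0)")
        object.__setattr__(self, "offsets", offs)

    @property
    def symmetric(self) -> bool:
        """True when B = -B."""
        return self.offsets == {(-dx, -dy) for dx, dy in self.offsets}

    def reflect(self) -> "StructuringElement":
        """The reflection -B over the origin."""
        return StructuringElement((-dx, -dy) for dx, dy in self.offsets)

    def issubset(self, other: "StructuringElement") -> bool:
        return self.offsets <= other.offsets

    def __len__(self) -> int:
        return len(self.offsets)

    def __iter__(self):
        return iter(sorted(self.offsets))

    def to_json(self) -> list:
        return [list(o) for o in sorted(self.offsets)]

    @classmethod
    def from_json(cls, data) -> "StructuringElement":
        return cls(tuple(o) for o in data)

    @classmethod
    def square(cls, k: int) -> "StructuringElement":
        """A k x k square of offsets anchored per the alternating-corner rule.

        Equivalent to the (k-1)-th element of :func:`square_se_sequence`.
        """
        if k < 1:
            raise ValueError("square side must be >= 1")
        return square_se_sequence(k - 1)[k - 1]


IDENTITY_SE = StructuringElement([(0, 0)])


@dataclass(frozen=True)
class SESequence:
    """A nested sequence B_0 c B_1 c ... c B_n of structuring elements."""

    elements: tuple

    def __init__(self, elements):
        elems = tuple(elements)
        if not elems:
            raise ValueError("sequence must contain at least B_0")
        if elems[0].offsets != {(0, 0)}:
            raise ValueError("B_0 must be the singleton {(0, 0)}")
        for i in range(len(elems) - 1):
            if not elems[i].issubset(elems[i + 1]):
                raise ValueError(f"nestedness violated: B_{i} is not a subset of B_{i + 1}")
        object.__setattr__(self, "elements", elems)

    @property
    def n(self) -> int:
        """Maximal index (the sequence has n + 1 elements)."""
        return len(self.elements) - 1

    def __len__(self) -> int:
        return len(self.elements)

    def __getitem__(self, i: int) -> StructuringElement:
        return self.elements[i]

    def __iter__(self):
        return iter(self.elements)

    def subsequence(self, step: int) -> "SESequence":
        """The subsequence (B_0, B_step, B_2*step, ...), e.g. step=2 for the
        even-index squares used in coarser filtrations."""
        if step < 1:
            raise ValueError("step must be >= 1")
        return SESequence(self.elements[::step])


def square_se_sequence(n: int) -> SESequence:
    """The default sequence of (i+1) x (i+1) square structuring elements.

    B_0 = {(0, 0)}; each step glues a copy of the previous square shifted by
    +e1, +e2, +e1+e2 (odd steps) or -e1, -e2, -e1-e2 (even steps), so squares
    grow alternately toward the positive and negative quadrants and every
    even-index square is symmetric.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    seqs = [{(0, 0)}]
    for i in range(1, n + 1):
        prev = seqs[-1]
        sign = 1 if i % 2 == 1 else -1
        cur = set(prev)
        for sx, sy in ((sign, 0), (0, sign), (sign, sign)):
            cur |= {(dx + sx, dy + sy) for dx, dy in prev}
        seqs.append(cur)
    return SESequence(StructuringElement(s) for s in seqs)


def _windowed(g: np.ndarray, offsets, reducer) -> np.ndarray:
    """Pixelwise min/max of g over {x + b : b in offsets, x + b in P}.

    Initialised with g itself (the b = (0,0) term), then folded with each
    shifted copy restricted to the in-domain region.
    """
    h, w = g.shape
    out = g.copy()
    for dx, dy in offsets:
        if dx == 0 and dy == 0:
            continue
        x0, x1 = max(0, -dx), min(w, w - dx)
        y0, y1 = max(0, -dy), min(h, h - dy)
        if x0 >= x1 or y0 >= y1:
            continue
        reducer(
            out[y0:y1, x0:x1],
            g[y0 + dy : y1 + dy, x0 + dx : x1 + dx],
            out=out[y0:y1, x0:x1],
        )
    return out


def erode(g, se: StructuringElement) -> np.ndarray:
    """Erosion: value at x is the minimum of g over (x + B) n P."""
    return _windowed(as_image(g), se.offsets, np.minimum)


def dilate(g, se: StructuringElement) -> np.ndarray:
    """Dilation: value at x is the maximum of g over (x - B) n P.

    For symmetric B this coincides with the maximum over (x + B) n P.
    """
    neg = [(-dx, -dy) for dx, dy in se.offsets]
    return _windowed(as_image(g), neg, np.maximum)


def opening(g, se: StructuringElement) -> np.ndarray:
    """Opening O_B = dilation after erosion; anti-extensive: O_B(g) <= g."""
    return dilate(erode(g, se), se)


def closing(g, se: StructuringElement) -> np.ndarray:
    """Closing C_B = erosion after dilation; extensive: g <= C_B(g)."""
    return erode(dilate(g, se), se)


def top_hats(g, se: StructuringElement):
    """White, black, and self-complementary top-hat transforms.

    Returns ``(WTH, BTH, STH)`` with ``WTH = g - O_B(g)``,
    ``BTH = C_B(g) - g`` and ``STH = C_B(g) - O_B(g) = WTH + BTH``.  All three
    are non-negative because opening is anti-extensive and closing extensive;
    a negative entry would indicate an internal error and raises.
    """
    g = as_image(g)
    opened = opening(g, se)
    closed = closing(g, se)
    wth = g - opened
    bth = closed - g
    sth = closed - opened
    for name, t in (("WTH", wth), ("BTH", bth), ("STH", sth)):
        if t.size and t.min() < 0:
            raise AssertionError(f"{name} produced a negative value")
    return wth, bth, sth


def threshold(g, t) -> np.ndarray:
    """Global thresholding tau_t: 0 (black) where g <= t, else 1 (white).

    The black set of the result is the t-sublevel set of g.
    """
    g = as_image(g)
    return np.where(g <= t, 0, 1).astype(np.uint8)
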