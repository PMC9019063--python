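"""One- and multi-parameter filtrations built from morphological operators.

A filtration here is a nested sequence of black-pixel sets, represented by
the binary images that carry them.  For a binary image ``f`` and a nested
structuring-element sequence ``B_0 c ... c B_n``:

* the erosion filtration grows black sets with the SE index;
* the dilation and closing filtrations shrink black sets with the SE index
  and are therefore stored in reversed order (labels -n..0, or 0..n for the
  Y-relabelled closing filtration used by the denoiser);
* the opening filtration grows black sets with the SE index;
* top-hat 0-level sets shrink with the SE index and are stored reversed.

Opening and closing only yield nested level sets for SE sequences with the
shift-inclusion property; the default nested squares satisfy it, and
nestedness is asserted whenever a filtration is materialised so an invalid
sequence raises instead of feeding bad input to persistence.

Multi-parameter levels follow the unified-operator convention: an index
``i >= 0`` applies the shrinking family (e.g. opening), ``i < 0`` applies
the growing family at ``|i|`` (e.g. closing), and a multi-index applies its
entries right-to-left, so ``(-1, 1)`` means "open with B_1, then close with
B_1".  For alternating multi-indices the black sets are monotone in the
componentwise partial order, which is what makes nondecreasing paths
through the grid valid one-parameter filtrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import (
    SESequence,
    as_image,
    closing,
    dilate,
    erode,
    is_binary,
    opening,
    threshold,
    top_hats,
)

__all__ = [
    "OneParamFiltration",
    "MultiFiltrationSpec",
    "is_alternating",
    "erosion_filtration",
    "dilation_filtration",
    "opening_filtration",
    "closing_filtration",
    "tophat_filtrations",
    "sublevel_filtration",
    "alternating_apply",
    "grayscale_multifiltration_level",
    "nondecreasing_path",
]


def _require_binary(f) -> np.ndarray:
    f = as_image(f)
    if not is_binary(f):
        raise ValueError("filtration input must be a binary image")
    return f


@dataclass(frozen=True)
class OneParamFiltration:
    """Nested binary levels X_0 c X_1 c ... c X_n (black sets increasing).

    ``index_labels`` keeps the source convention (e.g. -n..0 for closing),
    ``provenance`` names the operator and SE index that produced each level.
    Positional indices 0..n are what persistence diagrams refer to.
    """

    levels: tuple
    index_labels: tuple = None
    provenance: tuple = None

    def __post_init__(self):
        levels = tuple(np.asarray(l) for l in self.levels)
        if not levels:
            raise ValueError("filtration needs at least one level")
        for i, l in enumerate(levels):
            if not is_binary(l):
                raise ValueError(f"level {i} is not binary")
        for i in range(len(levels) - 1):
            if np.any(levels[i + 1] > levels[i]):
                raise ValueError(
                    f"nestedness violated between levels {i} and {i + 1}: "
                    "the black set must not lose pixels"
                )
        object.__setattr__(self, "levels", levels)
        if self.index_labels is None:
            object.__setattr__(self, "index_labels", tuple(range(len(levels))))
        else:
            object.__setattr__(self, "index_labels", tuple(self.index_labels))
        if self.provenance is not None:
            object.__setattr__(self, "provenance", tuple(self.provenance))

    @property
    def n(self) -> int:
        return len(self.levels) - 1

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.levels[i]

    def black_set(self, i: int) -> np.ndarray:
        """Boolean mask of the black pixels of level i."""
        return self.levels[i] == 0

    def birth_array(self) -> np.ndarray:
        """Per-pixel first black level; n + 1 where white throughout."""
        return np.sum(np.stack(self.levels), axis=0, dtype=np.int64)

    def relabel(self, labels) -> "OneParamFiltration":
        """Same levels with new index labels (e.g. Y_i = X^C_{-(n-i)})."""
        return OneParamFiltration(self.levels, tuple(labels), self.provenance)


def erosion_filtration(f, seq: SESequence) -> OneParamFiltration:
    """Level i has black set erode(f, B_i)^-1(0); increasing in i."""
    f = _require_binary(f)
    return OneParamFiltration(
        tuple(erode(f, b) for b in seq),
        tuple(range(len(seq))),
        tuple(f"erosion:B_{i}" for i in range(len(seq))),
    )


def dilation_filtration(f, seq: SESequence) -> OneParamFiltration:
    """Dilation black sets shrink with the SE index, so the stored levels
    run j = -n..0 with black set dilate(f, B_|j|)^-1(0)."""
    f = _require_binary(f)
    n = seq.n
    return OneParamFiltration(
        tuple(dilate(f, seq[n - k]) for k in range(len(seq))),
        tuple(range(-n, 1)),
        tuple(f"dilation:B_{n - k}" for k in range(len(seq))),
    )


def opening_filtration(f, seq: SESequence) -> OneParamFiltration:
    """Level i has black set opening(f, B_i)^-1(0); increasing in i."""
    f = _require_binary(f)
    return OneParamFiltration(
        tuple(opening(f, b) for b in seq),
        tuple(range(len(seq))),
        tuple(f"opening:B_{i}" for i in range(len(seq))),
    )


def closing_filtration(f, seq: SESequence, relabel: bool = False) -> OneParamFiltration:
    """Closing black sets shrink with the SE index; stored reversed.

    Stored level k carries the black set of closing(f, B_{n-k}).  Labels are
    -n..0 by default; with ``relabel=True`` the Y-convention labels 0..n are
    used (Y_i = X^C_{-(n-i)}), which is the form the denoiser's dim-0
    selection rule reads.
    """
    f = _require_binary(f)
    n = seq.n
    labels = tuple(range(n + 1)) if relabel else tuple(range(-n, 1))
    return OneParamFiltration(
        tuple(closing(f, seq[n - k]) for k in range(len(seq))),
        labels,
        tuple(f"closing:B_{n - k}" for k in range(len(seq))),
    )


def tophat_filtrations(f, seq: SESequence) -> tuple:
    """White, black, and self-complementary top-hat filtrations.

    The 0-level sets of each transform shrink as the SE grows, so levels are
    stored with the SE index reversed (level k uses B_{n-k}).  At the last
    stored level (B_0) every transform is the zero image, whose 0-set is the
    whole domain.
    """
    f = _require_binary(f)
    n = seq.n
    wth, bth, sth = [], [], []
    for k in range(len(seq)):
        w, b, s = top_hats(f, seq[n - k])
        wth.append(threshold(w, 0))
        bth.append(threshold(b, 0))
        sth.append(threshold(s, 0))
    labels = tuple(range(-n, 1))
    return tuple(
        OneParamFiltration(
            tuple(levels),
            labels,
            tuple(f"{name}:B_{n - k}" for k in range(len(seq))),
        )
        for name, levels in (("wth", wth), ("bth", bth), ("sth", sth))
    )


def sublevel_filtration(g, thresholds) -> OneParamFiltration:
    """Sublevel-set filtration: level i has black set {x : g(x) <= t_i}."""
    g = as_image(g)
    ts = list(thresholds)
    if any(ts[i] > ts[i + 1] for i in range(len(ts) - 1)):
        raise ValueError("thresholds must be nondecreasing")
    return OneParamFiltration(
        tuple(threshold(g, t) for t in ts),
        tuple(range(len(ts))),
        tuple(f"sublevel:t={t}" for t in ts),
    )


# ---------------------------------------------------------------------------
# multi-parameter levels


@dataclass(frozen=True)
class MultiFiltrationSpec:
    """A pair of operator families indexed 0..n driving a multifiltration.

    ``e_op(i, g)`` is the family applied for positive multi-index entries
    (shrinks black sets as i grows, e.g. opening or erosion), ``d_op(i, g)``
    for negative entries (grows black sets, e.g. closing or dilation).  Both
    must be the identity at i = 0, order-preserving in the image, monotone
    in the index, and — when a threshold axis is used — commute with global
    thresholding.
    """

    e_op: callable = field(repr=False)
    d_op: callable = field(repr=False)
    n: int = 0
    name: str = ""

    def unified(self, i: int, g) -> np.ndarray:
        """M_i: the e-family for i >= 0, the d-family at |i| for i < 0."""
        if abs(i) > self.n:
            raise ValueError(f"index {i} outside -{self.n}..{self.n}")
        return self.e_op(i, g) if i >= 0 else self.d_op(-i, g)

    @classmethod
    def opening_closing(cls, seq: SESequence) -> "MultiFiltrationSpec":
        return cls(
            e_op=lambda i, g: opening(g, seq[i]),
            d_op=lambda i, g: closing(g, seq[i]),
            n=seq.n,
            name="opening/closing",
        )

    @classmethod
    def erosion_dilation(cls, seq: SESequence) -> "MultiFiltrationSpec":
        return cls(
            e_op=lambda i, g: erode(g, seq[i]),
            d_op=lambda i, g: dilate(g, seq[i]),
            n=seq.n,
            name="erosion/dilation",
        )


def is_alternating(u) -> bool:
    """True when consecutive entries have non-positive product."""
    u = tuple(u)
    return all(u[l] * u[l + 1] <= 0 for l in range(len(u) - 1))


def alternating_apply(
    g,
    u,
    spec: MultiFiltrationSpec,
    permissive: bool = False,
    memo: dict | None = None,
) -> np.ndarray:
    """Apply the composite operator M_u = M_{u_1} o ... o M_{u_k}.

    The multi-index is in composition order: the rightmost entry acts
    first, so ``u = (-1, 1)`` opens with B_1 and then closes with B_1.  The
    black set of the result is the multifiltration level X_u.  Non-
    alternating indices are rejected unless ``permissive`` is set (the
    containment property holds for them too, but alternation is the
    intended use).  ``memo`` optionally caches intermediate images keyed by
    the multi-index suffix already applied.
    """
    g = as_image(g)
    u = tuple(int(i) for i in u)
    if not permissive and not is_alternating(u):
        raise ValueError(f"multi-index {u} is not alternating")
    for i in u:
        if abs(i) > spec.n:
            raise ValueError(f"index {i} outside -{spec.n}..{spec.n}")
    if memo is not None and u in memo:
        return memo[u]
    out = g
    for pos in range(len(u) - 1, -1, -1):
        suffix = u[pos:]
        if memo is not None and suffix in memo:
            out = memo[suffix]
            continue
        out = spec.unified(u[pos], out)
        if memo is not None:
            memo[suffix] = out
    return out


def grayscale_multifiltration_level(
    g, t, u, spec: MultiFiltrationSpec, permissive: bool = False
) -> np.ndarray:
    """Black set X_{t,u} = tau_t(M_u(g))^-1(0) of the (k+1)-parameter
    filtration that adds a threshold axis; equals M_u(tau_t(g))^-1(0) when
    the operator families commute with thresholding."""
    m = alternating_apply(g, u, spec, permissive=permissive)
    return threshold(m, t) == 0


def nondecreasing_path(g, path, spec: MultiFiltrationSpec, permissive: bool = False):
    """One-parameter filtration along a componentwise-nondecreasing path of
    multi-indices; a non-monotone path raises."""
    path = [tuple(int(i) for i in u) for u in path]
    if not path:
        raise ValueError("path must contain at least one multi-index")
    k = len(path[0])
    for u in path:
        if len(u) != k:
            raise ValueError("all multi-indices on a path must share one length")
    for a, b in zip(path, path[1:]):
        if not all(x <= y for x, y in zip(a, b)):
            raise ValueError(f"path is not nondecreasing between {a} and {b}")
    memo: dict = {}
    levels = []
    for u in path:
        m = alternating_apply(g, u, spec, permissive=permissive, memo=memo)
        levels.append(threshold(m, 0))
    return OneParamFiltration(
        tuple(levels),
        tuple(range(len(levels))),
        tuple(f"{spec.name}:{u}" for u in path),
    )
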