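"""Persistence-guided alternating opening/closing denoising.

The binary denoiser walks a nondecreasing path through the opening/closing
multifiltration, letting persistence diagrams choose each structuring
element.  A closing step reads the dim-0 diagram of the (relabelled)
closing filtration: essential births measure how much closing removes each
black component, and the rule

    i_c = (n + 1) - max{b : (b, n + 1) in P0}

picks the minimal closing that erases at least one smallest-scale black
feature.  An opening step reads the dim-1 diagram of the opening filtration
of the current image: deaths of holes born at level 0 measure hole sizes,
and

    i_o = min{d : (0, d) in P1, d <= n}

picks the minimal opening that fills at least one smallest white hole.
Only finite deaths qualify — an essential hole's death n + 1 indexes no
structuring element and the corresponding opening would be vacuous.

The iteration alternates closing and opening selections, starting with
closing.  A phase whose diagram offers no qualifying pair is skipped (the
other operator may still have work to do: pepper clusters are typically
exhausted before salt clusters, or vice versa), and the run stops when a
selected index exceeds ``size_tol`` (the preset upper bound on the noise
scale), when a full closing+opening round applies nothing, or after
``max_iter`` selections.  Each selection — applied, skipped, or stopping —
counts as one iteration.

Grayscale images are denoised threshold-by-threshold: every global
threshold t in 0..255 yields a binary image that is denoised independently,
and the outputs are summed (for the identity denoiser this reconstructs the
input exactly, since a pixel of value v is white in exactly v of the 256
thresholded images).  The per-threshold outputs need not be nested, so the
sum can reach 256 at pixels denoised to white at every threshold; the 8-bit
output is clamped to 255 and the raw sum is available on request.  RGB
images are processed channel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filtrations import closing_filtration, opening_filtration
from .morphology import (
    SESequence,
    as_image,
    closing,
    is_binary,
    opening,
    square_se_sequence,
    threshold,
)
from .persistence import PersistenceDiagram, persistence

__all__ = [
    "DenoiseParams",
    "DenoiseTrace",
    "select_closing_index",
    "select_opening_index",
    "denoise_binary",
    "denoise_grayscale",
    "denoise_rgb",
]


@dataclass(frozen=True)
class DenoiseParams:
    """Knobs of the alternating denoiser.

    size_tol : largest admissible SE index; selections above it stop the run.
    max_iter : maximum number of selections (closing or opening alike).
    se_sequence : nested SE sequence; defaults to the unit-step squares of
        length size_tol + 1 (so n = size_tol).  A coarser even-step sequence
        can be passed instead, e.g. ``square_se_sequence(2 * k).subsequence(2)``.
    """

    size_tol: int = 5
    max_iter: int = 10
    se_sequence: SESequence = None

    def __post_init__(self):
        if self.size_tol < 0:
            raise ValueError("size_tol must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.se_sequence is None:
            object.__setattr__(self, "se_sequence", square_se_sequence(self.size_tol))
        if self.size_tol > self.se_sequence.n:
            raise ValueError("size_tol exceeds the SE sequence length")


@dataclass
class DenoiseTrace:
    """Record of one binary denoising run.

    ``steps`` lists applied operations in application order with the sign
    convention of the composite-operator indices: negative entries are
    closings (C_{B_|i|}), positive entries openings (O_{B_i}).  Reversing
    the list gives the composition-order multi-index of the composite
    operator that maps the input to the output.
    """

    steps: list = field(default_factory=list)
    selections: list = field(default_factory=list)  # (kind, index or None)
    diagrams: list = field(default_factory=list)
    stop_reason: str = ""

    def as_multi_index(self) -> tuple:
        """Composition-order multi-index (rightmost entry acts first)."""
        return tuple(reversed(self.steps))

    def to_json(self) -> dict:
        return {
            "steps_application_order": list(self.steps),
            "multi_index": list(self.as_multi_index()),
            "selections": [[k, i] for k, i in self.selections],
            "stop_reason": self.stop_reason,
            "diagrams": [
                {"n": d.n, "pairs": [list(p) for p in d.pairs]} for d in self.diagrams
            ],
        }


def select_closing_index(diagram: PersistenceDiagram) -> int | None:
    """Closing index from the dim-0 diagram of a Y-relabelled closing
    filtration: (n + 1) - max essential birth, or None when no component is
    removable by any available closing (max birth 0 or no essential pair)."""
    births = [b for b, d in diagram.in_dim(0) if d == diagram.n + 1]
    if not births or max(births) == 0:
        return None
    return (diagram.n + 1) - max(births)


def select_opening_index(diagram: PersistenceDiagram) -> int | None:
    """Opening index from the dim-1 diagram of an opening filtration: the
    minimal finite death among holes born at level 0, or None."""
    deaths = [d for b, d in diagram.in_dim(1) if b == 0 and d <= diagram.n]
    if not deaths:
        return None
    return min(deaths)


def denoise_binary(f, params: DenoiseParams = None) -> tuple:
    """Alternating persistence-guided denoising of a binary image.

    Returns ``(denoised image, trace)``.
    """
    f = as_image(f)
    if not is_binary(f):
        raise ValueError("denoise_binary expects a binary image")
    if params is None:
        params = DenoiseParams()
    seq = params.se_sequence
    img = f.astype(np.uint8)
    trace = DenoiseTrace()
    iters = 0
    while not trace.stop_reason:
        progressed = False
        for phase in ("closing", "opening"):
            if iters >= params.max_iter:
                trace.stop_reason = "max-iter"
                break
            if phase == "closing":
                filt = closing_filtration(img, seq, relabel=True)
                diag = persistence(filt, dims=(0,))
                idx = select_closing_index(diag)
            else:
                filt = opening_filtration(img, seq)
                diag = persistence(filt, dims=(1,))
                idx = select_opening_index(diag)
            iters += 1
            trace.selections.append((phase, idx))
            trace.diagrams.append(diag)
            if idx is None:
                continue  # nothing this operator can remove; try the other
            if idx > params.size_tol:
                trace.stop_reason = "size-exceeded"
                break
            op = closing if phase == "closing" else opening
            img = op(img, seq[idx]).astype(np.uint8)
            trace.steps.append(-idx if phase == "closing" else idx)
            progressed = True
        if not trace.stop_reason and not progressed:
            trace.stop_reason = "degenerate-diagram"
    return img, trace


def denoise_grayscale(
    g,
    params: DenoiseParams = None,
    binary_denoiser=None,
    return_unclamped: bool = False,
):
    """Threshold-decomposition denoising of an 8-bit grayscale image.

    Each thresholded binary image g_t, t = 0..255, is denoised independently
    and the binary outputs are summed.  ``binary_denoiser`` may replace the
    default (it receives the binary image and the params and must return the
    denoised binary image); the identity reproduces the input exactly.
    Consecutive equal thresholded images reuse the previous result, which is
    a pure optimisation with bit-identical output.
    """
    g = as_image(g)
    if g.max(initial=0) > 255 or not np.issubdtype(np.asarray(g).dtype, np.integer):
        raise ValueError("expected an 8-bit image with integer values in 0..255")
    if params is None:
        params = DenoiseParams()
    if binary_denoiser is None:
        binary_denoiser = lambda b, p: denoise_binary(b, p)[0]
    total = np.zeros(g.shape, dtype=np.int64)
    prev_thresh = None
    prev_out = None
    for t in range(256):
        gt = threshold(g, t)
        if prev_thresh is not None and np.array_equal(gt, prev_thresh):
            out = prev_out
        else:
            out = np.asarray(binary_denoiser(gt, params), dtype=np.int64)
            prev_thresh, prev_out = gt, out
        total += out
    clamped = np.minimum(total, 255).astype(np.uint8)
    if return_unclamped:
        return clamped, total
    return clamped


def denoise_rgb(img, params: DenoiseParams = None) -> np.ndarray:
    """Channel-wise grayscale denoising of an 8-bit RGB image (H, W, 3)."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    channels = [denoise_grayscale(img[:, :, c], params) for c in range(3)]
    return np.stack(channels, axis=2)
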