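"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive: per-pixel double loops for the
morphological operators and GF(2) boundary-matrix ranks for Betti numbers,
so the production implementations are checked against code that shares
none of their machinery.
"""

from __future__ import annotations

import numpy as np


def naive_erode(g, offsets):
    """min over {g(x + b) : b in B, x + b in P}, by explicit loops."""
    g = np.asarray(g)
    h, w = g.shape
    out = np.empty_like(g)
    for y in range(h):
        for x in range(w):
            vals = [
                g[y + dy, x + dx]
                for dx, dy in offsets
                if 0 <= x + dx < w and 0 <= y + dy < h
            ]
            out[y, x] = min(vals)
    return out


def naive_dilate(g, offsets):
    """max over {g(x - b) : b in B, x - b in P}, by explicit loops."""
    g = np.asarray(g)
    h, w = g.shape
    out = np.empty_like(g)
    for y in range(h):
        for x in range(w):
            vals = [
                g[y - dy, x - dx]
                for dx, dy in offsets
                if 0 <= x - dx < w and 0 <= y - dy < h
            ]
            out[y, x] = max(vals)
    return out


def naive_opening(g, offsets):
    return naive_dilate(naive_erode(g, offsets), offsets)


def naive_closing(g, offsets):
    return naive_erode(naive_dilate(g, offsets), offsets)


def batch_erode(batch, offsets):
    """naive_erode vectorised over a stack of images (loops still run over
    every pixel and offset; only the image axis is vectorised)."""
    batch = np.asarray(batch)
    _, h, w = batch.shape
    out = np.empty_like(batch)
    for y in range(h):
        for x in range(w):
            vals = [
                batch[:, y + dy, x + dx]
                for dx, dy in offsets
                if 0 <= x + dx < w and 0 <= y + dy < h
            ]
            out[:, y, x] = np.minimum.reduce(vals)
    return out


def batch_dilate(batch, offsets):
    batch = np.asarray(batch)
    _, h, w = batch.shape
    out = np.empty_like(batch)
    for y in range(h):
        for x in range(w):
            vals = [
                batch[:, y - dy, x - dx]
                for dx, dy in offsets
                if 0 <= x - dx < w and 0 <= y - dy < h
            ]
            out[:, y, x] = np.maximum.reduce(vals)
    return out


# ---------------------------------------------------------------------------
# GF(2) linear-algebra Betti oracle over the filled-pixel cubical complex


def _gf2_rank(m: np.ndarray) -> int:
    m = (np.asarray(m, dtype=np.uint8) % 2).copy()
    rank = 0
    rows, cols = m.shape
    for c in range(cols):
        pivots = np.nonzero(m[rank:, c])[0]
        if pivots.size == 0:
            continue
        p = rank + pivots[0]
        m[[rank, p]] = m[[p, rank]]
        hits = np.nonzero(m[:, c])[0]
        hits = hits[hits != rank]
        m[hits] ^= m[rank]
        rank += 1
        if rank == rows:
            break
    return rank


def rank_betti(x) -> tuple:
    """(beta_0, beta_1) of the black set via boundary-matrix ranks over Z/2.

    Builds the filled-pixel complex explicitly: each black pixel is a closed
    unit square with its 4 edges and 4 vertices.
    """
    x = np.asarray(x)
    black = x == 0
    h, w = black.shape
    verts, edges, squares = {}, {}, []
    for r in range(h):
        for c in range(w):
            if not black[r, c]:
                continue
            vs = [(r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)]
            es = [("h", r, c), ("h", r + 1, c), ("v", r, c), ("v", r, c + 1)]
            for v in vs:
                verts.setdefault(v, len(verts))
            for e in es:
                edges.setdefault(e, len(edges))
            squares.append(es)
    nv, ne, ns = len(verts), len(edges), len(squares)
    if nv == 0:
        return 0, 0
    d1 = np.zeros((nv, ne), dtype=np.uint8)
    for e, j in edges.items():
        kind, r, c = e
        a, b = ((r, c), (r, c + 1)) if kind == "h" else ((r, c), (r + 1, c))
        d1[verts[a], j] = 1
        d1[verts[b], j] = 1
    d2 = np.zeros((ne, ns), dtype=np.uint8)
    for j, es in enumerate(squares):
        for e in es:
            d2[edges[e], j] = 1
    r1 = _gf2_rank(d1) if ne else 0
    r2 = _gf2_rank(d2) if ns else 0
    beta0 = nv - r1
    beta1 = (ne - r1) - r2
    return beta0, beta1
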