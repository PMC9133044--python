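"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by exhaustive computation on small
inputs, through a codepath disjoint from the package implementation.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy import ndimage

_SQ2 = float(np.sqrt(2.0))
_N8 = np.ones((3, 3), bool)


# -- shortest path ----------------------------------------------------------

def shortest_path_oracle(cost: np.ndarray, eps: float, p0, p1):
    """Exhaustive shortest path on the full 8-connected pixel graph (networkx).

    Edge weights mirror the declared metric: trapezoidal line integral of
    (cost + eps) with diagonal steps weighted sqrt(2).
    """
    ny, nx_ = cost.shape
    g = nx.Graph()
    for r in range(ny):
        for c in range(nx_):
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < ny and 0 <= cc < nx_:
                    step = 1.0 if dr * dc == 0 else _SQ2
                    w = ((cost[r, c] + cost[rr, cc]) / 2 + eps) * step
                    g.add_edge((r, c), (rr, cc), weight=w)
    length, path = nx.single_source_dijkstra(g, tuple(p0), tuple(p1))
    return length, path


def path_cost(cost: np.ndarray, eps: float, points2d: np.ndarray) -> float:
    """Re-sum a path's accumulated cost left-to-right under the same metric."""
    total = 0.0
    pts = np.asarray(points2d)
    for a, b in zip(pts[:-1], pts[1:]):
        step = 1.0 if (a[0] == b[0] or a[1] == b[1]) else _SQ2
        total += ((cost[a[0], a[1]] + cost[b[0], b[1]]) / 2 + eps) * step
    return total


# -- prominence maxima ------------------------------------------------------

def _regional_max_plateaus(img: np.ndarray):
    """All plateaus (connected equal-value components) with no higher neighbor."""
    out = []
    for v in np.unique(img):
        lab, n = ndimage.label(img == v, structure=_N8)
        for k in range(1, n + 1):
            comp = lab == k
            ring = ndimage.binary_dilation(comp, structure=_N8) & ~comp
            if not (img[ring] > v).any():
                idx = np.flatnonzero(comp.ravel())
                out.append({"value": float(v), "mask": comp, "key": int(idx.min())})
    return out


def plateau_prominences(img: np.ndarray):
    """Prominence of every regional-max plateau by threshold descent.

    A plateau is killed at the highest threshold level at which its connected
    component of ``img >= level`` contains a beating plateau (higher summit,
    or an equal summit with smaller minimum linear index); prominence =
    summit - kill level (infinite for never-beaten summits).
    """
    img = np.asarray(img, dtype=float)
    plateaus = _regional_max_plateaus(img)
    levels = np.unique(img)[::-1]
    for m in plateaus:
        prom = np.inf
        for lev in levels:
            if lev > m["value"]:
                continue
            lab, _ = ndimage.label(img >= lev, structure=_N8)
            comp = lab == lab[m["mask"]][0]
            beaten = any(
                comp[o["mask"]].any()
                and (
                    o["value"] > m["value"]
                    or (o["value"] == m["value"] and o["key"] < m["key"])
                )
                for o in plateaus
                if o is not m
            )
            if beaten:
                prom = m["value"] - lev
                break
        m["prominence"] = prom
    return plateaus


def prominence_maxima_oracle(
    img: np.ndarray, noise_tolerance: float, exclude_edge: bool, plateaus=None
):
    """Expected maxima (plateau centroids, x = col order) for one tolerance.

    Reported iff prominence >= tolerance (and > 0). Edge exclusion drops
    maxima whose component of ``img >= summit - tolerance`` touches the
    border.
    """
    img = np.asarray(img, dtype=float)
    if plateaus is None:
        plateaus = plateau_prominences(img)
    results = []
    for m in plateaus:
        prom = m["prominence"]
        if not (prom >= noise_tolerance and prom > 0):
            continue
        if exclude_edge:
            lab, _ = ndimage.label(img >= m["value"] - noise_tolerance, structure=_N8)
            comp = lab == lab[m["mask"]][0]
            if comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any():
                continue
        rows, cols = np.nonzero(m["mask"])
        results.append((cols.mean(), rows.mean()))
    return sorted(results)


def strict_local_maxima(img: np.ndarray):
    """All strict 8-neighborhood local maxima of an image without ties."""
    out = []
    ny, nx_ = img.shape
    for r in range(ny):
        for c in range(nx_):
            v = img[r, c]
            nb = img[max(0, r - 1): r + 2, max(0, c - 1): c + 2]
            if (nb < v).sum() == nb.size - 1:
                out.append((float(c), float(r)))
    return sorted(out)


# -- Ripley K ---------------------------------------------------------------

def ripley_k_bruteforce(points: np.ndarray, window, r_grid) -> np.ndarray:
    """Uncorrected K by the literal double sum over all ordered pairs."""
    x0, y0, x1, y1 = window
    area = (x1 - x0) * (y1 - y0)
    n = len(points)
    out = np.zeros(len(r_grid))
    for ri, r in enumerate(r_grid):
        s = 0
        for i in range(n):
            for j in range(n):
                if i != j and np.hypot(*(points[i] - points[j])) <= r:
                    s += 1
        out[ri] = area * s / (n * (n - 1))
    return out


# -- Phansalkar -------------------------------------------------------------

def phansalkar_bruteforce(img, radius, k=0.25, r=0.5, p=2.0, q=10.0):
    """Per-pixel evaluation with explicit symmetric padding and disk scan."""
    img = np.asarray(img, dtype=float)
    pad = np.pad(img, radius, mode="symmetric")
    offs = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    ny, nx_ = img.shape
    mask = np.zeros((ny, nx_), bool)
    for rr in range(ny):
        for cc in range(nx_):
            vals = np.array([pad[rr + radius + dr, cc + radius + dc] for dr, dc in offs])
            m = vals.mean()
            s = vals.std()
            t = m * (1 + p * np.exp(-q * m) + k * (s / r - 1))
            mask[rr, cc] = img[rr, cc] > t
    return mask
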