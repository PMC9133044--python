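"""Spatial statistics for stained-cell point patterns.

Implements the mast-cell analysis chain: prominence-based local-maxima
detection with edge exclusion (ImageJ "Find Maxima" semantics: a peak is kept
when its prominence — height above the highest saddle connecting it to a
higher peak — reaches the noise tolerance), quadrat counts with a normality
test per animal, Ripley's K-function with translation edge correction and
Monte-Carlo CSR envelopes, and densities in cells/mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "PointPattern",
    "QuadratGrid",
    "RipleyEnvelope",
    "find_maxima",
    "quadrat_counts",
    "quadrat_normality",
    "ripley_k",
    "csr_envelope",
    "density",
]

_NEIGH8 = np.ones((3, 3), bool)


@dataclass
class PointPattern:
    """Calibrated planar point set in a rectangular observation window (µm)."""

    points: np.ndarray
    window: tuple[float, float, float, float]  # (x0, y0, x1, y1) µm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        x0, y0, x1, y1 = self.window
        if x1 <= x0 or y1 <= y0:
            raise ValueError("window must have positive area")
        if len(self.points):
            inside = (
                (self.points[:, 0] >= x0) & (self.points[:, 0] <= x1)
                & (self.points[:, 1] >= y0) & (self.points[:, 1] <= y1)
            )
            if not inside.all():
                raise ValueError("points must lie inside the window")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.window
        return (x1 - x0) * (y1 - y0)


@dataclass
class QuadratGrid:
    """Per-quadrat point counts over an equal-rectangle partition."""

    rows: int
    cols: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.rows, self.cols):
            raise ValueError("counts shape must be (rows, cols)")


@dataclass
class RipleyEnvelope:
    """Observed K̂(r) with a pointwise Monte-Carlo CSR envelope."""

    r: np.ndarray
    k_obs: np.ndarray
    k_lo: np.ndarray
    k_hi: np.ndarray
    n_sims: int
    seed: int | None
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        inside = (self.k_obs >= self.k_lo) & (self.k_obs <= self.k_hi)
        self.verdict = "random" if bool(inside.all()) else "non_random"


# --------------------------------------------------------------------------
# prominence-flood maxima detection
# --------------------------------------------------------------------------

class _Regions:
    """Union-find over pixels carrying per-region peak metadata."""

    def __init__(self, n: int):
        self.parent = np.arange(n)
        self.peak_val: dict[int, float] = {}
        self.peak_pixels: dict[int, list[int]] = {}
        self.peak_key: dict[int, int] = {}  # min linear index of the peak plateau

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def union(self, winner: int, loser: int) -> None:
        self.parent[loser] = winner


def find_maxima(
    img: np.ndarray,
    noise_tolerance: float = 35.0,
    exclude_edge: bool = True,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> PointPattern:
    """Detect local maxima whose prominence reaches ``noise_tolerance``.

    Pixels are flooded in descending intensity order. When the region growing
    from a lower peak meets one growing from a higher peak, the lower peak's
    prominence is its height above that meeting (saddle) level: it is reported
    as a maximum if the prominence is at least the tolerance and silently
    merged otherwise. Equal-height peaks are ordered by the smallest linear
    index of their summit plateau. Plateau maxima are reported at the plateau
    centroid. With ``exclude_edge``, a maximum is dropped when its accepting
    region — the connected component of ``img >= peak - tolerance`` containing
    its summit — touches the image border.

    Returns a :class:`PointPattern` with positions in µm
    (``x = col * spacing[0]``, ``y = row * spacing[1]``) over the image extent.
    """
    if noise_tolerance < 0:
        raise ValueError("noise_tolerance must be >= 0")
    img = np.asarray(img, dtype=float)
    ny, nx = img.shape
    flat = img.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))  # descending value, then index
    reg = _Regions(flat.size)
    in_flood = np.zeros(flat.size, bool)
    accepted: list[tuple[float, list[int]]] = []  # (peak value, summit pixels)

    def neighbors(i: int):
        r, c = divmod(i, nx)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < ny and 0 <= cc < nx:
                    yield rr * nx + cc

    def beats(a: int, b: int) -> bool:
        """Does region-root a outrank region-root b?"""
        if reg.peak_val[a] != reg.peak_val[b]:
            return reg.peak_val[a] > reg.peak_val[b]
        return reg.peak_key[a] < reg.peak_key[b]

    for i in order:
        v = flat[i]
        roots = []
        for j in neighbors(i):
            if in_flood[j]:
                r = reg.find(j)
                if r not in roots:
                    roots.append(r)
        in_flood[i] = True
        if not roots:
            reg.peak_val[i] = v
            reg.peak_pixels[i] = [i]
            reg.peak_key[i] = i
            continue
        # rank the meeting regions; the best one survives
        best = roots[0]
        for r in roots[1:]:
            if beats(r, best):
                best = r
        for r in roots:
            if r == best:
                continue
            prom = reg.peak_val[r] - v
            if prom == 0 and reg.peak_val[best] == v:
                # fragments of one summit plateau meeting at their own level
                reg.peak_pixels[best].extend(reg.peak_pixels[r])
                reg.peak_key[best] = min(reg.peak_key[best], reg.peak_key[r])
            elif prom >= noise_tolerance and prom > 0:
                accepted.append((reg.peak_val[r], reg.peak_pixels[r]))
            reg.union(best, r)
        reg.parent[i] = best
        if v == reg.peak_val[best]:
            # still at summit level: extend the plateau
            reg.peak_pixels[best].append(i)
            reg.peak_key[best] = min(reg.peak_key[best], i)

    # regions never beaten survive as maxima
    seen = set()
    for i in order:
        r = reg.find(i)
        if r not in seen:
            seen.add(r)
            accepted.append((reg.peak_val[r], reg.peak_pixels[r]))

    pts = []
    for peak, pix in accepted:
        pix_arr = np.asarray(sorted(pix))
        rows, cols = np.divmod(pix_arr, nx)
        if exclude_edge:
            lab, _ = ndimage.label(img >= peak - noise_tolerance, structure=_NEIGH8)
            region = lab == lab[rows[0], cols[0]]
            if region[0, :].any() or region[-1, :].any() or region[:, 0].any() or region[:, -1].any():
                continue
        pts.append((cols.mean() * spacing[0], rows.mean() * spacing[1]))
    window = (0.0, 0.0, (nx - 1) * spacing[0] + 1e-9, (ny - 1) * spacing[1] + 1e-9)
    return PointPattern(points=np.array(pts).reshape(-1, 2), window=window)


# --------------------------------------------------------------------------
# quadrats
# --------------------------------------------------------------------------

def quadrat_counts(p: PointPattern, rows: int = 5, cols: int = 5) -> QuadratGrid:
    """Count points in an equal rows x cols partition of the window.

    Cells are half-open on their right/top edges except the last row/column,
    so every point is counted exactly once. ``counts[0, 0]`` is the cell at
    the window's (x0, y0) corner.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    x0, y0, x1, y1 = p.window
    h, _, _ = np.histogram2d(
        p.points[:, 1] if p.n else np.empty(0),
        p.points[:, 0] if p.n else np.empty(0),
        bins=[rows, cols],
        range=[[y0, y1], [x0, x1]],
    )
    return QuadratGrid(rows=rows, cols=cols, counts=h.astype(int))


def quadrat_normality(grid: QuadratGrid, method: str = "shapiro") -> float:
    """Normality p-value of the flattened quadrat counts.

    Shapiro–Wilk by default (D'Agostino K² via ``method="dagostino"``).
    p > 0.05 does not support rejecting the hypothesis that counts are
    Gaussian. Identical counts make the test undefined: returns NaN.
    """
    x = grid.counts.ravel().astype(float)
    if x.size < 3:
        raise ValueError("need at least 3 quadrats")
    if np.ptp(x) == 0:
        return float("nan")
    if method == "shapiro":
        return float(stats.shapiro(x).pvalue)
    if method == "dagostino":
        return float(stats.normaltest(x).pvalue)
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# Ripley's K
# --------------------------------------------------------------------------

def ripley_k(
    p: PointPattern,
    r_grid: np.ndarray | None = None,
    correction: str = "translation",
) -> tuple[np.ndarray, np.ndarray]:
    """Ripley's K-function estimate on a rectangular window.

    ``K̂(r) = (A / (n (n-1))) Σ_{i≠j} e_ij 1(d_ij <= r)`` with the translation
    edge-correction weight ``e_ij = A / ((W - |Δx|)(H - |Δy|))`` (exact for
    rectangles) or ``e_ij = 1`` for ``correction="none"``. Under CSR,
    ``E K(r) = π r²``. Returns ``(r_grid, k_hat)``.
    """
    if p.n < 2:
        raise ValueError("ripley_k needs at least 2 points")
    x0, y0, x1, y1 = p.window
    W, H = x1 - x0, y1 - y0
    if r_grid is None:
        r_grid = np.linspace(0, min(W, H) / 4, 50)[1:]
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.ndim != 1 or np.any(r_grid <= 0) or np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be positive and ascending")
    pts = p.points
    dxs = np.abs(pts[:, 0][:, None] - pts[:, 0][None, :])
    dys = np.abs(pts[:, 1][:, None] - pts[:, 1][None, :])
    d = np.hypot(dxs, dys)
    iu = np.triu_indices(p.n, k=1)
    d, dxs, dys = d[iu], dxs[iu], dys[iu]
    if correction == "translation":
        w = (W * H) / ((W - dxs) * (H - dys))
    elif correction == "none":
        w = np.ones_like(d)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    # cumulative weighted pair counts on the grid (each unordered pair twice)
    order = np.argsort(d)
    d_sorted, w_sorted = d[order], 2 * w[order]
    cum = np.concatenate([[0.0], np.cumsum(w_sorted)])
    counts = cum[np.searchsorted(d_sorted, r_grid, side="right")]
    area = p.area
    k = area * counts / (p.n * (p.n - 1))
    return r_grid, k


def csr_envelope(
    p: PointPattern,
    n_sims: int = 100,
    r_grid: np.ndarray | None = None,
    seed: int | None = None,
    correction: str = "translation",
) -> RipleyEnvelope:
    """Monte-Carlo CSR envelope test for spatial randomness.

    Simulates ``n_sims`` binomial (fixed-n CSR) patterns with the observed
    point count in the observed window, computes K̂ for each, and takes the
    pointwise min/max as the envelope. Verdict is "random" iff the observed
    K̂ stays inside the band at every distance.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    x0, y0, x1, y1 = p.window
    if r_grid is None:
        r_grid = np.linspace(0, min(x1 - x0, y1 - y0) / 4, 50)[1:]
    r_grid, k_obs = ripley_k(p, r_grid, correction=correction)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sims, len(r_grid)))
    for s in range(n_sims):
        pts = np.column_stack(
            [rng.uniform(x0, x1, p.n), rng.uniform(y0, y1, p.n)]
        )
        _, sims[s] = ripley_k(PointPattern(pts, p.window), r_grid, correction=correction)
    return RipleyEnvelope(
        r=r_grid,
        k_obs=k_obs,
        k_lo=sims.min(axis=0),
        k_hi=sims.max(axis=0),
        n_sims=n_sims,
        seed=seed,
    )


def density(p: PointPattern, area_mm2: float | None = None) -> float:
    """Point density in cells per mm² (window area by default)."""
    if area_mm2 is None:
        area_mm2 = p.area / 1e6  # µm² -> mm²
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return p.n / area_mm2
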