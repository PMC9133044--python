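"""Synthetic phantoms with exact ground truth.

Generates (i) 3D stacks of tubular branching neurite networks emulating
Tubb3-stained whole-mount meninges imaged at 1.14 x 1.14 µm² in-plane and
1 µm z-step, (ii) planar point patterns (CSR, Thomas-clustered, hard-core,
fixed-n) emulating dural mast-cell positions, and (iii) 2D blob images
emulating toluidine-blue cell stains. Every generator is a pure function of
(spec, seed) and returns exact ground truth alongside the rendered data, so
every downstream stage of the package is testable without any microscope
download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .enhance import ImageStack3D
from .pointstats import PointPattern

__all__ = [
    "NeuriteTruth",
    "ImagingSpec",
    "PointProcessSpec",
    "NeuriteGeometry",
    "sample_neurite_tree",
    "rasterize_neurites",
    "make_neurite_phantom",
    "straight_tube_truth",
    "y_tree_truth",
    "make_point_pattern",
    "render_blob_image",
]


# --------------------------------------------------------------------------
# specs and ground truth containers
# --------------------------------------------------------------------------

def _polyline_length(poly: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())


@dataclass
class NeuriteTruth:
    """Exact geometry of a phantom neurite tree.

    ``polylines`` holds one (N, 3) µm array per tree edge (x, y, z order).
    ``endpoints`` are termini incident to exactly one polyline;
    ``branch_points`` are termini shared by three or more polylines.
    """

    polylines: list[np.ndarray]
    radii: list[float]
    branch_points: np.ndarray
    endpoints: np.ndarray

    def __post_init__(self) -> None:
        self.polylines = [np.asarray(p, dtype=float) for p in self.polylines]
        self.radii = [float(r) for r in self.radii]
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if len(self.radii) != len(self.polylines):
            raise ValueError("one radius per polyline required")
        self.branch_points = np.asarray(self.branch_points, dtype=float).reshape(-1, 3)
        self.endpoints = np.asarray(self.endpoints, dtype=float).reshape(-1, 3)

    @property
    def total_length(self) -> float:
        """Sum of segment lengths over all polylines, in µm."""
        return float(sum(_polyline_length(p) for p in self.polylines))

    @classmethod
    def from_polylines(
        cls, polylines: list[np.ndarray], radii: list[float] | float
    ) -> "NeuriteTruth":
        """Derive endpoint/branch-point sets from polyline termini.

        Termini closer than 1e-6 µm are treated as the same node.
        """
        polylines = [np.asarray(p, dtype=float) for p in polylines]
        if np.isscalar(radii):
            radii = [float(radii)] * len(polylines)
        termini: list[np.ndarray] = []
        for p in polylines:
            termini.append(p[0])
            termini.append(p[-1])
        termini_arr = np.array(termini)
        # cluster identical termini
        used = np.zeros(len(termini_arr), bool)
        endpoints, branch_points = [], []
        for i in range(len(termini_arr)):
            if used[i]:
                continue
            d = np.linalg.norm(termini_arr - termini_arr[i], axis=1)
            grp = d < 1e-6
            used |= grp
            deg = int(grp.sum())
            if deg == 1:
                endpoints.append(termini_arr[i])
            elif deg >= 3:
                branch_points.append(termini_arr[i])
        return cls(
            polylines=polylines,
            radii=list(radii),
            branch_points=np.array(branch_points).reshape(-1, 3),
            endpoints=np.array(endpoints).reshape(-1, 3),
        )


@dataclass
class ImagingSpec:
    """Acquisition model: voxel grid, PSF and noise.

    Defaults match the acquisition geometry of the emulated confocal data
    (1.14 x 1.14 µm² in-plane pixels, 1 µm z-step).
    """

    voxel_spacing: tuple[float, float, float] = (1.14, 1.14, 1.0)
    psf_sigma: float = 1.0
    background_level: float = 10.0
    gaussian_sd: float = 0.0
    poisson_scale: float = 0.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must be positive")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


@dataclass
class PointProcessSpec:
    """Point-pattern generator spec: CSR null or clustered/regular alternatives."""

    kind: str = "csr"  # csr | thomas | hardcore | fixed_n
    window: tuple[float, float, float, float] = (0.0, 0.0, 3700.0, 2400.0)
    intensity: float | None = None  # points per µm²
    n: int | None = None
    parent_intensity: float | None = None  # parents per µm² (thomas)
    offspring_mean: float | None = None  # mean offspring per parent (thomas)
    cluster_sigma: float | None = None  # offspring dispersion, µm (thomas)
    hardcore_radius: float | None = None  # µm (hardcore)
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.window
        if x1 <= x0 or y1 <= y0:
            raise ValueError("window must have positive area")
        if self.kind not in ("csr", "thomas", "hardcore", "fixed_n"):
            raise ValueError(f"unknown point process kind {self.kind!r}")
        if self.kind == "thomas" and (
            self.parent_intensity is None
            or self.offspring_mean is None
            or self.cluster_sigma is None
        ):
            raise ValueError("thomas requires parent_intensity, offspring_mean, cluster_sigma")


# --------------------------------------------------------------------------
# neurite tree sampling
# --------------------------------------------------------------------------

@dataclass
class NeuriteGeometry:
    """Sampler parameters for random binary neurite trees.

    The tree grows in the xy plane with a gentle random z-wander, one straight
    segment per tree edge, a bounded in-plane branching angle and segment
    lengths drawn uniformly from ``segment_len_um``. ``n_endpoints`` counts
    the root terminus plus all leaves.
    """

    shape_px: tuple[int, int, int] = (6, 160, 160)  # (nz, ny, nx)
    n_endpoints: int | tuple[int, int] = (3, 6)
    segment_len_um: tuple[float, float] = (45.0, 70.0)
    branch_angle_deg: tuple[float, float] = (25.0, 50.0)
    wander_deg: float = 10.0
    radius_um: float = 2.0
    margin_um: float = 12.0
    min_clearance_um: float = 12.0  # between non-adjacent branches
    z_frac: tuple[float, float] = (0.3, 0.7)  # z range as fraction of depth


def _unit(theta: float) -> np.ndarray:
    return np.array([np.cos(theta), np.sin(theta)])


def _branches_clear(polylines: list[np.ndarray], clearance: float) -> bool:
    """True when all pairs of branches not sharing a terminus keep apart.

    Keeps phantom branches separated in the xy projection by more than the
    tube + PSF support, so the rendered tree has the same 2D topology as the
    truth (no spurious crossings).
    """
    if clearance <= 0 or len(polylines) < 2:
        return True
    samples = []
    for poly in polylines:
        a, b = poly[0, :2], poly[-1, :2]
        n = max(2, int(np.ceil(np.linalg.norm(b - a) / 2.0)) + 1)
        t = np.linspace(0, 1, n)[:, None]
        samples.append(a + t * (b - a))
    for i in range(len(polylines)):
        for j in range(i + 1, len(polylines)):
            ti = {tuple(np.round(polylines[i][k, :2], 6)) for k in (0, -1)}
            tj = {tuple(np.round(polylines[j][k, :2], 6)) for k in (0, -1)}
            d = np.linalg.norm(
                samples[i][:, None, :] - samples[j][None, :, :], axis=2
            )
            if ti & tj:
                continue  # adjacent branches meet at the shared node by design
            if d.min() < clearance:
                return False
    return True


def sample_neurite_tree(
    geom: NeuriteGeometry,
    imaging: ImagingSpec,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> NeuriteTruth:
    """Draw a random binary tree inside the stack extent.

    Rejection-samples whole trees until one fits inside the margins; raises
    after ``max_tries`` failures (geometry incompatible with stack bounds).
    """
    nz, ny, nx = geom.shape_px
    dx, dy, dz = imaging.voxel_spacing
    ext_x, ext_y, ext_z = (nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz
    m = geom.margin_um
    if ext_x <= 2 * m or ext_y <= 2 * m:
        raise ValueError("stack extent smaller than twice the margin")
    ne = geom.n_endpoints
    for _ in range(max_tries):
        n_end = int(rng.integers(ne[0], ne[1] + 1)) if not np.isscalar(ne) else int(ne)
        if n_end < 2:
            raise ValueError("need at least 2 endpoints")
        n_leaves = n_end - 1
        root = np.array(
            [
                rng.uniform(m, ext_x - m),
                rng.uniform(m, ext_y - m),
            ]
        )
        # aim the trunk at the window center so trees tend to stay inside
        center = np.array([ext_x / 2, ext_y / 2])
        aim = center - root
        theta0 = np.arctan2(aim[1], aim[0]) + rng.uniform(-0.5, 0.5)
        z0 = rng.uniform(geom.z_frac[0] * ext_z, geom.z_frac[1] * ext_z) if ext_z > 0 else 0.0
        # active tips: (position2d, z, direction angle)
        tips = [(root, z0, theta0)]
        splits_left = n_leaves - 1
        polylines: list[np.ndarray] = []
        ok = True
        # grow one segment per tip per round; split random tips between rounds
        while tips:
            new_tips = []
            for pos, z, theta in tips:
                L = rng.uniform(*geom.segment_len_um)
                theta = theta + np.deg2rad(rng.uniform(-geom.wander_deg, geom.wander_deg))
                end = pos + L * _unit(theta)
                z_end = float(
                    np.clip(z + rng.uniform(-2.0, 2.0), 0.15 * ext_z, 0.85 * ext_z)
                ) if ext_z > 0 else 0.0
                if not (m <= end[0] <= ext_x - m and m <= end[1] <= ext_y - m):
                    ok = False
                    break
                polylines.append(
                    np.array([[pos[0], pos[1], z], [end[0], end[1], z_end]])
                )
                if splits_left > 0 and rng.random() < 0.6:
                    splits_left -= 1
                    a = np.deg2rad(rng.uniform(*geom.branch_angle_deg))
                    new_tips.append((end, z_end, theta + a / 2))
                    new_tips.append((end, z_end, theta - a / 2))
                elif splits_left > 0 and len(new_tips) == 0 and len(tips) == 1:
                    # lone tip must eventually split
                    splits_left -= 1
                    a = np.deg2rad(rng.uniform(*geom.branch_angle_deg))
                    new_tips.append((end, z_end, theta + a / 2))
                    new_tips.append((end, z_end, theta - a / 2))
                else:
                    # terminate this tip as a leaf unless splits remain and
                    # no other tip can take them
                    pass
            if not ok:
                break
            tips = new_tips
            if splits_left > 0 and not tips:
                ok = False  # ran out of tips before placing all branches
                break
        if ok and len(polylines) == 2 * n_leaves - 1:
            if not _branches_clear(polylines, geom.min_clearance_um):
                continue
            truth = NeuriteTruth.from_polylines(polylines, geom.radius_um)
            if len(truth.endpoints) == n_end:
                return truth
    raise RuntimeError("could not fit a tree inside the stack bounds; "
                       "increase shape_px or relax the geometry")


def straight_tube_truth(
    length_um: float = 200.0,
    radius_um: float = 2.0,
    start_um: tuple[float, float, float] = (10.0, 20.0, 2.0),
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0),
) -> NeuriteTruth:
    """A single straight tube of prescribed length (two endpoints)."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    p0 = np.asarray(start_um, float)
    p1 = p0 + length_um * d
    return NeuriteTruth.from_polylines([np.array([p0, p1])], radius_um)


def y_tree_truth(
    branch_len_um: float = 100.0,
    radius_um: float = 2.0,
    origin_um: tuple[float, float, float] = (20.0, 110.0, 2.0),
) -> NeuriteTruth:
    """A Y-shaped tree: three branches meeting at one junction."""
    o = np.asarray(origin_um, float)
    j = o + np.array([branch_len_um, 0, 0])
    a = j + branch_len_um * np.array([np.cos(0.5), np.sin(0.5), 0.0])
    b = j + branch_len_um * np.array([np.cos(0.5), -np.sin(0.5), 0.0])
    return NeuriteTruth.from_polylines(
        [np.array([o, j]), np.array([j, a]), np.array([j, b])], radius_um
    )


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------

def rasterize_neurites(
    truth: NeuriteTruth,
    imaging: ImagingSpec,
    shape_px: tuple[int, int, int],
    amplitude: float = 100.0,
    seed: int | None = 0,
) -> ImageStack3D:
    """Render a truth tree into a noisy stack.

    Voxels whose center lies within the tube radius of any polyline get the
    foreground amplitude; the binary tube is blurred with a Gaussian PSF,
    a constant background is added, then Gaussian read noise and optional
    Poisson shot noise. Deterministic for a fixed seed.
    """
    nz, ny, nx = shape_px
    dx, dy, dz = imaging.voxel_spacing
    max_r = max(truth.radii)
    for p in truth.polylines:
        if (
            p[:, 0].min() < 0 or p[:, 0].max() > (nx - 1) * dx
            or p[:, 1].min() < 0 or p[:, 1].max() > (ny - 1) * dy
            or p[:, 2].min() < 0 or p[:, 2].max() > (nz - 1) * dz
        ):
            raise ValueError("neurite geometry exceeds stack bounds")

    # dense samples along every polyline, tagged with the tube radius
    step = 0.5 * min(dx, dy, dz)
    samples, radii = [], []
    for poly, r in zip(truth.polylines, truth.radii):
        for a, b in zip(poly[:-1], poly[1:]):
            seg = np.linalg.norm(b - a)
            n = max(2, int(np.ceil(seg / step)) + 1)
            t = np.linspace(0, 1, n)[:, None]
            samples.append(a + t * (b - a))
            radii.append(np.full(n, r))
    samples = np.vstack(samples)
    radii = np.concatenate(radii)
    tree = cKDTree(samples)

    zz, yy, xx = np.meshgrid(
        np.arange(nz) * dz, np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij"
    )
    coords = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    dist, idx = tree.query(coords, workers=-1)
    fg = (dist <= radii[idx]).reshape(nz, ny, nx)

    img = fg.astype(float) * amplitude
    if imaging.psf_sigma > 0:
        sig = (imaging.psf_sigma / dz, imaging.psf_sigma / dy, imaging.psf_sigma / dx)
        img = ndimage.gaussian_filter(img, sigma=sig)
    img += imaging.background_level
    rng = np.random.default_rng(seed)
    if imaging.poisson_scale > 0:
        img = rng.poisson(np.maximum(img, 0) * imaging.poisson_scale) / imaging.poisson_scale
    if imaging.gaussian_sd > 0:
        img = img + rng.normal(0, imaging.gaussian_sd, img.shape)
    maxval = 2 ** imaging.bit_depth - 1
    img = np.clip(img, 0, maxval)
    return ImageStack3D(img, spacing=imaging.voxel_spacing, bit_depth=imaging.bit_depth)


def make_neurite_phantom(
    geom: NeuriteGeometry,
    imaging: ImagingSpec | None = None,
    seed: int = 0,
    amplitude: float = 100.0,
) -> tuple[ImageStack3D, NeuriteTruth]:
    """Sample a random tree and render it (pure function of geometry + seed)."""
    imaging = imaging or ImagingSpec()
    rng = np.random.default_rng(seed)
    truth = sample_neurite_tree(geom, imaging, rng)
    stack = rasterize_neurites(
        truth, imaging, geom.shape_px, amplitude=amplitude, seed=int(rng.integers(2**31))
    )
    return stack, truth


# --------------------------------------------------------------------------
# point patterns
# --------------------------------------------------------------------------

def make_point_pattern(spec: PointProcessSpec) -> PointPattern:
    """Simulate a planar point pattern per the spec.

    kinds: ``csr`` (homogeneous Poisson: Poisson count, uniform positions),
    ``fixed_n`` (binomial process), ``thomas`` (Poisson parents, Gaussian
    offspring; parents drawn in a 4-sigma buffer so the pattern is
    edge-stationary), ``hardcore`` (sequential inhibition, minimum distance).
    """
    rng = np.random.default_rng(spec.seed)
    x0, y0, x1, y1 = spec.window
    w, h = x1 - x0, y1 - y0
    area = w * h

    def uniform(n: int) -> np.ndarray:
        return np.column_stack(
            [rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)]
        )

    if spec.kind == "fixed_n":
        if spec.n is None:
            raise ValueError("fixed_n requires n")
        pts = uniform(int(spec.n))
    elif spec.kind == "csr":
        if spec.intensity is None:
            raise ValueError("csr requires intensity")
        pts = uniform(int(rng.poisson(spec.intensity * area)))
    elif spec.kind == "thomas":
        buf = 4 * spec.cluster_sigma
        bw, bh = w + 2 * buf, h + 2 * buf
        n_par = rng.poisson(spec.parent_intensity * bw * bh)
        parents = np.column_stack(
            [rng.uniform(x0 - buf, x1 + buf, n_par), rng.uniform(y0 - buf, y1 + buf, n_par)]
        )
        pts_list = []
        for p in parents:
            k = rng.poisson(spec.offspring_mean)
            if k:
                pts_list.append(p + rng.normal(0, spec.cluster_sigma, (k, 2)))
        pts = np.vstack(pts_list) if pts_list else np.empty((0, 2))
        inside = (
            (pts[:, 0] >= x0) & (pts[:, 0] <= x1)
            & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
        )
        pts = pts[inside]
    else:  # hardcore
        if spec.n is None or spec.hardcore_radius is None:
            raise ValueError("hardcore requires n and hardcore_radius")
        accepted: list[np.ndarray] = []
        tries = 0
        while len(accepted) < spec.n and tries < 10000 * spec.n:
            cand = uniform(1)[0]
            tries += 1
            if all(np.linalg.norm(cand - q) >= spec.hardcore_radius for q in accepted):
                accepted.append(cand)
        pts = np.array(accepted).reshape(-1, 2)
    return PointPattern(points=pts, window=spec.window)


def render_blob_image(
    pattern: PointPattern,
    blob_sigma: float = 8.0,
    peak: float = 100.0,
    imaging: ImagingSpec | None = None,
    seed: int | None = 0,
) -> np.ndarray:
    """Render one Gaussian blob per point onto the window's pixel grid.

    The image extent is the pattern window divided by the in-plane pixel
    size; pixel (row, col) sits at µm position
    ``(x0 + col*dx, y0 + row*dy)``. Returns a float image of shape (ny, nx).
    """
    imaging = imaging or ImagingSpec()
    dx, dy = imaging.voxel_spacing[0], imaging.voxel_spacing[1]
    x0, y0, x1, y1 = pattern.window
    nx = int(np.floor((x1 - x0) / dx)) + 1
    ny = int(np.floor((y1 - y0) / dy)) + 1
    img = np.zeros((ny, nx))
    sx, sy = blob_sigma / dx, blob_sigma / dy
    half = int(np.ceil(4 * max(sx, sy)))
    for x, y in pattern.points:
        cx, cy = (x - x0) / dx, (y - y0) / dy
        if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
            raise ValueError("point outside image extent")
        r0, r1 = max(0, int(cy) - half), min(ny, int(cy) + half + 2)
        c0, c1 = max(0, int(cx) - half), min(nx, int(cx) + half + 2)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += peak * np.exp(
            -(((cc - cx) / sx) ** 2 + ((rr - cy) / sy) ** 2) / 2
        )
    img += imaging.background_level
    rng = np.random.default_rng(seed)
    if imaging.gaussian_sd > 0:
        img = img + rng.normal(0, imaging.gaussian_sd, img.shape)
    return np.clip(img, 0, 2 ** imaging.bit_depth - 1)
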