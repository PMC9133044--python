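"""Cohort orchestration: innervation and mast-cell analyses plus group stats.

Runs the two analysis tracks over a cohort (groups of subjects, one or more
replicate images per subject and side), averages left/right hemiskull
replicates per subject, compares groups per metric (Student's t or
Mann–Whitney U, Bonferroni-adjusted across the metric family) and emits a
deterministic JSON-serializable report.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from . import coverage as cov
from . import graph as graphmod
from . import pointstats as ps
from . import synthgen, trace
from .enhance import enhance_stack

logger = logging.getLogger("duratrace")

__all__ = [
    "ComparisonResult",
    "compare_groups",
    "run_innervation_pipeline",
    "run_mastcell_pipeline",
]


@dataclass
class ComparisonResult:
    """Two-group comparison of one metric."""

    metric: str
    groups: dict  # name -> {mean, sem, median, iqr, n}
    test: str
    statistic: float
    p_value: float
    adjusted_p: float


def _summary(x: np.ndarray) -> dict:
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "mean": float(np.mean(x)),
        "sem": float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
        "median": float(np.median(x)),
        "iqr": float(q3 - q1),
        "n": int(len(x)),
    }


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    test: str = "auto",
    n_comparisons: int = 1,
    metric: str = "",
) -> ComparisonResult:
    """Two-sample group comparison with Bonferroni adjustment.

    ``test="t"`` is the unpaired pooled-variance Student's t-test,
    ``"mann_whitney"`` the two-sided Mann–Whitney U. ``"auto"`` picks t when
    both groups pass Shapiro–Wilk at alpha = 0.05, else Mann–Whitney.
    ``adjusted_p = min(1, n_comparisons * p)``.
    """
    if len(values_by_group) != 2:
        raise ValueError("exactly two groups required")
    (na, a), (nb, b) = [(k, np.asarray(v, float)) for k, v in values_by_group.items()]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if test == "auto":
        normal = all(
            len(x) >= 3 and np.ptp(x) > 0 and stats.shapiro(x).pvalue > 0.05
            for x in (a, b)
        )
        test = "t" if normal else "mann_whitney"
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no within-group variance at all
        stat, p = (0.0, 1.0) if a[0] == b[0] else (float("inf"), 0.0)
    elif test == "t":
        res = stats.ttest_ind(a, b, equal_var=True)
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonResult(
        metric=metric,
        groups={na: _summary(a), nb: _summary(b)},
        test=test,
        statistic=stat,
        p_value=p,
        adjusted_p=min(1.0, n_comparisons * p),
    )


# --------------------------------------------------------------------------
# innervation track
# --------------------------------------------------------------------------

def _analyze_innervation_image(
    stack, truth, scales, contour_params, coverage_metrics, bit_depth
) -> dict:
    """Enhance, trace root -> every endpoint, build graph, measure coverage."""
    enh = enhance_stack(stack, scales=scales)
    dx, dy, _ = stack.spacing
    ny, nx = enh.P.shape

    def to_px(pt):
        return (
            int(np.clip(round(pt[1] / dy), 0, ny - 1)),
            int(np.clip(round(pt[0] / dx), 0, nx - 1)),
        )

    root = to_px(truth.endpoints[0])
    traces = []
    for ep in truth.endpoints[1:]:
        seeds = trace.SeedPair(root, to_px(ep))
        traces.append(
            trace.trace_axon(enh, seeds, stack, contour_params=contour_params)
        )
    g = graphmod.build_graph(traces)
    out = graphmod.graph_metrics(g)
    if coverage_metrics:
        mip = stack.voxels.max(axis=0)
        maxval = 2**bit_depth - 1
        mask = cov.phansalkar_threshold(mip / maxval)
        cr = cov.coverage_stats(mip, mask)
        out["percent_area"] = cr.percent_area
        out["mean_gray"] = cr.mean_gray
        spot_set = cov.detect_spots(
            mip, spacing=(dx, dy), intensity_scale=maxval, background_subtraction=False
        )
        window = (0.0, 0.0, (nx - 1) * dx + 1e-9, (ny - 1) * dy + 1e-9)
        if len(spot_set.spots) >= 3:
            grid = ps.quadrat_counts(spot_set.to_pattern(window), 10, 10)
            out["spot_grid_normality_p"] = ps.quadrat_normality(grid)
        else:
            out["spot_grid_normality_p"] = float("nan")
    return out


def run_innervation_pipeline(config: dict) -> dict:
    """Innervation analysis over a synthetic cohort.

    ``config`` keys: ``seed``; ``groups`` (name -> {"n_subjects": int,
    optional "geometry" overrides}); ``geometry`` (NeuriteGeometry fields);
    ``imaging`` (ImagingSpec fields); ``replicates_per_subject``;
    ``scales`` (vesselness scales, px); ``metrics`` (defaults to total
    length + endpoint count); ``coverage`` (bool: add %-area / mean gray /
    spot-grid metrics); ``alpha``.
    """
    rng = np.random.default_rng(config.get("seed", 0))
    scales = tuple(config.get("scales", (1.0, 2.0)))
    metrics = list(config.get("metrics", ["total_length", "endpoint_count"]))
    coverage_on = bool(config.get("coverage", False))
    reps = int(config.get("replicates_per_subject", 1))
    contour_params = config.get("contour_params")
    imaging = synthgen.ImagingSpec(**config.get("imaging", {}))
    alpha = float(config.get("alpha", 0.05))

    if "images" in config:
        return _run_innervation_images(config, scales, contour_params, coverage_on, alpha)

    per_subject: dict[str, dict[str, list]] = {}
    per_image = []
    for gname, gcfg in config["groups"].items():
        geo_kwargs = dict(config.get("geometry", {}))
        geo_kwargs.update(gcfg.get("geometry", {}))
        for key in ("shape_px", "n_endpoints", "segment_len_um", "branch_angle_deg", "z_frac"):
            if key in geo_kwargs and isinstance(geo_kwargs[key], list):
                geo_kwargs[key] = tuple(geo_kwargs[key])
        geom = synthgen.NeuriteGeometry(**geo_kwargs)
        for si in range(int(gcfg["n_subjects"])):
            sid = f"{gname}_{si:02d}"
            vals: dict[str, list] = {m: [] for m in metrics}
            for ri in range(reps):
                seed = int(rng.integers(2**31))
                stack, truth = synthgen.make_neurite_phantom(geom, imaging, seed=seed)
                res = _analyze_innervation_image(
                    stack, truth, scales, contour_params, coverage_on, imaging.bit_depth
                )
                res.update(
                    {"subject": sid, "group": gname, "replicate": ri, "seed": seed,
                     "truth_total_length": truth.total_length,
                     "truth_endpoints": len(truth.endpoints)}
                )
                per_image.append(res)
                for m in metrics:
                    vals[m].append(res[m])
            per_subject.setdefault(gname, {}).setdefault(sid, {})
            per_subject[gname][sid] = {
                m: float(np.nanmean(v)) for m, v in vals.items()
            }

    comparisons = _compare_all(per_subject, metrics)
    return {
        "analysis": "innervation",
        "alpha": alpha,
        "per_image": per_image,
        "per_subject": per_subject,
        "comparisons": comparisons,
    }


def _run_innervation_images(
    config, scales, contour_params, coverage_on, alpha
) -> dict:
    """Real-data mode: analyze listed TIFF stacks with seed CSVs.

    Each entry needs ``id``, ``group``, ``subject``, ``tiff`` and
    ``seeds_csv`` (columns ``axon_id,x0,y0,x1,y1``, pixel units, x = column).
    Images without a readable seed file are skipped with a warning.
    """
    import pandas as pd

    from . import io as dio

    metrics = list(config.get("metrics", ["total_length", "endpoint_count"]))
    per_subject: dict[str, dict[str, dict]] = {}
    subject_vals: dict[tuple[str, str], dict[str, list]] = {}
    per_image, skipped = [], []
    for entry in config["images"]:
        try:
            seeds_df = pd.read_csv(entry["seeds_csv"])
        except (OSError, KeyError):
            logger.warning("no seeds for image %s: skipped", entry.get("id"))
            skipped.append(entry.get("id"))
            continue
        stack = dio.read_stack_tiff(entry["tiff"])
        enh = enhance_stack(stack, scales=scales)
        traces = []
        for _, row in seeds_df.iterrows():
            seeds = trace.SeedPair(
                (int(row["y0"]), int(row["x0"])), (int(row["y1"]), int(row["x1"]))
            )
            traces.append(trace.trace_axon(enh, seeds, stack, contour_params=contour_params))
        g = graphmod.build_graph(traces)
        res = graphmod.graph_metrics(g)
        if coverage_on:
            mip = stack.voxels.max(axis=0)
            maxval = 2**stack.bit_depth - 1
            mask = cov.phansalkar_threshold(mip / maxval)
            cr = cov.coverage_stats(mip, mask)
            res["percent_area"], res["mean_gray"] = cr.percent_area, cr.mean_gray
        res.update({"id": entry.get("id"), "group": entry["group"], "subject": entry["subject"]})
        per_image.append(res)
        key = (entry["group"], entry["subject"])
        subject_vals.setdefault(key, {m: [] for m in metrics})
        for m in metrics:
            subject_vals[key][m].append(res[m])
    for (gname, sid), vals in subject_vals.items():
        per_subject.setdefault(gname, {})[sid] = {
            m: float(np.nanmean(v)) for m, v in vals.items()
        }
    report = {
        "analysis": "innervation",
        "alpha": alpha,
        "per_image": per_image,
        "per_subject": per_subject,
        "skipped": skipped,
    }
    if len(per_subject) == 2 and all(len(v) >= 2 for v in per_subject.values()):
        report["comparisons"] = _compare_all(per_subject, metrics)
    return report


def _compare_all(per_subject: dict, metrics: list[str]) -> dict:
    gnames = list(per_subject)
    comparisons = {}
    for m in metrics:
        values = {
            g: np.array([per_subject[g][s][m] for s in per_subject[g]])
            for g in gnames
        }
        if any(np.isnan(v).any() for v in values.values()):
            values = {g: v[~np.isnan(v)] for g, v in values.items()}
        res = compare_groups(values, n_comparisons=len(metrics), metric=m)
        comparisons[m] = asdict(res)
    return comparisons


# --------------------------------------------------------------------------
# mast-cell track
# --------------------------------------------------------------------------

def run_mastcell_pipeline(config: dict) -> dict:
    """Mast-cell spatial analysis over a synthetic cohort.

    Per image: density (cells/mm²), 5x5 quadrat normality p, Ripley
    envelope verdict (100 CSR simulations). Left/right sides are averaged
    per subject before the group comparison. ``config`` keys: ``seed``,
    ``groups`` (name -> {"n_subjects", optional "pattern" overrides}),
    ``pattern`` (PointProcessSpec fields minus seed), ``window_um``
    (defaults to the 3.7 x 2.4 mm² ROI), ``sides``, ``n_sims``,
    ``quadrats``, ``envelope`` (bool), ``r_points``.
    """
    rng = np.random.default_rng(config.get("seed", 0))
    window = tuple(config.get("window_um", (0.0, 0.0, 3700.0, 2400.0)))
    sides = int(config.get("sides", 2))
    n_sims = int(config.get("n_sims", 100))
    rows, cols = config.get("quadrats", (5, 5))
    do_env = bool(config.get("envelope", True))
    r_points = int(config.get("r_points", 20))
    metrics = list(config.get("metrics", ["density", "quadrat_normality_p"]))

    x0, y0, x1, y1 = window
    r_grid = np.linspace(0, min(x1 - x0, y1 - y0) / 4, r_points + 1)[1:]

    per_subject: dict[str, dict[str, dict]] = {}
    per_image = []
    n_random = n_images = 0
    for gname, gcfg in config["groups"].items():
        pat_kwargs = dict(config.get("pattern", {}))
        pat_kwargs.update(gcfg.get("pattern", {}))
        for si in range(int(gcfg["n_subjects"])):
            sid = f"{gname}_{si:02d}"
            side_vals: dict[str, list] = {m: [] for m in metrics}
            for side in range(sides):
                seed = int(rng.integers(2**31))
                spec = synthgen.PointProcessSpec(window=window, seed=seed, **pat_kwargs)
                pat = synthgen.make_point_pattern(spec)
                res = {"subject": sid, "group": gname, "side": side, "seed": seed,
                       "n_points": pat.n}
                res["density"] = ps.density(pat)
                grid = ps.quadrat_counts(pat, rows, cols)
                res["quadrat_normality_p"] = ps.quadrat_normality(grid)
                if do_env and pat.n >= 2:
                    env = ps.csr_envelope(
                        pat, n_sims=n_sims, r_grid=r_grid,
                        seed=int(rng.integers(2**31)),
                    )
                    res["verdict"] = env.verdict
                    n_images += 1
                    n_random += env.verdict == "random"
                per_image.append(res)
                for m in metrics:
                    side_vals[m].append(res[m])
            per_subject.setdefault(gname, {})[sid] = {
                m: float(np.nanmean(v)) for m, v in side_vals.items()
            }

    comparisons = _compare_all(per_subject, metrics)
    report = {
        "analysis": "mastcells",
        "window_um": list(window),
        "per_image": per_image,
        "per_subject": per_subject,
        "comparisons": comparisons,
    }
    if n_images:
        report["fraction_random_verdicts"] = n_random / n_images
    return report
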