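"""Voxelwise selectivity statistics for digit maps.

Two statistics quantify how exclusively a voxel (or cluster) responds to
one digit:

Overall selectivity (OS)
    OS = max(z_D1, z_D2, z_D5) / (z_D1 + z_D2 + z_D5)

    Simple — no winner-takes-all step needed — but ill-behaved when
    non-dominant z-scores are negative: the denominator can approach
    zero, producing excessive values or a division by zero.  Voxels
    where not all three z-scores are positive (or the denominator is
    below a small epsilon) are therefore flagged as outliers; the
    default policy excludes them from ROI aggregates and always reports
    the flagged fraction.

Digit selectivity (DS)
    DS = 0.5 * ((z_dom - z_nd1) + (z_dom - z_nd2)) / z_dom
       = 1 - (z_nd1 + z_nd2) / (2 * z_dom)

    Evaluated per winner-takes-all cluster with that cluster's digit
    dominant.  Because the dominant z exceeds a positive threshold, the
    denominator is safe by construction.  DS = 1 iff both non-dominant
    responses are exactly zero; DS = 0 for a completely unselective
    voxel; negative z crosstalk can push DS above 1.

OS2 variant
    OS2 = max(z) / (|z_D1| + |z_D2| + |z_D5|)

    Finite wherever any z is nonzero; equals OS when all inputs are
    positive but can over- or under-state selectivity when signs mix.

A threshold sweep reruns the full mask → winner-takes-all → Dice →
OS/DS chain over a grid of z thresholds to check that conclusions do
not hinge on the choice of cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from digitsel.constants import DIGITS, DIGIT_PAIRS, LABEL_CODES
from digitsel.overlap import pairwise_overlap
from digitsel.roi import (
    DigitLabelMap,
    RoiMask,
    ZStatMapSet,
    activation_mask,
    digit_cluster_masks,
    winner_takes_all,
)

__all__ = [
    "DENOM_EPS",
    "OS_OUTLIER_POLICIES",
    "DS_AGGREGATIONS",
    "DEFAULT_SWEEP_THRESHOLDS",
    "SelectivityResult",
    "SweepResult",
    "overall_selectivity_voxel",
    "overall_selectivity_map",
    "overall_selectivity_roi",
    "digit_selectivity_voxel",
    "digit_selectivity_cluster",
    "os2_absolute_variant",
    "analyze_selectivity",
    "threshold_sweep",
]

#: float-safety guard for the OS denominator, far below any meaningful z
DENOM_EPS = 1e-9

OS_OUTLIER_POLICIES = ("exclude", "clamp", "raw")
DS_AGGREGATIONS = ("voxel-mean", "means-of-means")

#: default z-threshold grid for sensitivity sweeps
DEFAULT_SWEEP_THRESHOLDS = (2.0, 2.5, 3.0, 3.5, 4.0)


def overall_selectivity_voxel(
    z1: float, z2: float, z5: float, eps: float = DENOM_EPS
) -> tuple[float, bool]:
    """OS at a single voxel.

    Returns ``(value, flagged)``.  The voxel is flagged (value NaN) when
    any input is non-positive or the denominator is below ``eps`` — the
    regime where the ratio degenerates.
    """
    vals = np.array([z1, z2, z5], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("z-scores must be finite")
    s = vals.sum()
    if np.all(vals > 0) and s > eps:
        return float(vals.max() / s), False
    return float("nan"), True


def overall_selectivity_map(
    z: ZStatMapSet, act: np.ndarray, policy: str = "exclude", eps: float = DENOM_EPS
) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise OS over an activation mask.

    Returns ``(os_volume, outlier_flags)``; OS is NaN outside the mask.
    Policies:

    - ``exclude``: flagged voxels (any z <= 0 or |sum| <= eps) carry NaN.
    - ``raw``: compute max/sum wherever |sum| > eps, flags mark only the
      near-zero denominators — exposes the unbounded behaviour.
    - ``clamp``: as ``raw`` but values clipped into [1/3, 1].
    """
    if policy not in OS_OUTLIER_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {OS_OUTLIER_POLICIES}")
    act = np.asarray(act).astype(bool)
    if act.shape != z.shape:
        raise ValueError("mask shape does not match z maps")
    stacked = z.stacked
    s = stacked.sum(axis=0)
    mx = stacked.max(axis=0)

    degenerate = ~np.all(stacked > 0, axis=0) | (s <= eps)
    near_zero = np.abs(s) <= eps

    if policy == "exclude":
        flags = act & degenerate
        valid = act & ~degenerate
    else:
        flags = act & near_zero
        valid = act & ~near_zero

    with np.errstate(divide="ignore", invalid="ignore"):
        os_vol = np.where(valid, mx / np.where(valid, s, 1.0), np.nan)
    if policy == "clamp":
        os_vol = np.where(valid, np.clip(os_vol, 1.0 / 3.0, 1.0), os_vol)
    return os_vol, flags


def overall_selectivity_roi(
    z: ZStatMapSet, act: np.ndarray, policy: str = "exclude", eps: float = DENOM_EPS
) -> tuple[float, float]:
    """ROI-aggregate OS: mean of unflagged voxelwise OS over the mask.

    Returns ``(mean_os, outlier_fraction)``.  An empty activation mask
    is rejected; a mask where every voxel is flagged yields NaN with
    outlier fraction 1.
    """
    act = np.asarray(act).astype(bool)
    n_act = int(act.sum())
    if n_act == 0:
        raise ValueError("activation mask is empty")
    os_vol, flags = overall_selectivity_map(z, act, policy=policy, eps=eps)
    vals = os_vol[act]
    vals = vals[np.isfinite(vals)]
    frac = float(flags.sum()) / n_act
    if vals.size == 0:
        return float("nan"), frac
    return float(vals.mean()), frac


def digit_selectivity_voxel(z_dom: float, z_nd1: float, z_nd2: float) -> float:
    """DS at a single voxel with a given dominant digit.

    DS = 1 - (z_nd1 + z_nd2) / (2 z_dom); requires z_dom > 0, which is
    guaranteed in pipeline flow (the voxel passed a positive threshold
    and the dominant z is the maximum).
    """
    if not (z_dom > 0):
        raise ValueError("dominant z must be > 0")
    return float(1.0 - (z_nd1 + z_nd2) / (2.0 * z_dom))


def digit_selectivity_cluster(
    z: ZStatMapSet, labels: DigitLabelMap, aggregation: str = "voxel-mean"
) -> dict[str, float]:
    """DS per digit over its winner-takes-all cluster.

    ``voxel-mean`` (default) averages the voxelwise DS over the cluster;
    ``means-of-means`` applies the DS formula once to the cluster-mean
    z-scores.  Empty clusters map to NaN.
    """
    if aggregation not in DS_AGGREGATIONS:
        raise ValueError(
            f"unknown aggregation {aggregation!r}; choose from {DS_AGGREGATIONS}"
        )
    if labels.labels.shape != z.shape:
        raise ValueError("label map shape does not match z maps")
    out: dict[str, float] = {}
    for d in DIGITS:
        vox = labels.labels == LABEL_CODES[d]
        if not vox.any():
            out[d] = float("nan")
            continue
        z_dom = z.maps[d][vox]
        nds = [z.maps[m][vox] for m in DIGITS if m != d]
        if aggregation == "voxel-mean":
            ds = 1.0 - (nds[0] + nds[1]) / (2.0 * z_dom)
            out[d] = float(ds.mean())
        else:
            out[d] = digit_selectivity_voxel(
                float(z_dom.mean()), float(nds[0].mean()), float(nds[1].mean())
            )
    return out


def os2_absolute_variant(
    z1: float, z2: float, z5: float, eps: float = DENOM_EPS
) -> tuple[float, bool]:
    """Absolute-denominator OS variant: max(z) / (|z1| + |z2| + |z5|).

    Finite whenever any input is nonzero; all-zero input is flagged.
    Agrees with OS when every input is positive.
    """
    vals = np.array([z1, z2, z5], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("z-scores must be finite")
    denom = np.abs(vals).sum()
    if denom <= eps:
        return float("nan"), True
    return float(vals.max() / denom), False


@dataclass
class SelectivityResult:
    """Full selectivity readout for one (subject, region, contrast).

    ROI aggregates exclude flagged voxels under the default policy; the
    flagged fraction is always reported alongside.
    """

    os_map: np.ndarray
    outlier_flags: np.ndarray
    outlier_fraction: float
    os_roi: float
    ds: dict[str, float]
    n_active: int
    tie_count: int
    subject: str
    region: str
    contrast: str
    threshold: float


def analyze_selectivity(
    z: ZStatMapSet,
    roi: RoiMask,
    threshold: float,
    *,
    act: np.ndarray | None = None,
    os_outlier_policy: str = "exclude",
    ds_aggregation: str = "voxel-mean",
) -> SelectivityResult:
    """Run mask → winner-takes-all → OS/DS for one z-map set.

    ``act`` overrides the activation mask (used when ROI inclusion is a
    conjunction across contrasts); by default it is recomputed from
    ``z`` at the threshold.
    """
    if act is None:
        act = activation_mask(z, roi, threshold)
    labels = winner_takes_all(z, act, threshold=threshold, roi_region=roi.region)
    n_active = int(np.asarray(act).sum())
    if n_active > 0:
        os_roi, frac = overall_selectivity_roi(z, act, policy=os_outlier_policy)
        os_map, flags = overall_selectivity_map(z, act, policy=os_outlier_policy)
        ds = digit_selectivity_cluster(z, labels, aggregation=ds_aggregation)
    else:
        os_roi, frac = float("nan"), float("nan")
        os_map = np.full(z.shape, np.nan)
        flags = np.zeros(z.shape, dtype=bool)
        ds = {d: float("nan") for d in DIGITS}
    return SelectivityResult(
        os_map=os_map,
        outlier_flags=flags,
        outlier_fraction=frac,
        os_roi=os_roi,
        ds=ds,
        n_active=n_active,
        tie_count=labels.tie_count,
        subject=z.subject,
        region=roi.region,
        contrast=z.contrast,
        threshold=threshold,
    )


@dataclass
class SweepResult:
    """Threshold-sensitivity sweep output.

    ``frame`` holds one row per threshold with the OS aggregate, per-
    digit DS, per-pair Dice and the active voxel count (non-increasing
    in threshold).  Thresholds where nothing survives are flagged.
    """

    region: str
    contrast: str
    thresholds: tuple[float, ...]
    frame: pd.DataFrame


def threshold_sweep(
    z: ZStatMapSet,
    roi: RoiMask,
    thresholds=DEFAULT_SWEEP_THRESHOLDS,
    *,
    os_outlier_policy: str = "exclude",
    ds_aggregation: str = "voxel-mean",
) -> SweepResult:
    """Rerun the full pipeline over a grid of z thresholds.

    The grid must be non-empty and sorted ascending.  Each row reports
    the metrics at one threshold; duplicate thresholds yield identical
    rows (the pipeline is deterministic).
    """
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) == 0:
        raise ValueError("threshold list is empty")
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")

    rows = []
    for t in thresholds:
        res = analyze_selectivity(
            z,
            roi,
            t,
            os_outlier_policy=os_outlier_policy,
            ds_aggregation=ds_aggregation,
        )
        clusters = digit_cluster_masks(z, roi, t)
        ov = pairwise_overlap(clusters, region=roi.region, contrast=z.contrast)
        row = {
            "threshold": t,
            "n_active": res.n_active,
            "os": res.os_roi,
            "outlier_fraction": res.outlier_fraction,
            "empty": res.n_active == 0,
        }
        for d in DIGITS:
            row[f"ds_{d}"] = res.ds[d]
        for (d1, d2) in DIGIT_PAIRS:
            row[f"dice_{d1}-{d2}"] = ov.pairs[(d1, d2)].dice
        rows.append(row)
    frame = pd.DataFrame(rows)
    return SweepResult(
        region=roi.region, contrast=z.contrast, thresholds=thresholds, frame=frame
    )
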