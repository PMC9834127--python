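"""ROI activation masks, per-digit cluster masks, winner-takes-all labels.

A voxel enters the activation mask when it lies inside the region of
interest and its strongest digit response exceeds the z threshold
(strictly — "greater than", not "at least").  Per-digit cluster masks
threshold each digit's map separately and MAY overlap; quantifying that
overlap is exactly what the Dice/Jaccard metrics downstream do.  The
winner-takes-all step then assigns every active voxel to the digit with
the maximal z, yielding a non-overlapping parcellation.

Shape mismatches between volumes are always an error, never an implicit
resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from digitsel.constants import DIGITS, LABEL_CODES

__all__ = [
    "ZStatMapSet",
    "RoiMask",
    "DigitLabelMap",
    "activation_mask",
    "digit_cluster_masks",
    "winner_takes_all",
]


@dataclass
class ZStatMapSet:
    """Aligned per-digit z-score volumes for one (subject, contrast).

    ``maps`` holds one volume per digit (D1, D2, D5) on a shared grid.
    """

    maps: dict[str, np.ndarray]
    contrast: str
    subject: str = "unknown"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        missing = [d for d in DIGITS if d not in self.maps]
        if missing:
            raise ValueError(f"missing digit maps: {missing}")
        shapes = {d: np.shape(m) for d, m in self.maps.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"digit maps must share one shape, got {shapes}")
        for d in DIGITS:
            if not np.all(np.isfinite(self.maps[d])):
                raise ValueError(f"non-finite z values in map {d}")

    @property
    def shape(self) -> tuple[int, ...]:
        return np.shape(self.maps[DIGITS[0]])

    @property
    def stacked(self) -> np.ndarray:
        """(3, x, y, z) array in digit order D1, D2, D5."""
        return np.stack([self.maps[d] for d in DIGITS])


@dataclass
class RoiMask:
    """Boolean region-of-interest volume (e.g. M1 or S1).

    ``provenance`` records where the mask came from: ``"manual"`` for a
    hand-drawn anatomical mask, ``"synthetic-ribbon"`` for the simulated
    ground-truth support.
    """

    mask: np.ndarray
    region: str
    provenance: str = "manual"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)


@dataclass
class DigitLabelMap:
    """Winner-takes-all digit assignment: codes {0: unassigned, 1: D1,
    2: D2, 5: D5}.  ``tie_count`` tallies active voxels whose maximum z
    was shared by two or more digits (broken toward the lowest digit)."""

    labels: np.ndarray
    threshold: float
    roi_region: str
    tie_count: int = 0

    def digit_mask(self, digit: str) -> np.ndarray:
        return self.labels == LABEL_CODES[digit]

    @property
    def n_assigned(self) -> int:
        return int(np.count_nonzero(self.labels))


def _check_shapes(z: ZStatMapSet, roi: RoiMask) -> None:
    if roi.mask.shape != z.shape:
        raise ValueError(
            f"ROI shape {roi.mask.shape} does not match z maps {z.shape}; "
            "volumes must be pre-aligned (no implicit resampling)"
        )


def activation_mask(z: ZStatMapSet, roi: RoiMask, threshold: float) -> np.ndarray:
    """Voxels inside the ROI responding to at least one digit.

    Inclusion rule: max(z_D1, z_D2, z_D5) > threshold, strict.  An
    infinite threshold yields an empty (or full) mask; NaN is rejected.
    """
    if np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    _check_shapes(z, roi)
    return roi.mask & (z.stacked.max(axis=0) > threshold)


def digit_cluster_masks(
    z: ZStatMapSet, roi: RoiMask, threshold: float
) -> dict[str, np.ndarray]:
    """Suprathreshold mask per digit within the ROI; masks may overlap.

    The union of the three masks equals ``activation_mask`` at the same
    threshold (a definitional identity).
    """
    if np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    _check_shapes(z, roi)
    return {d: roi.mask & (z.maps[d] > threshold) for d in DIGITS}


def winner_takes_all(z: ZStatMapSet, act: np.ndarray, *,
                     threshold: float = float("nan"),
                     roi_region: str = "unknown") -> DigitLabelMap:
    """Assign each active voxel to the digit with the maximal z.

    Ties go to the lowest digit ordinal (D1 < D2 < D5) and are counted in
    ``tie_count``; inactive voxels stay 0.  The result partitions the
    activation mask.
    """
    act = np.asarray(act).astype(bool)
    if act.shape != z.shape:
        raise ValueError(f"mask shape {act.shape} does not match z maps {z.shape}")
    stacked = z.stacked
    win = np.argmax(stacked, axis=0)  # first max wins -> lowest digit ordinal
    codes = np.array([LABEL_CODES[d] for d in DIGITS])
    labels = np.where(act, codes[win], 0).astype(np.int16)
    n_at_max = np.sum(stacked == stacked.max(axis=0), axis=0)
    tie_count = int(np.count_nonzero(act & (n_at_max > 1)))
    return DigitLabelMap(
        labels=labels, threshold=threshold, roi_region=roi_region, tie_count=tie_count
    )
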