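"""Spatial overlap (Dice, Jaccard) and crosstalk between digit clusters.

Dice = 2|A∩B| / (|A| + |B|) and Jaccard = |A∩B| / |A∪B| are computed on
the overlapping per-digit threshold masks; the two are linked by the
identity J = D / (2 - D), which holds exactly on the stored voxel
counts.  When both masks are empty the coefficients are defined as 0 and
flagged, avoiding a spurious "perfect overlap" reading.

Crosstalk is measured on the winner-takes-all parcellation: within each
dominant digit's cluster, the mean z evoked by movement of every digit.
By construction of the argmax assignment the dominant digit's mean is
never below the others' (diagonal dominance); a violation means the
labels were not derived from the supplied z maps and is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from digitsel.constants import DIGITS, DIGIT_PAIRS, LABEL_CODES

__all__ = [
    "PairOverlap",
    "OverlapResult",
    "CrosstalkTable",
    "dice",
    "jaccard",
    "mask_counts",
    "pairwise_overlap",
    "crosstalk_table",
]


def _as_mask(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if a.dtype != bool:
        vals = np.unique(a)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} is not a binary mask")
        a = a.astype(bool)
    return a


def mask_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(|A|, |B|, |A∩B|) as exact integers."""
    a = _as_mask(a, "a")
    b = _as_mask(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return int(a.sum()), int(b.sum()), int((a & b).sum())


def dice(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Dice similarity coefficient and a both-empty flag."""
    na, nb, ni = mask_counts(a, b)
    if na + nb == 0:
        return 0.0, True
    return 2.0 * ni / (na + nb), False


def jaccard(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """Jaccard similarity coefficient and a both-empty flag."""
    na, nb, ni = mask_counts(a, b)
    union = na + nb - ni
    if union == 0:
        return 0.0, True
    return ni / union, False


@dataclass(frozen=True)
class PairOverlap:
    """Overlap of one digit-cluster pair, with the raw voxel counts."""

    pair: tuple[str, str]
    n_a: int
    n_b: int
    n_intersection: int
    both_empty: bool

    @property
    def dice(self) -> float:
        if self.both_empty:
            return 0.0
        return float(self.dice_exact)

    @property
    def jaccard(self) -> float:
        if self.both_empty:
            return 0.0
        return float(self.jaccard_exact)

    @property
    def dice_exact(self) -> Fraction:
        return Fraction(2 * self.n_intersection, self.n_a + self.n_b)

    @property
    def jaccard_exact(self) -> Fraction:
        return Fraction(self.n_intersection, self.n_a + self.n_b - self.n_intersection)


@dataclass
class OverlapResult:
    """Dice/Jaccard for the three digit pairs of one (region, contrast)."""

    region: str
    contrast: str
    pairs: dict[tuple[str, str], PairOverlap]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (d1, d2), po in self.pairs.items():
            rows.append(
                {
                    "region": self.region,
                    "contrast": self.contrast,
                    "pair": f"{d1}-{d2}",
                    "dice": po.dice,
                    "jaccard": po.jaccard,
                    "n_a": po.n_a,
                    "n_b": po.n_b,
                    "n_intersection": po.n_intersection,
                    "both_empty": po.both_empty,
                }
            )
        return pd.DataFrame(rows)


def pairwise_overlap(
    clusters: dict[str, np.ndarray], region: str = "unknown", contrast: str = "unknown"
) -> OverlapResult:
    """Dice and Jaccard for the pairs D1–D2, D1–D5, D2–D5."""
    missing = [d for d in DIGITS if d not in clusters]
    if missing:
        raise ValueError(f"missing digit cluster masks: {missing}")
    pairs = {}
    for d1, d2 in DIGIT_PAIRS:
        na, nb, ni = mask_counts(clusters[d1], clusters[d2])
        pairs[(d1, d2)] = PairOverlap(
            pair=(d1, d2),
            n_a=na,
            n_b=nb,
            n_intersection=ni,
            both_empty=(na + nb == 0),
        )
    return OverlapResult(region=region, contrast=contrast, pairs=pairs)


@dataclass
class CrosstalkTable:
    """Mean z of each digit's movement within each dominant-digit cluster.

    ``table`` is indexed by the dominant digit with one column per moved
    digit plus the cluster voxel count; empty clusters keep their row
    (means NaN) and are listed in ``empty_clusters``.
    """

    region: str
    contrast: str
    table: pd.DataFrame
    empty_clusters: tuple[str, ...]

    def mean_z(self, dominant: str, moved: str) -> float:
        return float(self.table.loc[dominant, moved])


def crosstalk_table(z, labels, region: str = "unknown") -> CrosstalkTable:
    """Average z-scores of dominant and non-dominant digits per cluster.

    For each dominant digit d, the row holds the mean of z_D1, z_D2 and
    z_D5 over the voxels labelled d in the winner-takes-all map.
    """
    if labels.labels.shape != z.shape:
        raise ValueError("label map shape does not match z maps")
    rows = {}
    empty = []
    for d in DIGITS:
        vox = labels.labels == LABEL_CODES[d]
        n = int(vox.sum())
        if n == 0:
            empty.append(d)
            rows[d] = {m: np.nan for m in DIGITS} | {"n_voxels": 0}
        else:
            rows[d] = {m: float(z.maps[m][vox].mean()) for m in DIGITS} | {
                "n_voxels": n
            }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "dominant"

    for d in DIGITS:
        if d in empty:
            continue
        dom = table.loc[d, d]
        others = [table.loc[d, m] for m in DIGITS if m != d]
        if any(dom < o - 1e-12 for o in others):
            raise ValueError(
                f"diagonal dominance violated for cluster {d}: the labels were "
                "not produced by winner-takes-all on these z maps"
            )
    return CrosstalkTable(
        region=region, contrast=z.contrast, table=table, empty_clusters=tuple(empty)
    )
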