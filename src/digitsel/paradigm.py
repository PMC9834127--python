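"""Block paradigm, HRF regressor, and a minimal voxelwise OLS GLM.

Plumbing that turns simulated 4-D time series into z-statistic maps.
The default paradigm is the classic paced finger-movement block design:
an initial rest baseline followed by repeated one-minute cycles of 30 s
movement and 30 s rest.  The GLM is ordinary least squares with a task
regressor (boxcar convolved with a canonical double-gamma HRF) and an
intercept; t statistics are converted to z scores by matching two-sided
tail probabilities.

Sign convention: CBV-weighted (VASO) acquisitions record activation as
signal *decreases*.  This module, and the synthetic route feeding it,
work in activation units where responses are positive for every
contrast.  When adapting real VASO time series, flip the sign (or negate
the resulting z maps) before using the downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "Paradigm",
    "DesignMatrix",
    "total_duration",
    "boxcar",
    "double_gamma_hrf",
    "build_regressor",
    "build_design_matrix",
    "fit_glm",
    "GlmResult",
]


@dataclass(frozen=True)
class Paradigm:
    """Block-design run timing.

    Attributes
    ----------
    baseline_s : initial rest duration in seconds.
    on_s : movement block duration.
    off_s : rest block duration.
    n_cycles : number of (on + off) repetitions.
    tr_s : repetition time (sampling interval of the volumes).
    """

    baseline_s: float = 30.0
    on_s: float = 30.0
    off_s: float = 30.0
    n_cycles: int = 10
    tr_s: float = 3.0

    def __post_init__(self) -> None:
        for name in ("baseline_s", "on_s", "off_s", "tr_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def total_duration_s(self) -> float:
        return total_duration(self)

    @property
    def n_frames(self) -> int:
        """Number of volumes in a run; requires the TR to tile the blocks."""
        self.check_tr_divides()
        return round(self.total_duration_s / self.tr_s)

    def check_tr_divides(self) -> None:
        for name in ("baseline_s", "on_s", "off_s"):
            dur = getattr(self, name)
            k = dur / self.tr_s
            if abs(k - round(k)) > 1e-9:
                raise ValueError(
                    f"TR ({self.tr_s} s) must divide every block duration; "
                    f"{name} = {dur} s is not a multiple"
                )


def total_duration(p: Paradigm) -> float:
    """Total run duration: baseline + n_cycles * (on + off), in seconds."""
    return p.baseline_s + p.n_cycles * (p.on_s + p.off_s)


def boxcar(p: Paradigm) -> np.ndarray:
    """Frame-sampled task indicator: 1 during movement blocks, 0 at rest."""
    n = p.n_frames
    t = np.arange(n) * p.tr_s
    box = np.zeros(n)
    cycle = p.on_s + p.off_s
    in_cycles = t >= p.baseline_s
    phase = np.mod(t - p.baseline_s, cycle)
    box[in_cycles & (phase < p.on_s)] = 1.0
    return box


def double_gamma_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Standard parameters: response peak at 6 s, undershoot peak at 16 s,
    peak-to-undershoot ratio 6, unit time constants.  Normalized to unit
    sum so convolution preserves the regressor's integral scale.
    """
    t = np.arange(0.0, duration_s + 1e-9, tr_s)
    peak = stats.gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    s = h.sum()
    if s != 0:
        h = h / s
    return h


def build_regressor(p: Paradigm, hrf_kind: str = "canonical-double-gamma") -> np.ndarray:
    """Task regressor: the boxcar, optionally convolved with the HRF.

    ``hrf_kind`` is ``"canonical-double-gamma"`` or ``"none"`` (raw
    boxcar).  Convolution is causal and the result is truncated to the
    run's frame count.
    """
    box = boxcar(p)
    if hrf_kind == "none":
        return box
    if hrf_kind == "canonical-double-gamma":
        h = double_gamma_hrf(p.tr_s)
        return np.convolve(box, h)[: box.size]
    raise ValueError(f"unknown hrf_kind {hrf_kind!r}")


@dataclass
class DesignMatrix:
    """OLS design: task regressor + intercept (+ optional linear drift)."""

    X: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def task_column(self) -> int:
        return self.labels.index("task")


def build_design_matrix(
    p: Paradigm,
    hrf_kind: str = "canonical-double-gamma",
    linear_drift: bool = False,
) -> DesignMatrix:
    reg = build_regressor(p, hrf_kind)
    cols = [reg, np.ones_like(reg)]
    labels = ["task", "intercept"]
    if linear_drift:
        cols.append(np.linspace(-1.0, 1.0, reg.size))
        labels.append("drift")
    return DesignMatrix(X=np.column_stack(cols), labels=tuple(labels))


@dataclass
class GlmResult:
    """z map plus the degenerate-fit flag volume."""

    z: np.ndarray
    variance_zero: np.ndarray
    df: int


def _t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Convert t statistics to z scores by two-sided tail matching.

    Computed in log space (t.logsf -> ndtri_exp) so large statistics do
    not saturate to infinity.
    """
    t = np.asarray(t, dtype=float)
    logp = stats.t.logsf(np.abs(t), df)
    z = -special.ndtri_exp(logp)
    return np.sign(t) * z


def fit_glm(series: np.ndarray, design: DesignMatrix) -> GlmResult:
    """Voxelwise OLS fit of a 4-D series; returns the task-effect z map.

    t = beta_task / SE(beta_task) with df = frames - rank(X), converted
    to z by matched two-sided tail probabilities.  Voxels with zero
    residual variance (noiseless degenerate fits) get z = 0 and are
    flagged rather than propagating division by zero.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be 4-D (x, y, z, t)")
    X = design.X
    n, k = X.shape
    if series.shape[-1] != n:
        raise ValueError(
            f"series has {series.shape[-1]} frames but the design has {n}"
        )
    df = n - k
    if df <= 0:
        raise ValueError("not enough frames for the design")

    vol_shape = series.shape[:3]
    Y = series.reshape(-1, n).T  # frames x voxels
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df

    j = design.task_column
    xtx_inv = np.linalg.inv(X.T @ X)
    var_beta = sigma2 * xtx_inv[j, j]

    scale = np.abs(Y).max(initial=1.0)
    variance_zero = sigma2 <= (np.finfo(float).eps * max(scale, 1.0)) ** 2 * n
    se = np.sqrt(np.where(variance_zero, 1.0, var_beta))
    t = np.where(variance_zero, 0.0, beta[j] / se)
    z = _t_to_z(t, df)
    z[variance_zero] = 0.0

    return GlmResult(
        z=z.reshape(vol_shape),
        variance_zero=variance_zero.reshape(vol_shape),
        df=df,
    )
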