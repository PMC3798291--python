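"""Mean-dependent error model and the induction Z statistic.

Replicated control arrays are used to estimate, for every probe set, the
standard deviation of log2 expression across biological replicates.  Because
array noise is strongly expression-dependent (low-expressed probe sets are
noisier on the log scale), the per-probe-set SDs are smoothed against mean
expression with loess, giving a curve ``sd(mean)`` that predicts replicate
noise at any expression level.  The induction statistic for probe set *g* at
timepoint *t* is then

    Z(g, t) = (mean_t(g) - mean_0h(g)) / sd(mean_0h(g))

i.e. the log2 fold change expressed in units of predicted replicate noise.
Z is signed: negative values indicate downregulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ErrorModel", "ZMatrix", "fit_error_model", "compute_z", "loess"]

#: floor applied to fitted SDs so Z never divides by zero
SD_FLOOR = 1e-6


def loess(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Local polynomial regression with tricube weights.

    For each evaluation point the ``span`` fraction of nearest observations
    is weighted by the tricube kernel and a weighted polynomial of the given
    degree is fitted; the prediction is its value at the evaluation point.
    Matches the defaults of the canonical loess implementation
    (span 0.75, locally quadratic, Gaussian fitting, no robustness
    iterations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("loess requires at least one observation")
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    q = min(n, max(degree + 2, int(np.ceil(span * n))))
    out = np.empty(len(x_eval), dtype=float)
    for i, x0 in enumerate(np.asarray(x_eval, dtype=float)):
        d = np.abs(x - x0)
        dq = np.partition(d, q - 1)[q - 1]
        if dq <= 0:
            # all mass at x0 (duplicated design points): weighted mean
            w = (d == 0).astype(float)
        else:
            w = np.clip(1.0 - (d / dq) ** 3, 0.0, None) ** 3
        mask = w > 0
        xm = x[mask] - x0
        ym = y[mask]
        sw = np.sqrt(w[mask])
        # degenerate windows (few unique x) get a reduced degree
        deg = min(degree, np.unique(xm).size - 1)
        V = np.vander(xm, deg + 1)
        coef, *_ = np.linalg.lstsq(V * sw[:, None], ym * sw, rcond=None)
        out[i] = coef[-1]
    return out


@dataclass
class ErrorModel:
    """SD-versus-mean curve fitted on control replicates.

    The curve is stored as interpolation knots on a mean-expression grid;
    evaluation is linear interpolation inside the support and constant at the
    boundary values outside it (constant extrapolation avoids negative or
    exploding SD predictions).  Predictions are floored at ``SD_FLOOR``.
    """

    grid_mean: np.ndarray
    grid_sd: np.ndarray
    span: float = 0.75
    degree: int = 2
    n_points: int = 0

    def __post_init__(self) -> None:
        self.grid_mean = np.asarray(self.grid_mean, dtype=float)
        self.grid_sd = np.maximum(np.asarray(self.grid_sd, dtype=float), SD_FLOOR)
        if self.grid_mean.size != self.grid_sd.size or self.grid_mean.size == 0:
            raise ValueError("grid_mean and grid_sd must be equal-length, nonempty")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.grid_mean[0]), float(self.grid_mean[-1])

    def __call__(self, mean: np.ndarray | float) -> np.ndarray | float:
        """Predicted replicate SD at the given mean expression."""
        pred = np.interp(mean, self.grid_mean, self.grid_sd)
        return np.maximum(pred, SD_FLOOR)

    def to_json(self, path) -> None:
        payload = {
            "grid_mean": self.grid_mean.tolist(),
            "grid_sd": self.grid_sd.tolist(),
            "span": self.span,
            "degree": self.degree,
            "n_points": self.n_points,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ErrorModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            grid_mean=np.asarray(payload["grid_mean"]),
            grid_sd=np.asarray(payload["grid_sd"]),
            span=payload["span"],
            degree=payload["degree"],
            n_points=payload["n_points"],
        )


@dataclass
class ZMatrix:
    """Per-probe-set, per-timepoint Z values with their ingredients."""

    z: pd.DataFrame                 # probe set x timepoint (hours, ascending)
    control_mean: pd.Series         # per probe set
    timepoint_means: pd.DataFrame   # probe set x timepoint
    sd_at_control: pd.Series = field(repr=False, default=None)

    @property
    def timepoints(self) -> list[int]:
        return list(self.z.columns)


def control_samples(design: pd.Series) -> pd.Index:
    """Sample ids labelled 0 h in the design."""
    return design.index[design == 0]


def fit_error_model(
    expr: pd.DataFrame,
    design: pd.Series,
    span: float = 0.75,
    degree: int = 2,
    n_grid: int = 128,
) -> ErrorModel:
    """Fit the SD-versus-mean loess curve from the 0 h control replicates.

    Per probe set the mean and sample SD (ddof=1) over control arrays are
    computed; SD is then loess-smoothed against the mean and the fit is
    tabulated on an ``n_grid``-point grid over the observed mean range.
    """
    controls = control_samples(design)
    if len(controls) < 2:
        raise ValueError(
            f"error model needs >=2 control (0 h) samples, got {len(controls)}"
        )
    if expr.shape[0] < 50:
        warnings.warn(
            f"fitting the error model on only {expr.shape[0]} probe sets; "
            "the SD curve will be unstable",
            stacklevel=2,
        )
    ctrl = expr[controls]
    m = ctrl.mean(axis=1).to_numpy()
    s = ctrl.std(axis=1, ddof=1).to_numpy()
    lo, hi = float(m.min()), float(m.max())
    if hi - lo <= 0:
        # all probe sets at one mean: constant model at the pooled SD
        grid_mean = np.array([lo])
        grid_sd = np.array([float(np.mean(s))])
    else:
        grid_mean = np.linspace(lo, hi, n_grid)
        grid_sd = loess(m, s, grid_mean, span=span, degree=degree)
    return ErrorModel(
        grid_mean=grid_mean,
        grid_sd=grid_sd,
        span=span,
        degree=degree,
        n_points=expr.shape[0],
    )


def compute_z(
    expr: pd.DataFrame,
    design: pd.Series,
    model: ErrorModel,
    scale_by_replicates: bool = False,
) -> ZMatrix:
    """Z value per probe set and post-stimulus timepoint.

    The denominator SD is the error-model prediction at the *control* mean
    and is, by default, not rescaled by replicate counts — the statistic is
    the plain fold change over model SD, which is conservative for timepoint
    means of several replicates.  ``scale_by_replicates=True`` divides the
    SD by ``sqrt(1/n_t + 1/n_0)`` for a mean-difference calibration.
    """
    controls = control_samples(design)
    if len(controls) < 1:
        raise ValueError("design has no 0 h control samples")
    timepoints = sorted(int(t) for t in design.unique() if t != 0)
    if not timepoints:
        raise ValueError("design has no post-stimulus timepoints")
    m0 = expr[controls].mean(axis=1)
    sd0 = pd.Series(model(m0.to_numpy()), index=expr.index)
    means = {}
    zcols = {}
    n0 = len(controls)
    for t in timepoints:
        cols = design.index[design == t]
        if len(cols) == 0:
            raise ValueError(f"timepoint {t} h has zero samples")
        mt = expr[cols].mean(axis=1)
        denom = sd0
        if scale_by_replicates:
            denom = sd0 * np.sqrt(1.0 / len(cols) + 1.0 / n0)
        means[t] = mt
        zcols[t] = (mt - m0) / denom
    z = pd.DataFrame(zcols)
    if not np.isfinite(z.to_numpy()).all():
        raise ValueError("non-finite Z values; check input matrix")
    return ZMatrix(
        z=z,
        control_mean=m0,
        timepoint_means=pd.DataFrame(means),
        sd_at_control=sd0,
    )
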