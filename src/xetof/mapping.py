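"""Pixel-wise slope fitting, perfusion maps, HDR maps, flow correlation.

The dynamic series of SNR maps is fitted pixel-by-pixel with an ordinary
least-squares line in the TOF delay; in the short-time regime the slope is
proportional to the voxel's total perfusion, so dividing by the arterial
reference SNR and converting the time base yields an absolute perfusion map
(mL blood / mL tissue / min).  Subtracting a baseline slope map from a task
slope map gives the hemodynamic-response (HDR) map.

The fit includes an intercept by default: the in vivo delay triples do not
start at zero and saturation is never perfect, so forcing the line through
the origin is unsafe.  A through-origin option exists for controlled
simulations.  Negative slopes are retained (they are informative fit noise
and clipping would bias HDR subtraction) but flagged in the perfusion map's
quality layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .kinetics import CalibrationParams, UptakeCurve, slope_to_perfusion


@dataclass
class TOFSeries:
    """Ordered stack of per-dynamic maps with their recovery delays."""

    images: np.ndarray  # (n_dynamics, ny, nx)
    tof_delays: tuple[float, ...]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValidationError("images must be a (dynamics, y, x) stack")
        delays = tuple(float(t) for t in np.atleast_1d(self.tof_delays))
        if len(delays) != self.images.shape[0]:
            raise ValidationError("one delay per dynamic is required")
        if len(delays) < 2:
            raise ValidationError("at least 2 dynamics are needed for a fit")
        if any(b <= a for a, b in zip(delays, delays[1:])):
            raise ValidationError("tof_delays must be strictly increasing")
        object.__setattr__(self, "tof_delays", delays)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.images.shape[1:]:
                raise ValidationError("mask shape does not match images")


@dataclass
class SlopeMap:
    """Per-pixel linear-fit results of SNR vs TOF delay."""

    slope: np.ndarray        # SNR / s
    intercept: np.ndarray    # SNR
    r_squared: np.ndarray    # NaN where undefined (constant data)
    slope_se: np.ndarray     # propagated from the fit residual
    n_points: int
    tof_delays: tuple[float, ...]
    mask: np.ndarray | None = None


@dataclass
class PerfusionMap:
    """Absolute perfusion per pixel with its calibration and quality layer."""

    f_sum: np.ndarray        # mL blood / mL tissue / min
    calibration: CalibrationParams
    negative_mask: np.ndarray | None = None  # pixels with negative fit slope


@dataclass
class HDRMap:
    """Task-minus-baseline slope difference (hemodynamic response)."""

    delta_slope: np.ndarray  # SNR / s
    delta_se: np.ndarray | None = None
    mask: np.ndarray | None = None


def default_mask(images: np.ndarray, threshold: float = 3.0) -> np.ndarray:
    """Fitting mask: pixels whose maximum SNR across dynamics exceeds
    ``threshold`` (default 3)."""
    return np.asarray(images).max(axis=0) > threshold


def fit_slope_map(series: TOFSeries, through_origin: bool = False) -> SlopeMap:
    """Pixel-wise least squares of SNR versus TOF delay.

    Returns slope, intercept, R^2 and the slope standard error propagated
    from the fit residual (n-2 dof with intercept, n-1 through origin).
    R^2 is NaN where the data are constant (undefined); pixels outside the
    series mask are NaN everywhere.
    """
    tau = np.asarray(series.tof_delays, dtype=float)
    y = series.images
    n = tau.size
    if np.ptp(tau) == 0:
        raise ValidationError("delays are constant; no slope is identifiable")
    if through_origin:
        sxx = float(np.sum(tau**2))
        slope = np.tensordot(tau, y, axes=(0, 0)) / sxx
        intercept = np.zeros_like(slope)
        fitted = tau[:, None, None] * slope[None]
        ss_tot = np.sum(y**2, axis=0)
        dof = n - 1
    else:
        t_c = tau - tau.mean()
        sxx = float(np.sum(t_c**2))
        y_mean = y.mean(axis=0)
        slope = np.tensordot(t_c, y, axes=(0, 0)) / sxx
        intercept = y_mean - slope * tau.mean()
        fitted = intercept[None] + tau[:, None, None] * slope[None]
        ss_tot = np.sum((y - y_mean[None]) ** 2, axis=0)
        dof = n - 2
    ss_res = np.sum((y - fitted) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(
            ss_tot > 0,
            1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0),
            np.nan,
        )
        r2 = np.where(np.isfinite(r2), np.clip(r2, 0.0, 1.0), r2)
        if dof > 0:
            se = np.sqrt(ss_res / dof / sxx)
        else:
            se = np.full_like(slope, np.nan)
    if series.mask is not None:
        for arr in (slope, intercept, r2, se):
            arr[~series.mask] = np.nan
    return SlopeMap(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        slope_se=se,
        n_points=n,
        tof_delays=series.tof_delays,
        mask=series.mask,
    )


def make_perfusion_map(slopes: SlopeMap, c: CalibrationParams) -> PerfusionMap:
    """Recalculate a slope map into absolute perfusion, F = 60 slope / s_art.

    Negative slopes pass through unclipped and are flagged in
    ``negative_mask``.
    """
    if not isinstance(c, CalibrationParams):
        raise ValidationError("calibration must be a CalibrationParams")
    f_sum = slope_to_perfusion(slopes.slope, c)
    negative = np.isfinite(slopes.slope) & (slopes.slope < 0)
    return PerfusionMap(f_sum=f_sum, calibration=c, negative_mask=negative)


def hdr_map(task: SlopeMap, baseline: SlopeMap) -> HDRMap:
    """Hemodynamic-response map: task slope minus baseline slope.

    Antisymmetric by construction: hdr(a, b) == -hdr(b, a).
    """
    if task.slope.shape != baseline.slope.shape:
        raise ValidationError("task and baseline maps differ in shape")
    if task.tof_delays != baseline.tof_delays:
        raise ValidationError(
            "task and baseline were fitted on different TOF delays"
        )
    delta = task.slope - baseline.slope
    se = None
    if task.slope_se is not None and baseline.slope_se is not None:
        se = np.sqrt(task.slope_se**2 + baseline.slope_se**2)
    mask = None
    if task.mask is not None and baseline.mask is not None:
        mask = task.mask & baseline.mask
    elif task.mask is not None:
        mask = task.mask
    elif baseline.mask is not None:
        mask = baseline.mask
    return HDRMap(delta_slope=delta, delta_se=se, mask=mask)


def estimate_hdr_noise(hdr: HDRMap, region) -> float:
    """Std of the HDR map inside a (background) region -- the sigma-hat used
    for activation thresholding."""
    values = region.extract(hdr.delta_slope)
    finite = values[np.isfinite(values)]
    if finite.size < 2:
        raise ValidationError("noise region has fewer than 2 finite pixels")
    return float(np.std(finite, ddof=1))


def localize_activation(
    hdr: HDRMap,
    sigma: float,
    z: float = 2.0,
    mask: np.ndarray | None = None,
    two_sided: bool = False,
) -> np.ndarray:
    """Threshold the HDR map at ``z * sigma`` to localize activation.

    One-sided (positive response) by default since a stimulus raises
    perfusion; ``two_sided=True`` flags deviations of either sign.  This is
    a display/localization utility, not a multiple-comparison-controlled
    statistical test.
    """
    if sigma <= 0 or not np.isfinite(sigma):
        raise ValidationError("sigma must be finite and > 0")
    d = hdr.delta_slope
    detected = (np.abs(d) if two_sided else d) > z * sigma
    detected &= np.isfinite(d)
    if mask is None and hdr.mask is not None:
        mask = hdr.mask
    if mask is not None:
        detected &= mask
    return detected


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A & B| / (|A| + |B|); NaN if both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return float("nan")
    return 2.0 * float((a & b).sum()) / float(denom)


def window_slope(curve: UptakeCurve, window: tuple[float, float]) -> float:
    """OLS slope of an uptake curve restricted to a tau window (inclusive)."""
    sub = curve.window(*window)
    if len(sub.tau) < 2:
        raise ValidationError("window must contain >= 2 curve samples")
    tau = sub.tau_array
    sig = sub.signal_array
    t_c = tau - tau.mean()
    return float(np.sum(t_c * (sig - sig.mean())) / np.sum(t_c**2))


def flow_slope_correlation(
    flows,
    curves: list[UptakeCurve],
    window: tuple[float, float] = (0.2, 0.7),
) -> float:
    """Pearson correlation between pump flow rates and TOF recovery slopes.

    Each curve's slope is fitted by least squares on the quasilinear window
    (default 200-700 ms); the returned r lies in [-1, 1].
    """
    flows = np.asarray(flows, dtype=float)
    if flows.size < 3:
        raise ValidationError("at least 3 flow rates are required")
    if flows.size != len(curves):
        raise ValidationError("one curve per flow rate is required")
    slopes = np.array([window_slope(c, window) for c in curves])
    if np.ptp(slopes) == 0 or np.ptp(flows) == 0:
        raise ValidationError("degenerate (zero-variance) slopes or flows")
    return float(stats.pearsonr(flows, slopes).statistic)
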