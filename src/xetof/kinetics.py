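"""One-compartment kinetics of hyperpolarized :sup:`129`Xe wash-in.

The imaging experiment saturates all dissolved-phase :sup:`129`Xe in the
target volume with a 90 degree pulse and reads out after a recovery (time of
flight, TOF) delay ``tau``, so the measured signal comes only from fresh
hyperpolarized xenon carried into the voxel by arterial blood during the
delay.  Because the hyperpolarized state is not regenerated by spin-lattice
relaxation, the voxel magnetization obeys a one-way tracer balance per
tissue compartment::

    dM/dt = (f/60) * m_a0 * exp(-t/T1b) - k * M,      k = (f/60)/lambda + 1/T1t

where ``f`` is perfusion in mL blood / mL tissue / min (the /60 converts to
the seconds time base used throughout), ``m_a0`` the arterial magnetization
scale on arrival, ``T1b`` the longitudinal relaxation time of dissolved Xe
in blood, ``lambda`` the blood-tissue partition coefficient, and ``T1t`` the
tissue relaxation time.  The closed-form solution, its short-time
linearization (signal ~ slope * tau, slope proportional to the voxel's total
perfusion), and the slope -> perfusion conversion implemented here are the
quantitative backbone of TOF perfusion mapping.

A voxel containing several tissues is modelled as the sum of independent
one-compartment solutions sharing the same arterial input; the fitted slope
then estimates the *sum* of the compartment perfusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ValidationError

#: seconds per minute -- the single place where the perfusion unit
#: (mL/mL/min) is reconciled with the seconds time base of the TOF delays.
SECONDS_PER_MINUTE = 60.0

#: reduced gyromagnetic ratio of 129Xe, MHz/T
GAMMA_BAR_XE129_MHZ_PER_T = 11.777
#: reduced gyromagnetic ratio of 1H, MHz/T (for cross-checks)
GAMMA_BAR_1H_MHZ_PER_T = 42.576

#: |k - 1/T1b| below which the removable singularity of the closed form is
#: replaced by its L'Hopital limit, in 1/s.
SINGULARITY_TOL = 1e-10


def _as_float_tuple(x) -> tuple[float, ...]:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValidationError("compartment parameters must be scalars or 1-D")
    return tuple(float(v) for v in arr)


@dataclass(frozen=True)
class KineticsParams:
    """Physiological parameters of one voxel (possibly multi-compartment).

    ``f``, ``lam`` and ``t1_tissue`` may be scalars or equal-length sequences
    (one entry per tissue compartment); scalars are broadcast.

    Parameters
    ----------
    f : float or sequence
        Perfusion per compartment, mL blood / mL tissue / min, >= 0.
    lam : float or sequence
        Blood-tissue partition coefficient (dimensionless), > 0.
    t1_blood : float
        T1 of dissolved 129Xe in arterial blood, s, > 0.
    t1_tissue : float or sequence
        T1 of dissolved 129Xe in tissue, s, > 0.
    transit_delay : float
        Lung-to-voxel arterial transit time, s, >= 0.
    m_a0 : float
        Arterial magnetization scale at voxel arrival (a.u.), >= 0.
    """

    f: tuple[float, ...] = (0.55,)
    lam: tuple[float, ...] = (0.9,)
    t1_blood: float = 8.0
    t1_tissue: tuple[float, ...] = (16.0,)
    transit_delay: float = 0.0
    m_a0: float = 100.0

    def __post_init__(self) -> None:
        f = _as_float_tuple(self.f)
        lam = _as_float_tuple(self.lam)
        t1t = _as_float_tuple(self.t1_tissue)
        n = max(len(f), len(lam), len(t1t))
        f, lam, t1t = (
            t * n if len(t) == 1 and n > 1 else t for t in (f, lam, t1t)
        )
        if not len(f) == len(lam) == len(t1t):
            raise ValidationError(
                "f, lam and t1_tissue must have matching compartment counts"
            )
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "t1_tissue", t1t)
        scalars = (self.t1_blood, self.transit_delay, self.m_a0)
        if not all(np.isfinite(v) for v in f + lam + t1t + scalars):
            raise ValidationError("kinetics parameters must be finite")
        if any(v < 0 for v in f):
            raise ValidationError("perfusion f must be >= 0")
        if any(v <= 0 for v in lam):
            raise ValidationError("partition coefficient lam must be > 0")
        if any(v <= 0 for v in t1t) or self.t1_blood <= 0:
            raise ValidationError("relaxation times must be > 0")
        if self.transit_delay < 0 or self.m_a0 < 0:
            raise ValidationError("transit_delay and m_a0 must be >= 0")

    @property
    def f_total(self) -> float:
        """Sum of compartment perfusions, mL/mL/min."""
        return float(sum(self.f))

    def with_perfusion_scaled(self, factor: float) -> "KineticsParams":
        """Return a copy with every compartment perfusion multiplied."""
        return KineticsParams(
            f=tuple(v * factor for v in self.f),
            lam=self.lam,
            t1_blood=self.t1_blood,
            t1_tissue=self.t1_tissue,
            transit_delay=self.transit_delay,
            m_a0=self.m_a0,
        )


@dataclass(frozen=True)
class CalibrationParams:
    """Conversion from an SNR slope to absolute perfusion.

    ``s_arterial`` is the SNR a voxel would show if fully occupied by fresh
    arterial Xe-laden blood; it is the single proportionality constant
    between the fitted SNR slope (1/s) and total perfusion (mL/mL/min):
    ``F = time_unit_factor * slope / s_arterial``.
    """

    s_arterial: float
    time_unit_factor: float = SECONDS_PER_MINUTE

    def __post_init__(self) -> None:
        if not np.isfinite(self.s_arterial) or self.s_arterial <= 0:
            raise ValidationError("s_arterial must be finite and > 0")
        if self.time_unit_factor <= 0:
            raise ValidationError("time_unit_factor must be > 0")


@dataclass(frozen=True)
class UptakeCurve:
    """A measured or simulated TOF recovery curve.

    ``tau`` must be strictly increasing and nonnegative; ``signal`` holds the
    matching magnetization/SNR values.
    """

    tau: tuple[float, ...]
    signal: tuple[float, ...]

    def __post_init__(self) -> None:
        tau = _as_float_tuple(self.tau)
        sig = _as_float_tuple(self.signal)
        if len(tau) != len(sig):
            raise ValidationError("tau and signal lengths differ")
        if len(tau) == 0:
            raise ValidationError("curve must contain at least one point")
        if any(t < 0 for t in tau):
            raise ValidationError("tau values must be >= 0")
        if any(b <= a for a, b in zip(tau, tau[1:])):
            raise ValidationError("tau must be strictly increasing")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "signal", sig)

    @property
    def tau_array(self) -> np.ndarray:
        return np.asarray(self.tau, dtype=float)

    @property
    def signal_array(self) -> np.ndarray:
        return np.asarray(self.signal, dtype=float)

    def window(self, lo: float, hi: float) -> "UptakeCurve":
        """Sub-curve with lo <= tau <= hi (inclusive bounds)."""
        keep = [(t, s) for t, s in zip(self.tau, self.signal) if lo <= t <= hi]
        if not keep:
            raise ValidationError(
                f"window [{lo}, {hi}] s contains no curve samples"
            )
        tau, sig = zip(*keep)
        return UptakeCurve(tau=tau, signal=sig)


def _validate_tau(tau):
    t = np.asarray(tau, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValidationError("tau must be finite")
    if np.any(t < 0):
        raise DomainError("tau must be >= 0")
    return t


def analytic_uptake(p: KineticsParams, tau) -> np.ndarray | float:
    """Closed-form voxel magnetization M(tau) after saturation.

    Sum over compartments of
    ``(f/60) m_a0 (exp(-tau'/T1b) - exp(-k tau')) / (k - 1/T1b)`` with
    ``k = (f/60)/lambda + 1/T1t`` and ``tau' = max(tau - transit_delay, 0)``.
    At the removable singularity ``k == 1/T1b`` the limit form
    ``(f/60) m_a0 tau' exp(-tau'/T1b)`` is used, keeping M continuous in the
    parameters.

    Accepts a scalar or array ``tau`` (seconds) and returns the same shape.
    """
    t = _validate_tau(tau)
    tp = np.maximum(t - p.transit_delay, 0.0)
    a = 1.0 / p.t1_blood
    total = np.zeros_like(tp, dtype=float)
    for f, lam, t1t in zip(p.f, p.lam, p.t1_tissue):
        fs = f / SECONDS_PER_MINUTE
        k = fs / lam + 1.0 / t1t
        if abs(k - a) < SINGULARITY_TOL:
            total = total + fs * p.m_a0 * tp * np.exp(-a * tp)
        else:
            total = total + (
                fs * p.m_a0 * (np.exp(-a * tp) - np.exp(-k * tp)) / (k - a)
            )
    if np.isscalar(tau) or np.ndim(tau) == 0:
        return float(total)
    return total


def linearized_uptake(p: KineticsParams, tau) -> np.ndarray | float:
    """Short-time linear model M_lin(tau) = (sum f / 60) m_a0 tau'.

    First-order expansion of :func:`analytic_uptake`, valid while both the
    arterial decay ``tau/T1b`` and the clearance ``k tau`` are small; it
    always upper-bounds the analytic solution (fresh spins can only decay
    relative to the linear influx).  Its slope is proportional to the voxel's
    total perfusion, which is what pixel-wise TOF fitting estimates.
    """
    t = _validate_tau(tau)
    tp = np.maximum(t - p.transit_delay, 0.0)
    total_f = sum(p.f) / SECONDS_PER_MINUTE
    out = total_f * p.m_a0 * tp
    if np.isscalar(tau) or np.ndim(tau) == 0:
        return float(out)
    return out


def slope_to_perfusion(slope, c: CalibrationParams):
    """Convert a fitted SNR slope (1/s) to total perfusion (mL/mL/min).

    ``F = time_unit_factor * slope / s_arterial``; linear in ``slope``, so
    negative fit slopes map to negative (non-physical, flag-worthy) F values
    rather than being clipped.  Works elementwise on arrays.
    """
    if not isinstance(c, CalibrationParams):
        c = CalibrationParams(s_arterial=float(c))
    s = np.asarray(slope, dtype=float)
    out = c.time_unit_factor * s / c.s_arterial
    if np.isscalar(slope) or np.ndim(slope) == 0:
        return float(out)
    return out


def pulse_bandwidth(duration: float) -> float:
    """Excitation bandwidth (Hz) of a rectangular RF pulse: BW = 1/duration."""
    if not np.isfinite(duration) or duration <= 0:
        raise DomainError("pulse duration must be finite and > 0")
    return 1.0 / float(duration)


def bandwidth_ppm(bandwidth_hz: float, carrier_mhz: float) -> float:
    """Express an absolute bandwidth as ppm of the carrier frequency."""
    if carrier_mhz <= 0:
        raise DomainError("carrier frequency must be > 0")
    return float(bandwidth_hz) / float(carrier_mhz)


def larmor_frequency(
    b0: float, gyromag_ratio: float = GAMMA_BAR_XE129_MHZ_PER_T
) -> float:
    """Larmor frequency (MHz) at field b0 (T): f0 = gamma_bar * B0."""
    if not np.isfinite(b0) or b0 < 0:
        raise DomainError("B0 must be finite and >= 0")
    if gyromag_ratio <= 0:
        raise DomainError("gyromagnetic ratio must be > 0")
    return float(gyromag_ratio) * float(b0)
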