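"""Independent numerical oracles used by the tests.

These deliberately avoid the closed forms under test: the uptake model is
integrated with a fixed-step 4th-order Runge-Kutta scheme, and the laminar
flow curve is evaluated by radial trapezoid quadrature of the velocity
profile.
"""

import numpy as np


def rk4_uptake(p, tau: float, dt: float = 1e-3) -> float:
    """Integrate dM/dt = sum_c [(f_c/60) m_a0 e^(-t/T1b) - k_c M_c] to tau."""
    tp = max(tau - p.transit_delay, 0.0)
    f = np.asarray(p.f) / 60.0
    k = f / np.asarray(p.lam) + 1.0 / np.asarray(p.t1_tissue)
    a = 1.0 / p.t1_blood

    def deriv(t, m):
        return f * p.m_a0 * np.exp(-a * t) - k * m

    n = int(np.ceil(tp / dt))
    h = tp / n if n else 0.0
    m = np.zeros_like(f)
    t = 0.0
    for _ in range(n):
        k1 = deriv(t, m)
        k2 = deriv(t + h / 2, m + h / 2 * k1)
        k3 = deriv(t + h / 2, m + h / 2 * k2)
        k4 = deriv(t + h, m + h * k3)
        m = m + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return float(m.sum())


def laminar_fraction_quadrature(spec, tau: float, n_r: int = 10_000) -> float:
    """Radial trapezoid quadrature of the Poiseuille wash-in fraction:
    F = (1/(pi R^2 L)) int_0^R min(v(r) tau, L) 2 pi r dr."""
    radius = spec.radius_mm
    length = spec.sensitive_length
    v_mean = spec.flow_ml_s * 1000.0 / spec.cross_section_mm2  # mm/s
    r = np.linspace(0.0, radius, n_r)
    v = 2.0 * v_mean * (1.0 - (r / radius) ** 2)
    integrand = np.minimum(v * tau, length) * 2.0 * np.pi * r
    return float(
        np.trapezoid(integrand, r) / (np.pi * radius**2 * length)
    )


def dft_interpolate(img: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Evaluate the centered-DFT trigonometric interpolant of ``img`` at
    arbitrary (fractional) pixel positions, by direct summation."""
    ny, nx = img.shape
    ky = np.arange(ny) - ny // 2
    kx = np.arange(nx) - nx // 2
    yy = np.arange(ny) - ny // 2
    xx = np.arange(nx) - nx // 2
    k = (
        np.exp(-2j * np.pi * np.outer(ky, yy) / ny)
        @ img
        @ np.exp(-2j * np.pi * np.outer(xx, kx) / nx)
    ) / np.sqrt(ny * nx)
    ey = np.exp(2j * np.pi * np.outer(np.asarray(y) - ny // 2, ky) / ny)
    ex = np.exp(2j * np.pi * np.outer(kx, np.asarray(x) - nx // 2) / nx)
    return (ey @ k @ ex) / np.sqrt(ny * nx)
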