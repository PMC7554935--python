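"""Synthetic-data engine: flow phantom, digital brain phantom, acquisition.

Three generators live here:

* :func:`simulate_flow_curve` -- TOF recovery curves of a tube flow phantom
  fed by a syringe pump, with plug or laminar (Poiseuille) velocity
  profiles.  These emulate the in vitro validation of the pulse sequence.
* :func:`brain_phantom` / :func:`make_brain_phantom` -- a two-compartment
  (gray/white matter) digital brain on the acquisition grid, optionally with
  a focal "activation" region of elevated perfusion.
* :func:`simulate_tof_series` -- the forward model of the dynamic
  acquisition: per-pixel uptake kinetics at each TOF delay, Cartesian
  gradient-echo k-space sampling with flip-angle depletion of the
  (non-renewable) hyperpolarized magnetization, and seeded complex Gaussian
  noise.

Because each excitation consumes sin(alpha) of the remaining hyperpolarized
magnetization, the j-th acquired phase-encode line of a dynamic carries a
relative amplitude sin(alpha) * cos(alpha)**j (j = 0-based acquisition
order).  The saturation pulse resets the experiment between dynamics, so
depletion is applied within each dynamic only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .exceptions import ValidationError
from .kinetics import KineticsParams, UptakeCurve, analytic_uptake
from .presets import KINETICS_PRESETS

#: std of the magnitude of unit-variance complex Gaussian noise (Rayleigh).
RAYLEIGH_STD_FACTOR = math.sqrt(2.0 - math.pi / 2.0)


# --------------------------------------------------------------------------
# flow phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowPhantomSpec:
    """Tube flow phantom driven by a syringe pump.

    Defaults: 3.175 mm inner-diameter tube; a 20 mm coil-sensitive length
    (chosen so that the tube refills on the 1-2 s scale of the measured
    recovery curves); laminar velocity profile; additive per-point Gaussian
    noise of 1% of the plateau signal.
    """

    flow_rate: float
    tube_id: float = 3.175
    sensitive_length: float = 20.0
    profile: str = "laminar"
    s_max: float = 1.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise ValidationError("flow_rate must be > 0 (mL/min)")
        if self.tube_id <= 0 or self.sensitive_length <= 0:
            raise ValidationError("tube geometry must be positive")
        if self.profile not in ("plug", "laminar"):
            raise ValidationError("profile must be 'plug' or 'laminar'")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.s_max <= 0:
            raise ValidationError("s_max must be > 0")

    @property
    def radius_mm(self) -> float:
        return self.tube_id / 2.0

    @property
    def cross_section_mm2(self) -> float:
        return math.pi * self.radius_mm**2

    @property
    def fill_volume_ml(self) -> float:
        """Coil-sensitive volume V = pi r^2 L, mL."""
        return self.cross_section_mm2 * self.sensitive_length / 1000.0

    @property
    def flow_ml_s(self) -> float:
        return self.flow_rate / 60.0

    @property
    def fill_time_s(self) -> float:
        """Time for the mean flow to replace the sensitive volume, V/Q."""
        return self.fill_volume_ml / self.flow_ml_s


def _flow_fraction(spec: FlowPhantomSpec, tau: np.ndarray) -> np.ndarray:
    """Noiseless filled fraction of the sensitive volume at delay tau.

    With x = v_mean * tau / L (= Q tau / V):

    * plug flow: min(x, 1) -- exactly linear until the fill time, then flat;
    * laminar (Poiseuille, v(r) = 2 v_mean (1 - (r/R)^2)): the radial average
      of min(v(r) tau, L) has the closed form x for x <= 1/2 and
      1 - 1/(4x) beyond (leading-edge spins exit once 2 v_mean tau > L),
      approaching the plateau only asymptotically.
    """
    x = spec.flow_ml_s * tau / spec.fill_volume_ml
    if spec.profile == "plug":
        return np.minimum(x, 1.0)
    out = np.where(x <= 0.5, x, 1.0 - 1.0 / np.maximum(4.0 * x, 1e-300))
    return np.where(x == 0.0, 0.0, out)


def simulate_flow_curve(
    spec: FlowPhantomSpec, tau_grid, seed: int | None = None
) -> UptakeCurve:
    """Simulate a TOF recovery curve S(tau) = s_max * fraction + noise."""
    tau = np.asarray(tau_grid, dtype=float)
    if tau.size == 0:
        raise ValidationError("tau_grid must be nonempty")
    if np.any(tau < 0):
        raise ValidationError("tau_grid must be nonnegative")
    signal = spec.s_max * _flow_fraction(spec, tau)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
    return UptakeCurve(tau=tuple(tau), signal=tuple(signal))


# --------------------------------------------------------------------------
# digital brain phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates (x = column, y = row)."""

    cx: float
    cy: float
    rx: float
    ry: float

    def rasterize(self, grid: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside the ellipse."""
        ny, nx = grid
        yy, xx = np.mgrid[0:ny, 0:nx]
        return ((xx - self.cx) / self.rx) ** 2 + (
            (yy - self.cy) / self.ry
        ) ** 2 <= 1.0

    def scaled(self, zoom_x: float, zoom_y: float) -> "Ellipse":
        """Same physical ellipse on a grid rescaled by (zoom_x, zoom_y).

        Pixel centers map as x' = (x + 1/2) zoom - 1/2, which keeps the
        field of view aligned between acquisition and reconstruction grids.
        """
        return Ellipse(
            cx=(self.cx + 0.5) * zoom_x - 0.5,
            cy=(self.cy + 0.5) * zoom_y - 0.5,
            rx=self.rx * zoom_x,
            ry=self.ry * zoom_y,
        )


@dataclass
class Compartment:
    """A labeled tissue region with its kinetics."""

    label: str
    mask: np.ndarray
    kinetics: KineticsParams


@dataclass
class PhantomSpec:
    """Digital phantom: disjoint tissue compartments on an acquisition grid."""

    grid: tuple[int, int] = (20, 20)
    fov: tuple[float, float] = (250.0, 250.0)
    compartments: list[Compartment] | None = None

    def __post_init__(self) -> None:
        if not self.compartments:
            raise ValidationError("at least one compartment is required")
        cover = np.zeros(self.grid, dtype=int)
        for comp in self.compartments:
            if comp.mask.shape != tuple(self.grid):
                raise ValidationError(
                    f"mask of '{comp.label}' does not match grid {self.grid}"
                )
            cover += comp.mask.astype(int)
        if cover.max() > 1:
            raise ValidationError("compartment masks overlap")
        if any(f <= 0 for f in (*self.fov,)):
            raise ValidationError("fov must be positive")

    def mask(self, label: str) -> np.ndarray:
        for comp in self.compartments:
            if comp.label == label:
                return comp.mask
        raise KeyError(label)

    def union_mask(self) -> np.ndarray:
        out = np.zeros(self.grid, dtype=bool)
        for comp in self.compartments:
            out |= comp.mask
        return out


def brain_regions(grid: tuple[int, int] = (20, 20)) -> dict[str, Ellipse]:
    """Geometry of the standard brain phantom, scaled to ``grid``.

    ``brain`` is the outer cortex ellipse, ``white`` a deep white-matter
    core, and ``activation`` a posterior ("occipital") gray-matter patch used
    for hemodynamic-response studies.  All three are defined in acquisition
    pixel coordinates; use :meth:`Ellipse.scaled` to rasterize them on the
    reconstruction grid.
    """
    ny, nx = grid
    return {
        "brain": Ellipse((nx - 1) / 2, (ny - 1) / 2, 0.375 * nx, 0.425 * ny),
        "white": Ellipse((nx - 1) / 2, (ny - 1) / 2 - 0.075 * ny,
                         0.21 * nx, 0.21 * ny),
        "activation": Ellipse((nx - 1) / 2, (ny - 1) / 2 + 0.25 * ny,
                              0.225 * nx, 0.11 * ny),
    }


def brain_phantom(
    grid: tuple[int, int] = (20, 20),
    fov: tuple[float, float] = (250.0, 250.0),
    activation: float = 0.0,
    gray: KineticsParams | None = None,
    white: KineticsParams | None = None,
) -> PhantomSpec:
    """Two-compartment brain phantom, optionally with an activation patch.

    ``activation`` is the fractional perfusion increase (e.g. 0.2 for +20%)
    applied to the posterior gray-matter patch; at 0 the patch is plain gray
    matter and no extra compartment is created.
    """
    gray = gray or KINETICS_PRESETS["gray_matter"]
    white = white or KINETICS_PRESETS["white_matter"]
    regions = brain_regions(grid)
    brain = regions["brain"].rasterize(grid)
    wm = regions["white"].rasterize(grid) & brain
    gm = brain & ~wm
    comps = []
    if activation != 0.0:
        blob = regions["activation"].rasterize(grid) & gm
        gm = gm & ~blob
        comps.append(
            Compartment(
                "activation", blob, gray.with_perfusion_scaled(1.0 + activation)
            )
        )
    comps = [
        Compartment("gray", gm, gray),
        Compartment("white", wm, white),
        *comps,
    ]
    return PhantomSpec(grid=grid, fov=fov, compartments=comps)


def make_brain_phantom(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth perfusion image: each pixel carries its compartment's
    total perfusion (mL/mL/min); background pixels are 0."""
    out = np.zeros(spec.grid, dtype=float)
    for comp in spec.compartments:
        out[comp.mask] = comp.kinetics.f_total
    return out


def magnetization_image(spec: PhantomSpec, tau: float) -> np.ndarray:
    """Noiseless voxel magnetization at TOF delay ``tau`` (a.u.)."""
    out = np.zeros(spec.grid, dtype=float)
    for comp in spec.compartments:
        out[comp.mask] = analytic_uptake(comp.kinetics, float(tau))
    return out


# --------------------------------------------------------------------------
# acquisition forward model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionParams:
    """One dynamic TOF scan: sampling, excitation and noise parameters."""

    tof_delays: tuple[float, ...]
    flip_angle: float = 20.0
    matrix: tuple[int, int] = (20, 20)
    zero_pad_to: tuple[int, int] = (32, 32)
    noise_sd: float = 0.0
    phase_order: str = "linear"
    seed: int | None = None

    def __post_init__(self) -> None:
        delays = tuple(float(t) for t in np.atleast_1d(self.tof_delays))
        if any(t < 0 for t in delays):
            raise ValidationError("tof_delays must be >= 0")
        if any(b <= a for a, b in zip(delays, delays[1:])):
            raise ValidationError("tof_delays must be strictly increasing")
        object.__setattr__(self, "tof_delays", delays)
        if not 0 < self.flip_angle <= 90:
            raise ValidationError("flip_angle must be in (0, 90] degrees")
        if any(p < m for p, m in zip(self.zero_pad_to, self.matrix)):
            raise ValidationError("zero_pad_to must be >= matrix")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.phase_order not in ("linear", "centric"):
            raise ValidationError("phase_order must be 'linear' or 'centric'")

    def with_noise(self, noise_sd: float) -> "AcquisitionParams":
        return replace(self, noise_sd=noise_sd)


@dataclass
class KSpaceSeries:
    """Stack of dynamic k-spaces with their recovery delays."""

    kspace: np.ndarray  # (n_dynamics, ky, kx), complex
    tof_delays: tuple[float, ...]
    acq: AcquisitionParams
    fov: tuple[float, float] = (250.0, 250.0)


def line_acquisition_order(acq: AcquisitionParams) -> np.ndarray:
    """0-based acquisition position of each phase-encode row.

    Rows index the FFT-shifted (centered) k-space, row r <-> ky = r - Ny//2.
    ``linear`` sweeps ky from most negative to most positive; ``centric``
    acquires ky = 0 first and works outward (+k before -k on ties).
    """
    ny = acq.matrix[0]
    ky = np.arange(ny) - ny // 2
    if acq.phase_order == "linear":
        return np.arange(ny)
    # centric: smaller |ky| first, positive before negative on ties
    idx = sorted(range(ny), key=lambda r: (abs(ky[r]), ky[r] < 0))
    rank = np.empty(ny, dtype=int)
    rank[idx] = np.arange(ny)
    return rank


def line_weights(acq: AcquisitionParams) -> np.ndarray:
    """Relative amplitude sin(a) cos(a)**j of each centered k-space row."""
    a = math.radians(acq.flip_angle)
    j = line_acquisition_order(acq)
    return math.sin(a) * np.cos(a) ** j


def dc_line_weight(acq: AcquisitionParams) -> float:
    """Depletion weight of the ky = 0 line -- the effective amplitude scale
    of smooth image features."""
    return float(line_weights(acq)[acq.matrix[0] // 2])


def pad_scale(acq: AcquisitionParams) -> float:
    """Amplitude scale sqrt(N_in/N_out) that unitary zero-padded
    reconstruction applies to both signal and k-space noise."""
    n_in = acq.matrix[0] * acq.matrix[1]
    n_out = acq.zero_pad_to[0] * acq.zero_pad_to[1]
    return math.sqrt(n_in / n_out)


def _centered_fft2(img: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img), norm="ortho"))


def simulate_tof_series(spec: PhantomSpec, acq: AcquisitionParams) -> KSpaceSeries:
    """Forward-simulate the dynamic TOF acquisition.

    For each delay: evaluate the analytic uptake image, take its centered
    unitary 2-D DFT, weight each phase-encode line by the flip-angle
    depletion factor of its acquisition position, and add seeded complex
    Gaussian noise (sd per real/imaginary component).  The same
    (spec, acq, seed) triple reproduces the series exactly.
    """
    if spec.grid != acq.matrix:
        raise ValidationError(
            f"phantom grid {spec.grid} != acquisition matrix {acq.matrix}"
        )
    rng = np.random.default_rng(acq.seed)
    w = line_weights(acq)[:, None]
    ks = []
    for tau in acq.tof_delays:
        img = magnetization_image(spec, tau)
        k = _centered_fft2(img) * w
        if acq.noise_sd > 0:
            k = k + acq.noise_sd * (
                rng.standard_normal(k.shape)
                + 1j * rng.standard_normal(k.shape)
            )
        ks.append(k)
    return KSpaceSeries(
        kspace=np.stack(ks),
        tof_delays=acq.tof_delays,
        acq=acq,
        fov=spec.fov,
    )


# --------------------------------------------------------------------------
# calibration helpers (ground-truth quantities for simulation studies)
# --------------------------------------------------------------------------

def expected_background_std(acq: AcquisitionParams) -> float:
    """Expected std of background *magnitude* pixels after zero-padded
    unitary reconstruction: noise_sd * sqrt(N_in/N_out) * sqrt(2 - pi/2)."""
    if acq.noise_sd <= 0:
        raise ValidationError("noise_sd must be > 0 for a noise prediction")
    return acq.noise_sd * pad_scale(acq) * RAYLEIGH_STD_FACTOR


def arterial_reference_snr(acq: AcquisitionParams, m_a0: float) -> float:
    """Ground-truth ``s_arterial``: the SNR a voxel of fresh arterial blood
    (magnetization m_a0) would show in the reconstructed SNR map.

    The zero-padding amplitude factor cancels between signal and noise,
    leaving m_a0 * w_DC / (noise_sd * sqrt(2 - pi/2)), where w_DC is the
    flip-angle depletion weight of the central k-space line.
    """
    if acq.noise_sd <= 0:
        raise ValidationError("noise_sd must be > 0 to define an SNR")
    return m_a0 * dc_line_weight(acq) / (acq.noise_sd * RAYLEIGH_STD_FACTOR)


def calibrate_noise_sd(
    spec: PhantomSpec,
    acq: AcquisitionParams,
    target_map_snr: float = 10.0,
) -> float:
    """k-space noise sd that yields a perfusion-weighted (slope) map SNR of
    ``target_map_snr`` for this phantom and acquisition.

    The slope-map SNR is mean(brain slope)/std(background slope).  In SNR
    units the background slope noise is 1/sqrt(S_tt) (S_tt the centered
    sum of squares of the delays), while the brain slope is the noiseless
    reconstructed magnitude slope divided by the expected background
    magnitude std; solving for the k-space sd gives a closed form.
    """
    if target_map_snr <= 0:
        raise ValidationError("target_map_snr must be > 0")
    from .recon import reconstruct_series  # local import to avoid a cycle

    clean = simulate_tof_series(spec, acq.with_noise(0.0))
    images = reconstruct_series(clean)
    tau = np.asarray(acq.tof_delays)
    t_c = tau - tau.mean()
    s_tt = float(np.sum(t_c**2))
    slope = np.tensordot(t_c, images, axes=(0, 0)) / s_tt
    brain = _upscale_mask(spec.union_mask(), acq.zero_pad_to)
    mean_slope = float(slope[brain].mean())
    return (
        mean_slope
        * math.sqrt(s_tt)
        / (RAYLEIGH_STD_FACTOR * pad_scale(acq) * target_map_snr)
    )


def calibrate_noise_for_image_snr(
    spec: PhantomSpec,
    acq: AcquisitionParams,
    target_image_snr: float = 10.0,
    dynamic: int = 0,
) -> float:
    """k-space noise sd giving a brain-mean image SNR of ``target_image_snr``
    in the chosen dynamic (default: the first, weakest one, so every image
    of the series reaches at least the target)."""
    if target_image_snr <= 0:
        raise ValidationError("target_image_snr must be > 0")
    from .recon import reconstruct_series  # local import to avoid a cycle

    clean = simulate_tof_series(spec, acq.with_noise(0.0))
    images = reconstruct_series(clean)
    brain = _upscale_mask(spec.union_mask(), acq.zero_pad_to)
    mean_signal = float(images[dynamic][brain].mean())
    return mean_signal / (
        RAYLEIGH_STD_FACTOR * pad_scale(acq) * target_image_snr
    )


def _upscale_mask(mask: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsampling of a boolean mask onto a larger grid."""
    ny, nx = mask.shape
    ty, tx = target
    yi = np.clip(((np.arange(ty) + 0.5) * ny / ty - 0.5).round(), 0, ny - 1)
    xi = np.clip(((np.arange(tx) + 0.5) * nx / tx - 0.5).round(), 0, nx - 1)
    return mask[yi.astype(int)[:, None], xi.astype(int)[None, :]]


def upscale_mask(mask: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Public alias of the nearest-neighbour mask upsampler."""
    return _upscale_mask(mask, target)
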