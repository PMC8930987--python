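"""Image -> temporal waveform forward model.

An object pattern illuminated by a short laser pulse excites the guided
modes of the multimode fiber in proportion to its overlap with each mode
field. After a long fiber, intermodal dispersion stretches the pulse into a
train of per-mode subpulses whose envelope the photodetector records: the
waveform is the sum of delayed pulse replicas weighted by the per-mode
coupled powers, low-pass filtered by the detector impulse response, sampled,
and optionally degraded by additive white Gaussian noise.

Subpulse powers add incoherently at the detector (intensity detection, no
inter-modal interference terms); coherence enters only through the choice of
coupling model (amplitude overlap vs intensity overlap).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, qr

from .fiber import ModeBasis, group_delays
from .patterns import ImagePattern

__all__ = [
    "OpticalPulse",
    "DetectorSpec",
    "SceneGeometry",
    "Waveform",
    "CouplingResult",
    "couple_image",
    "couple_images",
    "perturb_coupling",
    "synthesize_waveform",
    "synthesize_waveforms",
    "waveform_train",
    "frame_support_ns",
    "max_frame_rate",
    "record_duration_us",
    "frame_depth",
]

log = logging.getLogger(__name__)

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class OpticalPulse:
    """Illumination pulse: Gaussian of given FWHM, fixed repetition period."""

    fwhm_ps: float = 45.1
    period_ns: float = 65.0
    energy: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm_ps <= 0:
            raise ValueError("fwhm_ps must be positive")
        if self.period_ns <= self.fwhm_ps / 1000.0:
            raise ValueError("period must exceed the pulse width")


@dataclass(frozen=True)
class DetectorSpec:
    """Photodetector + digitiser: Gaussian impulse response, uniform sampling."""

    bandwidth_ghz: float = 30.0
    sample_rate_gsps: float = 100.0
    noise_snr_db: float = 30.0
    impulse_fwhm_ps: float = 15.0

    def __post_init__(self) -> None:
        for name in ("bandwidth_ghz", "sample_rate_gsps", "impulse_fwhm_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sample_rate_gsps <= 2 * self.bandwidth_ghz:
            log.warning(
                "sample rate %.3g GS/s is below 2x bandwidth %.3g GHz",
                self.sample_rate_gsps,
                self.bandwidth_ghz,
            )

    @property
    def dt_ps(self) -> float:
        return 1000.0 / self.sample_rate_gsps


@dataclass(frozen=True)
class SceneGeometry:
    """Mapping from object pixels to the fiber input facet.

    ``magnification`` scales object-plane distances onto the facet;
    ``offset_um`` shifts the image centre off the fiber axis (real probes
    are never perfectly centred, and a slight decentre breaks the exact
    circular symmetry of an on-axis launch).
    """

    pixel_pitch_um: float = 7.56
    image_shape: tuple[int, int] = (28, 28)
    magnification: float = 0.24
    offset_um: tuple[float, float] = (2.0, 3.0)

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")

    def footprint_um(self) -> tuple[float, float]:
        r, c = self.image_shape
        return (r * self.pixel_pitch_um * self.magnification,
                c * self.pixel_pitch_um * self.magnification)


@dataclass
class Waveform:
    """One detector-sampled frame.

    ``t0_ps`` is the time of the first sample relative to the earliest mode
    arrival; all frames simulated for one fiber configuration share the same
    origin (oscilloscope-style triggering).
    """

    samples: np.ndarray
    dt_ps: float
    t0_ps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def t_ps(self) -> np.ndarray:
        return self.t0_ps + self.dt_ps * np.arange(len(self.samples))


@dataclass
class CouplingResult:
    """Per-mode excitation of one image."""

    mode_powers: np.ndarray
    mode_amplitudes: np.ndarray | None
    model: str  # "coherent" | "incoherent"
    total_input: float = 0.0  # input intensity over the facet window (for power fractions)


# --------------------------------------------------------------------------
# facet resampling


def _facet_sampling(basis: ModeBasis, geometry: SceneGeometry):
    """Bilinear interpolation indices/weights mapping images onto the facet grid.

    Returns (idx, wts) such that facet_values = sum_k wts[k] * image_flat[idx[k]]
    for each of the 4 bilinear neighbours; facet points falling outside the
    image footprint get zero weight.
    """
    rows, cols = geometry.image_shape
    coords = basis.grid_coords_um
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    scale = geometry.pixel_pitch_um * geometry.magnification
    # fractional pixel coordinates of each facet point
    col_f = (xx - geometry.offset_um[0]) / scale + (cols - 1) / 2.0
    row_f = (yy - geometry.offset_um[1]) / scale + (rows - 1) / 2.0

    r0 = np.floor(row_f).astype(int)
    c0 = np.floor(col_f).astype(int)
    fr = row_f - r0
    fc = col_f - c0

    idx_list, wts_list = [], []
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr, cc = r0 + dr, c0 + dc
        valid = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        idx = np.where(valid, rr * cols + cc, 0)
        idx_list.append(idx.ravel())
        wts_list.append(np.where(valid, w, 0.0).ravel())
    return np.stack(idx_list), np.stack(wts_list)


def _resample_stack(images: np.ndarray, basis: ModeBasis, geometry: SceneGeometry) -> np.ndarray:
    """(n, rows*cols) image stack -> (n, g*g) facet-grid intensities."""
    idx, wts = _facet_sampling(basis, geometry)
    flat = images.reshape(images.shape[0], -1)
    out = np.zeros((flat.shape[0], idx.shape[1]))
    for k in range(4):
        out += wts[k][None, :] * flat[:, idx[k]]
    return out




def couple_images(
    images: np.ndarray,
    basis: ModeBasis,
    geometry: SceneGeometry,
    model: str = "coherent",
    speckle_seed: int | None = None,
    normalize: bool = False,
) -> np.ndarray:
    """Vectorised coupling of an (n, rows, cols) stack -> (n, n_modes) powers.

    Identical arithmetic to :func:`couple_image` applied per frame; the
    coherent model uses one shared speckle-phase screen per call.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if images.shape[1:] != tuple(geometry.image_shape):
        raise ValueError(
            f"image stack shape {images.shape[1:]} does not match geometry "
            f"image_shape {tuple(geometry.image_shape)}"
        )
    psi = basis.fields_flat()
    if model == "incoherent":
        kernel = (psi**2).T
    elif model == "coherent":
        if speckle_seed is not None:
            phases = np.random.default_rng(speckle_seed).uniform(0, 2 * np.pi, psi.shape[1])
    else:
        raise ValueError(f"unknown coupling model {model!r}")

    # chunk the facet-grid resampling: the (n, grid**2) intermediate is by
    # far the largest array in the pipeline
    chunk = max(1, int(2e8 // (8 * psi.shape[1])))
    out = np.empty((len(images), psi.shape[0]))
    for lo in range(0, len(images), chunk):
        facet = _resample_stack(images[lo : lo + chunk], basis, geometry)
        if model == "incoherent":
            powers = facet @ kernel
        else:
            amp = np.sqrt(facet)
            if speckle_seed is not None:
                c_re = (amp * np.cos(phases)[None, :]) @ psi.T
                c_im = (amp * np.sin(phases)[None, :]) @ psi.T
                powers = c_re**2 + c_im**2
            else:
                powers = (amp @ psi.T) ** 2
        if normalize:
            total = facet.sum(axis=1)
            powers = np.where(
                total[:, None] > 0, powers / np.maximum(total, 1e-300)[:, None], 0.0
            )
        out[lo : lo + len(powers)] = powers
    return out


def couple_image(
    image: ImagePattern | np.ndarray,
    basis: ModeBasis,
    geometry: SceneGeometry,
    model: str = "coherent",
    speckle_seed: int | None = None,
    normalize: bool = False,
) -> CouplingResult:
    """Project one image onto the fiber's guided modes.

    Coherent model: amplitude overlap c_m = sum_px sqrt(I_px) e^{i phi_px}
    psi_m(px) with phi = 0 (plane-wave illumination) or random phases drawn
    from ``speckle_seed``; P_m = |c_m|^2. Incoherent model: P_m =
    sum_px I_px psi_m(px)^2, linear in intensity. With ``normalize=True``
    powers are divided by the input intensity over the facet window (power
    fractions bounded by 1, Bessel's inequality); the default keeps raw
    powers so the incoherent model stays linear in the image.
    """
    arr = image.intensities if isinstance(image, ImagePattern) else np.asarray(image, dtype=float)
    if arr.min() < 0:
        raise ValueError("image must be nonnegative")
    if arr.shape != tuple(geometry.image_shape):
        log.info("image shape %s resampled onto declared geometry %s", arr.shape, geometry.image_shape)
        geometry = SceneGeometry(
            pixel_pitch_um=geometry.pixel_pitch_um * geometry.image_shape[0] / arr.shape[0],
            image_shape=arr.shape,
            magnification=geometry.magnification,
            offset_um=geometry.offset_um,
        )
    facet = _resample_stack(arr[None], basis, geometry)[0]
    psi = basis.fields_flat()
    amps = None
    if model == "incoherent":
        powers = (psi**2) @ facet
    elif model == "coherent":
        amp = np.sqrt(facet)
        if speckle_seed is not None:
            phases = np.random.default_rng(speckle_seed).uniform(0, 2 * np.pi, facet.shape[0])
            c = psi @ (amp * np.exp(1j * phases))
        else:
            c = (psi @ amp).astype(complex)
        amps = c
        powers = np.abs(c) ** 2
    else:
        raise ValueError(f"unknown coupling model {model!r}")
    total = float(facet.sum())
    if normalize:
        if total > 0:
            powers = powers / total
            if amps is not None:
                amps = amps / math.sqrt(total)
        else:
            powers = np.zeros_like(powers)
    return CouplingResult(mode_powers=powers, mode_amplitudes=amps, model=model, total_input=total)


# --------------------------------------------------------------------------
# perturbation model for robustness studies


def _draw_perturbation(
    delays: np.ndarray,
    strength: float,
    delay_jitter_ps: float,
    seed: int,
    pulse_fwhm_ps: float,
) -> tuple[list[tuple[int, int, np.ndarray]], np.ndarray]:
    """Seeded block rotations + delay jitter shared by all perturbation paths.

    Modes whose unperturbed delays differ by less than one pulse FWHM are
    grouped into blocks (consecutive-gap clustering on the delay-sorted
    modes); each block of size >= 2 gets a random special-orthogonal
    rotation geodesically interpolated between identity (strength 0) and a
    full random rotation (strength 1): R(s) = expm(s*logm(Q)).
    """
    rng = np.random.default_rng(seed)
    gaps = np.diff(delays)
    bounds = np.concatenate([[0], np.nonzero(gaps >= pulse_fwhm_ps)[0] + 1, [len(delays)]])
    rotations = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        k = b - a
        if k < 2:
            continue
        gauss = rng.normal(size=(k, k))
        q, r = qr(gauss)
        q = q @ np.diag(np.sign(np.diag(r)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        rotations.append((int(a), int(b), expm(strength * _real_skew_log(q))))
    jitter = rng.normal(0.0, 1.0, size=len(delays)) * delay_jitter_ps * strength
    return rotations, jitter


def perturb_coupling(
    result: CouplingResult,
    basis: ModeBasis,
    strength: float,
    delay_jitter_ps: float,
    seed: int,
    pulse_fwhm_ps: float = 45.1,
    length_m: float | None = None,
) -> tuple[CouplingResult, np.ndarray]:
    """Abstract temperature/bending perturbation: crosstalk + delay jitter.

    Random orthogonal mixing among modes with near-degenerate delays
    (power-conserving) plus zero-mean Gaussian delay jitter of scale
    ``delay_jitter_ps * strength``. Deterministic given ``seed``.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    delays = group_delays(basis, length_m)
    rotations, jitter = _draw_perturbation(delays, strength, delay_jitter_ps, seed, pulse_fwhm_ps)
    amps = (
        result.mode_amplitudes.copy()
        if result.mode_amplitudes is not None
        else np.sqrt(result.mode_powers).astype(float)
    )
    for a, b, rot in rotations:
        amps[a:b] = rot @ amps[a:b]
    new = CouplingResult(
        mode_powers=np.abs(amps) ** 2,
        mode_amplitudes=amps if result.mode_amplitudes is not None else None,
        model=result.model,
        total_input=result.total_input,
    )
    return new, delays + jitter


def perturb_powers(
    powers: np.ndarray,
    delays: np.ndarray,
    strength: float,
    delay_jitter_ps: float,
    seed: int,
    pulse_fwhm_ps: float = 45.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch form of :func:`perturb_coupling` on an (n, n_modes) power stack."""
    if strength == 0.0:
        return powers.copy(), np.asarray(delays, dtype=float).copy()
    rotations, jitter = _draw_perturbation(
        np.asarray(delays, dtype=float), strength, delay_jitter_ps, seed, pulse_fwhm_ps
    )
    amps = np.sqrt(np.atleast_2d(powers))
    out = amps.copy()
    for a, b, rot in rotations:
        out[:, a:b] = amps[:, a:b] @ rot.T
    return out**2, np.asarray(delays, dtype=float) + jitter


def _real_skew_log(q: np.ndarray) -> np.ndarray:
    """Real skew-symmetric logarithm of a special orthogonal matrix."""
    from scipy.linalg import logm

    a = np.real(logm(q))
    return (a - a.T) / 2.0


# --------------------------------------------------------------------------
# waveform synthesis


def _combined_sigma_ps(pulse: OpticalPulse, det: DetectorSpec) -> float:
    """Gaussian pulse convolved with Gaussian detector impulse (both FWHM)."""
    sp = pulse.fwhm_ps * _FWHM_TO_SIGMA
    sd = det.impulse_fwhm_ps * _FWHM_TO_SIGMA
    return math.hypot(sp, sd)


def _time_window(delays_ps: np.ndarray, pulse: OpticalPulse, det: DetectorSpec):
    t_start = float(delays_ps.min()) - 5.0 * pulse.fwhm_ps
    t_end = float(delays_ps.max()) + 5.0 * pulse.fwhm_ps + 5.0 * det.impulse_fwhm_ps
    return t_start, t_end


def synthesize_waveform(
    result: CouplingResult,
    delays_ps: np.ndarray,
    pulse: OpticalPulse,
    det: DetectorSpec,
    noise_seed: int | None = None,
    window_ps: tuple[float, float] | None = None,
    meta: dict | None = None,
) -> Waveform:
    """Detector trace of one frame: sum of delayed, filtered subpulses.

    The ideal trace P(t) = sum_m P_m g(t - tau_m), with g a unit-energy
    Gaussian of the pulse FWHM, convolved with the (unit-DC-gain) Gaussian
    detector impulse — evaluated in closed form as a Gaussian of combined
    width — then sampled at the digitiser rate. White Gaussian noise at the
    detector's SNR is added when ``noise_seed`` is given.
    """
    delays_ps = np.asarray(delays_ps, dtype=float)
    powers = np.asarray(result.mode_powers, dtype=float)
    if len(delays_ps) != len(powers):
        raise ValueError("delays and mode powers must have equal length")
    if len(powers) == 0:
        raise ValueError("empty mode set")
    t_start, t_end = window_ps or _time_window(delays_ps, pulse, det)
    dt = det.dt_ps
    t = np.arange(t_start, t_end, dt)
    sigma = _combined_sigma_ps(pulse, det)
    kernel = np.exp(-((t[:, None] - delays_ps[None, :]) ** 2) / (2 * sigma * sigma))
    samples = kernel @ (powers * pulse.energy) / (sigma * math.sqrt(2 * math.pi))
    if noise_seed is not None:
        rms = float(np.sqrt(np.mean(samples**2)))
        noise_std = rms / (10 ** (det.noise_snr_db / 20.0))
        samples = samples + np.random.default_rng(noise_seed).normal(0, noise_std, len(samples))
    t0 = t_start - float(delays_ps.min())
    m = {"n_modes": len(powers), "model": result.model}
    if meta:
        m.update(meta)
    return Waveform(samples=samples, dt_ps=dt, t0_ps=t0, meta=m)


def synthesize_waveforms(
    powers: np.ndarray,
    delays_ps: np.ndarray,
    pulse: OpticalPulse,
    det: DetectorSpec,
    noise_seed: int | None = None,
    window_ps: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float, float]:
    """Batch form: (n, n_modes) powers -> (n, n_t) traces, shared window.

    Returns (samples, dt_ps, t0_ps). Per-frame noise streams are drawn from
    independent children of ``noise_seed``.
    """
    delays_ps = np.asarray(delays_ps, dtype=float)
    powers = np.atleast_2d(np.asarray(powers, dtype=float))
    t_start, t_end = window_ps or _time_window(delays_ps, pulse, det)
    dt = det.dt_ps
    t = np.arange(t_start, t_end, dt)
    sigma = _combined_sigma_ps(pulse, det)
    kernel = np.exp(-((t[:, None] - delays_ps[None, :]) ** 2) / (2 * sigma * sigma)) / (
        sigma * math.sqrt(2 * math.pi)
    )
    traces = (powers * pulse.energy) @ kernel.T
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        rms = np.sqrt(np.mean(traces**2, axis=1, keepdims=True))
        noise_std = rms / (10 ** (det.noise_snr_db / 20.0))
        # add noise in row chunks to cap the temporary normal-draw array;
        # the generator stream is identical to a single full-size draw
        chunk = max(1, int(2e8 // (8 * traces.shape[1])))
        for lo in range(0, len(traces), chunk):
            hi = min(lo + chunk, len(traces))
            traces[lo:hi] += rng.normal(size=(hi - lo, traces.shape[1])) * noise_std[lo:hi]
    return traces, dt, t_start - float(delays_ps.min())


def frame_support_ns(delays_ps: np.ndarray, pulse: OpticalPulse, det: DetectorSpec) -> float:
    """Temporal span of one frame (window length) in ns."""
    t_start, t_end = _time_window(np.asarray(delays_ps, dtype=float), pulse, det)
    return (t_end - t_start) / 1000.0


def waveform_train(
    images,
    basis: ModeBasis,
    geometry: SceneGeometry,
    pulse: OpticalPulse,
    det: DetectorSpec,
    model: str = "coherent",
    noise_seed: int | None = None,
) -> tuple[Waveform, bool]:
    """Concatenate per-image frames at the pulse repetition period.

    Frames are placed at integer multiples of ``pulse.period_ns``; the
    overlap flag is True iff a single frame's support strictly exceeds the
    period (closed-open convention: exact equality does not overlap).
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    stack = np.stack(
        [im.intensities if isinstance(im, ImagePattern) else np.asarray(im) for im in images]
    )
    powers = couple_images(stack, basis, geometry, model=model)
    delays = group_delays(basis)
    span_ns = frame_support_ns(delays, pulse, det)
    overlap = span_ns > pulse.period_ns
    frames, dt, t0 = synthesize_waveforms(powers, delays, pulse, det, noise_seed=noise_seed)
    n_t = frames.shape[1]
    period_samples = int(round(pulse.period_ns * 1000.0 / dt))
    total = period_samples * (len(images) - 1) + n_t
    stream = np.zeros(total)
    for i in range(len(images)):
        stream[i * period_samples : i * period_samples + n_t] += frames[i]
    wf = Waveform(
        samples=stream,
        dt_ps=dt,
        t0_ps=t0,
        meta={"n_frames": len(images), "period_ns": pulse.period_ns, "overlap": bool(overlap)},
    )
    return wf, bool(overlap)


def max_frame_rate(single_frame_span_ns: float) -> float:
    """Maximum non-overlapping frame rate in MHz, displayed at 3 sig. figs."""
    if single_frame_span_ns <= 0:
        raise ValueError("span must be positive")
    rate = 1000.0 / single_frame_span_ns
    return float(f"{rate:.3g}")


def record_duration_us(n_samples: float, sample_rate_gsps: float) -> float:
    """Record duration (us) of ``n_samples`` at the digitiser rate."""
    return n_samples / (sample_rate_gsps * 1e9) * 1e6


def frame_depth(record_us: float, period_ns: float) -> int:
    """Number of frames a single record can hold."""
    return int(record_us * 1000.0 / period_ns)
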