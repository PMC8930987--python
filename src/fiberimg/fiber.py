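"""Guided LP modes of a step-index multimode fiber.

Solves the weakly-guiding (scalar) characteristic equation for all guided
LP(l, m) modes of a step-index fiber, evaluates their propagation constants,
transverse field profiles and group delays, and provides the intermodal- vs
chromatic-dispersion dominance check that underpins temporal image encoding:
a short pulse launched into a long step-index fiber splits into per-mode
subpulses because each mode has its own group velocity.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import bisect
from scipy.special import jn_zeros, jv, kve

__all__ = [
    "C_M_PER_S",
    "FiberSpec",
    "LPMode",
    "ModeBasis",
    "v_number",
    "find_lp_modes",
    "group_delays",
    "delay_spread_ns",
    "dispersion_dominance_check",
    "export_mode_table",
]

log = logging.getLogger(__name__)

#: vacuum speed of light (m/s)
C_M_PER_S = 299_792_458.0

# Root-finder granularity: points per unit-l scan and bisection tolerance.
_SCAN_POINTS = 4000
_BISECT_XTOL = 1e-12


@dataclass(frozen=True)
class FiberSpec:
    """Step-index fiber geometry and operating point.

    The numerical aperture fixes the index contrast: n_core =
    sqrt(n_clad**2 + na**2). ``n_clad`` defaults to fused silica near
    1064 nm; only the NA (not the absolute indices) is usually quoted for
    commercial fiber, so absolute delays (but not spreads normalised by
    contrast) depend on this choice.
    """

    core_radius_um: float = 25.0
    na: float = 0.22
    length_m: float = 1000.0
    wavelength_nm: float = 1064.0
    n_clad: float = 1.4496

    def __post_init__(self) -> None:
        if self.core_radius_um <= 0:
            raise ValueError(f"core_radius_um must be > 0, got {self.core_radius_um}")
        if not 0 < self.na < self.n_clad:
            raise ValueError(f"need 0 < na < n_clad, got na={self.na}, n_clad={self.n_clad}")
        if self.length_m <= 0:
            raise ValueError(f"length_m must be > 0, got {self.length_m}")
        if self.wavelength_nm <= 0:
            raise ValueError(f"wavelength_nm must be > 0, got {self.wavelength_nm}")

    @property
    def n_core(self) -> float:
        return math.hypot(self.n_clad, self.na)

    @property
    def delta(self) -> float:
        """Relative index contrast (n_core - n_clad) / n_core."""
        return (self.n_core - self.n_clad) / self.n_core


@dataclass(frozen=True)
class LPMode:
    """One guided LP(l, m) mode (one orientation).

    ``u`` and ``w`` are the normalised transverse parameters in core and
    cladding (u**2 + w**2 = V**2), ``beta`` the propagation constant and
    ``group_delay_ps_per_m`` the transit time per metre, L*dbeta/domega / L.
    """

    l: int
    m: int
    orientation: str  # "even" (cos l*phi) or "odd" (sin l*phi)
    u: float
    w: float
    beta: float
    group_delay_ps_per_m: float


@dataclass
class ModeBasis:
    """The solved guided-mode set of one fiber.

    ``field_grid[i]`` is the transverse field of ``modes[i]`` sampled on a
    square grid of half-width ``grid_half_width_um``, discretely
    orthonormalised (sum of psi_i*psi_j over grid points = delta_ij).
    Modes are sorted by ascending group delay, so per-mode arrays align
    with the temporal ordering of the subpulses.
    """

    fiber: FiberSpec
    modes: list[LPMode]
    v_number: float
    field_grid: np.ndarray  # (n_modes, g, g) float64
    grid_half_width_um: float
    grid_coords_um: np.ndarray = field(repr=False, default=None)  # (g,) axis coords

    def __len__(self) -> int:
        return len(self.modes)

    @property
    def n_spatial_modes(self) -> int:
        return len(self.modes)

    @property
    def delays_ps_per_m(self) -> np.ndarray:
        return np.array([m.group_delay_ps_per_m for m in self.modes])

    def fields_flat(self) -> np.ndarray:
        """(n_modes, g*g) view of the orthonormal fields."""
        n = len(self.modes)
        return self.field_grid.reshape(n, -1)


def v_number(fiber: FiberSpec) -> float:
    """Normalised frequency V = 2*pi*a*NA/lambda."""
    lam_um = fiber.wavelength_nm * 1e-3
    return 2.0 * math.pi * fiber.core_radius_um * fiber.na / lam_um


def _char_eq(l: int, u: np.ndarray, v: float) -> np.ndarray:
    """Pole-free form of the LP characteristic equation.

    u*J_{l-1}(u)*K_l(w) + w*K_{l-1}(w)*J_l(u) = 0 with w = sqrt(V^2-u^2);
    the common factor exp(-w) of the modified Bessel functions is dropped
    (kve is the exponentially scaled K), which does not move the roots but
    keeps the expression finite at large V.
    """
    u = np.asarray(u, dtype=float)
    w = np.sqrt(np.maximum(v * v - u * u, 0.0))
    return u * jv(l - 1, u) * kve(l, w) + w * kve(l - 1, w) * jv(l, u)


def _solve_radial_roots(l: int, v: float) -> list[float]:
    """All u-roots for azimuthal order l: bracket on a uniform grid, bisect."""
    lo = 1e-9 * max(v, 1.0)
    hi = v * (1.0 - 1e-9)
    if hi <= lo:
        return []
    grid = np.linspace(lo, hi, _SCAN_POINTS)
    vals = _char_eq(l, grid, v)
    roots: list[float] = []
    sign = np.sign(vals)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in flips:
        a, b = grid[i], grid[i + 1]
        try:
            root = bisect(lambda u: float(_char_eq(l, u, v)), a, b, xtol=_BISECT_XTOL)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"LP root refinement failed for l={l} in bracket ({a:.6g}, {b:.6g})"
            ) from exc
        roots.append(float(root))
    return roots


def _solve_all_roots(v: float) -> dict[int, list[float]]:
    """u-roots for every azimuthal order until none are guided."""
    out: dict[int, list[float]] = {}
    l = 0
    while True:
        roots = _solve_radial_roots(l, v)
        if not roots:
            if l == 0:
                # Below every cutoff LP(0,1) is still guided; at very small V
                # the root hugs u ~ V and can slip through a coarse scan.
                fine = np.linspace(1e-12, v * (1 - 1e-12), 200_000)
                vals = _char_eq(0, fine, v)
                flips = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
                if len(flips):
                    i = flips[0]
                    roots = [
                        float(
                            bisect(
                                lambda u: float(_char_eq(0, u, v)),
                                fine[i],
                                fine[i + 1],
                                xtol=_BISECT_XTOL,
                            )
                        )
                    ]
                else:  # pragma: no cover - V <= 0 guarded upstream
                    raise RuntimeError("LP(0,1) root not found; invalid V")
                out[0] = roots
                break
            break
        out[l] = roots
        l += 1
    return out


def _beta(fiber: FiberSpec, u: float, lam_nm: float | None = None) -> float:
    lam_m = (lam_nm if lam_nm is not None else fiber.wavelength_nm) * 1e-9
    k = 2.0 * math.pi / lam_m
    a_m = fiber.core_radius_um * 1e-6
    return math.sqrt((k * fiber.n_core) ** 2 - (u / a_m) ** 2)


def _group_delays_for_order(
    fiber: FiberSpec, l: int, roots0: list[float], rel_step: float = 1e-4
) -> list[float]:
    """Group delays (ps/m) for all radial orders of one azimuthal order l.

    Centred finite difference of beta over wavelength: every root of order l
    is re-solved at lambda*(1 +/- rel_step) and matched by radial index;
    indices are held constant across the step (material dispersion
    neglected), so the derivative captures waveguide dispersion only. A mode
    that falls below cutoff at the longer wavelength (smaller V) is
    differenced one-sided toward shorter wavelength.
    """
    lam = fiber.wavelength_nm
    h = rel_step * lam

    def roots_at(lam_nm: float) -> list[float]:
        v = 2.0 * math.pi * fiber.core_radius_um * fiber.na / (lam_nm * 1e-3)
        return _solve_radial_roots(l, v)

    roots_plus = roots_at(lam + h)   # smaller V: modes may be lost
    roots_minus = roots_at(lam - h)  # larger V: all modes retained
    lam_m = lam * 1e-9
    scale = -(1.0 / 1e-9) * lam_m * lam_m / (2.0 * math.pi * C_M_PER_S)  # s/m per (rad/m/nm)
    out: list[float] = []
    for m_idx, u0 in enumerate(roots0):
        b_minus = _beta(fiber, roots_minus[m_idx], lam - h)
        if m_idx < len(roots_plus):
            b_plus = _beta(fiber, roots_plus[m_idx], lam + h)
            dbeta_dlam = (b_plus - b_minus) / (2.0 * h)
        else:
            log.warning(
                "LP(%d,%d) lost at perturbed wavelength; one-sided difference", l, m_idx + 1
            )
            dbeta_dlam = (_beta(fiber, u0, lam) - b_minus) / h
        out.append(dbeta_dlam * scale * 1e12)
    return out


def _mode_fields(
    fiber: FiberSpec,
    entries: list[tuple[int, int, str, float, float]],
    grid_size: int,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Analytic J/K fields on a square grid, Loewdin-orthonormalised.

    Grid spans 1.5x the core diameter. Symmetric (Loewdin) orthonormalisation
    S^(-1/2) Psi fixes the small non-orthogonality introduced by sampling and
    truncation while staying as close as possible to the analytic profiles.
    """
    a = fiber.core_radius_um
    half = 1.5 * a
    x = np.linspace(-half, half, grid_size)
    xx, yy = np.meshgrid(x, x, indexing="xy")
    r = np.hypot(xx, yy)
    phi = np.arctan2(yy, xx)
    rho = r / a

    fields = np.empty((len(entries), grid_size, grid_size))
    inside = rho <= 1.0
    for i, (l, _m, orient, u, w) in enumerate(entries):
        rad = np.zeros_like(r)
        ju = jv(l, u)
        rad[inside] = jv(l, u * rho[inside])
        out = ~inside
        # K_l(w*rho)/K_l(w) * J_l(u), written with scaled kve for stability
        rad[out] = ju * (kve(l, w * rho[out]) / kve(l, w)) * np.exp(-w * (rho[out] - 1.0))
        ang = np.cos(l * phi) if orient == "even" else np.sin(l * phi)
        fields[i] = rad * ang

    flat = fields.reshape(len(entries), -1)
    norms = np.linalg.norm(flat, axis=1)
    flat /= norms[:, None]
    gram = flat @ flat.T
    evals, evecs = np.linalg.eigh(gram)
    inv_sqrt = evecs @ np.diag(1.0 / np.sqrt(np.maximum(evals, 1e-12))) @ evecs.T
    flat = inv_sqrt @ flat
    return flat.reshape(len(entries), grid_size, grid_size), half, x


def find_lp_modes(fiber: FiberSpec, grid_size: int = 128) -> ModeBasis:
    """Solve every guided LP mode of ``fiber`` and sample its field.

    Returns a :class:`ModeBasis` with modes sorted by ascending group delay;
    for l > 0 both orientations (cos/sin) are enumerated and share u, w,
    beta and delay by construction.
    """
    if grid_size < 32:
        raise ValueError(f"grid_size must be >= 32, got {grid_size}")
    v = v_number(fiber)
    if v <= 0:
        raise ValueError("V-number must be positive")
    roots_by_l = _solve_all_roots(v)

    entries: list[tuple[int, int, str, float, float]] = []
    delays: list[float] = []
    betas: list[float] = []
    for l, roots in sorted(roots_by_l.items()):
        taus = _group_delays_for_order(fiber, l, roots)
        for m_idx, u in enumerate(roots):
            w = math.sqrt(max(v * v - u * u, 0.0))
            beta = _beta(fiber, u)
            tau = taus[m_idx]
            orientations = ("even",) if l == 0 else ("even", "odd")
            for orient in orientations:
                entries.append((l, m_idx + 1, orient, u, w))
                betas.append(beta)
                delays.append(tau)

    order = np.argsort(np.array(delays), kind="stable")
    entries = [entries[i] for i in order]
    betas = [betas[i] for i in order]
    delays = [delays[i] for i in order]

    fields, half, coords = _mode_fields(fiber, entries, grid_size)
    modes = [
        LPMode(l=e[0], m=e[1], orientation=e[2], u=e[3], w=e[4], beta=b, group_delay_ps_per_m=t)
        for e, b, t in zip(entries, betas, delays)
    ]
    return ModeBasis(
        fiber=fiber,
        modes=modes,
        v_number=v,
        field_grid=fields,
        grid_half_width_um=half,
        grid_coords_um=coords,
    )


def group_delays(basis: ModeBasis, length_m: float | None = None) -> np.ndarray:
    """Per-mode delays (ps) over ``length_m`` (default: the fiber's length).

    Delays are linear in length by construction and returned sorted
    ascending (the basis is delay-ordered).
    """
    length = basis.fiber.length_m if length_m is None else length_m
    return basis.delays_ps_per_m * length


def delay_spread_ns(basis: ModeBasis, length_m: float | None = None) -> float:
    """Intermodal delay spread max(tau) - min(tau) in ns."""
    d = group_delays(basis, length_m)
    return float(d.max() - d.min()) * 1e-3


def dispersion_dominance_check(
    fiber: FiberSpec,
    pulse_fwhm_ps: float,
    bandwidth_nm: float,
    chrom_disp_ps_nm_km: float,
    basis: ModeBasis | None = None,
    dominance_factor: float = 100.0,
    length_m: float | None = None,
) -> dict:
    """Compare intermodal delay spread against chromatic pulse broadening.

    Chromatic broadening = |D| * dlambda * L. The pulse evolution counts as
    intermodal-dispersion dominated when the intermodal spread exceeds
    ``dominance_factor`` times the chromatic broadening and there is any
    splitting at all (zero length -> not dominant by convention).
    """
    if pulse_fwhm_ps <= 0 or bandwidth_nm < 0 or chrom_disp_ps_nm_km < 0:
        raise ValueError("pulse width must be positive; bandwidth and dispersion nonnegative")
    length = fiber.length_m if length_m is None else length_m
    if length < 0:
        raise ValueError("length must be nonnegative")
    if basis is None:
        basis = find_lp_modes(fiber, grid_size=32)
    spread_ns = delay_spread_ns(basis, length_m=length)
    chromatic_ps = abs(chrom_disp_ps_nm_km) * bandwidth_nm * (length / 1000.0)
    dominant = spread_ns > 0 and (spread_ns * 1e3) > dominance_factor * chromatic_ps
    return {
        "intermodal_spread_ns": spread_ns,
        "chromatic_broadening_ps": chromatic_ps,
        "dominant": bool(dominant),
    }


def export_mode_table(basis: ModeBasis, path) -> None:
    """Write the solved mode table as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["l", "m", "orientation", "u", "w", "beta_rad_per_m", "delay_ps_per_m"])
        for mode in basis.modes:
            writer.writerow(
                [
                    mode.l,
                    mode.m,
                    mode.orientation,
                    f"{mode.u:.12g}",
                    f"{mode.w:.12g}",
                    f"{mode.beta:.12g}",
                    f"{mode.group_delay_ps_per_m:.12g}",
                ]
            )


def lp_mode_count_from_cutoffs(v: float, max_l: int = 200, max_m: int = 200) -> int:
    """Independent guided-mode count from closed-form LP cutoffs.

    LP(l, m) is guided iff V exceeds the m-th zero of J_{l-1} (with u = 0
    counting as the first 'zero' for l = 0, i.e. LP(0,1) is always guided).
    Counts both orientations for l > 0.
    """
    count = 0
    for l in range(0, max_l):
        if l == 0:
            cutoffs = np.concatenate([[0.0], jn_zeros(1, max_m)])
        else:
            cutoffs = jn_zeros(l - 1, max_m) if l != 1 else jn_zeros(0, max_m)
        n_guided = int(np.sum(cutoffs < v))
        if n_guided == 0:
            break
        count += n_guided if l == 0 else 2 * n_guided
    return count
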