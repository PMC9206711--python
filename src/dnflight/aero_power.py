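"""Mass-specific mechanical power model for flapping Drosophila flight.

The model splits muscle-mass-specific mechanical power ``P*_mech`` into

* induced power ``P*_ind`` — the actuator-disc momentum cost of producing the
  total flight force, and
* profile power ``P*_pro`` — the cost of overcoming profile drag on the
  flapping wings,

under the standard assumption that thoracic elastic storage absorbs inertial
power.  In SI form::

    P*_ind  = kappa * (F_t / m_M) * sqrt(F_t / (2 * rho * Phi * R**2))
    P*_pro  = rho * S * n**3 * Phi**3 * R**3 * r3_hat_cubed
              * mean_abs_angvel_cubed * C_D_pro / (16 * m_M)
    Re      = S * n * Phi / nu
    C_D_pro = 7 / sqrt(Re)      (unless a fixed measured value is supplied)

with wingbeat frequency ``n`` in Hz and stroke amplitude ``Phi`` in radians.
Because the profile term dominates at flight amplitudes, ``P*_mech`` is close
to proportional to ``(n * Phi)**3``, so a fixed muscle power budget forces an
inverse amplitude-frequency relationship along a power isoline.

Public functions are vectorised over ``n`` and ``Phi``; amplitudes may be
passed in degrees with ``degrees=True`` (wingbeat trackers report degrees),
but all internal evaluation is in radians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "Morphometrics",
    "KinematicState",
    "PowerBreakdown",
    "Isoline",
    "drosophila_morphometrics",
    "reynolds_number",
    "profile_drag_coefficient",
    "induced_power",
    "profile_power",
    "mechanical_power",
    "solve_isoline",
    "solve_frequency_for_power",
    "bounding_power",
]

# Interior amplitude bracket for root finding (radians).
_PHI_LO = 1e-3
_PHI_HI = 2.0 * np.pi - 1e-3


@dataclass(frozen=True)
class Morphometrics:
    """Wing, body and air parameters of the power model (SI units).

    Parameters
    ----------
    F_t : total flight force (N).
    rho : air density (kg m^-3).
    R : wing length (m).
    S : combined surface area of the two wings (m^2).
    m_M : flight-muscle mass (kg).
    g : gravitational acceleration (m s^-2).
    kappa : induced-power correction factor for periodic vortex shedding
        in the wake (dimensionless, >= 1 in practice).
    r3_hat_cubed : dimensionless third moment of wing area, r3_hat(S)**3.
    mean_abs_angvel_cubed : mean cube of the absolute dimensionless stroke
        angular velocity, <|dphi_hat/dt_hat|**3>, with the stroke angle
        normalised to the half-amplitude (sinusoidal value 32*pi**2/3).
    cd_pro_fixed : optional fixed mean profile drag coefficient.  When set it
        overrides the Reynolds-based 7/sqrt(Re) approximation globally for
        this parameter set.
    nu : kinematic viscosity of air (m^2 s^-1).
    """

    F_t: float
    rho: float
    R: float
    S: float
    m_M: float
    g: float = 9.81
    kappa: float = 1.2
    r3_hat_cubed: float = 0.26
    mean_abs_angvel_cubed: float = 105.3
    cd_pro_fixed: Optional[float] = None
    nu: float = 1.5e-5

    def __post_init__(self) -> None:
        for name in ("F_t", "rho", "R", "S", "m_M", "g", "kappa",
                     "r3_hat_cubed", "mean_abs_angvel_cubed", "nu"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"Morphometrics.{name} must be finite and >= 0, got {value!r}")
        # F_t = 0 is allowed (zero-lift limit); geometric/air parameters must be positive.
        for name in ("rho", "R", "S", "m_M", "nu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Morphometrics.{name} must be > 0")
        if 0 < self.kappa < 1:  # kappa=0 is the analytic profile-only limit
            warnings.warn("kappa < 1 is outside the usual wake-correction range", stacklevel=2)
        if self.cd_pro_fixed is not None and self.cd_pro_fixed <= 0:
            raise ValueError("cd_pro_fixed, when present, must be > 0")

    def with_(self, **kwargs) -> "Morphometrics":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def drosophila_morphometrics(cd_pro_fixed: Optional[float] = 1.36) -> Morphometrics:
    """A documented, plausible wild-type *Drosophila melanogaster* parameter set.

    Body mass ~1.1 mg hovering (flight force equals body weight), wing length
    2.5 mm, combined wing area 3.6 mm^2, flight muscle ~30% of body mass.
    By default the fixed measured mean profile drag coefficient 1.36 is used
    (robotic-wing measurement at tethered-flight kinematics); pass
    ``cd_pro_fixed=None`` for the 7/sqrt(Re) approximation.
    """
    return Morphometrics(
        F_t=1.1e-5,
        rho=1.2,
        R=2.5e-3,
        S=3.6e-6,
        m_M=3.3e-7,
        kappa=1.2,
        r3_hat_cubed=0.26,
        mean_abs_angvel_cubed=32.0 * np.pi**2 / 3.0,
        cd_pro_fixed=cd_pro_fixed,
        nu=1.5e-5,
    )


@dataclass(frozen=True)
class KinematicState:
    """One wingbeat kinematic sample: frequency ``n`` (Hz), amplitude ``phi`` (rad)."""

    n: float
    phi: float

    @classmethod
    def from_degrees(cls, n: float, phi_deg: float) -> "KinematicState":
        return cls(n=n, phi=np.deg2rad(phi_deg))

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"wingbeat frequency must be > 0, got {self.n}")
        if not (0 < self.phi < 2 * np.pi):
            raise ValueError(f"amplitude must lie in (0, 2*pi) rad, got {self.phi}")


@dataclass(frozen=True)
class PowerBreakdown:
    """Induced / profile / total mass-specific power (W kg^-1) for given kinematics."""

    P_ind: np.ndarray | float
    P_pro: np.ndarray | float
    P_mech: np.ndarray | float
    Re: np.ndarray | float
    cd_used: np.ndarray | float


@dataclass(frozen=True)
class Isoline:
    """A constant-power curve in the (frequency, amplitude) plane.

    ``n`` and ``phi`` hold the points where a root exists; ``n_omitted`` the
    grid frequencies at which no amplitude in the bracket attains ``P_level``.
    """

    P_level: float
    n: np.ndarray
    phi: np.ndarray
    n_omitted: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def phi_deg(self) -> np.ndarray:
        return np.rad2deg(self.phi)


def _as_radians(phi, degrees: bool) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    return np.deg2rad(phi) if degrees else phi


def _check_kinematics(n, phi) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0) or not np.all(np.isfinite(n)):
        raise ValueError("wingbeat frequency must be finite and > 0")
    if np.any(phi <= 0) or np.any(phi >= 2 * np.pi) or not np.all(np.isfinite(phi)):
        raise ValueError("wingbeat amplitude must be finite and in (0, 2*pi) rad")
    return n, phi


def reynolds_number(n, phi, morph: Morphometrics, *, degrees: bool = False):
    """Reynolds number of the flapping wing, Re = S*n*Phi/nu."""
    phi = _as_radians(phi, degrees)
    n, phi = _check_kinematics(n, phi)
    return morph.S * n * phi / morph.nu


def profile_drag_coefficient(Re, morph: Morphometrics):
    """Mean profile drag coefficient: fixed measured value if supplied, else 7/sqrt(Re)."""
    Re = np.asarray(Re, dtype=float)
    if np.any(Re <= 0) or not np.all(np.isfinite(Re)):
        raise ValueError("Reynolds number must be finite and > 0")
    if morph.cd_pro_fixed is not None:
        return np.broadcast_to(np.float64(morph.cd_pro_fixed), Re.shape)[()] if Re.shape else float(morph.cd_pro_fixed)
    out = 7.0 / np.sqrt(Re)
    return out if out.shape else float(out)


def induced_power(n, phi, morph: Morphometrics, *, degrees: bool = False):
    """Mass-specific induced power, kappa*(F_t/m_M)*sqrt(F_t/(2*rho*Phi*R^2)).

    Independent of wingbeat frequency; monotone decreasing in amplitude
    (larger stroke sweeps a larger actuator-disc area).
    """
    phi = _as_radians(phi, degrees)
    n, phi = _check_kinematics(n, phi)
    out = morph.kappa * (morph.F_t / morph.m_M) * np.sqrt(
        morph.F_t / (2.0 * morph.rho * phi * morph.R**2)
    )
    out = np.broadcast_to(out, np.broadcast_shapes(np.shape(n), np.shape(phi)))
    return float(out) if out.ndim == 0 else out.copy()


def profile_power(n, phi, morph: Morphometrics, *, degrees: bool = False):
    """Mass-specific profile power.

    rho*S*n^3*Phi^3*R^3*r3_hat^3*<|dphi_hat/dt_hat|^3>*C_D_pro / (16*m_M).
    With a fixed drag coefficient this is exactly proportional to (n*Phi)^3;
    with the 7/sqrt(Re) coefficient the exponent drops to 2.5.
    """
    phi = _as_radians(phi, degrees)
    n, phi = _check_kinematics(n, phi)
    cd = profile_drag_coefficient(reynolds_number(n, phi, morph), morph)
    out = (
        morph.rho * morph.S * n**3 * phi**3 * morph.R**3
        * morph.r3_hat_cubed * morph.mean_abs_angvel_cubed * cd
        / (16.0 * morph.m_M)
    )
    return float(out) if np.ndim(out) == 0 else out


def mechanical_power(n, phi, morph: Morphometrics, *, degrees: bool = False) -> PowerBreakdown:
    """Total mass-specific mechanical power P*_mech = P*_ind + P*_pro."""
    phi_rad = _as_radians(phi, degrees)
    Re = reynolds_number(n, phi_rad, morph)
    cd = profile_drag_coefficient(Re, morph)
    P_ind = induced_power(n, phi_rad, morph)
    P_pro = profile_power(n, phi_rad, morph)
    return PowerBreakdown(P_ind=P_ind, P_pro=P_pro, P_mech=P_ind + P_pro, Re=Re, cd_used=cd)


def _p_mech_scalar(n: float, phi: float, morph: Morphometrics) -> float:
    return float(mechanical_power(n, phi, morph).P_mech)


def _upper_root_in_phi(n: float, P_level: float, morph: Morphometrics) -> Optional[float]:
    """Amplitude on the profile-dominated branch with P_mech(n, phi) = P_level.

    At fixed n, P_mech diverges as phi -> 0 (induced term ~ phi^-0.5) and grows
    ~ phi^3 at large phi, so it has one interior minimum; the level equation may
    have a low-amplitude (induced) and a high-amplitude (profile) root.  The
    physical isoline is the upper branch.  Returns None when no root exists in
    the bracket.
    """
    f = lambda phi: _p_mech_scalar(n, phi, morph) - P_level
    if morph.kappa == 0.0 or morph.F_t == 0.0:
        # P_mech monotone increasing in phi: bracket from the lower edge.
        phi_lo = _PHI_LO
    else:
        res = minimize_scalar(lambda p: _p_mech_scalar(n, p, morph),
                              bounds=(_PHI_LO, _PHI_HI), method="bounded",
                              options={"xatol": 1e-12})
        phi_lo = float(res.x)
        if f(phi_lo) > 0:
            return None  # power at this n never drops to P_level
    if f(phi_lo) > 0 or f(_PHI_HI) < 0:
        return None
    return brentq(f, phi_lo, _PHI_HI, xtol=1e-14, rtol=8.9e-16)


def solve_isoline(P_level: float, n_grid: Sequence[float], morph: Morphometrics,
                  rtol: float = 1e-9) -> Isoline:
    """Trace the P_mech = P_level isoline over an ascending frequency grid.

    For each frequency a bracketed Brent root-find locates the amplitude on the
    profile-dominated branch; grid points with no root in (0, 2*pi) are omitted
    and reported in ``n_omitted``.  Residuals are verified against ``rtol``
    (relative, default 1e-9).

    Raises
    ------
    ValueError
        If ``P_level <= 0``, the grid is not ascending, or no grid point admits
        a root ("no isoline in range").
    """
    if P_level <= 0:
        raise ValueError("P_level must be > 0")
    n_grid = np.asarray(n_grid, dtype=float)
    if n_grid.ndim != 1 or n_grid.size == 0 or np.any(np.diff(n_grid) <= 0):
        raise ValueError("n_grid must be a non-empty strictly ascending 1-D array")
    ns, phis, omitted = [], [], []
    for n in n_grid:
        phi = _upper_root_in_phi(float(n), P_level, morph)
        if phi is None:
            omitted.append(n)
            continue
        resid = abs(_p_mech_scalar(float(n), phi, morph) - P_level)
        if resid > rtol * P_level:
            raise RuntimeError(f"isoline residual {resid:.3e} exceeds tolerance at n={n}")
        ns.append(n)
        phis.append(phi)
    if not ns:
        raise ValueError(f"no isoline in range: P_level={P_level} unreachable on the given grid")
    return Isoline(P_level=float(P_level), n=np.array(ns), phi=np.array(phis),
                   n_omitted=np.array(omitted))


def solve_frequency_for_power(phi, P_level: float, morph: Morphometrics,
                              *, degrees: bool = False):
    """Frequency at which P_mech(n, phi) = P_level for given amplitude(s).

    The inverse isoline in closed form: the induced term is n-independent and
    the profile term is a pure power law in n (exponent 3 with a fixed drag
    coefficient, 2.5 with the 7/sqrt(Re) coefficient), so

        n = [(P_level - P_ind(phi)) / K(phi)] ** (1/p).

    Vectorised over ``phi``; raises if P_level does not exceed the induced
    power at any requested amplitude (no frequency can reach that level).
    """
    scalar_in = np.ndim(phi) == 0
    phi = np.atleast_1d(_as_radians(phi, degrees))
    _check_kinematics(np.ones_like(phi), phi)
    P_ind = np.asarray(induced_power(np.ones_like(phi), phi, morph))
    avail = P_level - P_ind
    if np.any(avail <= 0):
        raise ValueError("P_level does not exceed induced power; no frequency solves it")
    A = (morph.rho * morph.S * morph.R**3 * morph.r3_hat_cubed
         * morph.mean_abs_angvel_cubed / (16.0 * morph.m_M))
    if morph.cd_pro_fixed is not None:
        K = A * morph.cd_pro_fixed * phi**3
        p = 3.0
    else:
        K = A * 7.0 * np.sqrt(morph.nu / (morph.S * phi)) * phi**3
        p = 2.5
    n = (avail / K) ** (1.0 / p)
    return float(n[0]) if scalar_in else n


def bounding_power(trajectory: Sequence[KinematicState] | tuple, morph: Morphometrics,
                   *, degrees: bool = False) -> tuple[float, int]:
    """Maximum P_mech over a kinematic trajectory and the index where it occurs.

    The returned level is the power isoline that bounds the observed (n, Phi)
    cloud from above.  ``trajectory`` is either a sequence of KinematicState
    or a ``(n_array, phi_array)`` pair.
    """
    if isinstance(trajectory, tuple) and len(trajectory) == 2:
        n, phi = trajectory
    else:
        traj = list(trajectory)
        if not traj:
            raise ValueError("empty trajectory")
        n = np.array([s.n for s in traj])
        phi = np.array([s.phi for s in traj])
        degrees = False
    n = np.asarray(n, dtype=float)
    phi = _as_radians(phi, degrees)
    if n.size == 0:
        raise ValueError("empty trajectory")
    if n.shape != phi.shape:
        raise ValueError("frequency and amplitude arrays must have the same shape")
    P = np.asarray(mechanical_power(n, phi, morph).P_mech)
    idx = int(np.argmax(P))
    return float(P.ravel()[idx] if P.ndim else P), idx
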