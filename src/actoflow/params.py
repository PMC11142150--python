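"""Model parameters and closed-form quantities of the 1D active-fluid cell model.

The model describes steady-state bulk flow of the crosslinked cytoskeletal
meshwork along a 1D cell of length ``L`` (x=0 is the cell rear, x=L the
leading edge).  Three stresses balance pointwise::

    F_m(x) + mu * v''(x) - xi(x) * v(x) = 0

* ``F_m`` -- contractile stress from molecular motors, proportional to the
  gradient of a Gaussian motor density centred on the convergence zone x_CZ;
* ``mu * v''`` -- internal viscous stress of the meshwork;
* ``xi * v`` -- traction: friction-like coupling to the substrate, with
  possibly different adhesion coefficients left (``xi_L``) and right
  (``xi_R``) of the convergence zone.

Only ratios of the mechanical coefficients affect the velocity field, so the
canonical parameterization normalizes ``xi_L = 1`` and works with
(sigma, x_CZ, L, xi_R/xi_L, Fmax/xi_L, mu/xi_L), matching how fitted
parameter sets for the five motility modes are usually reported.

Units: lengths in um, time in s (or any consistent time unit -- velocities
simply inherit it), stresses in an arbitrary consistent unit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellDomain",
    "MotorField",
    "AdhesionField",
    "ModelParams",
    "ScalarSummaries",
    "FMAX_COEFF",
    "motor_density",
    "motor_stress",
    "max_motor_stress",
    "peak_stress_locations",
    "lambda_param",
    "dissipation_length",
    "vc_estimate",
    "stress_partition_at_xc",
    "scalar_summaries",
]

#: sqrt(2) * exp(-1/2): peak motor stress is FMAX_COEFF * amplitude / sigma.
FMAX_COEFF = math.sqrt(2.0) * math.exp(-0.5)


@dataclass(frozen=True)
class CellDomain:
    """Uniform 1D spatial grid over the cell, from rear (0) to front (L)."""

    L: float
    n_grid: int = 2001

    def __post_init__(self) -> None:
        if not (np.isfinite(self.L) and self.L > 0):
            raise ValueError(f"cell length L must be positive and finite, got {self.L}")
        if self.n_grid < 51:
            raise ValueError(f"n_grid must be >= 51, got {self.n_grid}")

    @property
    def dx(self) -> float:
        return self.L / (self.n_grid - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.n_grid)


@dataclass(frozen=True)
class MotorField:
    """Gaussian motor distribution.

    ``amplitude`` is the combined motor forcing f*M0 (force per motor times
    peak motor density); the two factors never appear separately in any
    implemented equation, so they are stored as one number.
    """

    amplitude: float
    sigma: float
    x_cz: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.amplitude) and self.amplitude >= 0):
            raise ValueError(f"motor amplitude must be >= 0, got {self.amplitude}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"motor width sigma must be > 0, got {self.sigma}")
        if not np.isfinite(self.x_cz):
            raise ValueError(f"x_cz must be finite, got {self.x_cz}")


@dataclass(frozen=True)
class AdhesionField:
    """Piecewise adhesion coefficient: xi_left for x < x_CZ, xi_right beyond.

    ``smooth_width`` > 0 replaces the step with a logistic blend of that
    half-width (useful for extreme adhesion ratios).
    """

    xi_left: float
    xi_right: float
    smooth_width: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.xi_left) and self.xi_left > 0):
            raise ValueError(f"xi_left must be > 0, got {self.xi_left}")
        if not (np.isfinite(self.xi_right) and self.xi_right > 0):
            raise ValueError(f"xi_right must be > 0, got {self.xi_right}")
        if self.smooth_width < 0:
            raise ValueError(f"smooth_width must be >= 0, got {self.smooth_width}")

    @property
    def ratio(self) -> float:
        return self.xi_right / self.xi_left


@dataclass(frozen=True)
class ModelParams:
    """Full mechanical description of the 1D cell."""

    domain: CellDomain
    motors: MotorField
    adhesion: AdhesionField
    mu: float
    velocity_unit: str = "um/min"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"viscosity mu must be > 0, got {self.mu}")
        if not (0.0 < self.motors.x_cz < self.domain.L):
            raise ValueError(
                f"x_cz={self.motors.x_cz} must lie inside the cell (0, {self.domain.L})"
            )

    @classmethod
    def from_ratios(
        cls,
        sigma: float,
        x_cz: float,
        L: float,
        xi_ratio: float,
        force_scale: float,
        mu_ratio: float,
        n_grid: int = 2001,
        smooth_width: float = 0.0,
        velocity_unit: str = "um/min",
    ) -> "ModelParams":
        """Build from the ratio parameterization with xi_L normalized to 1.

        ``force_scale`` is Fmax/xi_L (peak motor stress over left adhesion),
        ``mu_ratio`` is mu/xi_L and ``xi_ratio`` is xi_R/xi_L.
        """
        amplitude = force_scale * sigma / FMAX_COEFF
        return cls(
            domain=CellDomain(L=L, n_grid=n_grid),
            motors=MotorField(amplitude=amplitude, sigma=sigma, x_cz=x_cz),
            adhesion=AdhesionField(xi_left=1.0, xi_right=xi_ratio,
                                   smooth_width=smooth_width),
            mu=mu_ratio,
            velocity_unit=velocity_unit,
        )

    @property
    def force_scale(self) -> float:
        """Fmax / xi_L."""
        return max_motor_stress(self.motors) / self.adhesion.xi_left

    @property
    def mu_ratio(self) -> float:
        """mu / xi_L."""
        return self.mu / self.adhesion.xi_left

    @property
    def lam(self) -> float:
        """Dimensionless lambda = 2 mu / (sigma^2 xi_L)."""
        return lambda_param(self.mu_ratio, self.motors.sigma)


@dataclass(frozen=True)
class ScalarSummaries:
    """Closed-form scalars derived from a parameter set."""

    f_max: float
    x_c_left: float
    x_c_right: float
    lam: float
    ell: float
    v_c: float


def _check_finite(x, name: str):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def motor_density(x, motors: MotorField):
    """Motor forcing density f*M(x) = amplitude * exp(-((x - x_CZ)/sigma)^2).

    Peaks at x = x_CZ with value ``amplitude`` and falls to amplitude/e at
    x = x_CZ +/- sigma.
    """
    xa = _check_finite(x, "position")
    u = (xa - motors.x_cz) / motors.sigma
    out = motors.amplitude * np.exp(-(u ** 2))
    return out if out.ndim else float(out)


def motor_stress(x, motors: MotorField):
    """Motor-induced stress F_m(x) = d(f*M)/dx.

    Antisymmetric about x_CZ: positive on the left (pulling material
    rightward toward the convergence zone), negative on the right.
    """
    xa = _check_finite(x, "position")
    u = (xa - motors.x_cz) / motors.sigma
    out = -2.0 * motors.amplitude / motors.sigma ** 2 * (xa - motors.x_cz) * np.exp(-(u ** 2))
    return out if out.ndim else float(out)


def max_motor_stress(motors: MotorField) -> float:
    """Peak motor stress Fmax = sqrt(2) e^{-1/2} amplitude / sigma (~0.86 a/sigma)."""
    return FMAX_COEFF * motors.amplitude / motors.sigma


def peak_stress_locations(motors: MotorField) -> tuple[float, float]:
    """Locations x_c = x_CZ -/+ sigma/sqrt(2) where |F_m| is maximal."""
    d = motors.sigma / math.sqrt(2.0)
    return (motors.x_cz - d, motors.x_cz + d)


def lambda_param(mu_over_xi: float, sigma: float) -> float:
    """Dimensionless lambda = 2 mu / (sigma^2 xi).

    Compares the internal dissipation length sqrt(mu/xi) with the motor
    distribution width: small lambda means traction-dominated, localized
    flow; large lambda means viscosity-dominated, near-uniform flow.
    """
    if not (mu_over_xi > 0 and sigma > 0):
        raise ValueError("mu_over_xi and sigma must be > 0")
    return 2.0 * mu_over_xi / sigma ** 2


def dissipation_length(mu: float, xi: float) -> float:
    """Characteristic decay length ell = sqrt(mu/xi) of internal stress."""
    if not (mu > 0 and xi > 0):
        raise ValueError("mu and xi must be > 0")
    return math.sqrt(mu / xi)


def vc_estimate(f_max: float, xi_left: float, lam: float) -> float:
    """Analytic flow-speed estimate at the peak-stress point x_c.

    v_c = (Fmax / xi_L) / (1 + lambda): the full motor stress driven through
    the combined resistance of traction and viscous coupling.
    """
    if xi_left <= 0 or lam < 0:
        raise ValueError("xi_left must be > 0 and lam >= 0")
    return (f_max / xi_left) / (1.0 + lam)


def stress_partition_at_xc(f_max: float, lam: float) -> tuple[float, float]:
    """Magnitudes (|F_visc|, |T|) of viscous stress and traction at x_c.

    |F_visc| = Fmax * lam/(1+lam) and |T| = Fmax / (1+lam); they always sum
    to Fmax.  Small lambda: motor stress is dissipated by traction; large
    lambda: it is dissipated internally by viscosity.
    """
    if f_max < 0 or lam < 0:
        raise ValueError("f_max and lam must be >= 0")
    return (f_max * lam / (1.0 + lam), f_max / (1.0 + lam))


def scalar_summaries(params: ModelParams) -> ScalarSummaries:
    """All closed-form scalars for a parameter set."""
    f_max = max_motor_stress(params.motors)
    x_left, x_right = peak_stress_locations(params.motors)
    lam = params.lam
    ell = dissipation_length(params.mu, params.adhesion.xi_left)
    v_c = vc_estimate(f_max, params.adhesion.xi_left, lam)
    return ScalarSummaries(f_max=f_max, x_c_left=x_left, x_c_right=x_right,
                           lam=lam, ell=ell, v_c=v_c)
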