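"""Phase-system parameters and the velocity-factor transforms.

All profile equations in this package are written in dimensionless variables:
time ``t = tau * F_x / V_c`` (x-phase basis) and concentration ``X = x / xbar``
with ``xbar = Q / V_c`` the mean column concentration of the loaded amount
``Q = x_s * F_x * tau_s``.  A solute is characterised by its equilibrium
distribution ratio ``K_D = y / x`` between the two liquid phases; the column by
its plate (equilibrium-cell) count ``N`` and the fractional volume ``S_f`` of
the y-phase it holds.

The velocity factor ``a = 1 / (1 - S_f + S_f * K_D)`` is the band's
dimensionless migration rate with the x-phase mobile; with the y-phase mobile
(second, phase-inverted stage) the corresponding rate is ``K_D * a``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


class ValidityWarning(UserWarning):
    """The configuration leaves the model's stated validity domain."""


def velocity_factor(K_D: float, Sf: float) -> float:
    """Band migration rate ``a = 1/(1 - Sf + Sf*K_D)`` for the mobile x-phase.

    Parameters
    ----------
    K_D : float
        Equilibrium distribution ratio y/x, ``K_D >= 0``.
    Sf : float
        Fractional column volume of the y-phase, ``0 < Sf < 1``.

    Returns
    -------
    float
        ``a`` in ``(0, 1/(1 - Sf)]``; the band's mean residence time per
        column passage is ``1/a`` in dimensionless time units.
    """
    if not 0.0 < Sf < 1.0:
        raise ValueError(f"Sf must lie in (0, 1), got {Sf}")
    if K_D < 0.0:
        raise ValueError(f"K_D must be nonnegative, got {K_D}")
    return 1.0 / (1.0 - Sf + Sf * K_D)


def y_phase_velocity_factor(K_D: float, Sf: float) -> float:
    """Band migration rate ``a_y = K_D * a`` for the mobile y-phase.

    Equal to ``velocity_factor(1/K_D, 1 - Sf)`` — inverting the phases swaps
    the roles of ``K_D`` and ``S_f``.  A compound with ``K_D = 0`` never
    partitions into the y-phase and cannot elute in the inverted mode.
    """
    if K_D <= 0.0:
        raise ValueError(
            f"K_D must be positive for y-phase elution, got {K_D}"
        )
    return K_D * velocity_factor(K_D, Sf)


@dataclass(frozen=True)
class Compound:
    """A solute, identified by its partition coefficient.

    ``relative_amount`` scales reported/plotted series for mixtures where the
    loaded amounts differ; each compound's profile is normalised independently
    (X = x/xbar per compound), so it defaults to 1 and does not enter the
    dimensionless model.
    """

    name: str
    K_D: float
    relative_amount: float = 1.0

    def __post_init__(self) -> None:
        if self.K_D < 0.0:
            raise ValueError(f"{self.name}: K_D must be >= 0, got {self.K_D}")
        if self.relative_amount <= 0.0:
            raise ValueError(
                f"{self.name}: relative_amount must be > 0, "
                f"got {self.relative_amount}"
            )


@dataclass(frozen=True)
class ColumnSpec:
    """Column plate count and stationary-phase retention.

    The closed-form dual-mode treatment assumes the column efficiency is the
    same in both elution modes, which holds only at ``Sf = 0.5``; other values
    are accepted but trigger a :class:`ValidityWarning`.
    """

    N: int
    Sf: float = 0.5

    def __post_init__(self) -> None:
        if self.N < 1 or int(self.N) != self.N:
            raise ValueError(f"N must be a positive integer, got {self.N}")
        if not 0.0 < self.Sf < 1.0:
            raise ValueError(f"Sf must lie in (0, 1), got {self.Sf}")
        if self.Sf != 0.5:
            warnings.warn(
                f"Sf = {self.Sf} != 0.5: outside the stated validity domain "
                "of the dual-mode model (column efficiency differs between "
                "stages); computing anyway.",
                ValidityWarning,
                stacklevel=2,
            )

    def velocity_factor(self, K_D: float) -> float:
        return velocity_factor(K_D, self.Sf)


@dataclass(frozen=True)
class RecycleLineSpec:
    """External recycling line: ``Nec`` mixing cells, relative volume ``b``.

    ``b = V_ec / V_c`` is the line volume as a fraction of the column volume;
    ``b = 0`` selects the ideal (short-line) model in which the line adds no
    delay or dispersion.  Each completed loop passage delays a band by ``b``
    time units and adds ``a^2 b^2 / Nec`` to its variance (in ``a*t`` units).
    """

    Nec: int = 1
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.Nec < 1 or int(self.Nec) != self.Nec:
            raise ValueError(f"Nec must be a positive integer, got {self.Nec}")
        if self.b < 0.0:
            raise ValueError(f"b must be nonnegative, got {self.b}")
        if self.b > 0.5:
            warnings.warn(
                f"b = {self.b} is far outside the usual 0.05-0.1 regime of "
                "recycling-line volumes; results may be physically "
                "unrealistic.",
                ValidityWarning,
                stacklevel=2,
            )

    @property
    def ideal(self) -> bool:
        return self.b == 0.0


@dataclass(frozen=True)
class LoadingSpec:
    """Dimensionless sample-loading duration ``ts = tau_s * F_x / V_c``.

    ``ts = 0`` is the impulse-injection limit.  The rectangular inlet pulse
    adds exactly ``ts^2/12`` to the band variance in ``t^2`` units.
    """

    ts: float = 0.0

    def __post_init__(self) -> None:
        if self.ts < 0.0:
            raise ValueError(f"ts must be nonnegative, got {self.ts}")

    def check_against_residence_time(self, a: float, name: str = "") -> bool:
        """Warn if loading exceeds 20% of the compound's residence time 1/a.

        Returns True when the validity bound is respected.
        """
        if self.ts > 0.2 / a:
            label = f" for {name}" if name else ""
            warnings.warn(
                f"loading time ts = {self.ts:g}{label} exceeds 20% of the "
                f"mean residence time 1/a = {1.0 / a:g}; profiles leave the "
                "stated validity domain.",
                ValidityWarning,
                stacklevel=2,
            )
            return False
        return True


@dataclass(frozen=True)
class PhysicalUnits:
    """Optional physical scales to convert dimensionless results.

    ``Q = xs * Fx * tau_s`` (loaded amount) holds by construction.
    """

    Fx: float
    Fy: float
    Vc: float
    xs: float
    tau_s: float

    def __post_init__(self) -> None:
        for field in ("Fx", "Fy", "Vc", "xs", "tau_s"):
            if getattr(self, field) <= 0.0:
                raise ValueError(f"{field} must be positive")

    @property
    def Q(self) -> float:
        """Loaded amount of compound."""
        return self.xs * self.Fx * self.tau_s


def dimensionalize(t, X, units: PhysicalUnits, phase: str = "x"):
    """Convert dimensionless (t, X) to actual (time, concentration).

    ``tau = t * Vc / F_phase`` and ``c = X * Q / Vc`` (the concentration
    normaliser is the mean column concentration ``xbar = Q / Vc``).
    """
    if phase not in ("x", "y"):
        raise ValueError(f"phase must be 'x' or 'y', got {phase!r}")
    F = units.Fx if phase == "x" else units.Fy
    return t * units.Vc / F, X * units.Q / units.Vc


def dedimensionalize(tau, c, units: PhysicalUnits, phase: str = "x"):
    """Inverse of :func:`dimensionalize`."""
    if phase not in ("x", "y"):
        raise ValueError(f"phase must be 'x' or 'y', got {phase!r}")
    F = units.Fx if phase == "x" else units.Fy
    return tau * F / units.Vc, c * units.Vc / units.Q
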