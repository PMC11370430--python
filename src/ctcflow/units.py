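"""Unit conversion between physical (SI) and lattice scales.

The solver works in lattice units (dx = dt = 1, reference density 1).
A single :class:`UnitConverter` owns the three independent scales
(length dx, time dt, density rho) and derives every other conversion
factor from them, so there is exactly one place where units can go wrong.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class UnitConverter:
    """Maps physical SI quantities onto lattice units and back.

    Parameters
    ----------
    dx : float
        Lattice spacing in metres.
    dt : float
        Time step in seconds.
    rho : float
        Physical fluid density in kg/m^3 (maps to lattice density 1).
    """

    dx: float
    dt: float
    rho: float = 1.0e3

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0 or self.rho <= 0:
            raise ValueError("dx, dt and rho must all be positive")

    # --- derived scales -------------------------------------------------
    @property
    def mass_scale(self) -> float:
        """Mass of one lattice cell of reference fluid (kg)."""
        return self.rho * self.dx**3

    @property
    def velocity_scale(self) -> float:
        return self.dx / self.dt

    @property
    def force_scale(self) -> float:
        """Force unit: mass_scale * dx / dt^2 (N)."""
        return self.mass_scale * self.dx / self.dt**2

    @property
    def force_density_scale(self) -> float:
        """Body-force density unit (N/m^3)."""
        return self.force_scale / self.dx**3

    @property
    def stress_scale(self) -> float:
        """Pressure/stress unit (Pa)."""
        return self.force_scale / self.dx**2

    @property
    def viscosity_scale(self) -> float:
        """Kinematic viscosity unit (m^2/s)."""
        return self.dx**2 / self.dt

    # --- conversions ----------------------------------------------------
    def length_to_lattice(self, x):
        return x / self.dx

    def length_to_physical(self, x):
        return x * self.dx

    def time_to_lattice(self, t):
        return t / self.dt

    def time_to_physical(self, t):
        return t * self.dt

    def velocity_to_lattice(self, u):
        return u / self.velocity_scale

    def velocity_to_physical(self, u):
        return u * self.velocity_scale

    def force_to_lattice(self, f):
        return f / self.force_scale

    def force_to_physical(self, f):
        return f * self.force_scale

    def viscosity_to_lattice(self, nu):
        return nu / self.viscosity_scale

    def stress_to_physical(self, s):
        return s * self.stress_scale
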