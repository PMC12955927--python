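"""Stokes-Einstein relations shared by the simulator and the sizing stage.

For a sphere of hydrodynamic diameter ``d`` in a medium of viscosity ``eta``
at temperature ``T`` the translational diffusion coefficient is

    D = k_B * T / (3 * pi * eta * d)

and the mean lateral dwell time in a Gaussian focus of 1/e^2 waist ``w`` is

    tau_D = w**2 / (4 * D)

Inverting the pair gives the hydrodynamic diameter from an observed transit
(burst) duration:

    d = 4 * k_B * T * tau / (3 * pi * eta * w**2)
"""

from __future__ import annotations

import math

#: CODATA exact value, J/K.
BOLTZMANN_J_PER_K = 1.380649e-23

#: Viscosity of water near 25 C, Pa s (default medium).
WATER_VISCOSITY_PA_S = 8.9e-4

#: Default medium temperature, K.
DEFAULT_TEMPERATURE_K = 298.15


def diffusion_coefficient_from_diameter(
    diameter: float, temperature: float, viscosity: float
) -> float:
    """Stokes-Einstein diffusion coefficient (m^2/s) of a sphere.

    Parameters
    ----------
    diameter : float
        Hydrodynamic diameter in meters.
    temperature : float
        Absolute temperature in kelvin.
    viscosity : float
        Dynamic viscosity in Pa s.
    """
    if diameter <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError(
            "diameter, temperature and viscosity must all be positive; got "
            f"d={diameter!r}, T={temperature!r}, eta={viscosity!r}"
        )
    return BOLTZMANN_J_PER_K * temperature / (3.0 * math.pi * viscosity * diameter)


def diffusion_time(diffusion_coefficient: float, waist_xy: float) -> float:
    """Lateral focal dwell time tau_D = w_xy^2 / (4 D), in seconds."""
    if diffusion_coefficient <= 0 or waist_xy <= 0:
        raise ValueError("diffusion coefficient and waist must be positive")
    return waist_xy**2 / (4.0 * diffusion_coefficient)


def diameter_from_transit_time(
    tau: float, waist: float, temperature: float, viscosity: float
) -> float:
    """Hydrodynamic diameter (m) from a transit/burst duration (s).

    This is the Stokes-Einstein sizing relation
    ``d = 4 k_B T tau / (3 pi eta w^2)``; it is the exact inverse of
    :func:`diffusion_coefficient_from_diameter` composed with
    :func:`diffusion_time`.
    """
    if tau <= 0:
        raise ValueError("transit duration must be positive")
    if waist <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("waist, temperature and viscosity must be positive")
    return 4.0 * BOLTZMANN_J_PER_K * temperature * tau / (3.0 * math.pi * viscosity * waist**2)
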