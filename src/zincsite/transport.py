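"""Antiport stoichiometry and energetics under the proton-motive force.

A forward transport cycle exchanges n Zn2+ ions (moved out) for m protons
(moved in):

    m H+_out + n Zn2+_in  <->  m H+_in + n Zn2+_out

The net charge exported per cycle is z = 2n - m; the 1 Zn2+ : 2 H+ cycle is
electroneutral. With the membrane potential defined as Vm = psi_in - psi_out
(physiological values are negative), the cycle free energy is

    dG = m RT ln([H+]_in / [H+]_out) + n RT ln([Zn]_out / [Zn]_in) - z F Vm

so that exporting net positive charge (z > 0) against an inside-negative
potential is unfavorable. Setting dG = 0 gives the equilibrium metal gradient

    log10([Zn]_out / [Zn]_in) = (m * dpH + z F Vm / (RT ln10)) / n

with dpH = pH_in - pH_out (positive when the outside is acidic), which
reduces to 10^(m*dpH/n) at Vm = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "TransportScenario",
    "net_charge",
    "transport_free_energy",
    "equilibrium_gradient",
    "log10_equilibrium_gradient",
    "ph_equivalent_of_potential",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.332  # C / mol
LN10 = math.log(10.0)


@dataclass(frozen=True)
class TransportScenario:
    """One antiport cycle specification with gradients and potential."""

    m: int  # protons per cycle
    n: int  # zinc ions per cycle
    ph_in: float
    ph_out: float
    zn_in: float  # molar
    zn_out: float  # molar
    vm: float = 0.0  # volts, psi_in - psi_out
    temperature: float = 298.15  # kelvin

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("m and n must be positive integers")
        if self.zn_in <= 0 or self.zn_out <= 0:
            raise ValueError("concentrations must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def net_charge(m: int, n: int) -> int:
    """Net positive charge exported per forward cycle, z = 2n - m."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be positive integers")
    return 2 * n - m


def transport_free_energy(scn: TransportScenario) -> float:
    """Cycle free energy dG in J/mol (negative = forward export favorable)."""
    rt = GAS_CONSTANT * scn.temperature
    z = net_charge(scn.m, scn.n)
    # [H+]_in / [H+]_out = 10^(pH_out - pH_in)
    chem_h = scn.m * rt * LN10 * (scn.ph_out - scn.ph_in)
    chem_zn = scn.n * rt * math.log(scn.zn_out / scn.zn_in)
    elec = -z * FARADAY * scn.vm
    return chem_h + chem_zn + elec


def log10_equilibrium_gradient(
    m: int, n: int, delta_ph: float, vm: float = 0.0,
    temperature: float = 298.15,
) -> float:
    """log10 of the equilibrium [Zn]_out/[Zn]_in ratio (dG = 0).

    ``delta_ph`` = pH_in - pH_out, positive when the outside is acidic.
    """
    z = net_charge(m, n)
    rt_ln10 = GAS_CONSTANT * temperature * LN10
    return (m * delta_ph + z * FARADAY * vm / rt_ln10) / n


def equilibrium_gradient(
    m: int, n: int, delta_ph: float, vm: float = 0.0,
    temperature: float = 298.15,
) -> float:
    """Equilibrium fold ratio [Zn]_out/[Zn]_in sustained by the cycle."""
    return 10.0 ** log10_equilibrium_gradient(m, n, delta_ph, vm, temperature)


def ph_equivalent_of_potential(
    z: int, vm: float, temperature: float = 298.15
) -> float:
    """Magnitude of the electrical term expressed in pH units."""
    return abs(z) * FARADAY * abs(vm) / (GAS_CONSTANT * temperature * LN10)
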