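"""Diffusion-limited association kinetics: Debye length, Debye-Smoluchowski
rate, and pseudo-first-order encounter statistics.

The encounter rate between a small ion and a protein is modelled as
diffusion-limited association with an electrostatic correction: the
Smoluchowski rate ``4 pi (D1 + D2) R`` is evaluated at an *effective*
radius

    1 / R_eff = integral_R^inf exp(U(r) / kT) / r^2 dr

for a screened-Coulomb (Debye-Hueckel) interaction

    U(r) / kT = z1 z2 l_B exp(-kappa (r - R)) / (r (1 + kappa R))

where ``l_B`` is the Bjerrum length and ``kappa`` the inverse Debye length.
Attractive potentials make ``R_eff > R`` and speed association; repulsive
ones slow it.  At a given free-ion concentration C the pseudo-first-order
rate is ``k_on * C`` and encounters arrive at mean intervals ``1/(k_on C)``.

Constants are CODATA (scipy.constants); water permittivity defaults to
78.5 at 300 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants as const
from scipy.integrate import quad

__all__ = [
    "DSParameters",
    "debye_length",
    "bjerrum_length",
    "ds_rate",
    "pseudo_first_order",
]


@dataclass(frozen=True)
class DSParameters:
    """Inputs of the Debye-Smoluchowski rate.

    Diffusion coefficients in cm^2/s, contact radius in nm, ionic strength
    in mol/L.  ``charge_product`` is z1*z2 (negative = attraction).
    """

    D_ion: float
    D_protein: float = 0.0
    contact_radius: float = 2.0  # nm
    charge_product: float = 0.0
    ionic_strength: float = 0.150  # M
    temperature: float = 300.0  # K
    relative_permittivity: float = 78.5

    def __post_init__(self) -> None:
        if self.D_ion < 0 or self.D_protein < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.contact_radius <= 0:
            raise ValueError("contact_radius must be > 0")
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be >= 0")


def debye_length(
    ionic_strength: float, temperature: float = 300.0, relative_permittivity: float = 78.5
) -> float:
    """Debye screening length kappa^-1 in nm.

    ``kappa^-1 = sqrt(eps eps0 kB T / (2 NA e^2 I * 1e3))`` with I in mol/L.
    Zero ionic strength returns ``inf`` (unscreened Coulomb).
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    if ionic_strength == 0:
        return math.inf
    num = relative_permittivity * const.epsilon_0 * const.k * temperature
    den = 2.0 * const.N_A * const.e**2 * ionic_strength * 1e3  # I: mol/L -> mol/m^3
    return math.sqrt(num / den) * 1e9  # m -> nm


def bjerrum_length(temperature: float = 300.0, relative_permittivity: float = 78.5) -> float:
    """Bjerrum length l_B = e^2 / (4 pi eps eps0 kB T) in nm (~0.7 nm in
    water at 300 K)."""
    lb = const.e**2 / (
        4.0 * math.pi * relative_permittivity * const.epsilon_0 * const.k * temperature
    )
    return lb * 1e9


def _beta_U(r_nm: np.ndarray, p: DSParameters, kappa: float, lB: float) -> np.ndarray:
    """Screened-Coulomb interaction in kT units at separation r (nm)."""
    R = p.contact_radius
    return (
        p.charge_product
        * lB
        * np.exp(-kappa * (r_nm - R))
        / (r_nm * (1.0 + kappa * R))
    )


def ds_rate(p: DSParameters, quad_tol: float = 1e-10) -> float:
    """Debye-Smoluchowski association rate in M^-1 s^-1.

    Neutral pairs reduce exactly to the Smoluchowski limit
    ``4 pi (D1 + D2) R NA * 1e-3``.  Otherwise the effective radius is
    computed by adaptive quadrature of ``exp(beta U)/r^2`` from the contact
    radius to infinity (substituted to a finite interval in u = 1/r).
    """
    D_sum_nm2_ps = (p.D_ion + p.D_protein) * 1e2  # cm^2/s -> nm^2/ps
    R = p.contact_radius
    if p.charge_product == 0.0:
        R_eff = R
    else:
        kappa_inv = debye_length(p.ionic_strength, p.temperature, p.relative_permittivity)
        kappa = 0.0 if math.isinf(kappa_inv) else 1.0 / kappa_inv
        lB = bjerrum_length(p.temperature, p.relative_permittivity)

        def integrand(u: float) -> float:
            # u = 1/r; integral_R^inf exp(bU)/r^2 dr = integral_0^{1/R} exp(bU(1/u)) du
            return math.exp(_beta_U(1.0 / u, p, kappa, lB))

        val, err = quad(integrand, 0.0, 1.0 / R, epsabs=quad_tol, epsrel=quad_tol, limit=500)
        if not np.isfinite(val) or val <= 0 or err > 1e-6 * max(abs(val), 1.0):
            raise RuntimeError("Debye-Smoluchowski quadrature failed to converge")
        R_eff = 1.0 / val
    # 4 pi D R in nm^3/ps -> L/s: 1 nm^3/ps = 1e-24 L * 1e12 /s = 1e-12 L/s
    k_per_molecule = 4.0 * math.pi * D_sum_nm2_ps * R_eff * 1e-12  # L/s
    return k_per_molecule * const.N_A  # M^-1 s^-1


def pseudo_first_order(k_on: float, concentration: float) -> dict[str, float]:
    """Apparent rate and mean encounter interval at a free-ion concentration.

    ``rate = k_on * C`` (s^-1); ``mean_interval = 1/rate`` reported in ns.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0:
        raise ValueError("mean interval undefined at zero concentration")
    rate = k_on * concentration
    return {"rate": rate, "mean_interval_ns": 1e9 / rate}
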