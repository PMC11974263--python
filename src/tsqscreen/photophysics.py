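"""Marcus-theory intersystem-crossing rates and photophysical criteria.

A triplet-state quencher works in multi-turnover imaging only if its own
T1 -> S0 relaxation is fast.  With the T1/S0 spin-orbit coupling H as the
electronic coupling, the semiclassical Marcus golden-rule rate is

    k_ISC = (2 pi / hbar) H^2 (4 pi lambda kB T)^(-1/2)
            * exp( -(lambda - E_T1)^2 / (4 lambda kB T) )

with the adiabatic triplet energy E_T1 as the driving force and lambda the
reorganization energy.  E_T1 <= lambda is the Marcus normal region; the
rate peaks (activationless) at E_T1 = lambda.  The weak-coupling premise
restricts quantitative use to SOC <= 10 cm^-1; rates outside that window
are still returned but flagged invalid.

Also here: SOC strength labels (weak < 10, medium 10-100, strong > 100
cm^-1), the singlet-oxygen sensitization energetics (3TSQ + 3O2 -> TSQ +
1O2 must be endergonic to avoid ROS), and photon wavelength/energy
conversions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import constants as const

from .errors import DomainError

# Unit conversions ----------------------------------------------------------

#: 1 cm^-1 expressed in kJ/mol.
CM1_TO_KJMOL = const.h * const.c * 100.0 * const.Avogadro / 1000.0
#: 1 eV expressed in kJ/mol.
EV_TO_KJMOL = const.e * const.Avogadro / 1000.0

#: Experimental 1Delta_g <- 3Sigma_g- excitation energy of O2, kJ/mol.
E_SINGLET_O2_KJMOL = 94.3

#: SOC window (cm^-1) inside which the weak-coupling rate is quantitative.
WEAK_SOC_CUTOFF = 10.0

DEFAULT_TEMPERATURE = 298.15  # K


def kjmol_to_joule(e_kjmol: float) -> float:
    """kJ/mol -> J per molecule."""
    return e_kjmol * 1000.0 / const.Avogadro


def cm1_to_joule(soc_cm1: float) -> float:
    """Wavenumber (cm^-1) -> J."""
    return soc_cm1 * const.h * const.c * 100.0


def wavelength_to_energy(lambda_nm: float) -> float:
    """Photon wavelength (nm) -> molar photon energy (kJ/mol)."""
    if lambda_nm <= 0:
        raise DomainError("wavelength must be positive")
    return const.Avogadro * const.h * const.c / (lambda_nm * 1e-9) / 1000.0


def energy_to_wavelength(e_kjmol: float) -> float:
    """Molar photon energy (kJ/mol) -> wavelength (nm); exact inverse."""
    if e_kjmol <= 0:
        raise DomainError("energy must be positive")
    return const.Avogadro * const.h * const.c / (e_kjmol * 1000.0) / 1e-9


# Records -------------------------------------------------------------------


class MarcusRegion(str, Enum):
    NORMAL = "normal"
    INVERTED = "inverted"


class SocClass(str, Enum):
    WEAK = "weak"
    MEDIUM = "medium"
    STRONG = "strong"


@dataclass(frozen=True)
class PhotophysicsRecord:
    """Per-compound photophysical descriptors, in the units screening uses.

    e_t1/e_s1: adiabatic excitation energies (kJ/mol); soc: T1<->S0
    spin-orbit coupling at the T1 geometry (cm^-1); lambda_reorg:
    reorganization energy (kJ/mol); dg_inversion: S0 ring-inversion barrier
    (kJ/mol); temperature in K.
    """

    e_t1: float
    e_s1: float | None = None
    soc: float = 0.0
    lambda_reorg: float | None = None
    dg_inversion: float | None = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.e_t1 < 0:
            raise DomainError("E_T1 must be non-negative")
        if self.soc < 0:
            raise DomainError("SOC must be non-negative")
        if self.temperature <= 0:
            raise DomainError("temperature must be positive")


@dataclass(frozen=True)
class RateResult:
    """Marcus ISC rate with its region and weak-coupling validity flag."""

    k_isc: float
    region: MarcusRegion
    valid: bool


# COT, the benchmark self-healing TSQ: E_T1 106 kJ/mol, SOC 1.0 cm^-1.
# lambda is not reported; 110 kJ/mol places it just inside the normal
# region, consistent with the puckered-S0/planar-T1 reorganization.
COT_REFERENCE = PhotophysicsRecord(e_t1=106.0, e_s1=300.0, soc=1.0, lambda_reorg=110.0)


# Operations ----------------------------------------------------------------


def marcus_k_isc(rec: PhotophysicsRecord) -> RateResult:
    """Semiclassical Marcus golden-rule T1 -> S0 ISC rate (s^-1).

    Raises :class:`DomainError` when lambda is missing or non-positive.
    SOC is treated as a single effective coupling (no triplet-sublevel
    degeneracy factor); constant factors cancel in
    :func:`isc_ratio_vs_reference`.
    """
    if rec.lambda_reorg is None or rec.lambda_reorg <= 0:
        raise DomainError("reorganization energy lambda must be positive for a rate")
    h_j = cm1_to_joule(rec.soc)
    lam = kjmol_to_joule(rec.lambda_reorg)
    e_t1 = kjmol_to_joule(rec.e_t1)
    kbt = const.k * rec.temperature
    prefactor = (2.0 * np.pi / const.hbar) * h_j**2 / np.sqrt(4.0 * np.pi * lam * kbt)
    k = prefactor * np.exp(-((lam - e_t1) ** 2) / (4.0 * lam * kbt))
    region = MarcusRegion.NORMAL if rec.e_t1 <= rec.lambda_reorg else MarcusRegion.INVERTED
    valid = 0.0 < rec.soc <= WEAK_SOC_CUTOFF
    return RateResult(k_isc=float(k), region=region, valid=valid)


def classify_soc(soc_cm1: float) -> SocClass:
    """Label SOC strength: weak < 10, medium 10-100, strong > 100 cm^-1."""
    if soc_cm1 < 0:
        raise DomainError("SOC must be non-negative")
    if soc_cm1 < 10.0:
        return SocClass.WEAK
    if soc_cm1 <= 100.0:
        return SocClass.MEDIUM
    return SocClass.STRONG


def singlet_oxygen_gap(
    e_t1: float, e_singlet_o2: float = E_SINGLET_O2_KJMOL
) -> tuple[float, bool]:
    """Energetics of 3TSQ + 3O2 -> TSQ + 1O2.

    Returns (dE, endergonic): dE = E(1O2) - E_T1 in kJ/mol; the sensitization
    channel is closed (safe) when dE > 0.  The effective O2 energy is
    configurable because free-energy treatments shift it well above the
    94.3 kJ/mol experimental excitation energy.
    """
    if e_t1 < 0 or e_singlet_o2 < 0:
        raise DomainError("energies must be non-negative")
    d_e = e_singlet_o2 - e_t1
    return d_e, d_e > 0


def isc_ratio_vs_reference(
    rec: PhotophysicsRecord, ref: PhotophysicsRecord = COT_REFERENCE
) -> float:
    """k_ISC(rec) / k_ISC(ref) via the explicit ratio formula.

    The (2 pi / hbar) prefactor and any constant coupling convention cancel
    analytically, which makes the ratio robust to the absolute-rate
    convention:

        ratio = (H/H_ref)^2 sqrt(lambda_ref/lambda)
                * exp(Delta_ref - Delta)   with Delta = (lambda-E)^2/(4 lambda kBT)
    """
    for r, name in ((rec, "rec"), (ref, "ref")):
        if r.lambda_reorg is None or r.lambda_reorg <= 0:
            raise DomainError(f"{name}: lambda must be positive")
    if ref.soc == 0:
        raise DomainError("reference rate is zero; ratio undefined")

    def _activation(r: PhotophysicsRecord) -> float:
        lam = kjmol_to_joule(r.lambda_reorg)
        e = kjmol_to_joule(r.e_t1)
        return (lam - e) ** 2 / (4.0 * lam * const.k * r.temperature)

    soc_ratio = (rec.soc / ref.soc) ** 2
    lam_ratio = np.sqrt(
        (ref.lambda_reorg * ref.temperature) / (rec.lambda_reorg * rec.temperature)
    )
    return float(soc_ratio * lam_ratio * np.exp(_activation(ref) - _activation(rec)))
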