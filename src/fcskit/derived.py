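"""Physical quantities derived from fitted diffusion times.

The lateral beam waist omega is calibrated from a reference dye of
known diffusion coefficient (omega = sqrt(4 D_ref tau_ref)); each
fitted diffusion time then converts to a diffusion coefficient
D_i = omega^2 / (4 tau_i), and — assuming a spherical diffusing
species, via the Stokes–Einstein relation — to an apparent molecular
mass relative to the 27 kDa EGFP monomer:

    Mw_i = 27 kDa * (tau_i / tau_EGFP)^3 .

Also provided: the expected genomic spacing of an IUPAC consensus
motif under an independent-base composition, used to judge how densely
a transcription-factor recognition site tiles a genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Molecular mass of the EGFP monomer (kDa); anchor of the cubic mass law.
EGFP_MASS_KDA = 27.0

#: Rhodamine 6G diffusion coefficient (um^2/s) at 25 C used for waist
#: calibration by default.  Instrument- and temperature-dependent:
#: confirm against your own calibration before trusting absolute D.
R6G_DIFFUSION_COEFFICIENT = 414.0

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def round_sig(x: float, sig: int) -> float:
    """Round ``x`` to ``sig`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class Calibration:
    """Beam-waist calibration from a reference dye."""

    lateral_waist: float  # um
    reference_dye: str
    reference_D: float  # um^2/s
    reference_tau: float  # s


@dataclass
class DerivedParams:
    """Per-component diffusion coefficients and apparent masses."""

    D: tuple  # um^2/s
    mass_kda: tuple  # unrounded
    mass_kda_2sf: tuple  # rounded to 2 significant figures
    monomer_mass_kda: float
    mass_ratios: tuple  # unrounded mass / monomer
    mass_ratios_rounded: tuple  # 2 s.f. mass / monomer


def calibrate_waist(
    tau_ref: float, D_ref: float = R6G_DIFFUSION_COEFFICIENT,
    dye: str = "rhodamine 6G",
) -> Calibration:
    """Lateral waist from a reference transit time: omega = sqrt(4 D tau)."""
    if tau_ref <= 0 or D_ref <= 0:
        raise ValueError("reference tau and D must be positive")
    return Calibration(
        lateral_waist=math.sqrt(4.0 * D_ref * tau_ref),
        reference_dye=dye,
        reference_D=D_ref,
        reference_tau=tau_ref,
    )


def diffusion_coefficient(tau: float, calibration: Calibration) -> float:
    """D = omega^2 / (4 tau), in um^2/s."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return calibration.lateral_waist**2 / (4.0 * tau)


def apparent_mass(tau: float, tau_egfp: float) -> float:
    """Apparent molecular mass (kDa) of a component, cubic in tau/tau_EGFP."""
    if tau <= 0 or tau_egfp <= 0:
        raise ValueError("diffusion times must be positive")
    return EGFP_MASS_KDA * (tau / tau_egfp) ** 3


def derive_params(
    taus, tau_egfp: float, calibration: Calibration,
    monomer_mass_kda: float,
) -> DerivedParams:
    """Bundle D_i, apparent masses and monomer mass ratios for a fit.

    Masses are reported unrounded and at 2 significant figures (the
    printing convention of the field); ratios are given in both
    conventions because rounding before or after the division can move
    the leading digit.
    """
    taus = tuple(float(t) for t in taus)
    D = tuple(diffusion_coefficient(t, calibration) for t in taus)
    mass = tuple(apparent_mass(t, tau_egfp) for t in taus)
    mass2 = tuple(round_sig(m, 2) for m in mass)
    return DerivedParams(
        D=D,
        mass_kda=mass,
        mass_kda_2sf=mass2,
        monomer_mass_kda=monomer_mass_kda,
        mass_ratios=tuple(m / monomer_mass_kda for m in mass),
        mass_ratios_rounded=tuple(m / monomer_mass_kda for m in mass2),
    )


def motif_expected_spacing(iupac_motif: str, base_frequencies=None) -> float:
    """Expected spacing (bp) between single-strand motif occurrences.

    Under independent bases with the given composition (uniform by
    default), the per-position match probability is the summed frequency
    of the bases each IUPAC code admits; the expected spacing is the
    reciprocal of the product over positions.
    """
    if base_frequencies is None:
        base_frequencies = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    total = sum(base_frequencies.get(b, 0.0) for b in "ACGT")
    if abs(total - 1.0) > 1e-9:
        raise ValueError("base frequencies must sum to 1")
    if not iupac_motif:
        raise ValueError("motif must be non-empty")
    p = 1.0
    for ch in iupac_motif.upper():
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code: {ch!r}")
        p *= sum(base_frequencies[b] for b in IUPAC_CODES[ch])
    if p == 0:
        raise ValueError("motif has zero match probability under this composition")
    return 1.0 / p
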