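"""Sedimentation-velocity interpretation: mass, stoichiometry, site size.

Sedimentation-velocity AUC yields, per species, a standardized sedimentation
coefficient s20,w and a frictional ratio f/f0.  With a partial specific
volume v-bar these determine the molar mass through the Svedberg relation

    M * (1 - vbar * rho) = s * N_A * f,
    f = (f/f0) * 6*pi*eta * (3*M*vbar / (4*pi*N_A))**(1/3)

(the Stokes friction of the equivalent anhydrous sphere scaled by f/f0),
which solves in closed form: M = [s*N_A*(f/f0)*6*pi*eta*
(3*vbar/(4*pi*N_A))**(1/3) / (1 - vbar*rho)]**(3/2).  All hydrodynamic
quantities are in CGS units; s20,w is by definition referenced to water at
20 degrees C, so those solvent constants are the default.

For a protein-DNA complex of unknown stoichiometry, the v-bar of the complex
depends on its composition while the composition is what is being inferred.
:func:`enumerate_stoichiometries` resolves the circularity by recomputing
the measured mass for every candidate bound state k with that state's own
mass-weighted v-bar, then ranking states by |M_measured - M_predicted|.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

__all__ = [
    "AUCSpecies",
    "BufferConditions",
    "ComplexHypothesis",
    "BuoyancyError",
    "WATER_20C",
    "SVEDBERG",
    "VBAR_PROTEIN_DEFAULT",
    "VBAR_DNA",
    "mass_from_sedimentation",
    "sedimentation_from_mass",
    "weighted_vbar",
    "enumerate_stoichiometries",
    "site_size_bounds",
    "SiteSizeRange",
]

#: one Svedberg in seconds
SVEDBERG = 1e-13

#: conventional partial specific volumes (cm^3/g)
VBAR_PROTEIN_DEFAULT = 0.73
VBAR_DNA = 0.56


class BuoyancyError(ValueError):
    """vbar * rho >= 1: the species is neutrally or positively buoyant."""


@dataclass(frozen=True)
class BufferConditions:
    """Solvent constants for the Svedberg relation (CGS units).

    eta: viscosity (g cm^-1 s^-1); rho: density (g/cm^3); N_A: Avogadro.
    """

    eta: float
    rho: float
    N_A: float = 6.02214076e23

    def __post_init__(self) -> None:
        if not (self.eta > 0 and self.rho > 0):
            raise ValueError("viscosity and density must be positive")


#: water at 20 degrees C — the reference state of s20,w
WATER_20C = BufferConditions(eta=1.002e-2, rho=0.99823)


@dataclass
class AUCSpecies:
    """One sedimenting species: observables plus (optionally) derived mass."""

    species_id: str
    s20w: float  # Svedberg
    f_f0: float
    vbar: float  # cm^3/g
    M: float | None = None  # g/mol, derived

    def __post_init__(self) -> None:
        if self.s20w <= 0:
            raise ValueError(f"s20,w must be > 0, got {self.s20w}")
        if self.f_f0 < 1:
            raise ValueError(f"frictional ratio must be >= 1, got {self.f_f0}")
        if self.vbar <= 0:
            raise ValueError(f"partial specific volume must be > 0, got {self.vbar}")


def _stokes_coefficient(f_f0: float, vbar: float, buffer: BufferConditions) -> float:
    """s*N_A*f / M^(1/3) prefactor: (f/f0)*6*pi*eta*(3*vbar/(4*pi*N_A))^(1/3)."""
    return f_f0 * 6.0 * math.pi * buffer.eta * (3.0 * vbar / (4.0 * math.pi * buffer.N_A)) ** (1.0 / 3.0)


def mass_from_sedimentation(
    s20w: float, f_f0: float, vbar: float, buffer: BufferConditions = WATER_20C
) -> float:
    """Molar mass (g/mol) from s20,w (Svedberg), f/f0 and vbar (cm^3/g).

    Closed-form solution of the Svedberg relation with Stokes friction of
    the equivalent sphere; strictly increasing in s, with M proportional to
    s**(3/2) at fixed f/f0 and vbar.

    Raises
    ------
    BuoyancyError
        If ``vbar * rho >= 1`` (no net buoyant force; the species does not
        sediment and the mass is undetermined).
    """
    if s20w <= 0:
        raise ValueError(f"s20,w must be > 0, got {s20w}")
    if f_f0 < 1:
        raise ValueError(f"frictional ratio must be >= 1, got {f_f0}")
    buoyancy = 1.0 - vbar * buffer.rho
    if buoyancy <= 0:
        raise BuoyancyError(
            f"vbar*rho = {vbar * buffer.rho:.4f} >= 1: species does not sediment"
        )
    s_sec = s20w * SVEDBERG
    m23 = s_sec * buffer.N_A * _stokes_coefficient(f_f0, vbar, buffer) / buoyancy
    return m23**1.5


def sedimentation_from_mass(
    M: float, f_f0: float, vbar: float, buffer: BufferConditions = WATER_20C
) -> float:
    """Exact inverse of :func:`mass_from_sedimentation`: s20,w in Svedberg."""
    if M <= 0:
        raise ValueError(f"molar mass must be > 0, got {M}")
    buoyancy = 1.0 - vbar * buffer.rho
    if buoyancy <= 0:
        raise BuoyancyError(
            f"vbar*rho = {vbar * buffer.rho:.4f} >= 1: species does not sediment"
        )
    s_sec = M ** (2.0 / 3.0) * buoyancy / (buffer.N_A * _stokes_coefficient(f_f0, vbar, buffer))
    return s_sec / SVEDBERG


def weighted_vbar(components: Sequence[tuple[float, float]]) -> float:
    """Mass-weighted partial specific volume of a complex.

    ``components`` is a sequence of ``(M, vbar)`` pairs (g/mol, cm^3/g).
    Returns ``sum(M_i * vbar_i) / sum(M_i)`` — a convex combination, always
    within the component vbar range.
    """
    comps = list(components)
    if not comps:
        raise ValueError("at least one component is required")
    for m, vb in comps:
        if m <= 0:
            raise ValueError(f"component mass must be > 0, got {m}")
        if vb <= 0:
            raise ValueError(f"component vbar must be > 0, got {vb}")
    total = sum(m for m, _ in comps)
    return sum(m * vb for m, vb in comps) / total


@dataclass
class ComplexHypothesis:
    """Candidate bound state: k proteins on one DNA molecule."""

    k: int
    M_pred: float  # M_DNA + k * M_protein (g/mol)
    vbar_weighted: float  # cm^3/g
    M_measured: float  # g/mol, per-k if derived from (s, f/f0)
    residual: float = field(init=False)

    def __post_init__(self) -> None:
        self.residual = abs(self.M_measured - self.M_pred)


def enumerate_stoichiometries(
    measured: float | tuple[float, float],
    M_DNA: float,
    M_protein: float,
    vbar_protein: float = VBAR_PROTEIN_DEFAULT,
    vbar_DNA: float = VBAR_DNA,
    buffer: BufferConditions = WATER_20C,
    k_max: int = 8,
) -> list[ComplexHypothesis]:
    """Rank candidate bound states k = 0..k_max for one observed species.

    ``measured`` is either a molar mass (g/mol) or an ``(s20w, f_f0)`` pair.
    In the latter case the measured mass is recomputed for every k using that
    hypothesis's own mass-weighted vbar, because the s-to-M conversion
    depends on the composition being tested.  Hypotheses are returned sorted
    by ``|M_measured - M_pred|`` ascending (ties broken by smaller k).
    """
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    if M_DNA <= 0 or M_protein <= 0:
        raise ValueError("component masses must be > 0")

    from_s = isinstance(measured, tuple)
    hypotheses: list[ComplexHypothesis] = []
    for k in range(k_max + 1):
        m_pred = M_DNA + k * M_protein
        comps = [(M_DNA, vbar_DNA)] + [(M_protein, vbar_protein)] * k
        vbar_k = weighted_vbar(comps)
        if from_s:
            s20w, f_f0 = measured
            m_meas = mass_from_sedimentation(s20w, f_f0, vbar_k, buffer)
        else:
            m_meas = float(measured)
        hypotheses.append(ComplexHypothesis(k=k, M_pred=m_pred, vbar_weighted=vbar_k, M_measured=m_meas))
    hypotheses.sort(key=lambda h: (h.residual, h.k))
    return hypotheses


class SiteSizeRange(NamedTuple):
    """Site-size bounds in bp; ``lower`` is None for a one-sided upper bound."""

    lower: int | None
    upper: int


def site_size_bounds(N_bp: int, k, saturated: bool) -> SiteSizeRange:
    """Site-size range implied by k proteins bound to an N_bp duplex.

    A saturated duplex observed with bound states ``k_low..k_high`` bounds the
    site size to ``[ceil(N/k_high), floor(N/k_low)]`` bp.  An unsaturated
    complex with k proteins only bounds it from above: ``floor(N/k)`` bp.

    ``k`` may be an int or an iterable of ints (saturated case).
    """
    ks = sorted({int(x) for x in k}) if isinstance(k, Iterable) else [int(k)]
    if not ks or ks[0] < 1:
        raise ValueError(f"number of proteins bound must be >= 1, got {k}")
    if N_bp < 1:
        raise ValueError(f"duplex length must be >= 1 bp, got {N_bp}")
    if saturated:
        return SiteSizeRange(math.ceil(N_bp / ks[-1]), math.floor(N_bp / ks[0]))
    if len(ks) != 1:
        raise ValueError("unsaturated bound uses a single k")
    return SiteSizeRange(None, math.floor(N_bp / ks[0]))
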