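"""Redfield theory for backbone amide ¹⁵N relaxation.

The N–H bond vector of each residue reorients with a second-order
rotational correlation function g(t).  Assuming a (normalized)
multi-exponential decay

    g(t) = Σᵢ αᵢ exp(−t/τᵢ),        Σᵢ αᵢ = 1,

the spectral density is the cosine Fourier transform

    J(ω) = Σᵢ αᵢ · 2τᵢ / (1 + ω²τᵢ²),

a convention under which J(0) = 2·Σαᵢτᵢ = 2·τ_eff, where τ_eff is the
total effective correlation time (the area under g).  The Redfield
expressions implemented here map such a dynamics model, at a given
magnetic field, to the longitudinal rate R₁, the exchange-free
transverse rate R₂° and the heteronuclear ¹H–¹⁵N NOE.  Both the
¹H–¹⁵N dipolar coupling and the ¹⁵N chemical shift anisotropy (CSA,
axially symmetric, Δσ = −160 ppm) relaxation mechanisms are included:

    R₁  = (d²/40)[J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + (Δσ²ωN²/15)·J(ωN)
    R₂° = (d²/40)[4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)]
          + (Δσ²ωN²/90)[4J(0) + 3J(ωN)]
    NOE = 1 + (γH/γN)(d²/40)[6J(ωH+ωN) − J(ωH−ωN)] / R₁

with d the dipolar coupling constant for a single amide proton
(N_H = 1).  All internal quantities are SI: frequencies in rad/s,
times in s, rates in s⁻¹; unit conversion happens only at I/O
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PhysicalConstants",
    "FieldSettings",
    "SpectralDensityModel",
    "RelaxationRates",
    "CONSTANTS",
    "make_field",
    "spectral_density",
    "effective_correlation_time",
    "relaxation_rates",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants entering ¹⁵N amide relaxation.

    Defaults are CODATA gyromagnetic ratios and the conventional
    effective N–H bond length of 1.01 Å; ``delta_sigma`` is the ¹⁵N CSA
    expressed as a dimensionless fraction (−160 ppm).  ``d_nh`` is the
    dipolar coupling constant (rad/s)

        d = (μ₀/4π) · ℏ γH |γN| / ⟨r_NH³⟩

    and is recomputed from the other fields at construction.
    """

    mu0: float = 4.0e-7 * math.pi          # T·m/A
    hbar: float = 1.054571817e-34          # J·s
    gamma_h: float = 2.6752218744e8        # rad s⁻¹ T⁻¹
    gamma_n: float = -2.7126180436e7       # rad s⁻¹ T⁻¹ (negative)
    delta_sigma: float = -160e-6           # dimensionless (−160 ppm)
    r_nh_cubed: float = (1.01e-10) ** 3    # m³
    d_nh: float = field(init=False)        # rad/s, derived

    def __post_init__(self) -> None:
        if self.gamma_n >= 0:
            raise ValueError("gamma_n must be negative for 15N")
        d = (self.mu0 / (4 * math.pi)) * self.hbar * self.gamma_h \
            * abs(self.gamma_n) / self.r_nh_cubed
        object.__setattr__(self, "d_nh", d)

    def without_csa(self) -> "PhysicalConstants":
        """Copy with the CSA mechanism switched off (Δσ = 0)."""
        return replace(self, delta_sigma=0.0)


#: Module-wide default constants.
CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class FieldSettings:
    """Magnetic field stated as the proton Larmor frequency in MHz.

    ``omega_h`` and ``omega_n`` are the ¹H and ¹⁵N angular Larmor
    frequencies (rad/s); ``omega_n`` is stored as a magnitude — the
    sign of γN enters only through the NOE expression.
    """

    proton_mhz: float
    omega_h: float
    omega_n: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.proton_mhz) and self.proton_mhz > 0):
            raise ValueError(
                f"proton Larmor frequency must be a positive finite number "
                f"of MHz, got {self.proton_mhz!r}"
            )


def make_field(proton_mhz: float,
               constants: PhysicalConstants = CONSTANTS) -> FieldSettings:
    """Build :class:`FieldSettings` from a proton Larmor frequency in MHz."""
    proton_mhz = float(proton_mhz)
    if not (math.isfinite(proton_mhz) and proton_mhz > 0):
        raise ValueError(
            f"proton Larmor frequency must be a positive finite number of "
            f"MHz, got {proton_mhz!r}"
        )
    omega_h = 2.0 * math.pi * proton_mhz * 1e6
    omega_n = omega_h * abs(constants.gamma_n) / constants.gamma_h
    return FieldSettings(proton_mhz=proton_mhz, omega_h=omega_h,
                         omega_n=omega_n)


@dataclass(frozen=True)
class SpectralDensityModel:
    """Normalized multi-exponential model of N–H rotational dynamics.

    ``weights`` (αᵢ ≥ 0, Σαᵢ = 1) and ``timescales`` (τᵢ > 0, seconds)
    describe g(t) = Σ αᵢ exp(−t/τᵢ).
    """

    weights: np.ndarray
    timescales: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        t = np.asarray(self.timescales, dtype=float)
        if w.ndim != 1 or t.ndim != 1 or w.size != t.size or w.size == 0:
            raise ValueError("weights and timescales must be equal-length "
                             "non-empty 1-D sequences")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and non-negative")
        if np.any(t <= 0) or not np.all(np.isfinite(t)):
            raise ValueError("timescales must be finite and positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r}); "
                             "g(0) = 1 normalization is required")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "timescales", t)

    @property
    def n_components(self) -> int:
        return int(self.weights.size)

    @classmethod
    def single(cls, tau: float) -> "SpectralDensityModel":
        """Single-timescale model g(t) = exp(−t/τ)."""
        return cls(weights=np.array([1.0]), timescales=np.array([float(tau)]))

    @classmethod
    def from_components(cls, weights: Sequence[float],
                        timescales: Sequence[float]) -> "SpectralDensityModel":
        return cls(weights=np.asarray(weights, dtype=float),
                   timescales=np.asarray(timescales, dtype=float))


@dataclass(frozen=True)
class RelaxationRates:
    """R₁, exchange-free R₂° (s⁻¹) and hetNOE at one magnetic field."""

    r1: float
    r2: float
    het_noe: float
    field: FieldSettings


def spectral_density(model: SpectralDensityModel, omega: float) -> float:
    """Evaluate J(ω) = Σᵢ αᵢ·2τᵢ/(1+ω²τᵢ²) in seconds."""
    t = model.timescales
    return float(np.sum(model.weights * 2.0 * t / (1.0 + (omega * t) ** 2)))


def effective_correlation_time(model: SpectralDensityModel) -> float:
    """Total effective correlation time τ_eff = Σ αᵢτᵢ (seconds).

    Equals the area under g(t) and J(0)/2.
    """
    return float(np.dot(model.weights, model.timescales))


def relaxation_rates(model: SpectralDensityModel, field: FieldSettings,
                     constants: PhysicalConstants = CONSTANTS
                     ) -> RelaxationRates:
    """Forward Redfield calculation: dynamics model → (R₁, R₂°, hetNOE).

    ``constants.without_csa()`` may be passed to isolate the dipolar
    mechanism (e.g. extreme-narrowing limit checks).
    """
    wh, wn = field.omega_h, field.omega_n
    j0 = spectral_density(model, 0.0)
    j_hmn = spectral_density(model, wh - wn)
    j_n = spectral_density(model, wn)
    j_h = spectral_density(model, wh)
    j_hpn = spectral_density(model, wh + wn)

    d2_40 = constants.d_nh ** 2 / 40.0
    csa2 = (constants.delta_sigma * wn) ** 2

    r1 = d2_40 * (j_hmn + 3.0 * j_n + 6.0 * j_hpn) + (csa2 / 15.0) * j_n
    r2 = d2_40 * (4.0 * j0 + j_hmn + 3.0 * j_n + 6.0 * j_h + 6.0 * j_hpn) \
        + (csa2 / 90.0) * (4.0 * j0 + 3.0 * j_n)
    noe = 1.0 + (constants.gamma_h / constants.gamma_n) * d2_40 \
        * (6.0 * j_hpn - j_hmn) / r1
    return RelaxationRates(r1=r1, r2=r2, het_noe=noe, field=field)


def _r2_single_tau(tau, field: FieldSettings,
                   constants: PhysicalConstants = CONSTANTS):
    """Vectorized R₂°(τ) for single-timescale models (internal)."""
    tau = np.asarray(tau, dtype=float)
    wh, wn = field.omega_h, field.omega_n

    def j(w):
        return 2.0 * tau / (1.0 + (w * tau) ** 2)

    d2_40 = constants.d_nh ** 2 / 40.0
    csa2 = (constants.delta_sigma * wn) ** 2
    j0 = 2.0 * tau
    return (d2_40 * (4.0 * j0 + j(wh - wn) + 3.0 * j(wn) + 6.0 * j(wh)
                     + 6.0 * j(wh + wn))
            + (csa2 / 90.0) * (4.0 * j0 + 3.0 * j(wn)))
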