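"""Spectral densities and amide ¹⁵N relaxation rates.

Relaxation of a backbone ¹⁵N nucleus bonded to an amide proton is driven by
the ¹H–¹⁵N dipolar interaction and the ¹⁵N chemical shift anisotropy (CSA).
Every observable implemented here — longitudinal rate R1, transverse rate
R2, the heteronuclear NOE, and the transverse CSA/dipole–dipole
cross-correlated rate η_xy — is a linear combination of the orientational
spectral density J(ω) sampled at a handful of fixed frequencies
(0, ωN, ωH, ωH±ωN).

Three J(ω) parameterisations are provided:

* simple Lipari–Szabo: one order parameter S² and an overall tumbling
  time τc (no explicit internal time scale),
* extended Lipari–Szabo: fast/slow order parameters S²_fast, S²_slow and
  an internal correlation time τe,
* multi-Lorentzian: the spectral density obtained from a multi-exponential
  fit of an N–H vector autocorrelation function computed from an MD
  trajectory, C(t) = A0 + Σ_j A_j exp(−t/τj), combined with isotropic
  tumbling at τc.

Internal units are SI throughout: seconds, rad/s, tesla. ppm and Å are
accepted at the interface and converted once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import constants as _const

__all__ = [
    "GAMMA_H",
    "GAMMA_N",
    "InteractionConstants",
    "ModelFreeParams",
    "MultiExpSpectrum",
    "eval_J_simple",
    "eval_J_extended",
    "eval_J_multiexp",
    "rate_R1",
    "rate_R2",
    "rate_NOE",
    "rate_eta_xy",
]

#: gyromagnetic ratio of ¹H (rad s⁻¹ T⁻¹)
GAMMA_H: float = _const.physical_constants["proton gyromag. ratio"][0]
#: gyromagnetic ratio of ¹⁵N (rad s⁻¹ T⁻¹); negative
GAMMA_N: float = -2.7126e7

JFunc = Callable[[float], float]


@dataclass(frozen=True)
class InteractionConstants:
    """Physical constants of the ¹H–¹⁵N spin pair at a given field.

    Parameters
    ----------
    proton_freq_mhz:
        Spectrometer ¹H frequency in MHz (600.13 for a nominal 600 MHz
        instrument).
    r_nh_angstrom:
        Effective N–H bond length in Å.
    delta_sigma_ppm:
        ¹⁵N CSA Δσ in ppm; enters R1 and R2.
    delta_sigma_p2_ppm:
        Δσ·P2(cos θ), the CSA tensor projected on the N–H vector, in ppm;
        enters η_xy only.
    """

    proton_freq_mhz: float = 600.13
    r_nh_angstrom: float = 1.023
    delta_sigma_ppm: float = -166.0
    delta_sigma_p2_ppm: float = -145.0
    gamma_H: float = GAMMA_H
    gamma_N: float = GAMMA_N

    def __post_init__(self) -> None:
        if self.proton_freq_mhz <= 0:
            raise ValueError("proton_freq_mhz must be positive")
        if self.r_nh_angstrom <= 0:
            raise ValueError("r_nh_angstrom must be positive")

    @property
    def omega_H(self) -> float:
        """¹H Larmor angular frequency magnitude (rad/s)."""
        return 2.0 * math.pi * self.proton_freq_mhz * 1e6

    @property
    def omega_N(self) -> float:
        """¹⁵N Larmor angular frequency magnitude (rad/s).

        J(ω) is even, so all rate expressions are evaluated at magnitude
        frequencies; the sign of γN is retained only where it matters
        (the NOE prefactor).
        """
        return self.omega_H * abs(self.gamma_N) / abs(self.gamma_H)

    @property
    def d_dipolar(self) -> float:
        """Dipolar coupling constant |(μ0/4π)·ħ·γH·γN / r³| (rad/s)."""
        r = self.r_nh_angstrom * 1e-10
        return abs(
            _const.mu_0 / (4.0 * math.pi) * _const.hbar
            * self.gamma_H * self.gamma_N / r**3
        )

    @property
    def csa_n(self) -> float:
        """Dimensionless Δσ (ppm → fraction)."""
        return self.delta_sigma_ppm * 1e-6

    @property
    def csa_p2(self) -> float:
        """Dimensionless Δσ·P2(cos θ)."""
        return self.delta_sigma_p2_ppm * 1e-6


@dataclass(frozen=True)
class ModelFreeParams:
    """Extended Lipari–Szabo parameters.

    ``s2_fast`` and ``s2_slow`` are the order parameters of the fast and
    slow internal motions (the observable order parameter is their
    product), ``tau_e`` the internal correlation time of the slow motion
    and ``tau_c`` the overall isotropic tumbling time, all in seconds.
    With ``simple=True`` the object represents the one-timescale model:
    S² = s2_fast·s2_slow and tau_e is ignored.
    """

    s2_fast: float
    s2_slow: float = 1.0
    tau_e: float = 0.0
    tau_c: float = 14.7e-9
    simple: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.s2_fast <= 1.0 and 0.0 <= self.s2_slow <= 1.0):
            raise ValueError("order parameters must lie in [0, 1]")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if self.tau_e < 0:
            raise ValueError("tau_e must be non-negative")

    @property
    def s2(self) -> float:
        return self.s2_fast * self.s2_slow

    @property
    def tau_e_eff(self) -> float:
        """Effective internal time τe′ = τc·τe/(τc+τe)."""
        if self.tau_e == 0.0:
            return 0.0
        return self.tau_c * self.tau_e / (self.tau_c + self.tau_e)


@dataclass(frozen=True)
class MultiExpSpectrum:
    """Spectral density from a multi-exponential ACF fit plus tumbling.

    ``a0`` is the plateau amplitude of the internal correlation function,
    ``terms`` the (amplitude, internal time constant τj in s) pairs, and
    ``tau_c`` the tumbling time. The Lorentzian time constants are the
    combined τj′ = τc·τj/(τc+τj).
    """

    a0: float
    terms: tuple[tuple[float, float], ...] = ()
    tau_c: float = 14.7e-9

    def __post_init__(self) -> None:
        if self.a0 < 0 or any(a < 0 for a, _ in self.terms):
            raise ValueError("amplitudes must be non-negative")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if any(tau <= 0 for _, tau in self.terms):
            raise ValueError("internal time constants must be positive")
        total = self.a0 + sum(a for a, _ in self.terms)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=5e-2):
            raise ValueError(
                f"amplitudes must sum to 1 within tolerance, got {total:.4f}"
            )

    def tau_primes(self) -> list[float]:
        return [self.tau_c * t / (self.tau_c + t) for _, t in self.terms]

    def time_domain(self, t: np.ndarray) -> np.ndarray:
        """Total correlation function e^(−t/τc)·(A0 + Σ Aj e^(−t/τj))."""
        t = np.asarray(t, dtype=float)
        internal = np.full_like(t, self.a0)
        for a, tau in self.terms:
            internal = internal + a * np.exp(-t / tau)
        return np.exp(-t / self.tau_c) * internal


def eval_J_simple(s2: float, tau_c: float, omega) -> float | np.ndarray:
    """Simple Lipari–Szabo spectral density J(ω) = S²τc/(1+(ωτc)²)."""
    if not 0.0 <= s2 <= 1.0:
        raise ValueError("s2 must lie in [0, 1]")
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    omega = np.asarray(omega, dtype=float)
    out = s2 * tau_c / (1.0 + (omega * tau_c) ** 2)
    return out if out.ndim else float(out)


def eval_J_extended(params: ModelFreeParams, omega) -> float | np.ndarray:
    """Extended Lipari–Szabo spectral density (two Lorentzians).

    J(ω) = S²_f S²_s τc/(1+(ωτc)²) + S²_f (1−S²_s) τe′/(1+(ωτe′)²)
    with τe′ = τc·τe/(τc+τe). Reduces to :func:`eval_J_simple` when
    s2_slow = 1 or tau_e = 0 (or in simple mode).
    """
    omega = np.asarray(omega, dtype=float)
    if params.simple:
        return eval_J_simple(params.s2, params.tau_c, omega)
    tep = params.tau_e_eff
    out = params.s2 * params.tau_c / (1.0 + (omega * params.tau_c) ** 2)
    if tep > 0.0 and params.s2_slow < 1.0:
        out = out + (
            params.s2_fast * (1.0 - params.s2_slow) * tep
            / (1.0 + (omega * tep) ** 2)
        )
    return out if out.ndim else float(out)


def eval_J_multiexp(spec: MultiExpSpectrum, omega) -> float | np.ndarray:
    """Multi-Lorentzian spectral density from an ACF fit.

    J(ω) = A0 τc/(1+(ωτc)²) + Σj Aj τj′/(1+(ωτj′)²).
    """
    omega = np.asarray(omega, dtype=float)
    out = spec.a0 * spec.tau_c / (1.0 + (omega * spec.tau_c) ** 2)
    for (a, _), tp in zip(spec.terms, spec.tau_primes()):
        out = out + a * tp / (1.0 + (omega * tp) ** 2)
    return out if out.ndim else float(out)


def _as_jfunc(J) -> JFunc:
    if isinstance(J, ModelFreeParams):
        return lambda w: eval_J_extended(J, w)
    if isinstance(J, MultiExpSpectrum):
        return lambda w: eval_J_multiexp(J, w)
    return J


def rate_R1(J, k: InteractionConstants) -> float:
    """Longitudinal ¹⁵N relaxation rate R1 (s⁻¹).

    (1/10)·d²·[J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + (2/15)·ωN²Δσ²·J(ωN).
    """
    J = _as_jfunc(J)
    d2 = k.d_dipolar**2
    wH, wN = k.omega_H, k.omega_N
    dip = 0.1 * d2 * (J(wH - wN) + 3.0 * J(wN) + 6.0 * J(wH + wN))
    csa = (2.0 / 15.0) * (wN * k.csa_n) ** 2 * J(wN)
    return dip + csa


def rate_R2(J, k: InteractionConstants) -> float:
    """Transverse ¹⁵N relaxation rate R2 (s⁻¹), no exchange contribution.

    (1/20)·d²·[4J(0)+3J(ωN)+J(ωH−ωN)+6J(ωH)+6J(ωH+ωN)]
    + (ωN²Δσ²/45)·[4J(0)+3J(ωN)].
    """
    J = _as_jfunc(J)
    d2 = k.d_dipolar**2
    wH, wN = k.omega_H, k.omega_N
    dip = 0.05 * d2 * (
        4.0 * J(0.0) + 3.0 * J(wN) + J(wH - wN)
        + 6.0 * J(wH) + 6.0 * J(wH + wN)
    )
    csa = (wN * k.csa_n) ** 2 / 45.0 * (4.0 * J(0.0) + 3.0 * J(wN))
    return dip + csa


def rate_NOE(J, k: InteractionConstants, r1: float) -> float:
    """Steady-state ¹H→¹⁵N heteronuclear NOE (dimensionless, signed).

    1 + (γH/γN)·(d²/10R1)·[6J(ωH+ωN) − J(ωH−ωN)]. Because γN < 0 the
    cross-relaxation term is negative; in the extreme-narrowing limit with
    dipolar-only R1 the NOE tends to 1 + γH/(2γN) ≈ −3.93.
    """
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    J = _as_jfunc(J)
    d2 = k.d_dipolar**2
    wH, wN = k.omega_H, k.omega_N
    sigma = 0.1 * d2 * (6.0 * J(wH + wN) - J(wH - wN))
    return 1.0 + (k.gamma_H / k.gamma_N) * sigma / r1


def rate_eta_xy(J, k: InteractionConstants, *, j_zero: bool = True) -> float:
    """Transverse ¹⁵N CSA/DD cross-correlated relaxation rate η_xy (s⁻¹).

    Default (``j_zero=True``): (1/15)·d·ωN·|ΔσP2|·[4J(0) + 3J(ωN)] — the
    transverse cross-correlation combination that shares its J(0)-dominated
    profile with R2 and gives the observed ~14 s⁻¹ rigid-residue plateau at
    τc ≈ 14.7 ns and 600 MHz. ``j_zero=False`` replaces J(0) by J(ωH−ωN)
    (a literal alternative reading of the rate expression), retained for
    transparency; it does not reproduce the rigid plateau.

    Reported as a magnitude (positive for rigid residues).
    """
    J = _as_jfunc(J)
    wN = k.omega_N
    w_low = 0.0 if j_zero else (k.omega_H - wN)
    return (
        (1.0 / 15.0) * k.d_dipolar * wN * abs(k.csa_p2)
        * (4.0 * J(w_low) + 3.0 * J(wN))
    )


def all_rates(J, k: InteractionConstants, *, eta_xy_j_zero: bool = True,
              with_r2: bool = True) -> dict[str, float]:
    """Convenience: evaluate R1, NOE, η_xy (and optionally R2) for one J."""
    r1 = rate_R1(J, k)
    out = {
        "r1": r1,
        "noe": rate_NOE(J, k, r1),
        "eta_xy": rate_eta_xy(J, k, j_zero=eta_xy_j_zero),
    }
    if with_r2:
        out["r2"] = rate_R2(J, k)
    return out
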