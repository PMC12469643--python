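"""Per-residue (S², τc) from experimental R1 and η_xy; global tumbling time.

Under the simple Lipari–Szabo spectral density J(ω) = S²τc/(1+(ωτc)²) both
R1 and η_xy are proportional to S², so the ratio η_xy/R1 depends on τc
alone and is strictly monotone in τc over the range relevant for folded
proteins. Each residue's τc therefore follows from bracketed root-finding
on the ratio, after which S² is read off as R1/R1_model(τc, S²=1).

The global tumbling time is the mean of per-residue τc over residues that
are both rigid (S² above a threshold, default 0.8) and well measured
(relative errors on R1 and η_xy below a cut, default 10%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .spin import (
    InteractionConstants,
    eval_J_simple,
    rate_R1,
    rate_eta_xy,
)

__all__ = [
    "ResidueRates",
    "TaucEstimate",
    "solve_s2_tauc",
    "estimate_global_tauc",
    "relaxation_profile_grid",
]

TAU_C_BRACKET = (0.5e-9, 100e-9)  # search range for tumbling time (s)


@dataclass
class ResidueRates:
    """One residue's relaxation observables with uncertainties.

    Missing observables are None, never zero-filled; ``flags`` carries
    bookkeeping markers such as "proline" or "missing".
    """

    residue: int
    r1: float | None = None
    r1_err: float | None = None
    noe: float | None = None
    noe_err: float | None = None
    eta_xy: float | None = None
    eta_xy_err: float | None = None
    chain: str = "A"
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for err in (self.r1_err, self.noe_err, self.eta_xy_err):
            if err is not None and err < 0:
                raise ValueError("errors must be non-negative")
        if self.r1 is None or self.eta_xy is None or self.noe is None:
            self.flags.add("missing")

    @property
    def complete(self) -> bool:
        return self.r1 is not None and self.eta_xy is not None


def _rigid_rates(tau_c: float, k: InteractionConstants,
                 eta_xy_j_zero: bool = True) -> tuple[float, float]:
    """(R1, η_xy) for S²=1 at the given τc."""
    J = lambda w: eval_J_simple(1.0, tau_c, w)  # noqa: E731
    return rate_R1(J, k), rate_eta_xy(J, k, j_zero=eta_xy_j_zero)


def solve_s2_tauc(
    rates: ResidueRates,
    k: InteractionConstants,
    *,
    eta_xy_j_zero: bool = True,
    s2_max: float = 1.05,
) -> tuple[float, float, bool]:
    """Invert (R1, η_xy) to (S², τc) under the simple Lipari–Szabo model.

    Returns ``(s2, tau_c, converged)``. Raises ValueError when the ratio
    η_xy/R1 falls outside the range attainable for τc in 0.5–100 ns, and
    flags (but keeps) S² up to ``s2_max``; larger values raise.
    """
    if not rates.complete or rates.r1 <= 0 or rates.eta_xy <= 0:
        raise ValueError(
            f"residue {rates.residue}: positive r1 and eta_xy required"
        )
    target = rates.eta_xy / rates.r1
    lo, hi = TAU_C_BRACKET

    def ratio_gap(log_tc: float) -> float:
        r1m, etam = _rigid_rates(10.0**log_tc, k, eta_xy_j_zero)
        return etam / r1m - target

    gap_lo, gap_hi = ratio_gap(math.log10(lo)), ratio_gap(math.log10(hi))
    if gap_lo * gap_hi > 0:
        raise ValueError(
            f"residue {rates.residue}: eta_xy/R1 = {target:.3f} outside the "
            f"range attainable for tau_c in [{lo*1e9:.1f}, {hi*1e9:.0f}] ns"
        )
    log_tc = brentq(ratio_gap, math.log10(lo), math.log10(hi),
                    xtol=1e-12, rtol=1e-14)
    tau_c = 10.0**log_tc
    r1_rigid, _ = _rigid_rates(tau_c, k, eta_xy_j_zero)
    s2 = rates.r1 / r1_rigid
    if s2 > s2_max:
        raise ValueError(
            f"residue {rates.residue}: unphysical S^2 = {s2:.3f} > {s2_max}"
        )
    return s2, tau_c, True


@dataclass(frozen=True)
class TaucEstimate:
    """Global tumbling-time estimate over the rigid, well-measured subset."""

    tau_c_mean: float
    tau_c_sd: float
    tau_c_sem: float
    n_selected: int
    selected_ids: tuple[int, ...]
    s2_by_residue: dict[int, float]
    tau_c_by_residue: dict[int, float]


def estimate_global_tauc(
    table: Sequence[ResidueRates],
    k: InteractionConstants,
    *,
    s2_threshold: float = 0.8,
    max_rel_err: float = 0.10,
    eta_xy_j_zero: bool = True,
) -> TaucEstimate:
    """Mean tumbling time from rigid residues with small experimental errors.

    A residue enters the average when its inverted S² exceeds
    ``s2_threshold`` (residues with S² marginally above 1 from noise are
    excluded from the rigid set), and both relative errors, where given,
    are at most ``max_rel_err``.
    """
    s2s: dict[int, float] = {}
    tcs: dict[int, float] = {}
    selected: list[int] = []
    for rec in table:
        if not rec.complete or rec.r1 <= 0 or rec.eta_xy <= 0:
            continue
        if rec.r1_err is not None and rec.r1_err > max_rel_err * rec.r1:
            continue
        if (rec.eta_xy_err is not None
                and rec.eta_xy_err > max_rel_err * rec.eta_xy):
            continue
        try:
            s2, tc, _ = solve_s2_tauc(rec, k, eta_xy_j_zero=eta_xy_j_zero)
        except ValueError:
            continue
        s2s[rec.residue] = s2
        tcs[rec.residue] = tc
        if s2_threshold < s2 <= 1.0:
            selected.append(rec.residue)
    if not selected:
        raise ValueError(
            f"no residues passed S^2 > {s2_threshold} with relative errors "
            f"<= {max_rel_err:.0%}"
        )
    vals = np.array([tcs[i] for i in selected])
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return TaucEstimate(
        tau_c_mean=float(vals.mean()),
        tau_c_sd=sd,
        tau_c_sem=sd / math.sqrt(len(vals)) if len(vals) > 1 else 0.0,
        n_selected=len(selected),
        selected_ids=tuple(sorted(selected)),
        s2_by_residue=s2s,
        tau_c_by_residue=tcs,
    )


def relaxation_profile_grid(
    tau_e_range: Sequence[float],
    s2_slow_range: Sequence[float],
    k: InteractionConstants,
    *,
    s2_fast: float = 0.9,
    tau_c: float = 14.7e-9,
    r_ex: float = 0.0,
    eta_xy_j_zero: bool = True,
) -> dict[str, np.ndarray]:
    """Rate surfaces over an (τe, S²_slow) grid of internal-motion models.

    Returns R1, NOE, R2, η_xy matrices of shape
    (len(tau_e_range), len(s2_slow_range)) computed with the extended
    Lipari–Szabo spectral density at fixed ``s2_fast`` and ``tau_c``.
    ``r_ex`` adds a constant exchange offset to R2 only, emulating the
    systematic error that η_xy is free of.
    """
    from .spin import ModelFreeParams, rate_NOE, rate_R2  # local to avoid cycle

    tau_e_range = np.asarray(list(tau_e_range), dtype=float)
    s2_slow_range = np.asarray(list(s2_slow_range), dtype=float)
    if tau_e_range.size == 0 or s2_slow_range.size == 0:
        raise ValueError("parameter ranges must be non-empty")
    shape = (tau_e_range.size, s2_slow_range.size)
    grids = {name: np.empty(shape) for name in ("r1", "noe", "r2", "eta_xy")}
    for i, te in enumerate(tau_e_range):
        for j, s2s in enumerate(s2_slow_range):
            p = ModelFreeParams(s2_fast=s2_fast, s2_slow=s2s,
                                tau_e=te, tau_c=tau_c)
            r1 = rate_R1(p, k)
            grids["r1"][i, j] = r1
            grids["noe"][i, j] = rate_NOE(p, k, r1)
            grids["r2"][i, j] = rate_R2(p, k) + r_ex
            grids["eta_xy"][i, j] = rate_eta_xy(p, k, j_zero=eta_xy_j_zero)
    grids["tau_e"] = tau_e_range
    grids["s2_slow"] = s2_slow_range
    grids["s2"] = s2_fast * s2_slow_range
    return grids
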