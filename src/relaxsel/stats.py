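"""Experimental-vs-back-calculated rate comparison and segment ranking.

The yardstick for a single residue is Δ/σ — the difference between the
back-calculated and experimental rate in units of the experimental error —
together with runs of consecutive residues exceeding 1σ, 2σ or 3σ
(systematic misfits show up as contiguous stretches, not isolated points).
The set-level comparison uses the nonparametric Mann–Whitney U test, which
tolerates non-normal and residue-correlated deviations that would
invalidate a χ² statistic; p ≤ 0.05 rejects agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .model_free import ResidueRates

__all__ = [
    "RateComparison",
    "delta_in_sigma",
    "mann_whitney_u",
    "rank_segments",
]


@dataclass
class RateComparison:
    """Residue-matched comparison of one rate across two data sets."""

    residues: np.ndarray
    exp: np.ndarray
    exp_err: np.ndarray
    calc: np.ndarray
    delta_sigma: np.ndarray
    u_stat: float
    p_value: float
    n_pairs: int
    method: str
    stretches: dict[float, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def max_abs_delta_sigma(self) -> float:
        return float(np.abs(self.delta_sigma).max())


def _matched_arrays(
    exp: Sequence[ResidueRates],
    calc: Sequence[ResidueRates],
    param: str,
    *,
    combine_errors: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    err_name = f"{param}_err"
    exp_by_res = {r.residue: r for r in exp
                  if getattr(r, param) is not None}
    rows = []
    for c in calc:
        e = exp_by_res.get(c.residue)
        if e is None or getattr(c, param) is None:
            continue
        sigma = getattr(e, err_name)
        if sigma is None or sigma == 0:
            continue
        if combine_errors and getattr(c, err_name):
            sigma = float(np.hypot(sigma, getattr(c, err_name)))
        rows.append((c.residue, getattr(e, param), sigma, getattr(c, param)))
    if not rows:
        raise ValueError(f"no residues matched between data sets for {param}")
    rows.sort()
    resids, ev, se, cv = map(np.array, zip(*rows))
    return resids.astype(int), ev, se, cv


def _stretches(resids: np.ndarray, exceed: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive residue numbers where ``exceed`` holds."""
    runs: list[tuple[int, int]] = []
    start = prev = None
    for r, flag in zip(resids, exceed):
        if flag and start is None:
            start = prev = int(r)
        elif flag and r == prev + 1:
            prev = int(r)
        elif flag:
            runs.append((start, prev))
            start = prev = int(r)
        elif start is not None:
            runs.append((start, prev))
            start = prev = None
    if start is not None:
        runs.append((start, prev))
    return runs


def delta_in_sigma(
    exp: Sequence[ResidueRates],
    calc: Sequence[ResidueRates],
    *,
    param: str = "eta_xy",
    thresholds: Sequence[float] = (1.0, 2.0, 3.0),
    combine_errors: bool = False,
) -> RateComparison:
    """Per-residue Δ/σ and outlier stretches, plus the Mann–Whitney test.

    σ defaults to the experimental error alone; ``combine_errors=True``
    adds the back-calculated error in quadrature. Only residues present
    (with errors) in both sets enter.
    """
    resids, ev, se, cv = _matched_arrays(exp, calc, param,
                                         combine_errors=combine_errors)
    delta = (cv - ev) / se
    u, p, method = mann_whitney_u(ev, cv)
    stretches = {
        thr: _stretches(resids, np.abs(delta) > thr) for thr in thresholds
    }
    return RateComparison(
        residues=resids, exp=ev, exp_err=se, calc=cv, delta_sigma=delta,
        u_stat=u, p_value=p, n_pairs=len(resids), method=method,
        stretches=stretches,
    )


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    *,
    alternative: str = "two-sided",
    exact_max_n: int = 8,
) -> tuple[float, float, str]:
    """Mann–Whitney U statistic and p-value; returns (U, p, method).

    The exact null distribution is used for small samples
    (min(n, m) ≤ ``exact_max_n``) without ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if min(x.size, y.size) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue), method


@dataclass(frozen=True)
class SegmentRanking:
    """Per-segment and pairwise Mann–Whitney results, best fit first."""

    order: tuple[str, ...]
    p_values: dict[str, float]
    u_stats: dict[str, float]
    accepted: dict[str, bool]
    pairwise_p: dict[tuple[str, str], float]
    param: str
    alpha: float


def rank_segments(
    exp: Sequence[ResidueRates],
    calc_by_segment: dict[str, Sequence[ResidueRates]],
    *,
    param: str = "eta_xy",
    alpha: float = 0.05,
    on_deltas: bool = False,
) -> SegmentRanking:
    """Rank candidate segments by agreement with the experimental rates.

    For each segment, the Mann–Whitney test compares the experimental and
    back-calculated rate samples over matched residues (default), or the
    Δ-values against zero-centred reference when ``on_deltas`` is set.
    Segments are ordered by descending p (larger p = better agreement);
    ``accepted`` marks p > alpha. Pairwise segment-vs-segment p-values are
    reported for every segment pair.
    """
    if not calc_by_segment:
        raise ValueError("at least one segment required")
    samples: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    p_values: dict[str, float] = {}
    u_stats: dict[str, float] = {}
    for label, calc in calc_by_segment.items():
        _, ev, se, cv = _matched_arrays(exp, calc, param)
        if on_deltas:
            a, b = (cv - ev) / se, np.zeros_like(cv)
        else:
            a, b = ev, cv
        u, p, _ = mann_whitney_u(a, b)
        samples[label] = (ev, cv)
        p_values[label] = p
        u_stats[label] = u
    labels = sorted(p_values, key=p_values.get, reverse=True)
    pairwise: dict[tuple[str, str], float] = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            _, p, _ = mann_whitney_u(samples[la][1], samples[lb][1])
            pairwise[(la, lb)] = p
    return SegmentRanking(
        order=tuple(labels),
        p_values=p_values,
        u_stats=u_stats,
        accepted={l: p_values[l] > alpha for l in labels},
        pairwise_p=pairwise,
        param=param,
        alpha=alpha,
    )
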