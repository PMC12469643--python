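"""From an MD trajectory segment to back-calculated ¹⁵N relaxation rates.

Pipeline: superpose all frames on the mean structure of the rigid core
(removing overall tumbling), extract unit N→H bond vectors per residue,
estimate the internal P2 orientational autocorrelation function
C(t) = ⟨P2(μ(s)·μ(s+t))⟩ over all time origins, fit it to
C(t) = A0 + Σ Aj exp(−t/τj), convert the fit to a multi-Lorentzian
spectral density by recombining with isotropic tumbling at the
experimental τc, and evaluate R1, NOE and η_xy. Uncertainties come from a
moving-block bootstrap over contiguous frame blocks, which preserves the
time correlation that an i.i.d. resample would destroy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, nnls

from .model_free import ResidueRates
from .spin import InteractionConstants, MultiExpSpectrum, all_rates

__all__ = [
    "VectorTrajectory",
    "AcfSeries",
    "MultiExpFit",
    "align_trajectory",
    "extract_nh_vectors",
    "compute_p2_acf",
    "fit_acf_multiexp",
    "backcalc_segment_rates",
    "bootstrap_rate_errors",
]


@dataclass
class VectorTrajectory:
    """Unit N→H vectors for a set of residues over uniformly spaced frames."""

    residues: np.ndarray          # (n_res,) author residue numbers
    vectors: np.ndarray           # (n_res, n_frames, 3), unit norm
    dt_ns: float                  # frame spacing
    skipped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError("vectors must have shape (n_res, n_frames, 3)")
        if self.dt_ns <= 0:
            raise ValueError("dt_ns must be positive")
        norms = np.linalg.norm(self.vectors, axis=2)
        if not np.all(np.isfinite(norms)):
            raise ValueError("NaN frames are not allowed")
        if np.abs(norms - 1.0).max() > 1e-6:
            raise ValueError("vectors must be unit-norm to 1e-6")

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[1]

    @property
    def duration_ns(self) -> float:
        return (self.n_frames - 1) * self.dt_ns


@dataclass
class AcfSeries:
    """P2 autocorrelation values on a uniform lag grid starting at 0."""

    lags_ns: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lags_ns = np.asarray(self.lags_ns, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if abs(self.values[0] - 1.0) > 1e-9:
            raise ValueError("C(0) must equal 1")
        # -0.5 <= P2 <= 1, small numerical excursions tolerated
        if np.abs(self.values).max() > 1.0 + 1e-9:
            raise ValueError("|C(t)| must not exceed 1")


@dataclass
class MultiExpFit:
    """Result of constrained multi-exponential ACF fitting.

    Amplitudes are non-negative and sum to one (a0 is the plateau, the
    trajectory estimate of the internal order parameter S²); τj are in ns,
    sorted ascending. ``aicc`` is the corrected-AIC model-selection score
    used to pick the number of exponentials.
    """

    a0: float
    terms: tuple[tuple[float, float], ...]   # (amplitude, tau_ns)
    rss: float
    aicc: float
    n_points: int

    @property
    def m(self) -> int:
        return len(self.terms)

    def evaluate(self, t_ns: np.ndarray) -> np.ndarray:
        t_ns = np.asarray(t_ns, dtype=float)
        out = np.full_like(t_ns, self.a0, dtype=float)
        for a, tau in self.terms:
            out = out + a * np.exp(-t_ns / tau)
        return out

    def to_spectrum(self, tau_c_s: float) -> MultiExpSpectrum:
        terms = tuple((a, tau * 1e-9) for a, tau in self.terms)
        return MultiExpSpectrum(a0=self.a0, terms=terms, tau_c=tau_c_s)


# ---------------------------------------------------------------------------
# alignment and vector extraction (MDAnalysis-backed)

def _rigid_selection(rigid_ranges: Sequence[tuple[int, int]],
                     atom_names: str = "N CA C O") -> str:
    if not rigid_ranges:
        raise ValueError("rigid_ranges must be non-empty")
    resid_clause = " or ".join(f"resid {a}-{b}" for a, b in rigid_ranges)
    return f"name {atom_names} and ({resid_clause})"


def align_trajectory(universe, rigid_ranges: Sequence[tuple[int, int]]):
    """Superpose every frame on the iterated mean structure of the rigid core.

    Two passes of least-squares (Kabsch) fitting on the heavy backbone
    atoms (N, Cα, C, O) of the rigid residue ranges: first onto frame 0,
    then onto the mean structure from that pass. The universe is loaded
    into memory and modified in place; it is also returned.
    """
    import MDAnalysis as mda
    from MDAnalysis.analysis import align as mda_align

    selection = _rigid_selection(rigid_ranges)
    if len(universe.select_atoms(selection)) < 3:
        raise ValueError(f"selection '{selection}' matches fewer than 3 atoms")
    universe.transfer_to_memory()

    for _pass in range(2):
        if _pass == 0:
            universe.trajectory[0]
            ref = universe
        else:
            coords = np.stack([universe.atoms.positions.copy()
                               for _ in universe.trajectory])
            ref = mda.Merge(universe.atoms)
            ref.load_new(coords.mean(axis=0)[None, :, :])
        mda_align.AlignTraj(universe, ref, select=selection,
                            in_memory=True).run()
    return universe


def extract_nh_vectors(universe, *, dt_ns: float | None = None,
                       h_names: tuple[str, ...] = ("H", "HN")) -> VectorTrajectory:
    """Unit N→H vectors per residue per frame from an (aligned) universe.

    Prolines, the N-terminal residue, and any residue lacking an amide
    proton are skipped and recorded in the skip list.
    """
    pairs: list[tuple[int, int, int]] = []   # (resid, N index, H index)
    skipped: list[tuple[int, str]] = []
    first_resid = universe.residues.resids.min()
    for res in universe.residues:
        if res.resname in ("PRO", "HYP"):
            skipped.append((int(res.resid), "proline"))
            continue
        if res.resid == first_resid:
            skipped.append((int(res.resid), "n-terminus"))
            continue
        names = {a.name: a.ix for a in res.atoms}
        if "N" not in names:
            skipped.append((int(res.resid), "no backbone N"))
            continue
        h_ix = next((names[h] for h in h_names if h in names), None)
        if h_ix is None:
            skipped.append((int(res.resid), "no amide H"))
            continue
        pairs.append((int(res.resid), names["N"], h_ix))
    if not pairs:
        raise ValueError("no residues with extractable N-H vectors")

    resids = np.array([p[0] for p in pairs])
    n_ix = np.array([p[1] for p in pairs])
    h_ix = np.array([p[2] for p in pairs])
    n_frames = len(universe.trajectory)
    vectors = np.empty((len(pairs), n_frames, 3))
    for t, _ in enumerate(universe.trajectory):
        pos = universe.atoms.positions
        v = pos[h_ix] - pos[n_ix]
        vectors[:, t, :] = v / np.linalg.norm(v, axis=1, keepdims=True)
    if dt_ns is None:
        dt_ns = universe.trajectory.dt / 1000.0   # MDAnalysis dt is in ps
    return VectorTrajectory(residues=resids, vectors=vectors,
                            dt_ns=dt_ns, skipped=skipped)


# ---------------------------------------------------------------------------
# P2 autocorrelation

def _p2_products(vecs: np.ndarray) -> np.ndarray:
    """Six product time series q_k(t) with Σ_k q_k(s)q_k(s+t) = (μ(s)·μ(s+t))²."""
    x, y, z = vecs[:, 0], vecs[:, 1], vecs[:, 2]
    s2 = math.sqrt(2.0)
    return np.stack([x * x, y * y, z * z, s2 * x * y, s2 * x * z, s2 * y * z])


def _acf_direct(vecs: np.ndarray, n_lags: int) -> np.ndarray:
    n = vecs.shape[0]
    dot2_sums = np.empty(n_lags)
    for lag in range(n_lags):
        d = np.einsum("ij,ij->i", vecs[: n - lag], vecs[lag:])
        dot2_sums[lag] = np.sum(d * d)
    return dot2_sums


def _acf_fft(vecs: np.ndarray, n_lags: int) -> np.ndarray:
    n = vecs.shape[0]
    q = _p2_products(vecs)
    nfft = 1 << (2 * n - 1).bit_length()
    fq = np.fft.rfft(q, nfft, axis=1)
    corr = np.fft.irfft(fq * np.conj(fq), nfft, axis=1)[:, :n_lags]
    return corr.sum(axis=0)


def compute_p2_acf(
    vec: VectorTrajectory,
    lag_max_ns: float,
    *,
    tau_c_ns: float | None = None,
    method: str = "fft",
) -> dict[int, AcfSeries]:
    """Per-residue P2 ACF, C(t) = ⟨P2(μ(s)·μ(s+t))⟩ over all time origins.

    ``method`` may be "fft" (default; exact all-origin estimator computed
    through product autocorrelations) or "direct" (explicit lag loop, used
    as a cross-check — the two agree to floating-point precision).
    A warning is raised when the segment is shorter than 10×τc, below
    which time averaging of C(t) becomes unreliable.
    """
    if lag_max_ns > vec.duration_ns:
        raise ValueError(
            f"lag_max {lag_max_ns} ns exceeds segment duration "
            f"{vec.duration_ns} ns"
        )
    if tau_c_ns is not None and vec.duration_ns < 10.0 * tau_c_ns:
        warnings.warn(
            f"segment duration {vec.duration_ns:.1f} ns is below 10*tau_c "
            f"= {10 * tau_c_ns:.1f} ns; C(t) averaging may be unreliable",
            stacklevel=2,
        )
    n_lags = int(round(lag_max_ns / vec.dt_ns)) + 1
    n = vec.n_frames
    n_pairs = n - np.arange(n_lags)
    lags_ns = np.arange(n_lags) * vec.dt_ns
    worker = {"fft": _acf_fft, "direct": _acf_direct}[method]
    out: dict[int, AcfSeries] = {}
    for i, resid in enumerate(vec.residues):
        dot2 = worker(vec.vectors[i], n_lags)
        values = 0.5 * (3.0 * dot2 / n_pairs - 1.0)
        values[0] = 1.0   # exact by construction; clear rounding residue
        out[int(resid)] = AcfSeries(lags_ns=lags_ns, values=values,
                                    n_pairs=n_pairs)
    return out


# ---------------------------------------------------------------------------
# multi-exponential fitting

_SUM_PENALTY = 1e4


def _solve_amplitudes(t: np.ndarray, c: np.ndarray,
                      taus: np.ndarray) -> tuple[np.ndarray, float]:
    """Non-negative amplitudes with Σ=1 (penalty-enforced) for fixed τj."""
    design = np.column_stack(
        [np.ones_like(t)] + [np.exp(-t / tau) for tau in taus]
    )
    aug = np.vstack([design, _SUM_PENALTY * np.ones(design.shape[1])])
    rhs = np.concatenate([c, [_SUM_PENALTY]])
    amps, _ = nnls(aug, rhs)
    total = amps.sum()
    if total > 0:
        amps = amps / total
    rss = float(np.sum((design @ amps - c) ** 2))
    return amps, rss


def _log_thin(n: int, max_points: int = 256) -> np.ndarray:
    """Log-spaced lag indices including 0 and n-1; information in C(t) is
    logarithmic in time, so dense linear sampling adds cost, not content."""
    if n <= max_points:
        return np.arange(n)
    idx = np.unique(np.round(
        np.logspace(0, math.log10(n - 1), max_points - 1)
    ).astype(int))
    return np.concatenate([[0], idx])


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    score = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        score += 2 * k * (k + 1) / (n - k - 1)
    else:
        score = math.inf
    return score


def fit_acf_multiexp(
    acf: AcfSeries,
    *,
    m_max: int = 4,
    max_fit_points: int = 256,
    taus_init_ns: Sequence[float] | None = None,
    tau_max_ns: float | None = None,
) -> MultiExpFit:
    """Fit C(t) = A0 + Σ_{j=1..m} Aj exp(−t/τj) with constrained amplitudes.

    Separable least squares: the nonlinear search runs over log τj only
    (Nelder–Mead from log-spaced initialisations), with amplitudes solved
    at each step by non-negative least squares under Σ amplitudes = 1.
    The number of exponentials m is chosen from 0..m_max by corrected AIC.
    A decay slower than ``tau_max_ns`` (default 3× the longest lag) is not
    identifiable within the observation window, so such terms are folded
    into the plateau a0. Deterministic for fixed inputs.
    """
    if len(acf.lags_ns) < 10:
        raise ValueError("need at least 10 lag points to fit")
    keep = _log_thin(len(acf.lags_ns), max_fit_points)
    t, c = acf.lags_ns[keep], acf.values[keep]
    n = len(t)
    t_lo = max(acf.lags_ns[1], 1e-6)
    t_hi = max(acf.lags_ns[-1], 10 * t_lo)
    if tau_max_ns is None:
        tau_max_ns = 3.0 * t_hi

    candidates: list[MultiExpFit] = []
    # m = 0: plateau only; the sum constraint pins a0 = 1
    rss0 = float(np.sum((c - 1.0) ** 2))
    candidates.append(MultiExpFit(a0=1.0, terms=(), rss=rss0,
                                  aicc=_aicc(rss0, n, 1), n_points=n))

    for m in range(1, m_max + 1):
        inits: list[np.ndarray] = []
        if taus_init_ns is not None and len(taus_init_ns) == m:
            inits.append(np.log(np.asarray(taus_init_ns, dtype=float)))
        # spread initial taus across the sampled decades
        grid = np.log(np.logspace(math.log10(t_lo), math.log10(t_hi), m + 2))
        inits.append(grid[1:-1])
        inits.append(grid[:-2])

        best = None
        for x0 in inits:
            res = minimize(
                lambda x: _solve_amplitudes(
                    t, c, np.minimum(np.exp(x), tau_max_ns))[1],
                x0, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-14, "maxiter": 400 * m},
            )
            if best is None or res.fun < best.fun:
                best = res
        taus = np.minimum(np.exp(best.x), tau_max_ns)
        amps, rss = _solve_amplitudes(t, c, taus)
        a0 = float(amps[0])
        order = np.argsort(taus)
        terms = []
        for j in order:
            if amps[1 + j] <= 1e-6:
                continue
            if taus[j] >= 0.999 * tau_max_ns:   # unresolvable: plateau weight
                a0 += float(amps[1 + j])
            else:
                terms.append((float(amps[1 + j]), float(taus[j])))
        terms = tuple(terms)
        k = 1 + 2 * len(terms)
        candidates.append(MultiExpFit(a0=a0, terms=terms,
                                      rss=rss, aicc=_aicc(rss, n, k),
                                      n_points=n))

    return min(candidates, key=lambda f: f.aicc)


# ---------------------------------------------------------------------------
# back-calculation and bootstrap

def backcalc_segment_rates(
    fits: dict[int, MultiExpFit],
    tau_c: float,
    k: InteractionConstants,
    *,
    eta_xy_j_zero: bool = True,
    with_r2: bool = False,
    errors: dict[int, dict[str, float]] | None = None,
) -> list[ResidueRates]:
    """Relaxation rates per residue from ACF fits at experimental τc (s)."""
    if tau_c <= 0:
        raise ValueError("tau_c must be positive")
    out: list[ResidueRates] = []
    for resid in sorted(fits):
        spec = fits[resid].to_spectrum(tau_c)
        rates = all_rates(spec, k, eta_xy_j_zero=eta_xy_j_zero,
                          with_r2=with_r2)
        err = (errors or {}).get(resid, {})
        out.append(ResidueRates(
            residue=resid,
            r1=rates["r1"], r1_err=err.get("r1"),
            noe=rates["noe"], noe_err=err.get("noe"),
            eta_xy=rates["eta_xy"], eta_xy_err=err.get("eta_xy"),
        ))
    return out


def _block_resample(n: int, block: int, rng: np.random.Generator) -> np.ndarray:
    """Moving-block bootstrap frame indices: contiguous blocks, original length."""
    n_blocks = math.ceil(n / block)
    starts = rng.integers(0, n - block + 1, size=n_blocks)
    idx = np.concatenate([np.arange(s, s + block) for s in starts])
    return idx[:n]


def bootstrap_rate_errors(
    vec: VectorTrajectory,
    tau_c: float,
    k: InteractionConstants,
    *,
    lag_max_ns: float,
    block_length_ns: float | None = None,
    n_boot: int = 100,
    seed: int = 0,
    eta_xy_j_zero: bool = True,
    m_max: int = 4,
) -> dict[int, dict[str, float]]:
    """Per-residue rate standard deviations from a moving-block bootstrap.

    Contiguous frame blocks (default length = lag_max) are resampled with
    replacement to the original trajectory length; ACF estimation, the
    multi-exponential fit and rate back-calculation are repeated on each
    replicate. Fits reuse the replicate-independent full-data τj as warm
    starts and the full-data m, which keeps replicates comparable and the
    procedure fast. Reproducible for a fixed seed.
    """
    if block_length_ns is None:
        block_length_ns = lag_max_ns
    block = max(2, int(round(block_length_ns / vec.dt_ns)))
    n = vec.n_frames
    if block >= n / 5:
        raise ValueError(
            f"block length {block_length_ns} ns too long for a "
            f"{vec.duration_ns:.1f} ns trajectory (need < duration/5)"
        )
    rng = np.random.default_rng(seed)
    base_acf = compute_p2_acf(vec, lag_max_ns)
    base_fit = {r: fit_acf_multiexp(a, m_max=m_max)
                for r, a in base_acf.items()}

    samples: dict[int, dict[str, list[float]]] = {
        int(r): {"r1": [], "noe": [], "eta_xy": []} for r in vec.residues
    }
    n_lags = int(round(lag_max_ns / vec.dt_ns)) + 1
    n_pairs = n - np.arange(n_lags)
    lags_ns = np.arange(n_lags) * vec.dt_ns
    for _ in range(n_boot):
        idx = _block_resample(n, block, rng)
        for i, resid in enumerate(vec.residues):
            resid = int(resid)
            dot2 = _acf_fft(vec.vectors[i][idx], n_lags)
            values = 0.5 * (3.0 * dot2 / n_pairs - 1.0)
            values[0] = 1.0
            np.clip(values, -1.0, 1.0, out=values)
            acf = AcfSeries(lags_ns=lags_ns, values=values, n_pairs=n_pairs)
            warm = [tau for _, tau in base_fit[resid].terms]
            fit = fit_acf_multiexp(
                acf, m_max=max(1, base_fit[resid].m),
                taus_init_ns=warm if warm else None,
            )
            rates = all_rates(fit.to_spectrum(tau_c), k,
                              eta_xy_j_zero=eta_xy_j_zero, with_r2=False)
            for key in ("r1", "noe", "eta_xy"):
                samples[resid][key].append(rates[key])

    return {
        resid: {key: float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                for key, vals in per.items()}
        for resid, per in samples.items()
    }
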