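"""Synthetic inputs with known ground truth for every stage of the pipeline.

Three internal-motion models generate unit N–H vector paths whose order
parameter is known in closed form:

* ``rigid`` — a static vector, S² = 1;
* ``cone`` — Brownian wobbling restricted to a cone of semi-angle θ0
  (reflected angular random walk; equilibrium uniform over the spherical
  cap), S² = [cos θ0 (1 + cos θ0)/2]²;
* ``jump`` — symmetric two-site exchange between orientations separated
  by angle β, S² = (1 + P2(cos β))/2, internal time τe = dt/(−ln(1−2p))
  with per-frame switch probability p.

Only S² has a closed form for the cone; its effective internal time is
calibrated numerically from the simulated correlation function
(:func:`estimate_tau_e_from_acf`). Optional isotropic overall tumbling
multiplies the internal motion by rotational diffusion with
C2(t) = exp(−t/τc), i.e. D_r = 1/(6 τc).

Generators also emit noisy per-residue relaxation tables (forward model:
the Lipari–Szabo rate equations), exponential peak-intensity series, and
poly-alanine trajectory files readable by the trajectory pipeline. All
randomness flows through a mandatory seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .model_free import ResidueRates
from .spin import InteractionConstants, ModelFreeParams, all_rates
from .trajectory import AcfSeries, VectorTrajectory
from .intensity import (
    ETA_ZETA_DELAYS_S,
    IntensitySeries,
    R1_DELAYS_S,
)

__all__ = [
    "ResidueDynamics",
    "DynamicsSpec",
    "SimulatedVectors",
    "cone_order_parameter",
    "jump_order_parameter",
    "simulate_nh_vectors",
    "estimate_tau_e_from_acf",
    "build_synthetic_trajectory_files",
    "synth_relaxation_table",
    "synth_intensity_series",
]


def cone_order_parameter(theta0_deg: float) -> float:
    """S² for diffusion in a cone of semi-angle θ0 (uniform over the cap)."""
    c = math.cos(math.radians(theta0_deg))
    return (c * (1.0 + c) / 2.0) ** 2


def jump_order_parameter(beta_deg: float) -> float:
    """S² for symmetric two-site jumps separated by angle β."""
    c = math.cos(math.radians(beta_deg))
    p2 = 0.5 * (3.0 * c * c - 1.0)
    return 0.5 * (1.0 + p2)


@dataclass(frozen=True)
class ResidueDynamics:
    """Internal-motion model for one residue of the synthetic chain."""

    model: Literal["rigid", "cone", "jump"] = "rigid"
    theta0_deg: float = 30.0        # cone semi-angle
    wobble_step_deg: float = 4.0    # RMS angular step per frame (cone)
    beta_deg: float = 45.0          # jump angle
    switch_prob: float = 0.05       # per-frame jump probability
    proline: bool = False
    jitter_A: float = 0.0           # extra positional noise for RMSF tests

    def __post_init__(self) -> None:
        if not 0.0 < self.theta0_deg <= 90.0:
            raise ValueError("theta0 must lie in (0, 90] degrees")
        if self.model == "jump" and not 0.0 < self.switch_prob < 0.5:
            raise ValueError("switch_prob must lie in (0, 0.5)")

    @property
    def s2(self) -> float:
        if self.model == "rigid":
            return 1.0
        if self.model == "cone":
            return cone_order_parameter(self.theta0_deg)
        return jump_order_parameter(self.beta_deg)


@dataclass(frozen=True)
class DynamicsSpec:
    """Full specification of a synthetic N–H vector ensemble."""

    residues: tuple[ResidueDynamics, ...]
    dt_ps: float = 10.0
    n_frames: int = 10000
    tumbling_tau_c_ns: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("at least one residue required")
        if self.dt_ps <= 0 or self.n_frames < 2:
            raise ValueError("dt_ps must be positive and n_frames >= 2")
        if self.tumbling_tau_c_ns is not None and self.tumbling_tau_c_ns <= 0:
            raise ValueError("tumbling tau_c must be positive")


@dataclass
class SimulatedVectors:
    """Simulated vectors in the molecular frame plus ground truth."""

    internal: VectorTrajectory                 # tumbling removed
    total: VectorTrajectory                    # with tumbling (if any)
    truth: dict[int, dict]                     # resid -> {"s2": ..., "model": ...}
    tumbling: Rotation | None = None           # per-frame lab rotations


def _cone_walk(n: int, theta0: float, step: float,
               rng: np.random.Generator) -> np.ndarray:
    """Reflected Brownian walk on the spherical cap, (n, 3) unit vectors.

    Each move proposes an isotropic tangent rotation of the current vector
    by a Gaussian arc (the metrically correct small-step Brownian motion
    on the sphere — stepping in (θ, φ) coordinates instead would
    equilibrate to the wrong measure). A proposal leaving the cap is
    rejected (the walker stays put): with a symmetric proposal this is a
    Metropolis chain whose stationary distribution is exactly uniform on
    the cap, so the plateau of the simulated ACF converges to the analytic
    S² without boundary-layer bias. The walk starts in equilibrium,
    cos θ ~ U(cos θ0, 1).
    """
    theta = math.acos(rng.uniform(math.cos(theta0), 1.0))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    alphas = rng.normal(0.0, step, size=n)
    psis = rng.uniform(0.0, 2.0 * math.pi, size=n)
    cos_cap = math.cos(theta0)
    out = np.empty((n, 3))
    for t in range(n):
        st, ct = math.sin(theta), math.cos(theta)
        cp, sp = math.cos(phi), math.sin(phi)
        u = (st * cp, st * sp, ct)
        out[t] = u
        # propose: rotate u by arc alpha in tangent direction psi
        e1 = (ct * cp, ct * sp, -st)              # d u / d theta
        e2 = (-sp, cp, 0.0)                       # azimuthal unit vector
        ca, sa = math.cos(alphas[t]), math.sin(alphas[t])
        cpsi, spsi = math.cos(psis[t]), math.sin(psis[t])
        vz = ca * u[2] + sa * (cpsi * e1[2] + spsi * e2[2])
        if vz < cos_cap:                           # outside the cap: reject
            continue
        vx = ca * u[0] + sa * (cpsi * e1[0] + spsi * e2[0])
        vy = ca * u[1] + sa * (cpsi * e1[1] + spsi * e2[1])
        theta = math.acos(max(-1.0, min(1.0, vz)))
        phi = math.atan2(vy, vx)
    return out


def _jump_path(n: int, beta: float, p: float,
               rng: np.random.Generator) -> np.ndarray:
    u_a = np.array([0.0, 0.0, 1.0])
    u_b = np.array([math.sin(beta), 0.0, math.cos(beta)])
    state = rng.integers(0, 2)
    switches = rng.random(n) < p
    states = (state + np.cumsum(switches)) % 2
    return np.where(states[:, None] == 0, u_a, u_b)


def simulate_nh_vectors(spec: DynamicsSpec) -> SimulatedVectors:
    """Stochastic unit-vector paths for each residue, with analytic truth."""
    rng = np.random.default_rng(spec.seed)
    n, n_res = spec.n_frames, len(spec.residues)
    internal = np.empty((n_res, n, 3))
    truth: dict[int, dict] = {}
    for i, rd in enumerate(spec.residues):
        resid = i + 1
        if rd.model == "rigid":
            internal[i] = np.array([0.0, 0.0, 1.0])
        elif rd.model == "cone":
            internal[i] = _cone_walk(
                n, math.radians(rd.theta0_deg),
                math.radians(rd.wobble_step_deg), rng,
            )
        else:
            internal[i] = _jump_path(
                n, math.radians(rd.beta_deg), rd.switch_prob, rng,
            )
        entry = {"s2": rd.s2, "model": rd.model}
        if rd.model == "jump":
            entry["tau_e_ns"] = (
                -spec.dt_ps / 1000.0 / math.log1p(-2.0 * rd.switch_prob)
            )
        truth[resid] = entry

    dt_ns = spec.dt_ps / 1000.0
    resids = np.arange(1, n_res + 1)
    vec_internal = VectorTrajectory(residues=resids, vectors=internal,
                                    dt_ns=dt_ns)
    tumbling = None
    total = internal
    if spec.tumbling_tau_c_ns is not None:
        d_r = 1.0 / (6.0 * spec.tumbling_tau_c_ns)       # ns^-1
        sigma = math.sqrt(2.0 * d_r * dt_ns)
        rotvecs = rng.normal(0.0, sigma, size=(n, 3))
        increments = Rotation.from_rotvec(rotvecs)
        mats = np.empty((n, 3, 3))
        acc = Rotation.identity()
        for t in range(n):
            acc = increments[t] * acc
            mats[t] = acc.as_matrix()
        tumbling = Rotation.from_matrix(mats)
        total = np.einsum("tab,itb->ita", mats, internal)
    vec_total = VectorTrajectory(residues=resids.copy(),
                                 vectors=total, dt_ns=dt_ns)
    return SimulatedVectors(internal=vec_internal, total=vec_total,
                            truth=truth, tumbling=tumbling)


def estimate_tau_e_from_acf(acf: AcfSeries, plateau: float | None = None,
                            tail_fraction: float = 0.5) -> float:
    """Effective internal correlation time (ns) by the ACF-area estimator.

    τe = ∫ (C(t) − p)/(1 − p) dt with plateau p taken from the mean of the
    tail half of the measured ACF (a measured plateau absorbs the finite
    sampling offset that an analytic S² would leak into the area), or
    supplied explicitly. Numerical calibration used for motion models (the
    cone walk) whose τe has no closed form; integration stops once the
    normalized ACF first drops below 2% so plateau noise stays out of the
    area.
    """
    if plateau is None:
        plateau = float(acf.values[int(len(acf.values) * tail_fraction):].mean())
    if not 0.0 <= plateau < 1.0:
        raise ValueError("tau_e is undefined for a rigid vector")
    norm = (acf.values - plateau) / (1.0 - plateau)
    below = np.nonzero(norm < 0.02)[0]
    stop = below[0] if below.size else len(norm)
    return float(np.trapezoid(norm[:stop], acf.lags_ns[:stop]))


# ---------------------------------------------------------------------------
# trajectory file generation

_BACKBONE_OFFSETS = {
    "N": np.array([0.0, 0.0, 0.0]),
    "CA": np.array([1.2, 0.8, 0.0]),
    "C": np.array([2.4, 0.0, 0.0]),
    "O": np.array([2.4, 1.0, 0.7]),
}
_RESIDUE_SPACING = 3.8   # Å along x
_NH_BOND = 1.02          # Å


def build_synthetic_trajectory_files(
    spec: DynamicsSpec,
    out_prefix: str,
    *,
    traj_format: str = "pdb",
) -> tuple[str, str, SimulatedVectors]:
    """Write a poly-alanine chain realizing the simulated N–H geometry.

    Each residue contributes backbone atoms N, CA, C, O (static in the
    molecular frame, so the rigid-core alignment is exact) plus an amide H
    placed 1.02 Å from N along the simulated unit vector; prolines get no
    H. When tumbling is enabled the whole frame is rigid-body rotated.
    Returns (topology_path, trajectory_path, simulated) where the
    trajectory is a multi-model PDB (``traj_format="pdb"``, text) or XTC.
    """
    import MDAnalysis as mda

    sim = simulate_nh_vectors(spec)
    n_res, n = len(spec.residues), spec.n_frames

    atom_names: list[str] = []
    atom_resindex: list[int] = []
    resnames: list[str] = []
    base_positions: list[np.ndarray] = []
    h_slot: dict[int, int] = {}
    for i, rd in enumerate(spec.residues):
        resnames.append("PRO" if rd.proline else "ALA")
        origin = np.array([i * _RESIDUE_SPACING, 0.0, 0.0])
        for name, off in _BACKBONE_OFFSETS.items():
            atom_names.append(name)
            atom_resindex.append(i)
            base_positions.append(origin + off)
        if not rd.proline:
            h_slot[i] = len(atom_names)
            atom_names.append("H")
            atom_resindex.append(i)
            base_positions.append(origin)     # placeholder, set per frame

    base = np.array(base_positions)
    n_atoms = len(atom_names)
    coords = np.empty((n, n_atoms, 3), dtype=np.float32)
    rng = np.random.default_rng(spec.seed + 1)
    jitter = np.array([spec.residues[r].jitter_A for r in atom_resindex])
    for t in range(n):
        frame = base.copy()
        for i, slot in h_slot.items():
            origin = np.array([i * _RESIDUE_SPACING, 0.0, 0.0])
            frame[slot] = origin + _NH_BOND * sim.internal.vectors[i, t]
        if jitter.any():
            frame = frame + rng.normal(0.0, 1.0, frame.shape) * jitter[:, None]
        if sim.tumbling is not None:
            frame = frame @ sim.tumbling[t].as_matrix().T
        coords[t] = frame

    u = mda.Universe.empty(
        n_atoms, n_residues=n_res, atom_resindex=np.array(atom_resindex),
        residue_segindex=np.zeros(n_res, dtype=int), trajectory=True,
    )
    u.add_TopologyAttr("names", atom_names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    u.add_TopologyAttr("elements", [nm[0] for nm in atom_names])
    _mass = {"N": 14.007, "C": 12.011, "O": 15.999, "H": 1.008}
    u.add_TopologyAttr("masses", [_mass[nm[0]] for nm in atom_names])
    u.load_new(coords, dt=spec.dt_ps)

    top_path = f"{out_prefix}_top.pdb"
    u.trajectory[0]
    u.atoms.write(top_path)
    if traj_format == "pdb":
        traj_path = f"{out_prefix}_traj.pdb"
        with mda.Writer(traj_path, n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    elif traj_format == "xtc":
        traj_path = f"{out_prefix}_traj.xtc"
        with mda.Writer(traj_path, n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    else:
        raise ValueError(f"unsupported trajectory format: {traj_format}")
    return top_path, traj_path, sim


# ---------------------------------------------------------------------------
# tables and intensity series

def synth_relaxation_table(
    truth: Sequence[tuple[int, ModelFreeParams]],
    k: InteractionConstants,
    *,
    noise_pct: float = 0.0,
    seed: int = 0,
    eta_xy_j_zero: bool = True,
) -> list[ResidueRates]:
    """Forward-computed R1/NOE/η_xy table with Gaussian noise.

    ``noise_pct`` is the relative noise (and reported error) per rate, in
    percent. Noise-free tables round-trip exactly through the (S², τc)
    solver.
    """
    if noise_pct < 0:
        raise ValueError("noise_pct must be non-negative")
    rng = np.random.default_rng(seed)
    frac = noise_pct / 100.0
    out: list[ResidueRates] = []
    for resid, params in truth:
        rates = all_rates(params, k, eta_xy_j_zero=eta_xy_j_zero,
                          with_r2=False)
        noisy = {
            key: val * (1.0 + frac * rng.standard_normal()) if frac else val
            for key, val in rates.items()
        }
        out.append(ResidueRates(
            residue=resid,
            r1=noisy["r1"], r1_err=frac * abs(rates["r1"]),
            noe=noisy["noe"], noe_err=frac * abs(rates["noe"]),
            eta_xy=noisy["eta_xy"], eta_xy_err=frac * abs(rates["eta_xy"]),
        ))
    return out


def synth_intensity_series(
    rate: float,
    mode: Literal["r1", "eta"],
    *,
    delays: Sequence[float] | None = None,
    noise_pct: float = 0.0,
    seed: int = 0,
    i0: float = 100.0,
    exponent_factor: float = 4.0,
    constant_time: float | None = None,
) -> IntensitySeries:
    """Exponential peak-intensity series for one residue.

    ``mode="r1"``: I(t) = I0·exp(−R·t) on the standard relaxation-delay
    grid; ``mode="eta"``: I(ζ) = I0·exp(−c·η·ζ) on the constant-time ζ
    grid. Gaussian noise of ``noise_pct`` percent of I0 is added.
    """
    if delays is None:
        delays = R1_DELAYS_S if mode == "r1" else ETA_ZETA_DELAYS_S
    t = np.asarray(delays, dtype=float)
    if mode == "r1":
        y = i0 * np.exp(-rate * t)
        ct = None
    elif mode == "eta":
        y = i0 * np.exp(-exponent_factor * rate * t)
        ct = constant_time
    else:
        raise ValueError(f"unknown mode: {mode}")
    noise = noise_pct / 100.0 * i0
    if noise_pct:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise, size=y.shape)
    return IntensitySeries(delays=t, intensities=y,
                           noise=noise or None, constant_time=ct)
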