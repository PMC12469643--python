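"""RMSD time series, plateau-based segment selection, and per-residue RMSF.

Candidate trajectory segments for relaxation back-calculation are stable
stretches ("plateaus") of the backbone-RMSD time series: fixed-length
windows whose internal scatter is small and which contain no sharp
frame-to-frame transition. Selection thresholds are explicit parameters
and are echoed into the output so a report is self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "SegmentSpec",
    "compute_rmsd_series",
    "detect_plateau_segments",
    "compute_rmsf",
]

DEFAULT_RIGID_RANGES: tuple[tuple[int, int], ...] = (
    (131, 152), (162, 193), (204, 265), (296, 342), (351, 366), (383, 392),
)


@dataclass(frozen=True)
class SegmentSpec:
    """A candidate trajectory segment on an RMSD plateau."""

    start_ns: float
    end_ns: float
    rmsd_mean: float     # Å
    rmsd_sd: float       # Å
    label: str = ""
    thresholds: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def compute_rmsd_series(universe, *, selection: str,
                        reference=None) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit RMSD (Å) of the selection to a reference, per frame.

    ``reference`` defaults to frame 0 of the trajectory. Returns
    (times_ns, rmsd_angstrom).
    """
    from MDAnalysis.analysis.rms import RMSD as _RMSD

    if len(universe.select_atoms(selection)) == 0:
        raise ValueError(f"selection '{selection}' matches no atoms")
    ref = reference if reference is not None else universe
    analysis = _RMSD(universe, ref, select=selection)
    analysis.run()
    res = analysis.results.rmsd
    return res[:, 1] / 1000.0, res[:, 2]   # ps -> ns, Å


def detect_plateau_segments(
    times_ns: np.ndarray,
    rmsd: np.ndarray,
    *,
    window_ns: float = 500.0,
    sd_max: float = 0.3,
    jump_max: float = 1.0,
    equilibration_ns: float = 0.0,
    step_ns: float | None = None,
) -> list[SegmentSpec]:
    """Fixed-length windows where the RMSD series is flat.

    A window qualifies when its internal standard deviation is at most
    ``sd_max`` Å and no frame-to-frame change inside it exceeds
    ``jump_max`` Å. Overlapping qualifying windows are merged into runs,
    and the earliest-start window of each run is reported. Windows start
    on a grid of ``step_ns`` (default: the frame spacing) at or after the
    equilibration cutoff. An empty list is a valid result.
    """
    times_ns = np.asarray(times_ns, dtype=float)
    rmsd = np.asarray(rmsd, dtype=float)
    if times_ns.shape != rmsd.shape or times_ns.ndim != 1:
        raise ValueError("times and rmsd must be 1-D arrays of equal length")
    duration = times_ns[-1] - times_ns[0]
    if duration < window_ns:
        raise ValueError(
            f"series duration {duration:.1f} ns shorter than the "
            f"{window_ns:.0f} ns window"
        )
    dt = float(np.median(np.diff(times_ns)))
    if step_ns is None:
        step_ns = dt
    w = max(2, int(round(window_ns / dt)))
    stride = max(1, int(round(step_ns / dt)))
    start_min = times_ns[0] + equilibration_ns
    jumps = np.abs(np.diff(rmsd))
    thresholds = {"window_ns": window_ns, "sd_max": sd_max,
                  "jump_max": jump_max, "equilibration_ns": equilibration_ns}

    ok_starts: list[int] = []
    for i0 in range(0, len(rmsd) - w + 1, stride):
        if times_ns[i0] < start_min:
            continue
        chunk = rmsd[i0: i0 + w]
        if chunk.std() > sd_max:
            continue
        if jumps[i0: i0 + w - 1].max(initial=0.0) > jump_max:
            continue
        ok_starts.append(i0)

    segments: list[SegmentSpec] = []
    run_start: int | None = None
    prev: int | None = None
    for i0 in ok_starts + [None]:
        contiguous = (i0 is not None and prev is not None
                      and i0 - prev <= stride)
        if contiguous:
            prev = i0
            continue
        if run_start is not None:
            chunk = rmsd[run_start: run_start + w]
            segments.append(SegmentSpec(
                start_ns=float(times_ns[run_start]),
                end_ns=float(times_ns[run_start] + window_ns),
                rmsd_mean=float(chunk.mean()),
                rmsd_sd=float(chunk.std()),
                thresholds=thresholds,
            ))
        run_start = prev = i0
    for n, seg in enumerate(segments):
        object.__setattr__(seg, "label", f"segment-{n + 1}")
    return segments


def compute_rmsf(universe, *, selection: str = "name CA") -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF (Å) about the mean position of an aligned trajectory.

    Returns (resids, rmsf_angstrom) for the atoms of ``selection``
    (default: one Cα per residue). Frame order does not matter.
    """
    atoms = universe.select_atoms(selection)
    if len(atoms) == 0:
        raise ValueError(f"selection '{selection}' matches no atoms")
    coords = np.stack([atoms.positions.copy() for _ in universe.trajectory])
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    return atoms.resids.copy(), rmsf
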