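"""Trajectory reduction to the two design quantities.

A molecular-dynamics trajectory of a candidate sequence, together with a
per-frame per-residue energy decomposition, is collapsed into the two
numbers the design problem optimizes: the time-averaged deviation of the
coordinates from the target fold (stability, an RMSD) and the time-averaged
energy.  Both are kept per residue as well, because the surrogate network
regresses them node-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import CaTrace, InvalidInputError


@dataclass
class TrajectoryEnsemble:
    """A stack of coordinate frames with optional per-residue energies.

    ``frames`` is (T, n, 3) in Angstrom; ``frame_energies`` (T, n) in
    kcal/mol if present; ``times`` optional timestamps in ns.
    """

    frames: np.ndarray
    frame_energies: np.ndarray | None = None
    times: np.ndarray | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InvalidInputError(f"frames must be (T, n, 3); got {self.frames.shape}")
        if self.frame_energies is not None:
            self.frame_energies = np.asarray(self.frame_energies, dtype=float)
            if self.frame_energies.shape != self.frames.shape[:2]:
                raise InvalidInputError(
                    "frame_energies must be (T, n) matching frames; got "
                    f"{self.frame_energies.shape} vs {self.frames.shape[:2]}"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return self.frames.shape[1]


@dataclass
class TrajectorySummary:
    """Per-residue and aggregate stability / energy of one trajectory.

    ``per_residue_rmsd[i]`` is the root-mean over frames of residue *i*'s
    squared displacement from the target (Angstrom); ``rmsd_total`` pools
    frames and residues.  ``per_residue_energy`` is the frame-mean energy
    per residue (kcal/mol) and ``energy_total`` its sum.
    """

    per_residue_rmsd: np.ndarray
    rmsd_total: float
    per_residue_energy: np.ndarray | None = None
    energy_total: float | None = None
    id: str = ""

    @property
    def has_energy(self) -> bool:
        return self.per_residue_energy is not None

    def targets(self) -> np.ndarray:
        """The (2, n) training-target matrix: energy row, deviation row."""
        if not self.has_energy:
            raise InvalidInputError("summary has no energy channel")
        return np.vstack([self.per_residue_energy, self.per_residue_rmsd])


def subsample_frames(traj: TrajectoryEnsemble, count: int = 50) -> TrajectoryEnsemble:
    """Retain ``count`` frames at regular index intervals, ending at the last.

    With ``T`` stored frames and stride ``T // count`` the retained indices
    form an arithmetic progression whose final element is ``T - 1``.  A
    trajectory shorter than ``count`` is returned whole with a warning.
    The default of 50 matches the coordinate-set count extracted per design
    from each production run.
    """
    t = traj.n_frames
    if t < count:
        warnings.warn(
            f"trajectory has {t} frames, fewer than requested {count}; returning all",
            stacklevel=2,
        )
        return traj
    step = t // count
    idx = t - 1 - step * np.arange(count - 1, -1, -1)
    return TrajectoryEnsemble(
        frames=traj.frames[idx],
        frame_energies=None if traj.frame_energies is None else traj.frame_energies[idx],
        times=None if traj.times is None else np.asarray(traj.times)[idx],
        id=traj.id,
    )


def superpose(frame: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rigid superposition of ``frame`` onto ``target``.

    Kabsch: the proper rotation (no reflection) plus translation minimizing
    the sum of squared point distances.  Degenerate (collinear) point sets
    still return a valid minimizer.
    """
    frame = np.asarray(frame, dtype=float)
    target = np.asarray(target, dtype=float)
    if frame.shape != target.shape:
        raise InvalidInputError(f"shape mismatch {frame.shape} vs {target.shape}")
    fc = frame.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, frame - fc)
    return rot.apply(frame - fc) + tc


def summarize(
    traj: TrajectoryEnsemble,
    target: CaTrace | np.ndarray,
    align: bool = True,
    frame_count: int | None = None,
) -> TrajectorySummary:
    """Reduce a trajectory to its stability and mean-energy summary.

    Each frame is (by default) rigidly superposed onto the target before the
    deviation is measured, so the stability metric reports internal motion
    rather than diffusive drift; pass ``align=False`` for raw deviations.
    The time integrals are realized as uniform averages over the retained
    frames, the natural quadrature for regular-interval sampling.  Pass
    ``frame_count`` to subsample first.
    """
    xtar = target.coords if isinstance(target, CaTrace) else np.asarray(target, dtype=float)
    if frame_count is not None:
        traj = subsample_frames(traj, frame_count)
    if traj.frames.shape[1:] != xtar.shape:
        raise InvalidInputError(
            f"frame shape {traj.frames.shape[1:]} does not match target {xtar.shape}"
        )

    frames = traj.frames
    if align:
        frames = np.stack([superpose(f, xtar) for f in frames])

    sq = np.einsum("tij,tij->ti", frames - xtar, frames - xtar)  # (T, n)
    per_residue_rmsd = np.sqrt(sq.mean(axis=0))
    rmsd_total = float(np.sqrt(sq.mean()))

    per_residue_energy = None
    energy_total = None
    if traj.frame_energies is not None:
        per_residue_energy = traj.frame_energies.mean(axis=0)
        energy_total = float(per_residue_energy.sum())
    else:
        warnings.warn("trajectory carries no energies; energy fields absent", stacklevel=2)

    return TrajectorySummary(
        per_residue_rmsd=per_residue_rmsd,
        rmsd_total=rmsd_total,
        per_residue_energy=per_residue_energy,
        energy_total=energy_total,
        id=traj.id,
    )
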