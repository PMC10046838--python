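"""Synthetic molecular-dynamics stand-in with known ground truth.

Real training data for the surrogate comes from an expensive pipeline:
structure generation, explicit-solvent MD, and an end-point binding-energy
decomposition per residue.  This module emulates the *shape* of that data —
for each candidate sequence, ~50 coordinate snapshots fluctuating around a
target C-alpha trace plus a per-frame per-residue energy table — from a
seeded generative model whose ground truth is known exactly, so every other
module can be tested quantitatively without any simulation software.

The ground-truth energy is a distance-kernel pairwise (Potts-like) model:
residue *i* of sequence *s* contributes

    e_i = a[s_i] + sum_{j != i} exp(-d_ij^2 / scale^2) * W[s_i, s_j],

a one-body letter preference plus contact-weighted two-body couplings.
Structural fluctuation is tied to energy: high-energy residues fluctuate
with larger amplitude, so the energy and deviation channels are correlated
(but not identical) exactly when the sensitivity parameter is nonzero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import ALPHABET, CaTrace, InvalidInputError
from .trajectory import TrajectoryEnsemble, TrajectorySummary, summarize


@dataclass
class SyntheticWorld:
    """Ground-truth parameters of the synthetic energy/fluctuation model.

    ``letter_energies`` (k,) are one-body energies in kcal/mol-like units,
    drawn in [-5, 5]; ``couplings`` (k, k) is symmetric; ``kernel_scale``
    (Angstrom) sets the contact decay; ``fluct_base`` (Angstrom) the
    baseline positional noise; ``fluct_sensitivity`` how strongly a
    residue's normalized energy inflates its own fluctuation;
    ``obs_noise_sd`` (kcal/mol) the per-frame energy observation noise.
    """

    letter_energies: np.ndarray
    couplings: np.ndarray
    kernel_scale: float = 8.0
    fluct_base: float = 0.5
    fluct_sensitivity: float = 0.3
    obs_noise_sd: float = 0.5
    seed: int = 0
    alphabet: str = ALPHABET

    def __post_init__(self) -> None:
        self.letter_energies = np.asarray(self.letter_energies, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        k = len(self.alphabet)
        if self.letter_energies.shape != (k,):
            raise InvalidInputError(f"letter_energies must be ({k},)")
        if self.couplings.shape != (k, k) or not np.allclose(
            self.couplings, self.couplings.T
        ):
            raise InvalidInputError(f"couplings must be symmetric ({k}, {k})")
        if self.fluct_base < 0:
            raise InvalidInputError("fluct_base must be >= 0")

    @classmethod
    def from_seed(cls, seed: int = 0, **overrides) -> "SyntheticWorld":
        """Draw a random world: letter energies in [-5, 5], couplings ~ N(0, 1)."""
        rng = np.random.default_rng(seed)
        k = len(overrides.get("alphabet", ALPHABET))
        a = rng.uniform(-5.0, 5.0, size=k)
        w = rng.standard_normal((k, k))
        w = 0.5 * (w + w.T)
        return cls(letter_energies=a, couplings=w, seed=seed, **overrides)

    def manifest(self) -> dict:
        d = asdict(self)
        d["letter_energies"] = self.letter_energies.tolist()
        d["couplings"] = self.couplings.tolist()
        return d

    @classmethod
    def from_manifest(cls, d: dict) -> "SyntheticWorld":
        return cls(
            letter_energies=np.array(d["letter_energies"]),
            couplings=np.array(d["couplings"]),
            kernel_scale=d["kernel_scale"],
            fluct_base=d["fluct_base"],
            fluct_sensitivity=d["fluct_sensitivity"],
            obs_noise_sd=d["obs_noise_sd"],
            seed=d["seed"],
            alphabet=d["alphabet"],
        )


def make_target(n: int, kind: str = "helix", seed: int = 0) -> CaTrace:
    """Generate a target C-alpha trace.

    ``helix`` places residues on an ideal alpha-helix (radius 2.3 A, rise
    1.5 A per residue, 100 degrees per residue); ``random_smooth`` is a
    seeded smoothed random walk with consecutive C-alpha spacing close to
    the physical 3.8 A.  The placeholder sequence is poly-alanine.
    """
    if n < 4:
        raise InvalidInputError("need n >= 4")
    if kind == "helix":
        t = np.arange(n) * np.deg2rad(100.0)
        coords = np.column_stack(
            [2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n)]
        )
    elif kind == "random_smooth":
        rng = np.random.default_rng(seed)
        steps = rng.standard_normal((n - 1, 3))
        # smooth the step directions so the walk bends gently
        for _ in range(3):
            steps[1:-1] = (steps[:-2] + 2 * steps[1:-1] + steps[2:]) / 4.0
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        lengths = 3.8 + 0.1 * rng.standard_normal(n - 1)
        coords = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps * lengths[:, None], axis=0)])
    else:
        raise InvalidInputError(f"unknown target kind {kind!r}")
    return CaTrace(sequence="A" * n, coords=coords, id=f"{kind}-{n}")


def true_energy(sequence: str, trace: CaTrace, world: SyntheticWorld) -> np.ndarray:
    """Exact ground-truth per-residue energy of ``sequence`` on ``trace``."""
    if len(sequence) != len(trace):
        raise InvalidInputError("sequence/trace length mismatch")
    idx = np.array([world.alphabet.index(c) for c in sequence])
    x = trace.coords
    diff = x[:, None, :] - x[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    kern = np.exp(-d2 / world.kernel_scale**2)
    np.fill_diagonal(kern, 0.0)
    pair = world.couplings[np.ix_(idx, idx)]  # (n, n): W[s_i, s_j]
    return world.letter_energies[idx] + (kern * pair).sum(axis=1)


def fluctuation_sd(sequence: str, trace: CaTrace, world: SyntheticWorld) -> np.ndarray:
    """Per-residue isotropic displacement SD sigma_i (Angstrom).

    ``sigma_i = base * (1 + sensitivity * z_i)`` with ``z`` the per-design
    z-score of the true energy, clipped from below at 0.05 A.
    """
    e = true_energy(sequence, trace, world)
    sd = e.std()
    z = (e - e.mean()) / (sd if sd > 1e-12 else 1.0)
    sigma = world.fluct_base * (1.0 + world.fluct_sensitivity * z)
    if np.any(sigma <= 0):
        import warnings

        warnings.warn("fluctuation SD clipped at 0.05 A for some residues", stacklevel=2)
        sigma = np.maximum(sigma, 0.05)
    return sigma


def simulate_trajectory(
    sequence: str,
    target: CaTrace,
    world: SyntheticWorld,
    frames: int = 50,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Emulated production run: seeded fluctuations around the target.

    Every frame is the target plus per-residue isotropic Gaussian
    displacements with SD :func:`fluctuation_sd`; every frame's per-residue
    energy is the ground truth plus observation noise.  Identical seeds give
    identical ensembles.
    """
    if frames < 2:
        raise InvalidInputError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    sigma = fluctuation_sd(sequence, target, world)
    n = len(target)
    disp = rng.standard_normal((frames, n, 3)) * sigma[None, :, None]
    e = true_energy(sequence, target, world)
    noise = world.obs_noise_sd * rng.standard_normal((frames, n))
    return TrajectoryEnsemble(
        frames=target.coords[None] + disp,
        frame_energies=e[None, :] + noise,
        id=f"sim-{sequence[:8]}",
    )


@dataclass
class SyntheticDataset:
    """Generated corpus: (trace, ensemble, summary) triples plus manifest."""

    entries: list  # of (CaTrace, TrajectoryEnsemble, TrajectorySummary)
    target: CaTrace
    world: SyntheticWorld
    seed: int = 0
    frames: int = 50

    def __len__(self) -> int:
        return len(self.entries)

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "frames": self.frames,
            "n_designs": len(self.entries),
            "n_residues": len(self.target),
            "target_kind": self.target.id,
            "world": self.world.manifest(),
        }

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def random_sequence(n: int, rng, alphabet: str = ALPHABET) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def make_dataset(
    n_designs: int,
    n_residues: int,
    world: SyntheticWorld,
    frames: int = 50,
    seed: int = 0,
    target: CaTrace | None = None,
    target_kind: str = "random_smooth",
    align: bool = True,
) -> SyntheticDataset:
    """Generate a labelled corpus of random designs on one shared target.

    Each of ``n_designs`` random sequences is simulated for ``frames``
    snapshots (default 50, the per-design coordinate-set count of the real
    pipeline) and summarized into per-residue energy and deviation targets.
    Fully regenerable from (seed, world): sequence draws and per-design
    simulation seeds all derive from ``seed``.
    """
    rng = np.random.default_rng(seed)
    if target is None:
        target = make_target(n_residues, kind=target_kind, seed=seed)
    entries = []
    for i in range(n_designs):
        seq = random_sequence(n_residues, rng, world.alphabet)
        sim_seed = int(rng.integers(0, 2**31 - 1))
        traj = simulate_trajectory(seq, target, world, frames=frames, seed=sim_seed)
        summ = summarize(traj, target, align=align)
        trace = CaTrace(sequence=seq, coords=target.coords, id=f"design-{i}")
        entries.append((trace, traj, summ))
    return SyntheticDataset(
        entries=entries, target=target, world=world, seed=seed, frames=frames
    )
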