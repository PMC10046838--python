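"""Reduce a (synthetic) MD trajectory to the two design quantities.

Simulates 500 snapshots of a random sequence fluctuating around its target,
subsamples to the standard 50 frames, and summarizes: per-residue mean
energy (kcal/mol) and per-residue RMSD from the target (Angstrom).
"""

import numpy as np

import pinndesign as P

world = P.SyntheticWorld.from_seed(7)
target = P.make_target(20, "random_smooth", seed=7)
sequence = "MKWVTFISLLFLFSSAYSRG"

traj = P.simulate_trajectory(sequence, target, world, frames=500, seed=7)
traj50 = P.subsample_frames(traj, 50)
summary = P.summarize(traj50, target)

print(f"simulated {traj.n_frames} frames, retained {traj50.n_frames}")
print(f"total mean energy  E* = {summary.energy_total:8.2f} kcal/mol")
print(f"total stability    r  = {summary.rmsd_total:8.3f} A")
i = int(np.argmax(summary.per_residue_rmsd))
print(f"most mobile residue: {sequence[i]}{i} "
      f"(rmsd {summary.per_residue_rmsd[i]:.3f} A, "
      f"energy {summary.per_residue_energy[i]:+.2f} kcal/mol)")
print()
print("E* is the time-averaged binding energy the design problem minimizes;")
print("r is the time-averaged deviation from the target fold it constrains.")
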