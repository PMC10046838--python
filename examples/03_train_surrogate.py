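"""Train the graph-network surrogate on a small synthetic corpus.

Uses a reduced corpus (100 designs of length 20) so the script finishes in
well under a minute; the benchmark profile (300 designs, length 25) is what
the test suite exercises.
"""

import numpy as np

import pinndesign as P

cfg = P.RunConfig(
    n_designs=100, n_residues=20, seed=7,
    train=P.TrainConfig(epochs=120, seed=7),
)
model, history, dataset, world = P.run_train(cfg)

rel = P.validation_relative_error(model, P.standardize_targets(
    P.dataset_to_examples(dataset))[0])
print(f"corpus: {len(dataset)} designs x {dataset.frames} frames")
print(f"model: width {model.width}, depth {model.depth}, "
      f"{P.count_parameters(model):,} parameters")
print(f"final training loss   {history.train_loss[-1]:.4f}")
print(f"final validation loss {history.val_loss[-1]:.4f}")
print(f"relative error (energy, deviation) = ({rel[0]:.3f}, {rel[1]:.3f})")
print()
print("The two relative errors compare de-normalized per-residue predictions")
print("with the generator's (noisy) labels over the whole corpus; the loss")
print("is the mean squared error on standardized targets.")
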