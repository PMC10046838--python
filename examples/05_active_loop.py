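"""Active-learning loop: design, re-simulate with the synthetic world,
append to the corpus, retrain.
"""

import pinndesign as P

cfg = P.RunConfig(
    n_designs=80, n_residues=15, n_starts=10, width=32, seed=7,
    train=P.TrainConfig(epochs=60, seed=7),
)
model, dataset, rounds = P.run_active_loop(cfg, rounds=2)

for entry in rounds:
    print(f"round {entry['round']}: corpus {entry['n_examples']} designs, "
          f"validation loss {entry['val_loss']:.4f}")
print()
print("Each round the campaign's designs are re-simulated by the synthetic")
print("MD stand-in and folded back into the training corpus, so the")
print("surrogate sharpens exactly where the optimizer is exploring.")
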