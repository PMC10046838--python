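r"""Residual graph network surrogate for trajectory-derived design metrics.

The network maps a per-residue feature matrix ``X`` ((k+3) x n: one-hot
sequence plus geometric channels) and a graph Laplacian ``L`` to a 2 x n
output: the per-residue binding energy and the per-residue structural
deviation that a molecular-dynamics run of that sequence would produce.
Its layers are

.. math::
    Y_0 = K_0 X, \qquad
    Y_{j+1} = Y_j + \sigma(K_j Y_j L), \qquad
    X_{out} = K_{out} Y_N,

with :math:`\sigma` the leaky rectifier.  Multiplication by ``L`` diffuses
residue features along the contact graph, so each residual block couples
local sequence identity to its structural neighbourhood.  There are no bias
terms, giving exactly :math:`s(k+3) + N s^2 + 2 s` learnable scalars —
1,323,520 (about 1.3 M) at the full profile (width 512, depth 5, 23 input
channels).

Training, prediction and the analytic gradient of the design objective with
respect to the (relaxed) sequence block are all implemented here with
explicit forward/backward passes over the weight list, so the same code
path serves regression and sequence optimization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import GraphLaplacian, ParameterError


@dataclass
class NormStats:
    """Per-channel standardization statistics for the two target channels."""

    mean: np.ndarray  # (2,)
    std: np.ndarray  # (2,)

    def transform(self, targets: np.ndarray) -> np.ndarray:
        return (targets - self.mean[:, None]) / self.std[:, None]

    def inverse(self, standardized: np.ndarray) -> np.ndarray:
        return standardized * self.std[:, None] + self.mean[:, None]


@dataclass
class LabeledExample:
    """One training triple: features, Laplacian, and (2, n) targets.

    Target row 0 is per-residue energy, row 1 per-residue deviation, both on
    whatever scale the dataset currently carries (raw before
    :func:`standardize_targets`, standardized after).
    """

    features: np.ndarray
    laplacian: GraphLaplacian
    targets: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        n = self.features.shape[1]
        if self.laplacian.matrix.shape != (n, n) or self.targets.shape != (2, n):
            raise ValueError(
                f"inconsistent example: features n={n}, "
                f"L {self.laplacian.matrix.shape}, targets {self.targets.shape}"
            )


@dataclass
class SurrogateModel:
    """Weights and normalization state of the surrogate network."""

    K0: np.ndarray  # (s, k+3)
    hidden: list  # N matrices, each (s, s)
    Kout: np.ndarray  # (2, s)
    slope: float = 0.01
    norm_stats: NormStats | None = None

    @property
    def width(self) -> int:
        return self.K0.shape[0]

    @property
    def depth(self) -> int:
        return len(self.hidden)

    @property
    def in_channels(self) -> int:
        return self.K0.shape[1]

    def weights(self) -> list:
        return [self.K0, *self.hidden, self.Kout]

    def set_weights(self, ws: list) -> None:
        self.K0 = ws[0]
        self.hidden = list(ws[1:-1])
        self.Kout = ws[-1]

    def copy(self) -> "SurrogateModel":
        return SurrogateModel(
            K0=self.K0.copy(),
            hidden=[k.copy() for k in self.hidden],
            Kout=self.Kout.copy(),
            slope=self.slope,
            norm_stats=None
            if self.norm_stats is None
            else NormStats(self.norm_stats.mean.copy(), self.norm_stats.std.copy()),
        )

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Write a single portable .npz checkpoint (weights + norm stats)."""
        arrays = {"K0": self.K0, "Kout": self.Kout}
        for i, k in enumerate(self.hidden):
            arrays[f"K{i + 1}"] = k
        meta = {"depth": self.depth, "slope": self.slope}
        if self.norm_stats is not None:
            arrays["norm_mean"] = self.norm_stats.mean
            arrays["norm_std"] = self.norm_stats.std
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            hidden = [z[f"K{i + 1}"] for i in range(meta["depth"])]
            stats = None
            if "norm_mean" in z:
                stats = NormStats(mean=z["norm_mean"], std=z["norm_std"])
            return cls(
                K0=z["K0"],
                hidden=hidden,
                Kout=z["Kout"],
                slope=meta["slope"],
                norm_stats=stats,
            )


def init_model(
    in_channels: int = 23,
    width: int = 64,
    depth: int = 5,
    slope: float = 0.01,
    seed: int = 0,
) -> SurrogateModel:
    """Seeded scaled-Gaussian initialization.

    Hidden blocks start small (residual branches near identity) so the deep
    stack is stable from the first step.  ``width=512, depth=5`` is the full
    profile; ``width=64`` is the desk-scale default used throughout testing.
    """
    rng = np.random.default_rng(seed)
    k0 = rng.standard_normal((width, in_channels)) / np.sqrt(in_channels)
    hidden = [
        rng.standard_normal((width, width)) * (0.1 / np.sqrt(width)) for _ in range(depth)
    ]
    kout = rng.standard_normal((2, width)) / np.sqrt(width)
    return SurrogateModel(K0=k0, hidden=hidden, Kout=kout, slope=slope)


def count_parameters(model: SurrogateModel) -> int:
    """Number of learnable scalars: ``s(k+3) + N s^2 + 2 s`` (no biases)."""
    return int(sum(w.size for w in model.weights()))


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _leaky(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def _leaky_grad(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, 1.0, slope)


def _forward_batch(model: SurrogateModel, X: np.ndarray, L: np.ndarray, keep: bool):
    """Batched forward pass.  X: (B, f, n), L: (B, n, n) symmetric.

    Returns (out, cache); cache holds per-layer (Z, Yprev @ L) for backward.
    """
    Y = np.matmul(model.K0, X)  # (B, s, n)
    cache = {"X": X, "L": L, "Y0": Y, "layers": []} if keep else None
    for K in model.hidden:
        YL = np.matmul(Y, L)
        Z = np.matmul(K, YL)
        A = _leaky(Z, model.slope)
        if keep:
            cache["layers"].append((Z, YL))
        Y = Y + A
    out = np.matmul(model.Kout, Y)
    if keep:
        cache["YN"] = Y
    return out, cache


def _backward_batch(model: SurrogateModel, cache: dict, Gout: np.ndarray):
    """Backpropagate an upstream gradient on the output.

    Gout: (B, 2, n) = d(scalar)/d(out).  Returns (weight grads in the order
    of ``model.weights()``, gradient with respect to X of shape (B, f, n)).
    """
    L = cache["L"]
    dKout = np.einsum("bon,bsn->os", Gout, cache["YN"])
    dY = np.einsum("os,bon->bsn", model.Kout, Gout)
    dHidden = [None] * len(model.hidden)
    for j in range(len(model.hidden) - 1, -1, -1):
        Z, YL = cache["layers"][j]
        dZ = dY * _leaky_grad(Z, model.slope)
        dHidden[j] = np.einsum("bpn,bqn->pq", dZ, YL)
        # Z = K Yprev L with L symmetric: dYprev = (K^T dZ) L
        dY = dY + np.matmul(np.einsum("pq,bpn->bqn", model.hidden[j], dZ), L)
    dK0 = np.einsum("bsn,bfn->sf", dY, cache["X"])
    dX = np.einsum("sf,bsn->bfn", model.K0, dY)
    return [dK0, *dHidden, dKout], dX


def forward(model: SurrogateModel, X: np.ndarray, L: GraphLaplacian | np.ndarray) -> np.ndarray:
    """Evaluate the network on one example; returns the raw (2, n) output."""
    Lm = L.matrix if isinstance(L, GraphLaplacian) else np.asarray(L, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != model.in_channels:
        raise ValueError(
            f"feature matrix has {X.shape[0]} rows, model expects {model.in_channels}"
        )
    if Lm.shape != (X.shape[1], X.shape[1]):
        raise ValueError(f"Laplacian {Lm.shape} does not match n={X.shape[1]}")
    out, _ = _forward_batch(model, X[None], Lm[None], keep=False)
    return out[0]


# ---------------------------------------------------------------------------
# dataset handling and training
# ---------------------------------------------------------------------------


def standardize_targets(dataset: list) -> tuple[list, NormStats]:
    """Standardize both target channels over the pooled dataset.

    Means and standard deviations are computed over every residue of every
    example (pooled, not per protein), then each example's targets are
    replaced by their z-scores.  The returned :class:`NormStats` inverts the
    transform at prediction time.
    """
    if len(dataset) < 2:
        raise ParameterError("standardization needs at least 2 examples")
    stacked = np.concatenate([ex.targets for ex in dataset], axis=1)
    mean = stacked.mean(axis=1)
    std = stacked.std(axis=1)
    if np.any(std < 1e-12):
        raise ParameterError("a target channel has zero variance; cannot standardize")
    stats = NormStats(mean=mean, std=std)
    out = [
        LabeledExample(
            features=ex.features,
            laplacian=ex.laplacian,
            targets=stats.transform(ex.targets),
            id=ex.id,
        )
        for ex in dataset
    ]
    return out, stats


@dataclass
class TrainConfig:
    """Training-loop settings (adaptive-moment gradient descent)."""

    learning_rate: float = 2e-3
    epochs: int = 300
    batch_size: int = 32  # 0 = full batch
    validation_fraction: float = 0.15
    seed: int = 0
    patience: int = 0  # 0 = no early stopping
    lr_schedule: str = "cosine"  # "cosine" anneals to final_lr_fraction * lr
    final_lr_fraction: float = 0.05
    weight_decay: float = 0.0  # decoupled (AdamW-style)
    ema_decay: float = 0.995  # 0 = off; weight averaging over recent steps
    # per-channel loss weights (energy, deviation): at 50 frames the
    # deviation labels carry roughly ten times the sampling noise of the
    # energy labels in standardized units, so their residuals are
    # down-weighted (mild heteroscedastic correction)
    channel_weights: tuple = (1.0, 0.25)

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ParameterError("validation fraction must be in (0, 1)")
        self.channel_weights = tuple(self.channel_weights)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    seed: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
            }
        )


def _stack(dataset: list) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([ex.features for ex in dataset])
    L = np.stack([ex.laplacian.matrix for ex in dataset])
    T = np.stack([ex.targets for ex in dataset])
    return X, L, T


def _mse_and_grads(model, X, L, T, channel_weights=(1.0, 1.0)):
    out, cache = _forward_batch(model, X, L, keep=True)
    resid = out - T
    w = np.asarray(channel_weights, dtype=float)[None, :, None]
    loss = float(np.mean(w * resid**2))
    Gout = 2.0 * w * resid / resid.size
    grads, _ = _backward_batch(model, cache, Gout)
    return loss, grads


def train(
    model: SurrogateModel,
    dataset: list,
    config: TrainConfig | None = None,
) -> tuple[SurrogateModel, TrainHistory]:
    """Fit the network to standardized per-residue targets by Adam.

    The loss is the mean squared error over the 2 x n outputs.  The dataset
    is split into train/validation by a seeded shuffle; all randomness
    (split, minibatch order) flows from ``config.seed``, so two runs with
    the same seed produce bit-identical weights.  Training aborts with a
    diagnostic if the loss goes non-finite.
    """
    config = config or TrainConfig()
    if model.norm_stats is None:
        raise ParameterError(
            "model has no norm_stats; run standardize_targets and attach them first"
        )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(config.validation_fraction * len(dataset))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    Xt, Lt, Tt = _stack([dataset[i] for i in train_idx])
    Xv, Lv, Tv = _stack([dataset[i] for i in val_idx])

    model = model.copy()
    ws = [w.copy() for w in model.weights()]
    ema_ws = [w.copy() for w in ws] if config.ema_decay else None
    m = [np.zeros_like(w) for w in ws]
    v = [np.zeros_like(w) for w in ws]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate
    history = TrainHistory(seed=config.seed)

    best_val = np.inf
    best_ws = None
    stale = 0
    step = 0
    bsz = config.batch_size or len(train_idx)

    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            frac = config.final_lr_fraction
            lr = config.learning_rate * (
                frac + (1 - frac) * 0.5 * (1 + np.cos(np.pi * epoch / max(1, config.epochs - 1)))
            )
        perm = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        nb = 0
        for lo in range(0, len(perm), bsz):
            sel = perm[lo : lo + bsz]
            model.set_weights(ws)
            loss, grads = _mse_and_grads(
                model, Xt[sel], Lt[sel], Tt[sel], config.channel_weights
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            step += 1
            bc1 = 1.0 - beta1**step
            bc2 = 1.0 - beta2**step
            for i, g in enumerate(grads):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                ws[i] = ws[i] - lr * (
                    (m[i] / bc1) / (np.sqrt(v[i] / bc2) + eps)
                    + config.weight_decay * ws[i]
                )
            if ema_ws is not None:
                d = config.ema_decay
                for i in range(len(ws)):
                    ema_ws[i] = d * ema_ws[i] + (1 - d) * ws[i]
            epoch_loss += loss
            nb += 1
        model.set_weights(ema_ws if ema_ws is not None else ws)
        val_out, _ = _forward_batch(model, Xv, Lv, keep=False)
        val_loss = float(np.mean((val_out - Tv) ** 2))
        history.train_loss.append(epoch_loss / nb)
        history.val_loss.append(val_loss)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_ws = [w.copy() for w in (ema_ws if ema_ws is not None else ws)]
            stale = 0
        else:
            stale += 1
            if config.patience and stale >= config.patience:
                break

    if config.patience and best_ws is not None:
        model.set_weights(best_ws)
    return model, history


def validation_relative_error(model: SurrogateModel, dataset: list) -> np.ndarray:
    """Norm-ratio error per channel, on the de-normalized scale.

    ``||pred_c - y_c|| / ||y_c||`` with predictions and targets both mapped
    back through the stored normalization, pooled over all residues of all
    examples.  Returns a length-2 array (energy, deviation).
    """
    X, L, T = _stack(dataset)
    out, _ = _forward_batch(model, X, L, keep=False)
    stats = model.norm_stats
    pred = out * stats.std[None, :, None] + stats.mean[None, :, None]
    truth = T * stats.std[None, :, None] + stats.mean[None, :, None]
    num = np.sqrt(np.sum((pred - truth) ** 2, axis=(0, 2)))
    den = np.sqrt(np.sum(truth**2, axis=(0, 2)))
    return num / den


# ---------------------------------------------------------------------------
# design-time evaluation
# ---------------------------------------------------------------------------


def _design_forward(model, S, geo_rows, Lm, keep=False):
    X = np.vstack([S, geo_rows])
    out, cache = _forward_batch(model, X[None], Lm[None], keep=keep)
    return out[0], cache


def predict_design_metrics(
    model: SurrogateModel,
    S: np.ndarray,
    geo_rows: np.ndarray,
    L: GraphLaplacian | np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """Predicted design metrics for a (relaxed) sequence matrix.

    Stacks the k x n sequence block ``S`` over the fixed geometric rows of
    the target structure, runs the network, de-normalizes, and aggregates:
    total energy is the sum of the per-residue energy channel; stability is
    the root-mean-square of the per-residue deviation channel.  Returns
    ``(energy_total, stability_total, per_residue)`` with ``per_residue``
    the de-normalized (2, n) matrix.
    """
    import warnings as _w

    if np.min(S) < -1e-9 or np.max(S) > 1 + 1e-9:
        _w.warn("sequence matrix has entries outside [0, 1]; project first", stacklevel=2)
    Lm = L.matrix if isinstance(L, GraphLaplacian) else np.asarray(L, dtype=float)
    out, _ = _design_forward(model, S, geo_rows, Lm)
    if model.norm_stats is not None:
        out = model.norm_stats.inverse(out)
    energy_total = float(out[0].sum())
    stability_total = float(np.sqrt(np.mean(out[1] ** 2)))
    return energy_total, stability_total, out


def objective_value_and_grad(
    model: SurrogateModel,
    S: np.ndarray,
    geo_rows: np.ndarray,
    L: GraphLaplacian | np.ndarray,
    stability_weight: float = 1.0,
    stability_tol: float = 0.0,
) -> tuple[float, np.ndarray]:
    r"""Design objective and its analytic gradient with respect to ``S``.

    The objective is the predicted total energy plus a soft quadratic
    penalty on the stability constraint,

    .. math::
        f(S) = E(S) + \lambda \, \max(0,\; r(S) - \delta_{stab})^2,

    which with :math:`\lambda = 0` reduces to pure energy minimization.
    Gradients flow only into the sequence block; the geometric rows are
    fixed properties of the target.  Returns ``(value, (k, n) gradient)``.
    """
    Lm = L.matrix if isinstance(L, GraphLaplacian) else np.asarray(L, dtype=float)
    k = S.shape[0]
    out, cache = _design_forward(model, S, geo_rows, Lm, keep=True)
    stats = model.norm_stats
    if stats is not None:
        phys = stats.inverse(out)
        scale = stats.std
    else:
        phys = out
        scale = np.ones(2)

    n = phys.shape[1]
    energy_total = float(phys[0].sum())
    stability_total = float(np.sqrt(np.mean(phys[1] ** 2)))
    gap = stability_total - stability_tol
    value = energy_total + stability_weight * max(0.0, gap) ** 2

    # d(value)/d(raw network output)
    Gout = np.zeros_like(out)
    Gout[0, :] = scale[0]
    if stability_weight != 0.0 and gap > 0.0 and stability_total > 1e-12:
        # d r / d phys1_i = phys1_i / (n r);   chain through the penalty
        Gout[1, :] = 2.0 * stability_weight * gap * phys[1] / (n * stability_total) * scale[1]
    _, dX = _backward_batch(model, cache, Gout[None])
    return value, dX[0, :k, :]
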