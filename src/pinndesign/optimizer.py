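r"""Projected-gradient sequence design over the relaxed one-hot matrix.

A discrete sequence of length ``n`` over a ``k``-letter alphabet is a
binary ``k x n`` matrix with one nonzero per column.  The design problem —
minimize the surrogate-predicted energy subject to structural stability —
is relaxed onto the convex set

.. math::
    0 \le S_{ij} \le 1, \qquad \sum_i S_{ij} = 1, \qquad
    \|S\|_{1,2}^2 = \sum_j \sum_i S_{ij}^2 \le n,

i.e. every column lies on the probability simplex.  (The group-sparsity
bound is implied by the first two conditions — for entries in [0, 1] with
unit column sums, :math:`\sum_{ij} S_{ij}^2 \le n` always holds — so the
Euclidean projection onto the set is exactly per-column simplex projection,
computed by sort-and-threshold.)  The solver alternates a steepest-descent
step on the objective with this projection, and exits on a fixed point, an
iteration limit, or when the discretized iterate accumulates more mutations
from its start than a preassigned cap (default 10).

The batch driver adds the accounting rule used for design campaigns: a run
over many starting sequences stops accepting mutations once the *mean*
mutation count per design reaches a configured stop (default 5), so 50
starts yield exactly 250 mutations in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ALPHABET, InvalidInputError, one_hot
from .surrogate import SurrogateModel, objective_value_and_grad, predict_design_metrics


def project_feasible(Sstar: np.ndarray) -> np.ndarray:
    """Euclidean projection of each column onto the probability simplex.

    Sort-and-threshold (simple thresholding): each column ``c`` becomes
    ``max(c - theta, 0)`` with ``theta`` the unique shift making the
    positive part sum to one.  Idempotent; a feasible matrix passes through
    unchanged.
    """
    S = np.asarray(Sstar, dtype=float)
    if not np.all(np.isfinite(S)):
        raise InvalidInputError("projection input contains non-finite values")
    k = S.shape[0]
    u = -np.sort(-S, axis=0)  # descending per column
    css = np.cumsum(u, axis=0) - 1.0
    rho_idx = np.arange(1, k + 1)[:, None]
    cond = u - css / rho_idx > 0
    rho = np.maximum(cond.cumsum(axis=0).max(axis=0), 1)  # last True per column
    theta = css[rho - 1, np.arange(S.shape[1])] / rho
    return np.maximum(S - theta[None, :], 0.0)


def discretize(S: np.ndarray, alphabet: str = ALPHABET) -> str:
    """Hard sequence from a relaxed matrix: per-column argmax letter.

    Ties go to the lowest alphabet index (numpy argmax), deterministically.
    """
    return "".join(alphabet[i] for i in np.argmax(S, axis=0))


def count_mutations(seq: str, seq0: str) -> int:
    """Hamming distance between two equal-length sequences."""
    if len(seq) != len(seq0):
        raise InvalidInputError(f"length mismatch: {len(seq)} vs {len(seq0)}")
    return sum(a != b for a, b in zip(seq, seq0))


def perturb(S: np.ndarray, scale: float, seed: int) -> np.ndarray:
    """Add seeded zero-mean Gaussian noise and re-project to feasibility."""
    if scale == 0:
        return np.array(S, dtype=float, copy=True)
    rng = np.random.default_rng(seed)
    return project_feasible(S + scale * rng.standard_normal(S.shape))


@dataclass
class DesignConfig:
    """Knobs of the projected-gradient design loop.

    ``step_size`` acts on the standardized objective; ``stability_tol`` is
    the acceptable RMSD from the target (Angstrom) and ``stability_weight``
    the soft-penalty weight on exceeding it.  ``mutation_cap`` bounds the
    Hamming distance any single design may move from its start;
    ``batch_mean_stop`` bounds the campaign-wide mean.
    """

    step_size: float = 0.1
    max_iter: int = 200
    stability_tol: float = 1.0
    stability_weight: float = 1.0
    mutation_cap: int = 10
    batch_mean_stop: float = 5.0
    fixed_point_tol: float = 1e-7
    perturb_scale: float = 0.3
    backtracking: bool = False
    max_halvings: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_size < 0:
            raise InvalidInputError("step_size must be >= 0")
        if self.mutation_cap < 1:
            raise InvalidInputError("mutation_cap must be a positive integer")


@dataclass
class DesignResult:
    """Outcome of one design run."""

    S: np.ndarray
    sequence: str
    start_sequence: str
    energy_trace: list = field(default_factory=list)
    stability_trace: list = field(default_factory=list)
    mutation_trace: list = field(default_factory=list)
    termination: str = "max_iter"  # fixed_point | cap_exceeded | max_iter | budget

    @property
    def mutations(self) -> int:
        return count_mutations(self.sequence, self.start_sequence)


class SurrogateObjective:
    """Design objective bound to a trained surrogate and a fixed target.

    Exposes ``value_and_grad(S)`` and ``metrics(S)``; any object with the
    same two methods (e.g. a toy quadratic) can drive the design loop.
    """

    def __init__(self, model: SurrogateModel, geo_rows, L, config: DesignConfig):
        self.model = model
        self.geo_rows = np.asarray(geo_rows, dtype=float)
        self.L = L
        self.config = config

    def value_and_grad(self, S: np.ndarray) -> tuple[float, np.ndarray]:
        return objective_value_and_grad(
            self.model,
            S,
            self.geo_rows,
            self.L,
            stability_weight=self.config.stability_weight,
            stability_tol=self.config.stability_tol,
        )

    def metrics(self, S: np.ndarray) -> tuple[float, float]:
        e, r, _ = predict_design_metrics(self.model, S, self.geo_rows, self.L)
        return e, r


def objective(
    model: SurrogateModel, S, geo_rows, L, config: DesignConfig
) -> float:
    """Scalar design objective: energy plus soft stability penalty."""
    value, _ = objective_value_and_grad(
        model,
        S,
        geo_rows,
        L,
        stability_weight=config.stability_weight,
        stability_tol=config.stability_tol,
    )
    return value


def _step(obj, S, mu, config):
    """One projected-gradient step; returns (S_new, f_value_at_S)."""
    f, g = obj.value_and_grad(S)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient in design step")
    S_new = project_feasible(S - mu * g)
    if config.backtracking:
        for _ in range(config.max_halvings):
            f_new, _ = obj.value_and_grad(S_new)
            if f_new <= f:
                break
            mu *= 0.5
            S_new = project_feasible(S - mu * g)
    return S_new, f


def design(
    S0: np.ndarray,
    objective_fn,
    config: DesignConfig | None = None,
    alphabet: str = ALPHABET,
) -> DesignResult:
    """Run projected gradient descent from one starting sequence matrix.

    ``objective_fn`` is any object with ``value_and_grad(S)`` (a
    :class:`SurrogateObjective`, typically).  Iterates
    ``S <- P(S - mu * grad f(S))`` until a fixed point
    (``||S_new - S||_F <= tol``), the iteration limit, or until the
    discretized iterate exceeds the per-design mutation cap — in which case
    the last iterate *within* the cap is returned and the run is marked
    ``cap_exceeded``.
    """
    config = config or DesignConfig()
    S = project_feasible(S0)
    start_seq = discretize(S, alphabet)
    result = DesignResult(S=S, sequence=start_seq, start_sequence=start_seq)

    for it in range(config.max_iter):
        S_new, f_val = _step(objective_fn, S, config.step_size, config)
        seq_new = discretize(S_new, alphabet)
        muts = count_mutations(seq_new, start_seq)
        if muts > config.mutation_cap:
            result.termination = "cap_exceeded"
            break
        delta = float(np.linalg.norm(S_new - S))
        S = S_new
        result.energy_trace.append(f_val)
        result.mutation_trace.append(muts)
        if hasattr(objective_fn, "metrics"):
            result.stability_trace.append(objective_fn.metrics(S)[1])
        if delta <= config.fixed_point_tol:
            result.termination = "fixed_point"
            break
    else:
        result.termination = "max_iter"

    result.S = S
    result.sequence = discretize(S, alphabet)
    return result


def design_with_restarts(
    S0: np.ndarray,
    objective_fn,
    config: DesignConfig | None = None,
    n_restarts: int = 5,
    alphabet: str = ALPHABET,
):
    """Best-of-restarts wrapper: perturb the start, design, keep the best.

    The non-convex relaxed landscape has many basins; seeded random
    perturbations of the feasible start explore them, and the run with the
    lowest final objective value wins.
    """
    config = config or DesignConfig()
    best, best_f = None, np.inf
    for r in range(n_restarts):
        start = project_feasible(S0) if r == 0 else perturb(S0, config.perturb_scale, config.seed + r)
        res = design(start, objective_fn, config, alphabet)
        f, _ = objective_fn.value_and_grad(res.S)
        if f < best_f:
            best, best_f = res, f
    return best


def _merge_limited(S_prev, S_new, start_seq, budget_left, alphabet):
    """Accept mutating columns of ``S_new`` in residue order within budget.

    Columns whose discrete letter newly differs from both the previous
    iterate and the start are accepted only while the mutation budget
    lasts; the rest revert to the previous iterate's columns.  Returns the
    merged matrix and the number of *new* mutations accepted.
    """
    prev_seq = discretize(S_prev, alphabet)
    new_seq = discretize(S_new, alphabet)
    S = np.array(S_new, copy=True)
    accepted = 0
    for j in range(len(start_seq)):
        was_mut = prev_seq[j] != start_seq[j]
        now_mut = new_seq[j] != start_seq[j]
        if now_mut and not was_mut:
            if accepted < budget_left:
                accepted += 1
            else:
                S[:, j] = S_prev[:, j]
    return S, accepted


def batch_design(
    starts: list,
    objective_fns,
    config: DesignConfig | None = None,
    alphabet: str = ALPHABET,
) -> list:
    """Design a batch of starts under the campaign mutation-accounting rule.

    Designs are advanced round-robin, one projected-gradient step per sweep.
    The driver maintains a global mutation budget
    ``batch_mean_stop * len(starts)``; once the summed mutation count
    reaches it, no further mutations are accepted and the campaign stops —
    a step that would overshoot is truncated column-by-column in residue
    order, so the total lands exactly on the budget whenever enough
    mutation pressure exists.  A design that reaches a fixed point while
    budget remains is re-seeded by a feasible perturbation of its current
    iterate (seeded, so the whole campaign is reproducible); a design whose
    next step would exceed the per-design cap is frozen at its last iterate
    within the cap.

    ``objective_fns`` is either one objective shared by all starts or a
    list with one per start.  Returns one :class:`DesignResult` per start,
    in the input order.
    """
    config = config or DesignConfig()
    m = len(starts)
    if m == 0:
        raise InvalidInputError("batch_design needs at least one start")
    if not isinstance(objective_fns, (list, tuple)):
        objective_fns = [objective_fns] * m
    budget = int(round(config.batch_mean_stop * m))

    S_cur = [project_feasible(np.asarray(s, dtype=float)) for s in starts]
    start_seqs = [discretize(S, alphabet) for S in S_cur]
    results = [
        DesignResult(S=S_cur[i], sequence=start_seqs[i], start_sequence=start_seqs[i])
        for i in range(m)
    ]
    muts = [0] * m
    active = [config.batch_mean_stop > 0] * m
    stalls = [0] * m
    if budget == 0:
        for r in results:
            r.termination = "budget"
        return results

    max_sweeps = config.max_iter
    for sweep in range(max_sweeps):
        total = sum(muts)
        if total >= budget or not any(active):
            break
        for i in range(m):
            total = sum(muts)
            if total >= budget:
                break
            if not active[i]:
                continue
            obj = objective_fns[i]
            S_new, f_val = _step(obj, S_cur[i], config.step_size, config)
            delta = float(np.linalg.norm(S_new - S_cur[i]))
            new_seq = discretize(S_new, alphabet)
            new_muts = count_mutations(new_seq, start_seqs[i])

            if new_muts > config.mutation_cap:
                active[i] = False
                results[i].termination = "cap_exceeded"
                continue
            if new_muts > muts[i]:
                # global budget check; truncate the step if it overshoots
                gained = new_muts - muts[i]
                room = budget - total
                if gained > room:
                    S_new, acc = _merge_limited(
                        S_cur[i], S_new, start_seqs[i], room, alphabet
                    )
                    new_seq = discretize(S_new, alphabet)
                    new_muts = count_mutations(new_seq, start_seqs[i])
            S_cur[i] = S_new
            muts[i] = new_muts
            results[i].energy_trace.append(f_val)
            results[i].mutation_trace.append(new_muts)
            if delta <= config.fixed_point_tol:
                stalls[i] += 1
                if stalls[i] > 3:
                    active[i] = False
                    results[i].termination = "fixed_point"
                else:
                    # budget remains: explore a new basin from here
                    S_cur[i] = perturb(
                        S_cur[i],
                        config.perturb_scale,
                        config.seed + 7919 * (i + 1) + sweep,
                    )
            else:
                stalls[i] = 0

    if sum(muts) >= budget:
        for i in range(m):
            if active[i]:
                results[i].termination = "budget"

    for i in range(m):
        results[i].S = S_cur[i]
        results[i].sequence = discretize(S_cur[i], alphabet)
    return results


def start_matrix(sequence: str, alphabet: str = ALPHABET) -> np.ndarray:
    """One-hot starting matrix for a discrete sequence."""
    return one_hot(sequence, alphabet)
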