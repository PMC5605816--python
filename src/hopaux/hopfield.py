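"""Single-network Hopfield model: Hebbian weights and sign-threshold dynamics.

The network holds binary neurons S_i ∈ {−1, +1}.  Memories are stored with
the outer-product (Hebbian) rule W = M Mᵀ with the diagonal zeroed, so the
input potential h_i = Σ_{j≠i} w_ij S_j is a single matrix-vector product.
States evolve under S_i(t+1) = g(h_i(t)) with the hard threshold
g(x) = +1 for x ≥ 0 and −1 otherwise.  Updates run either synchronously (all
neurons at once, the form the dynamical map is written in) or as an
asynchronous sweep in seeded random order, which with symmetric zero-diagonal
weights never increases the energy E = −½ SᵀWS and therefore always settles
in a fixed point.

No 1/N weight normalisation is applied: the threshold nonlinearity depends
only on the sign of h, so the dynamics are invariant to any positive
rescaling of W (a property the test suite locks in).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .patterns import MemoryPattern, MemorySet

__all__ = [
    "NetworkState",
    "WeightMatrix",
    "DynamicsConfig",
    "ConvergenceResult",
    "gain",
    "hebbian_weights",
    "input_potential",
    "update",
    "run_to_convergence",
    "energy",
    "overlap",
    "is_retrieved",
    "save_weights_csv",
    "load_weights_csv",
    "save_weights_npz",
    "load_weights_npz",
]

_WEIGHTS_FORMAT_VERSION = 1


@dataclasses.dataclass(eq=False)
class NetworkState:
    """Current ±1 spins plus the number of sweeps applied so far."""

    spins: np.ndarray
    time_step: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.spins).astype(np.int8)
        if arr.ndim != 1:
            raise ValueError("spins must be a 1-D vector")
        if not np.all(np.abs(arr) == 1):
            raise ValueError("spins must all be +1 or -1")
        self.spins = arr

    @property
    def n_neurons(self) -> int:
        return int(self.spins.size)


def _spins_of(state) -> np.ndarray:
    """Accept a NetworkState, MemoryPattern, or raw ±1 vector."""
    if isinstance(state, NetworkState):
        return state.spins
    if isinstance(state, MemoryPattern):
        return state.values
    return NetworkState(np.asarray(state)).spins


@dataclasses.dataclass(eq=False)
class WeightMatrix:
    """Square synaptic weight matrix w_ij.

    Hebbian construction yields a symmetric, zero-diagonal, integer-valued
    matrix; the zero diagonal realises the j ≠ i exclusion in the input
    potential.  A float64 copy is cached lazily for fast repeated products.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        self.weights = w
        self._f64: np.ndarray | None = None

    @property
    def n_neurons(self) -> int:
        return int(self.weights.shape[0])

    @property
    def dense_f64(self) -> np.ndarray:
        if self._f64 is None:
            self._f64 = np.ascontiguousarray(self.weights, dtype=np.float64)
        return self._f64

    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.weights, self.weights.T))


def _weights_of(weights) -> WeightMatrix:
    if isinstance(weights, WeightMatrix):
        return weights
    return WeightMatrix(np.asarray(weights))


@dataclasses.dataclass(frozen=True)
class DynamicsConfig:
    """Iteration scheme for the threshold dynamics.

    ``synchronous`` applies the update map to all neurons at once and, with
    ``cycle_detection``, also stops on the period-2 limit cycles that map can
    fall into (reported as not converged).  ``asynchronous_random_order``
    performs one full sweep per step, visiting neurons in a seeded random
    order and recomputing each potential from the partially updated state.
    Convergence means an update sweep reproduced the previous state exactly.
    """

    update_mode: str = "synchronous"
    max_sweeps: int = 50
    cycle_detection: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.update_mode not in ("synchronous", "asynchronous_random_order"):
            raise ValueError(f"unknown update mode {self.update_mode!r}")
        if self.max_sweeps < 1:
            raise ValueError("max_sweeps must be >= 1")


class ConvergenceResult(NamedTuple):
    state: NetworkState
    converged: bool
    sweeps: int
    cycle: bool = False


def gain(x):
    """Hard sign threshold: +1 for x ≥ 0 (zero maps to +1), −1 for x < 0."""
    arr = np.asarray(x)
    out = np.where(arr >= 0, 1, -1).astype(np.int8)
    if arr.ndim == 0:
        return int(out)
    return out


def hebbian_weights(memories) -> WeightMatrix:
    """Outer-product storage rule: W = M Mᵀ with the diagonal zeroed.

    Accepts a :class:`MemorySet` or a (K, N) ±1 array.  Entries are exact
    integers with |w_ij| ≤ K for K stored patterns.
    """
    M = memories.matrix if isinstance(memories, MemorySet) else np.asarray(memories)
    if M.ndim != 2 or M.shape[0] == 0:
        raise ValueError("need a non-empty (K, N) pattern matrix")
    Mf = M.astype(np.float64)
    W = np.rint(Mf.T @ Mf).astype(np.int32)
    np.fill_diagonal(W, 0)
    return WeightMatrix(W)


def input_potential(state, weights, bias: np.ndarray | None = None) -> np.ndarray:
    """h = W·S (+ optional external field); the j ≠ i exclusion holds via w_ii = 0."""
    s = _spins_of(state)
    w = _weights_of(weights)
    if w.n_neurons != s.size:
        raise ValueError(f"state length {s.size} != weight dimension {w.n_neurons}")
    h = w.dense_f64 @ s.astype(np.float64)
    if bias is not None:
        bias = np.asarray(bias, dtype=np.float64)
        if bias.shape != h.shape:
            raise ValueError("bias shape does not match state")
        h = h + bias
    return h


def update(state, weights, config: DynamicsConfig | None = None,
           rng: np.random.Generator | None = None,
           bias: np.ndarray | None = None,
           energy_log: list | None = None) -> NetworkState:
    """Apply one sweep of the threshold dynamics.

    Synchronous mode replaces every spin by g(h_i) simultaneously.
    Asynchronous mode updates neurons one at a time in a random order drawn
    from ``rng`` (or a generator seeded from ``config.seed``), recomputing
    each potential from the current, partially updated state; if
    ``energy_log`` is given, the energy is appended after every single-spin
    update, which makes the Lyapunov descent directly observable.
    """
    config = config or DynamicsConfig()
    s = _spins_of(state)
    w = _weights_of(weights)
    t = state.time_step if isinstance(state, NetworkState) else 0
    if config.update_mode == "synchronous":
        new = gain(input_potential(s, w, bias))
        return NetworkState(new, time_step=t + 1)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cur = np.array(s, copy=True)
    wf = w.dense_f64
    b = None if bias is None else np.asarray(bias, dtype=np.float64)
    for i in rng.permutation(cur.size):
        h_i = float(wf[i] @ cur)
        if b is not None:
            h_i += b[i]
        cur[i] = 1 if h_i >= 0 else -1
        if energy_log is not None:
            energy_log.append(energy(cur, w, bias=b))
    return NetworkState(cur, time_step=t + 1)


def run_to_convergence(initial, weights, config: DynamicsConfig | None = None,
                       bias: np.ndarray | None = None) -> ConvergenceResult:
    """Iterate update sweeps until the state stops changing.

    Stops at a fixed point (state equal to its predecessor, converged=True),
    at a detected period-2 cycle under synchronous updates (converged=False,
    cycle=True), or after ``max_sweeps`` sweeps (converged=False).
    """
    config = config or DynamicsConfig()
    rng = (np.random.default_rng(config.seed)
           if config.update_mode == "asynchronous_random_order" else None)
    state = (initial if isinstance(initial, NetworkState)
             else NetworkState(_spins_of(initial)))
    prev = state.spins
    prev_prev = None
    for sweep in range(1, config.max_sweeps + 1):
        state = update(state, weights, config, rng=rng, bias=bias)
        if np.array_equal(state.spins, prev):
            return ConvergenceResult(state, True, sweep, False)
        if (config.update_mode == "synchronous" and config.cycle_detection
                and prev_prev is not None
                and np.array_equal(state.spins, prev_prev)):
            return ConvergenceResult(state, False, sweep, True)
        prev_prev, prev = prev, state.spins
    return ConvergenceResult(state, False, config.max_sweeps, False)


def energy(state, weights, bias: np.ndarray | None = None) -> float:
    """Lyapunov energy E = −½ SᵀWS (− b·S under an external field).

    Requires symmetric weights; with a zero diagonal, asynchronous
    single-spin updates can only lower or preserve this quantity.
    """
    w = _weights_of(weights)
    if not w.is_symmetric():
        raise ValueError("energy requires a symmetric weight matrix")
    s = _spins_of(state).astype(np.float64)
    e = -0.5 * float(s @ (w.dense_f64 @ s))
    if bias is not None:
        e -= float(np.asarray(bias, dtype=np.float64) @ s)
    return e


def overlap(state, pattern) -> float:
    """Normalised overlap (S · m) / N in [−1, 1]; 1 means exact retrieval."""
    s = _spins_of(state)
    m = _spins_of(pattern)
    if s.size != m.size:
        raise ValueError(f"length mismatch: {s.size} vs {m.size}")
    return float(s.astype(np.float64) @ m.astype(np.float64)) / s.size


def is_retrieved(state, pattern) -> bool:
    """Full retrieval is an exact match (overlap 1); the negated memory does not count."""
    s = _spins_of(state)
    m = _spins_of(pattern)
    if s.size != m.size:
        raise ValueError(f"length mismatch: {s.size} vs {m.size}")
    return bool(np.array_equal(s, m))


# ---------------------------------------------------------------------------
# Weight matrix serialisation
# ---------------------------------------------------------------------------

def save_weights_csv(weights, path) -> None:
    """Dense CSV export; integer matrices round-trip bit-exactly."""
    w = _weights_of(weights).weights
    fmt = "%d" if np.issubdtype(w.dtype, np.integer) else "%.17g"
    np.savetxt(path, w, fmt=fmt, delimiter=",")


def load_weights_csv(path) -> WeightMatrix:
    w = np.loadtxt(path, delimiter=",", ndmin=2)
    if np.all(w == np.rint(w)):
        w = w.astype(np.int32) if np.abs(w).max(initial=0) < 2 ** 31 else w
    return WeightMatrix(w)


def save_weights_npz(weights, path) -> None:
    """Compressed binary container with a format-version header."""
    w = _weights_of(weights).weights
    np.savez_compressed(path, format_version=np.int64(_WEIGHTS_FORMAT_VERSION),
                        weights=w)


def load_weights_npz(path) -> WeightMatrix:
    with np.load(path) as data:
        version = int(data["format_version"])
        if version != _WEIGHTS_FORMAT_VERSION:
            raise ValueError(f"unsupported weight container version {version}")
        return WeightMatrix(data["weights"])
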