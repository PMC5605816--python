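"""Coupled original + auxiliary network with staged calibration and recovery.

The original N-neuron Hopfield network (block A) is wired to a smaller
auxiliary network — an external memory prosthesis — through two sparse
interface blocks: C (original → auxiliary) carries the read-out used to
calibrate auxiliary memory codes, and B (auxiliary → original) feeds the
auxiliary state back into the damaged network.  D is the auxiliary network's
own Hebbian matrix.  Together they form the block connectivity

    W̃ = [[A, B],
          [C, D]]

of the augmented system over memories m̃^μ = [m_o^μ; m_a^μ].

Calibration proceeds in five stages, each activating a subset of blocks:
stage 1 builds A, stage 2 inserts C and records the auxiliary code
m_a^μ = g(C m_o^μ) that each original memory evokes, stage 3 stores those
codes in D, stage 4 checks they are fixed points of the auxiliary dynamics
alone, and stage 5 builds the feedback block B.  Recovery mirrors the same
staging with A replaced by its lesioned version A_inj: the damaged original
settles on the cue, its state is read out into the auxiliary network, the
auxiliary cleans it up into a stored code, and the feedback B then biases the
original network back toward the correct memory.

During each recovery stage, the network not being updated is held clamped;
an unclamped mode in which both populations co-evolve under the stage's
block matrix is available via ``clamped=False``.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np

from .hopfield import (ConvergenceResult, DynamicsConfig, NetworkState,
                       WeightMatrix, gain, hebbian_weights, run_to_convergence)
from .patterns import MemoryPattern, MemorySet

__all__ = [
    "STAGE_BLOCKS",
    "AugmentedMemorySet",
    "BlockConnectivity",
    "DamageSpec",
    "sparse_mask",
    "build_interface_C",
    "derive_auxiliary_patterns",
    "build_auxiliary_weights",
    "build_feedback_B",
    "train_augmented_network",
    "inject_damage",
    "recover_memory",
    "full_stage_matrix",
    "save_network",
    "load_network",
]

# Which blocks are active in the stage-n connectivity matrix, for both the
# training sequence and the recovery sequence (A standing for A_inj there).
STAGE_BLOCKS = {
    1: ("A",),
    2: ("A", "C"),
    3: ("A", "C", "D"),
    4: ("A", "D"),
    5: ("A", "B", "D"),
}

_NETWORK_FORMAT_VERSION = 1


@dataclasses.dataclass(eq=False)
class AugmentedMemorySet:
    """Original memories paired with their calibrated auxiliary codes."""

    originals: MemorySet
    auxiliaries: MemorySet

    def __post_init__(self) -> None:
        if len(self.originals) != len(self.auxiliaries):
            raise ValueError("originals and auxiliaries must have equal counts")

    def __len__(self) -> int:
        return len(self.originals)

    @property
    def n_orig(self) -> int:
        return self.originals.n_neurons

    @property
    def n_aux(self) -> int:
        return self.auxiliaries.n_neurons


@dataclasses.dataclass(eq=False)
class BlockConnectivity:
    """The four blocks of the augmented connectivity matrix plus stage metadata.

    ``stage`` records how far the training sequence has run; blocks required
    by later stages may be None before then.  ``unstable_auxiliaries`` lists
    labels of auxiliary codes that failed the stage-4 fixed-point check.
    """

    A: WeightMatrix
    B: np.ndarray | None
    C: np.ndarray | None
    D: WeightMatrix | None
    stage: int
    density_B: float = 0.0
    density_C: float = 0.0
    unstable_auxiliaries: tuple = ()

    def __post_init__(self) -> None:
        if self.stage not in STAGE_BLOCKS:
            raise ValueError(f"stage must be in 1..5, got {self.stage}")
        n, na = self.n_orig, self.n_aux
        if self.C is not None and self.C.shape != (na, n):
            raise ValueError(f"C must be ({na}, {n}), got {self.C.shape}")
        if self.B is not None and self.B.shape != (n, na):
            raise ValueError(f"B must be ({n}, {na}), got {self.B.shape}")

    @property
    def n_orig(self) -> int:
        return self.A.n_neurons

    @property
    def n_aux(self) -> int:
        if self.D is not None:
            return self.D.n_neurons
        if self.C is not None:
            return self.C.shape[0]
        if self.B is not None:
            return self.B.shape[1]
        return 0

    def require(self, *blocks: str) -> None:
        for name in blocks:
            if getattr(self, name) is None:
                raise ValueError(f"network is missing block {name}; train it first")


@dataclasses.dataclass(frozen=True)
class DamageSpec:
    """Random lesion of the original network's connections.

    ``level`` is the fraction p of currently nonzero connections eliminated.
    With ``symmetric`` (default) a connection is the unordered pair {i, j}
    and both w_ij and w_ji are severed together, as befits the bidirectional
    couplings of a Hopfield network.
    """

    level: float
    seed: int
    symmetric: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"damage level must be in [0, 1], got {self.level}")


# ---------------------------------------------------------------------------
# Interface construction
# ---------------------------------------------------------------------------

def _mask_from_rng(rng: np.random.Generator, n_rows: int, n_cols: int,
                   density: float) -> np.ndarray:
    total = n_rows * n_cols
    k = int(np.rint(density * total))
    mask = np.zeros(total, dtype=np.int8)
    if k:
        mask[rng.choice(total, size=k, replace=False)] = 1
    return mask.reshape(n_rows, n_cols)


def sparse_mask(n_rows: int, n_cols: int, density: float, seed: int) -> np.ndarray:
    """0/1 matrix with exactly ``round(density · n_rows · n_cols)`` ones."""
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {density}")
    return _mask_from_rng(np.random.default_rng(seed), n_rows, n_cols, density)


def build_interface_C(n_aux: int, n_orig: int, density: float, seed: int) -> np.ndarray:
    """Sparse random read-out interface, original → auxiliary.

    Nonzero entries sit on a seeded-uniform mask of the given density and
    carry independent ±1 weights; sign-balanced random weights give distinct
    original memories near-orthogonal auxiliary codes.
    """
    if not 0.0 < density <= 1.0:
        raise ValueError(f"interface density must be in (0, 1], got {density}")
    rng = np.random.default_rng(seed)
    mask = _mask_from_rng(rng, n_aux, n_orig, density)
    signs = rng.choice(np.array([-1, 1], dtype=np.int8), size=mask.shape)
    return (mask * signs).astype(np.int32)


def derive_auxiliary_patterns(memories: MemorySet, C: np.ndarray) -> AugmentedMemorySet:
    """Calibrate auxiliary codes: m_a^μ = g(C m_o^μ), one feedforward pass.

    This is the stage-2 configuration [[A, 0], [C, 0]] with the original
    network clamped at each stored memory in turn.
    """
    C = np.asarray(C)
    if C.ndim != 2 or C.shape[1] != memories.n_neurons:
        raise ValueError(
            f"C must have {memories.n_neurons} columns, got shape {C.shape}")
    if not np.any(C):
        warnings.warn("interface C is all zero; every auxiliary code is the "
                      "constant +1 pattern", stacklevel=2)
    Cf = C.astype(np.float64)
    aux = tuple(
        MemoryPattern(gain(Cf @ m.values.astype(np.float64)),
                      label=f"{m.label}_aux")
        for m in memories)
    return AugmentedMemorySet(
        originals=memories,
        auxiliaries=MemorySet(aux, source=memories.source))


def build_auxiliary_weights(aux: MemorySet) -> WeightMatrix:
    """Auxiliary Hebbian matrix D storing the calibrated codes."""
    return hebbian_weights(aux)


def build_feedback_B(memories: MemorySet, aux: MemorySet, density: float,
                     seed: int, weights: str = "hebbian") -> np.ndarray:
    """Sparse feedback block B, auxiliary → original.

    Default ``weights="hebbian"``: the cross-correlation term
    Σ_μ m_o^μ (m_a^μ)ᵀ of the augmented outer-product matrix, thinned by a
    seeded mask of the given density — a retrieved auxiliary code then biases
    the original network toward its paired memory.  ``weights="random"``
    places ±1 weights on the same style of mask instead (a control that
    cannot steer retrieval).
    """
    if len(memories) != len(aux):
        raise ValueError("memory and auxiliary counts differ")
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"feedback density must be in [0, 1], got {density}")
    n, na = memories.n_neurons, aux.n_neurons
    rng = np.random.default_rng(seed)
    mask = _mask_from_rng(rng, n, na, density)
    if weights == "hebbian":
        Mo = memories.matrix.astype(np.float64)
        Ma = aux.matrix.astype(np.float64)
        cross = np.rint(Mo.T @ Ma).astype(np.int32)
        return cross * mask
    if weights == "random":
        signs = rng.choice(np.array([-1, 1], dtype=np.int8), size=mask.shape)
        return (mask * signs).astype(np.int32)
    raise ValueError(f"unknown feedback weight convention {weights!r}")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _derived_seeds(seed: int, n: int) -> list[int]:
    states = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in states]


def train_augmented_network(memories: MemorySet, n_aux: int = 200,
                            density_C: float = 0.05, density_B: float = 0.25,
                            seed: int = 0, feedback_weights: str = "hebbian",
                            ) -> tuple[BlockConnectivity, AugmentedMemorySet]:
    """Run the five-stage calibration and return the stage-5 network.

    Stage 1 stores the memories in A; stage 2 wires the random interface C
    and records the auxiliary code each memory evokes; stage 3 stores those
    codes in D; stage 4 verifies each code is a fixed point of the auxiliary
    dynamics alone (codes that are not are reported in
    ``unstable_auxiliaries``, not rejected); stage 5 builds the feedback
    block B.  All randomness derives from ``seed``.
    """
    seed_c, seed_b = _derived_seeds(seed, 2)
    try:
        A = hebbian_weights(memories)                              # stage 1
        C = build_interface_C(n_aux, memories.n_neurons, density_C, seed_c)
        augmented = derive_auxiliary_patterns(memories, C)         # stage 2
        D = build_auxiliary_weights(augmented.auxiliaries)         # stage 3
        unstable = []                                              # stage 4
        for code in augmented.auxiliaries:
            step = gain(D.dense_f64 @ code.values.astype(np.float64))
            if not np.array_equal(step, code.values):
                unstable.append(code.label)
        if unstable:
            warnings.warn(
                f"{len(unstable)} auxiliary code(s) are not fixed points of "
                f"the auxiliary dynamics: {unstable}", stacklevel=2)
        B = build_feedback_B(memories, augmented.auxiliaries, density_B,
                             seed_b, weights=feedback_weights)     # stage 5
    except Exception as exc:
        raise type(exc)(f"network training failed: {exc}") from exc
    net = BlockConnectivity(A=A, B=B, C=C, D=D, stage=5,
                            density_B=density_B, density_C=density_C,
                            unstable_auxiliaries=tuple(unstable))
    return net, augmented


# ---------------------------------------------------------------------------
# Damage
# ---------------------------------------------------------------------------

def inject_damage(A, damage: DamageSpec) -> WeightMatrix:
    """Sever ``round(p · n_connections)`` of the nonzero connections in A.

    Connections are counted among currently nonzero off-diagonal entries; in
    symmetric mode (default) they are unordered pairs {i, j} and both
    directions are zeroed together.  Returns a new matrix (A_inj); the input
    is unmodified.
    """
    wm = A if isinstance(A, WeightMatrix) else WeightMatrix(np.asarray(A))
    w = np.array(wm.weights, copy=True)
    rng = np.random.default_rng(damage.seed)
    if damage.symmetric:
        iu, ju = np.triu_indices(w.shape[0], k=1)
        nz = np.flatnonzero(w[iu, ju])
        n_cut = int(np.rint(damage.level * nz.size))
        if n_cut:
            cut = rng.choice(nz, size=n_cut, replace=False)
            w[iu[cut], ju[cut]] = 0
            w[ju[cut], iu[cut]] = 0
    else:
        off = ~np.eye(w.shape[0], dtype=bool)
        flat = np.flatnonzero((w != 0) & off)
        n_cut = int(np.rint(damage.level * flat.size))
        if n_cut:
            cut = rng.choice(flat, size=n_cut, replace=False)
            w.flat[cut] = 0
    return WeightMatrix(w)


# ---------------------------------------------------------------------------
# Recovery
# ---------------------------------------------------------------------------

def full_stage_matrix(net: BlockConnectivity, stage: int) -> np.ndarray:
    """Assemble the (N+N_a)² stage-n matrix with only its active blocks."""
    if stage not in STAGE_BLOCKS:
        raise ValueError(f"stage must be in 1..5, got {stage}")
    n, na = net.n_orig, net.n_aux
    full = np.zeros((n + na, n + na), dtype=np.float64)
    active = STAGE_BLOCKS[stage]
    full[:n, :n] = net.A.dense_f64
    if "B" in active:
        net.require("B")
        full[:n, n:] = np.asarray(net.B, dtype=np.float64)
    if "C" in active:
        net.require("C")
        full[n:, :n] = np.asarray(net.C, dtype=np.float64)
    if "D" in active:
        net.require("D")
        full[n:, n:] = net.D.dense_f64
    return full


def _snapshot(s_orig, s_aux, result: ConvergenceResult | None = None) -> dict:
    return {
        "original": np.array(s_orig, copy=True),
        "auxiliary": None if s_aux is None else np.array(s_aux, copy=True),
        "converged": None if result is None else result.converged,
        "sweeps": None if result is None else result.sweeps,
    }


def recover_memory(net: BlockConnectivity, cue, config: DynamicsConfig | None = None,
                   clamped: bool = True) -> tuple[NetworkState, dict]:
    """Run the five-stage recovery on a (possibly damaged) trained network.

    ``net.A`` is taken as the lesioned matrix A_inj (pass the healthy network
    for an undamaged control).  Stages, with the idle population clamped:

    1. the original network runs to convergence on the cue under A_inj alone;
    2. the auxiliary state is initialised to g(C · s_orig);
    3. the auxiliary runs to convergence under D with the read-out C·s_orig
       as a standing external field;
    4. the auxiliary re-converges under D alone (interface severed);
    5. the original re-converges under h = A_inj·S + B·s_aux with the
       auxiliary clamped at its settled code.

    Returns the final original-network state and a per-stage trace of
    ``{"original", "auxiliary", "converged", "sweeps"}`` snapshots.  With
    ``clamped=False`` both populations instead co-evolve to convergence under
    each stage's full block matrix.
    """
    net.require("A", "B", "C", "D")
    config = config or DynamicsConfig()
    cue_spins = cue.values if isinstance(cue, MemoryPattern) else \
        (cue.spins if isinstance(cue, NetworkState) else np.asarray(cue))
    if cue_spins.size != net.n_orig:
        raise ValueError(f"cue length {cue_spins.size} != N_orig {net.n_orig}")
    trace: dict[str, dict] = {}

    if not clamped:
        return _recover_unclamped(net, cue_spins, config, trace)

    Cf = np.asarray(net.C, dtype=np.float64)
    Bf = np.asarray(net.B, dtype=np.float64)

    res1 = run_to_convergence(cue_spins, net.A, config)
    s_o = res1.state.spins
    trace["inj1"] = _snapshot(s_o, None, res1)

    readout = Cf @ s_o.astype(np.float64)
    s_a = gain(readout)
    trace["inj2"] = _snapshot(s_o, s_a)

    res3 = run_to_convergence(s_a, net.D, config, bias=readout)
    trace["inj3"] = _snapshot(s_o, res3.state.spins, res3)

    res4 = run_to_convergence(res3.state.spins, net.D, config)
    s_a = res4.state.spins
    trace["inj4"] = _snapshot(s_o, s_a, res4)

    res5 = run_to_convergence(s_o, net.A, config,
                              bias=Bf @ s_a.astype(np.float64))
    trace["inj5"] = _snapshot(res5.state.spins, s_a, res5)
    return res5.state, trace


def _recover_unclamped(net: BlockConnectivity, cue_spins: np.ndarray,
                       config: DynamicsConfig, trace: dict) -> tuple[NetworkState, dict]:
    n, na = net.n_orig, net.n_aux
    state = np.concatenate([cue_spins,
                            np.ones(na, dtype=np.int8)])  # idle aux: g(0) = +1
    for stage in range(1, 6):
        res = run_to_convergence(state, full_stage_matrix(net, stage), config)
        state = res.state.spins
        trace[f"inj{stage}"] = _snapshot(state[:n], state[n:], res)
    return NetworkState(state[:n]), trace


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def save_network(net: BlockConnectivity, augmented: AugmentedMemorySet, path) -> None:
    """Write a trained network and its augmented memories to one .npz container."""
    net.require("A", "B", "C", "D")
    np.savez_compressed(
        path,
        format_version=np.int64(_NETWORK_FORMAT_VERSION),
        A=net.A.weights, B=net.B, C=net.C, D=net.D.weights,
        stage=np.int64(net.stage),
        density_B=float(net.density_B), density_C=float(net.density_C),
        unstable=np.array(net.unstable_auxiliaries, dtype="U"),
        originals=augmented.originals.matrix,
        original_labels=np.array(augmented.originals.labels, dtype="U"),
        original_source=str(augmented.originals.source),
        auxiliaries=augmented.auxiliaries.matrix,
        auxiliary_labels=np.array(augmented.auxiliaries.labels, dtype="U"),
    )


def load_network(path) -> tuple[BlockConnectivity, AugmentedMemorySet]:
    with np.load(path) as data:
        version = int(data["format_version"])
        if version != _NETWORK_FORMAT_VERSION:
            raise ValueError(f"unsupported network container version {version}")
        net = BlockConnectivity(
            A=WeightMatrix(data["A"]), B=data["B"], C=data["C"],
            D=WeightMatrix(data["D"]), stage=int(data["stage"]),
            density_B=float(data["density_B"]),
            density_C=float(data["density_C"]),
            unstable_auxiliaries=tuple(data["unstable"].tolist()))
        source = str(data["original_source"])
        originals = MemorySet(tuple(
            MemoryPattern(v, label=l) for v, l in
            zip(data["originals"], data["original_labels"].tolist())),
            source=source)
        auxiliaries = MemorySet(tuple(
            MemoryPattern(v, label=l) for v, l in
            zip(data["auxiliaries"], data["auxiliary_labels"].tolist())),
            source=source)
    return net, AugmentedMemorySet(originals, auxiliaries)
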