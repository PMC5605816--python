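"""Retrieval trials, failure-rate estimation, and parameter sweeps.

A *trial* lesions the original network at a given damage level, corrupts one
stored memory into a noisy cue, runs the staged recovery (or the damaged
original network alone, as a control), and scores the outcome:

* **failure rate** — the fraction of trials in which the final original
  state is not exactly the cued memory (full retrieval is an exact match);
* **performance** — the mean fraction of correctly recovered pixels,
  (1 + overlap) / 2 averaged over trials.

The sweep harness crosses noise level (0–50%), damage level (0–80%),
feedback density in B (0–50%) and auxiliary size (200 or 400 neurons) for an
orthogonality-optimised memory set and a nonoptimal control sharing 15 of
its 20 members.  The interface C and feedback B are calibrated once per
memory set and auxiliary size — before any damage, as a preventive
prosthesis would be — while lesions and cue noise are redrawn per
realisation.  Everything is reproducible from one master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .coupled import (BlockConnectivity, DamageSpec, build_feedback_B,
                      inject_damage, recover_memory, train_augmented_network)
from .hopfield import DynamicsConfig, is_retrieved, overlap, run_to_convergence
from .patterns import (MemorySet, NoiseSpec, corrupt_cue, make_candidate_pool,
                       make_nonoptimal_set, select_optimal_subset)

__all__ = [
    "TrialCondition",
    "TrialResult",
    "FailureRateEstimate",
    "SweepConfig",
    "SweepResult",
    "run_trial",
    "estimate_failure_rate",
    "compute_performance",
    "run_sweep",
    "write_sweep_outputs",
    "read_sweep_csv",
]

logger = logging.getLogger(__name__)

_CELL_COLUMNS = ["memory_set", "n_aux", "density_B", "noise_level",
                 "damage_level", "auxiliary_enabled"]
_FLOAT_FORMAT = "%.8f"


def derive_seed(master: int, *parts) -> int:
    """Deterministic child seed from a master seed and string/int tokens."""
    tokens = [int(master)] + [zlib.crc32(str(p).encode()) for p in parts]
    return int(np.random.SeedSequence(tokens).generate_state(1)[0] & 0x7FFFFFFF)


@dataclasses.dataclass(frozen=True)
class TrialCondition:
    """One cell of the parameter grid plus the seed of its random stream."""

    noise_level: float
    damage_level: float
    density_B: float
    n_aux: int
    memory_set_kind: str = "optimal"
    auxiliary_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_level <= 0.5:
            raise ValueError(f"noise_level must be in [0, 0.5], got {self.noise_level}")
        if not 0.0 <= self.damage_level <= 1.0:
            raise ValueError(f"damage_level must be in [0, 1], got {self.damage_level}")
        if not 0.0 <= self.density_B <= 1.0:
            raise ValueError(f"density_B must be in [0, 1], got {self.density_B}")
        if self.n_aux < 1:
            raise ValueError("n_aux must be positive")


@dataclasses.dataclass(frozen=True)
class TrialResult:
    retrieved: bool
    overlap: float
    converged: bool
    sweeps: int


@dataclasses.dataclass(frozen=True)
class FailureRateEstimate:
    """Failure rate over K memories × n_repeats lesion/noise realisations."""

    failure_rate: float
    stderr: float
    performance: float
    n_trials: int
    n_failures: int


def _check_condition_matches(condition: TrialCondition, trained: BlockConnectivity) -> None:
    if trained.n_aux != condition.n_aux:
        raise ValueError(f"trained network has n_aux={trained.n_aux}, "
                         f"condition expects {condition.n_aux}")
    if abs(trained.density_B - condition.density_B) > 1e-12:
        raise ValueError(f"trained network has density_B={trained.density_B}, "
                         f"condition expects {condition.density_B}")


def _run_one(cue, memory, net_damaged: BlockConnectivity, auxiliary_enabled: bool,
             config: DynamicsConfig) -> TrialResult:
    if auxiliary_enabled:
        final, trace = recover_memory(net_damaged, cue, config)
        last = trace["inj5"]
        converged, sweeps = bool(last["converged"]), int(last["sweeps"])
    else:
        res = run_to_convergence(cue, net_damaged.A, config)
        final, converged, sweeps = res.state, res.converged, res.sweeps
    return TrialResult(retrieved=is_retrieved(final, memory),
                       overlap=overlap(final, memory),
                       converged=converged, sweeps=sweeps)


def run_trial(condition: TrialCondition, trained: BlockConnectivity,
              memories: MemorySet, memory_index: int,
              config: DynamicsConfig | None = None) -> TrialResult:
    """Lesion, corrupt, recover, and score one memory.

    The lesion and noise realisations are derived deterministically from
    ``condition.seed`` and ``memory_index``, so a repeated call reproduces
    the same trial bit for bit.
    """
    if not 0 <= memory_index < len(memories):
        raise IndexError(f"memory_index {memory_index} out of range 0..{len(memories) - 1}")
    _check_condition_matches(condition, trained)
    config = config or DynamicsConfig()
    states = np.random.SeedSequence([condition.seed, memory_index]).generate_state(2)
    damage_seed, noise_seed = (int(s & 0x7FFFFFFF) for s in states)
    net = dataclasses.replace(
        trained, A=inject_damage(trained.A, DamageSpec(condition.damage_level,
                                                       damage_seed)))
    cue = corrupt_cue(memories[memory_index],
                      NoiseSpec(condition.noise_level, noise_seed))
    return _run_one(cue, memories[memory_index], net,
                    condition.auxiliary_enabled, config)


def estimate_failure_rate(condition: TrialCondition, trained: BlockConnectivity,
                          memories: MemorySet, n_repeats: int = 10,
                          config: DynamicsConfig | None = None,
                          ) -> FailureRateEstimate:
    """Failure rate over every memory × ``n_repeats`` lesion/noise realisations.

    Each realisation draws one lesion of the original network (shared across
    the K cued memories, the way a single injured brain is probed with every
    memory) and fresh cue noise per memory.  All seeds derive from
    ``condition.seed``.  The standard error is binomial.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    _check_condition_matches(condition, trained)
    config = config or DynamicsConfig()
    K = len(memories)
    failures = 0
    overlaps = []
    for r in range(n_repeats):
        states = np.random.SeedSequence([condition.seed, r]).generate_state(1 + K)
        seeds = [int(s & 0x7FFFFFFF) for s in states]
        net = dataclasses.replace(
            trained, A=inject_damage(trained.A, DamageSpec(condition.damage_level,
                                                           seeds[0])))
        for mu in range(K):
            cue = corrupt_cue(memories[mu], NoiseSpec(condition.noise_level,
                                                      seeds[1 + mu]))
            result = _run_one(cue, memories[mu], net,
                              condition.auxiliary_enabled, config)
            failures += not result.retrieved
            overlaps.append(result.overlap)
    n = K * n_repeats
    rate = failures / n
    return FailureRateEstimate(
        failure_rate=rate,
        stderr=float(np.sqrt(rate * (1.0 - rate) / n)),
        performance=float(np.mean([(1.0 + o) / 2.0 for o in overlaps])),
        n_trials=n, n_failures=failures)


def compute_performance(trial_results: Iterable, metric: str = "pixel") -> float:
    """Aggregate trial outcomes into a single [0, 1] performance score.

    ``pixel`` (default): mean fraction of correctly recovered pixels,
    (1 + overlap) / 2 averaged over trials.  ``exact``: fraction of trials
    with full retrieval (the complement of the failure rate).
    """
    results = list(trial_results)
    if not results:
        raise ValueError("compute_performance requires at least one trial")
    if metric == "pixel":
        return float(np.mean([(1.0 + r.overlap) / 2.0 for r in results]))
    if metric == "exact":
        return float(np.mean([bool(r.retrieved) for r in results]))
    raise ValueError(f"unknown performance metric {metric!r}")


# ---------------------------------------------------------------------------
# Sweep configuration
# ---------------------------------------------------------------------------

def _grid(stop: float, step: float) -> tuple:
    return tuple(np.round(np.arange(0.0, stop + step / 2, step), 10).tolist())


@dataclasses.dataclass
class SweepConfig:
    """Parameter grids and replication settings for a failure-rate sweep.

    Defaults reproduce the full study grid: 1000 original neurons, 20 of 30
    candidate memories, interface density 5%, feedback density 0–50% in 5%
    steps, noise 0–50% in 5% steps, damage 0–80% in 10% steps, auxiliary
    sizes 200 and 400.  ``n_seeds`` independent replicate streams each run
    ``repeats`` lesion/noise realisations per cell.
    """

    n_orig: int = 1000
    n_aux_grid: tuple = (200, 400)
    k_memories: int = 20
    n_candidates: int = 30
    n_shared: int = 15
    density_C: float = 0.05
    density_B_grid: tuple = dataclasses.field(default_factory=lambda: _grid(0.50, 0.05))
    noise_grid: tuple = dataclasses.field(default_factory=lambda: _grid(0.50, 0.05))
    damage_grid: tuple = dataclasses.field(default_factory=lambda: _grid(0.80, 0.10))
    memory_sets: tuple = ("optimal",)
    auxiliary_enabled: bool = True
    feedback_weights: str = "hebbian"
    max_abs_overlap: float = 0.2
    relative_flip_fraction: float = 0.25
    repeats: int = 10
    n_seeds: int = 1
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name, grid, hi in (("noise_grid", self.noise_grid, 0.5),
                               ("damage_grid", self.damage_grid, 0.8),
                               ("density_B_grid", self.density_B_grid, 0.5)):
            for v in grid:
                if not 0.0 <= v <= hi + 1e-12:
                    raise ValueError(f"{name} value {v} outside [0, {hi}]")
        if not 0.0 < self.density_C <= 1.0:
            raise ValueError(f"density_C {self.density_C} outside (0, 1]")
        for kind in self.memory_sets:
            if kind not in ("optimal", "nonoptimal"):
                raise ValueError(f"memory_sets entries must be 'optimal' or "
                                 f"'nonoptimal', got {kind!r}")
        if self.repeats < 1 or self.n_seeds < 1:
            raise ValueError("repeats and n_seeds must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown sweep config keys: {sorted(unknown)}")
        for key in ("n_aux_grid", "density_B_grid", "noise_grid", "damage_grid",
                    "memory_sets"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in out.items()}


@dataclasses.dataclass(eq=False)
class SweepResult:
    """Tidy sweep tables: one per (cell, seed) and one aggregated per cell."""

    per_seed: pd.DataFrame
    cells: pd.DataFrame
    config: SweepConfig


def build_memory_sets(config: SweepConfig) -> dict[str, MemorySet]:
    """Candidate pool → optimal subset (+ nonoptimal control) per the config."""
    pool = make_candidate_pool(
        n_candidates=config.n_candidates, n_neurons=config.n_orig,
        n_base=config.k_memories, max_abs_overlap=config.max_abs_overlap,
        relative_flip_fraction=config.relative_flip_fraction,
        seed=derive_seed(config.master_seed, "candidate_pool"))
    optimal = select_optimal_subset(pool, k=config.k_memories)
    sets = {"optimal": optimal}
    if "nonoptimal" in config.memory_sets:
        sets["nonoptimal"] = make_nonoptimal_set(
            optimal, pool, n_shared=config.n_shared,
            seed=derive_seed(config.master_seed, "nonoptimal"))
    return sets


def train_for_sweep(config: SweepConfig, memories: MemorySet, set_kind: str,
                    n_aux: int):
    """Calibrate once per (memory set, auxiliary size); B is rebuilt per density."""
    seed = derive_seed(config.master_seed, "train", set_kind, n_aux)
    return train_augmented_network(
        memories, n_aux=n_aux, density_C=config.density_C,
        density_B=0.0, seed=seed, feedback_weights=config.feedback_weights)


def _with_density_B(config: SweepConfig, net: BlockConnectivity,
                    memories: MemorySet, augmented_aux: MemorySet,
                    set_kind: str, n_aux: int, density_B: float) -> BlockConnectivity:
    seed = derive_seed(config.master_seed, "B", set_kind, n_aux,
                       int(round(density_B * 1000)))
    B = build_feedback_B(memories, augmented_aux, density_B, seed,
                         weights=config.feedback_weights)
    return dataclasses.replace(net, B=B, density_B=density_B)


def run_sweep(config: SweepConfig, progress: bool = False) -> SweepResult:
    """Cross the full parameter grid and estimate failure rate per cell.

    Training (A, C, auxiliary codes, D) happens once per memory set and
    auxiliary size; the feedback block B is re-masked per density value with
    a seed fixed by the master seed.  Lesions and cue noise are redrawn per
    seed stream and repeat.  Identical master seeds give identical tables.
    """
    import warnings as _warnings

    sets = build_memory_sets(config)
    rows = []
    n_cells = (len(config.memory_sets) * len(config.n_aux_grid)
               * len(config.density_B_grid) * len(config.noise_grid)
               * len(config.damage_grid))
    done = 0
    iterator_note = f"{n_cells} cells x {config.n_seeds} seed stream(s)"
    logger.info("sweep: %s", iterator_note)
    for set_kind in config.memory_sets:
        memories = sets[set_kind]
        for n_aux in config.n_aux_grid:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # stage-4 instabilities are data
                base, augmented = train_for_sweep(config, memories, set_kind, n_aux)
            for density_B in config.density_B_grid:
                net = _with_density_B(config, base, memories,
                                      augmented.auxiliaries, set_kind, n_aux,
                                      density_B)
                for damage in config.damage_grid:
                    for noise in config.noise_grid:
                        for s in range(config.n_seeds):
                            cond = TrialCondition(
                                noise_level=noise, damage_level=damage,
                                density_B=density_B, n_aux=n_aux,
                                memory_set_kind=set_kind,
                                auxiliary_enabled=config.auxiliary_enabled,
                                seed=derive_seed(config.master_seed, "cell",
                                                 set_kind, n_aux, density_B,
                                                 damage, noise, s))
                            est = estimate_failure_rate(cond, net, memories,
                                                        n_repeats=config.repeats)
                            rows.append({
                                "memory_set": set_kind, "n_aux": n_aux,
                                "density_B": density_B, "noise_level": noise,
                                "damage_level": damage,
                                "auxiliary_enabled": config.auxiliary_enabled,
                                "seed_index": s,
                                "failure_rate": est.failure_rate,
                                "performance": est.performance,
                                "stderr": est.stderr,
                                "n_trials": est.n_trials,
                                "n_failures": est.n_failures,
                            })
                        done += 1
                        if progress and done % 10 == 0:
                            logger.info("sweep progress: %d/%d cells", done, n_cells)
    per_seed = pd.DataFrame(rows)
    cells = _aggregate_cells(per_seed)
    return SweepResult(per_seed=per_seed, cells=cells, config=config)


def _aggregate_cells(per_seed: pd.DataFrame) -> pd.DataFrame:
    if per_seed.empty:
        return pd.DataFrame(columns=_CELL_COLUMNS + ["failure_rate", "performance",
                                                     "stderr", "n_trials"])
    grouped = per_seed.groupby(_CELL_COLUMNS, as_index=False).agg(
        n_failures=("n_failures", "sum"), n_trials=("n_trials", "sum"),
        performance=("performance", "mean"))
    grouped["failure_rate"] = grouped["n_failures"] / grouped["n_trials"]
    grouped["stderr"] = np.sqrt(grouped["failure_rate"]
                                * (1.0 - grouped["failure_rate"])
                                / grouped["n_trials"])
    cols = _CELL_COLUMNS + ["failure_rate", "performance", "stderr", "n_trials"]
    return grouped[cols].sort_values(_CELL_COLUMNS, kind="mergesort",
                                     ignore_index=True)


# ---------------------------------------------------------------------------
# Outputs
# ---------------------------------------------------------------------------

def write_sweep_outputs(result: SweepResult, out_dir, plots: bool = False) -> list:
    """Write tidy CSVs (+ run manifest, optional heatmaps) into ``out_dir``.

    ``sweep_cells.csv`` holds one row per grid cell with failure rate,
    performance, binomial standard error and trial count;
    ``sweep_per_seed.csv`` keeps the per-seed replicates.  Float formatting
    is pinned so identical sweeps serialise to identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    cells_path = out / "sweep_cells.csv"
    result.cells.to_csv(cells_path, index=False, float_format=_FLOAT_FORMAT)
    written.append(cells_path)

    per_seed_path = out / "sweep_per_seed.csv"
    if not result.per_seed.empty:
        ordered = result.per_seed.sort_values(
            _CELL_COLUMNS + ["seed_index"], kind="mergesort", ignore_index=True)
    else:
        ordered = result.per_seed
    ordered.to_csv(per_seed_path, index=False, float_format=_FLOAT_FORMAT)
    written.append(per_seed_path)

    manifest = {
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": result.config.to_dict(),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)

    if plots and not result.cells.empty:
        written.extend(_write_heatmaps(result.cells, out))
    return written


def _write_heatmaps(cells: pd.DataFrame, out: Path) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    keys = cells[["memory_set", "n_aux", "density_B"]].drop_duplicates()
    for _, key in keys.iterrows():
        sub = cells[(cells["memory_set"] == key["memory_set"])
                    & (cells["n_aux"] == key["n_aux"])
                    & (cells["density_B"] == key["density_B"])]
        pivot = sub.pivot(index="damage_level", columns="noise_level",
                          values="performance")
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto",
                       vmin=0.0, vmax=1.0, cmap="viridis",
                       extent=[pivot.columns.min(), pivot.columns.max(),
                               pivot.index.min(), pivot.index.max()])
        ax.set_xlabel("noise level")
        ax.set_ylabel("damage level")
        ax.set_title(f"{key['memory_set']}, N_aux={key['n_aux']}, "
                     f"density_B={key['density_B']:.2f}")
        fig.colorbar(im, ax=ax, label="performance")
        name = (f"performance_{key['memory_set']}_naux{key['n_aux']}"
                f"_B{int(round(key['density_B'] * 100)):02d}.png")
        path = out / name
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written


def read_sweep_csv(path) -> pd.DataFrame:
    """Read back a cells CSV written by :func:`write_sweep_outputs`."""
    return pd.read_csv(path)
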