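"""Binary memory patterns for Hopfield associative networks.

A memory is a vector of ±1 "pixel" states (default 1000 entries, viewed as a
40×25 bitmap).  This module generates candidate pattern pools, selects the
most mutually orthogonal subset (the *optimal* memory set), builds a
*nonoptimal* control set sharing a fixed number of members with it, corrupts
cues with pixel-flip noise, and reads/writes a plain-text pattern format.

Two pattern sources are supported:

* :func:`render_glyph_patterns` rasterises Unicode glyphs to 40×25 binary
  tiles, mirroring character-based memory sets.
* :func:`generate_synthetic_patterns` draws random ±1 vectors under a
  pairwise-overlap bound; it is the canonical, font-free input for tests and
  simulations.  :func:`make_candidate_pool` additionally mixes in correlated
  "relatives" so that subset optimisation has real work to do, the way highly
  correlated character sets confuse retrieval.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
import zlib
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "DEFAULT_N_NEURONS",
    "DEFAULT_HEIGHT",
    "DEFAULT_WIDTH",
    "MemoryPattern",
    "MemorySet",
    "NoiseSpec",
    "PatternGenerationError",
    "render_glyph_patterns",
    "generate_synthetic_patterns",
    "make_candidate_pool",
    "pairwise_overlap_matrix",
    "select_optimal_subset",
    "make_nonoptimal_set",
    "corrupt_cue",
    "write_patterns",
    "read_patterns",
    "write_pbm",
]

DEFAULT_N_NEURONS = 1000
DEFAULT_HEIGHT = 40
DEFAULT_WIDTH = 25


class PatternGenerationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the overlap constraint."""


def _as_spin_vector(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 1:
        raise ValueError(f"pattern values must be 1-D, got shape {arr.shape}")
    arr = arr.astype(np.int8, copy=True)
    if not np.all(np.abs(arr) == 1):
        raise ValueError("pattern values must all be +1 or -1")
    arr.setflags(write=False)
    return arr


@dataclasses.dataclass(frozen=True, eq=False)
class MemoryPattern:
    """One stored memory: a ±1 state vector with a short label.

    ``degenerate`` marks constant (all-on or all-off) patterns, which carry no
    retrievable structure; they arise e.g. from rasterising whitespace glyphs.
    """

    values: np.ndarray
    label: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_spin_vector(self.values))

    @property
    def n_neurons(self) -> int:
        return int(self.values.size)

    def negated(self) -> "MemoryPattern":
        return MemoryPattern(-self.values, label=f"-{self.label}",
                             degenerate=self.degenerate)

    def same_values(self, other: "MemoryPattern") -> bool:
        return np.array_equal(self.values, other.values)


@dataclasses.dataclass(frozen=True, eq=False)
class MemorySet:
    """Ordered collection of memory patterns of equal length.

    ``source`` tags the provenance of the set: ``candidate_pool`` for raw
    pools, ``optimal`` for orthogonality-optimised subsets, ``nonoptimal`` for
    the control sets sharing part of their membership with an optimal set.
    """

    patterns: tuple
    source: str = "candidate_pool"

    def __post_init__(self) -> None:
        pats = tuple(self.patterns)
        object.__setattr__(self, "patterns", pats)
        if not pats:
            raise ValueError("MemorySet requires at least one pattern")
        lengths = {p.n_neurons for p in pats}
        if len(lengths) != 1:
            raise ValueError(f"patterns have mixed lengths: {sorted(lengths)}")
        labels = [p.label for p in pats]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate pattern labels: {dupes}")

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self) -> Iterator[MemoryPattern]:
        return iter(self.patterns)

    def __getitem__(self, key) -> MemoryPattern:
        if isinstance(key, str):
            for p in self.patterns:
                if p.label == key:
                    return p
            raise KeyError(key)
        return self.patterns[key]

    @property
    def n_neurons(self) -> int:
        return self.patterns[0].n_neurons

    @property
    def labels(self) -> tuple:
        return tuple(p.label for p in self.patterns)

    @property
    def matrix(self) -> np.ndarray:
        """Stacked patterns, shape ``(K, N)``, one memory per row."""
        return np.stack([p.values for p in self.patterns]).astype(np.int8)


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Cue corruption: flip exactly ``round(level * N)`` pixels.

    ``level`` is the fraction of pixels flipped, restricted to [0, 0.5] — at
    0.5 a cue is orthogonal to its memory and carries no net information.
    """

    level: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 0.5:
            raise ValueError(f"noise level must be in [0, 0.5], got {self.level}")


# ---------------------------------------------------------------------------
# Pattern generation
# ---------------------------------------------------------------------------

def render_glyph_patterns(glyphs: Sequence[str], height: int = DEFAULT_HEIGHT,
                          width: int = DEFAULT_WIDTH, threshold: float = 0.5,
                          n_neurons: int | None = None) -> MemorySet:
    """Rasterise glyphs to binary ``height × width`` tiles.

    Each glyph is drawn centred on a white tile with a monospaced default
    font; pixels with luminance fraction below ``threshold`` map to −1
    (ink/off), the rest to +1 (background/on).  Tiles are flattened row-major
    with row 0 at the top of the glyph.  Whitespace glyphs produce constant
    tiles, which are flagged ``degenerate``; any other glyph the font cannot
    draw raises a ``ValueError`` naming it.
    """
    from PIL import Image, ImageDraw, ImageFont

    if n_neurons is not None and height * width != n_neurons:
        raise ValueError(
            f"tile of {height}x{width} has {height * width} pixels, "
            f"expected {n_neurons}")
    try:
        font = ImageFont.load_default(size=int(height * 0.8))
    except TypeError:  # very old Pillow without sized default font
        font = ImageFont.load_default()

    out = []
    for glyph in glyphs:
        ink = font.getmask(glyph).getbbox()
        if ink is None and not glyph.isspace():
            raise ValueError(f"glyph {glyph!r} is not renderable in the default font")
        img = Image.new("L", (width, height), color=255)
        draw = ImageDraw.Draw(img)
        left, top, right, bottom = draw.textbbox((0, 0), glyph, font=font)
        draw.text(((width - (right - left)) / 2 - left,
                   (height - (bottom - top)) / 2 - top), glyph,
                  font=font, fill=0)
        lum = np.asarray(img, dtype=np.float64) / 255.0
        spins = np.where(lum < threshold, -1, 1).astype(np.int8)
        flat = spins.reshape(-1)
        degenerate = bool(np.all(flat == flat[0]))
        if degenerate:
            warnings.warn(f"glyph {glyph!r} rendered to a constant tile; "
                          "pattern flagged degenerate", stacklevel=2)
        out.append(MemoryPattern(flat, label=glyph, degenerate=degenerate))
    return MemorySet(tuple(out), source="candidate_pool")


def generate_synthetic_patterns(n_patterns: int, n_neurons: int = DEFAULT_N_NEURONS,
                                max_abs_overlap: float = 0.2, seed: int = 0,
                                label_prefix: str = "S",
                                max_attempts_per_pattern: int = 2000) -> MemorySet:
    """Draw random ±1 patterns whose pairwise |overlap|/N stays bounded.

    Rejection sampling: candidate vectors are drawn uniformly and accepted
    only if their normalised overlap with every already-accepted pattern is
    at most ``max_abs_overlap`` in magnitude.  Raises
    :class:`PatternGenerationError` (reporting the best overlap achieved) if
    the budget of ``max_attempts_per_pattern`` rejections is exhausted.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    if not 0.0 < max_abs_overlap <= 1.0:
        raise ValueError("max_abs_overlap must be in (0, 1]")
    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    for k in range(n_patterns):
        best = np.inf
        for _ in range(max_attempts_per_pattern):
            cand = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_neurons)
            if accepted:
                ovl = np.abs(np.stack(accepted).astype(np.float64) @ cand) / n_neurons
                worst = float(ovl.max())
            else:
                worst = 0.0
            best = min(best, worst)
            if worst <= max_abs_overlap:
                accepted.append(cand)
                break
        else:
            raise PatternGenerationError(
                f"could not draw pattern {k + 1}/{n_patterns} with pairwise "
                f"|overlap| <= {max_abs_overlap}; best attempt reached {best:.4f}")
    pats = tuple(MemoryPattern(v, label=f"{label_prefix}{i:02d}")
                 for i, v in enumerate(accepted))
    return MemorySet(pats, source="candidate_pool")


def make_candidate_pool(n_candidates: int = 30, n_neurons: int = DEFAULT_N_NEURONS,
                        n_base: int = 20, max_abs_overlap: float = 0.2,
                        relative_flip_fraction: float = 0.25,
                        seed: int = 0) -> MemorySet:
    """Candidate pool emulating a correlated character collection.

    ``n_base`` patterns are drawn nearly orthogonal; the remaining
    ``n_candidates - n_base`` are correlated *relatives*, each obtained by
    flipping ``relative_flip_fraction`` of the pixels of a randomly chosen
    base pattern (flip fraction f gives overlap 1 − 2f with its base, 0.5 at
    the default).  Subset optimisation over such a pool recovers the
    low-correlation base patterns, while the nonoptimal control set picks up
    confusable relatives — the situation character-based memory sets create.
    """
    if n_base > n_candidates:
        raise ValueError("n_base cannot exceed n_candidates")
    rng = np.random.default_rng(seed)
    base = generate_synthetic_patterns(
        n_base, n_neurons, max_abs_overlap,
        seed=int(rng.integers(2 ** 31)), label_prefix="S")
    extras = []
    n_flip = int(np.rint(relative_flip_fraction * n_neurons))
    for i in range(n_candidates - n_base):
        parent = base[int(rng.integers(n_base))]
        vals = parent.values.copy()
        idx = rng.choice(n_neurons, size=n_flip, replace=False)
        vals[idx] *= -1
        extras.append(MemoryPattern(vals, label=f"R{i:02d}"))
    return MemorySet(base.patterns + tuple(extras), source="candidate_pool")


# ---------------------------------------------------------------------------
# Overlap and subset selection
# ---------------------------------------------------------------------------

def pairwise_overlap_matrix(memory_set: MemorySet) -> np.ndarray:
    """Normalised overlaps ``(m_mu · m_nu) / N`` as a symmetric (K, K) matrix."""
    M = memory_set.matrix.astype(np.float64)
    return (M @ M.T) / memory_set.n_neurons


def _subset_score(abs_overlaps: np.ndarray, idx: Sequence[int]) -> float:
    sub = abs_overlaps[np.ix_(idx, idx)]
    return float(np.triu(sub, k=1).sum())


def select_optimal_subset(candidates: MemorySet, k: int = 20) -> MemorySet:
    """Choose the k most mutually orthogonal patterns by greedy elimination.

    Minimises the collective correlation score Σ_{μ<ν} |overlap(μ, ν)| by
    repeatedly discarding the pattern with the largest summed |overlap| to
    the remaining candidates (ties broken toward the lowest index).  The
    procedure is deterministic and, on small pools, agrees with exhaustive
    minimisation over all k-subsets.
    """
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds candidate count {len(candidates)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    absG = np.abs(pairwise_overlap_matrix(candidates))
    np.fill_diagonal(absG, 0.0)
    alive = list(range(len(candidates)))
    while len(alive) > k:
        sums = absG[np.ix_(alive, alive)].sum(axis=1)
        alive.pop(int(np.argmax(sums)))  # first max -> lowest-index tie-break
    return MemorySet(tuple(candidates.patterns[i] for i in alive), source="optimal")


def make_nonoptimal_set(optimal: MemorySet, candidates: MemorySet,
                        n_shared: int = 15, seed: int = 0) -> MemorySet:
    """Control set sharing exactly ``n_shared`` members with the optimal set.

    A seeded-uniform choice of ``n_shared`` optimal members is kept (in their
    original order); the remainder are replaced by seeded-uniform draws from
    the candidates outside the optimal set.
    """
    k = len(optimal)
    if not set(optimal.labels) <= set(candidates.labels):
        raise ValueError("optimal set members must be drawn from the candidates")
    if not 0 <= n_shared <= k:
        raise ValueError(f"n_shared must be in [0, {k}]")
    if n_shared == k:
        return optimal
    non_members = [p for p in candidates if p.label not in set(optimal.labels)]
    need = k - n_shared
    if len(non_members) < need:
        raise ValueError(
            f"need {need} replacement candidates outside the optimal set, "
            f"only {len(non_members)} available")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(k, size=n_shared, replace=False))
    repl = rng.choice(len(non_members), size=need, replace=False)
    pats = tuple(optimal.patterns[int(i)] for i in keep)
    pats += tuple(non_members[int(j)] for j in repl)
    return MemorySet(pats, source="nonoptimal")


# ---------------------------------------------------------------------------
# Cue corruption
# ---------------------------------------------------------------------------

def corrupt_cue(pattern: MemoryPattern, noise: NoiseSpec) -> MemoryPattern:
    """Flip exactly ``round(level * N)`` pixel states, seeded-uniform.

    The flip count is deterministic per trial (not per-pixel Bernoulli), so
    every cue at a given noise level has overlap exactly
    ``1 − 2·round(level·N)/N`` with its memory.  The input is unmodified.
    """
    n = pattern.n_neurons
    n_flip = int(np.rint(noise.level * n))
    vals = np.array(pattern.values, copy=True)
    if n_flip:
        rng = np.random.default_rng(noise.seed)
        idx = rng.choice(n, size=n_flip, replace=False)
        vals[idx] *= -1
    return MemoryPattern(vals, label=pattern.label, degenerate=pattern.degenerate)


# ---------------------------------------------------------------------------
# Plain-text pattern file format
# ---------------------------------------------------------------------------
#
# One record per pattern:
#     >label height width
#     <height lines of width characters in {0,1}>   (0 <-> -1, 1 <-> +1)

def _tile_shape(n: int, height: int | None, width: int | None) -> tuple[int, int]:
    if height is not None and width is not None:
        if height * width != n:
            raise ValueError(f"{height}x{width} tile incompatible with N={n}")
        return height, width
    if n == DEFAULT_HEIGHT * DEFAULT_WIDTH:
        return DEFAULT_HEIGHT, DEFAULT_WIDTH
    return 1, n


def write_patterns(memory_set: MemorySet, path, height: int | None = None,
                   width: int | None = None) -> None:
    """Write a memory set in the text record format (bit-exact round trip)."""
    h, w = _tile_shape(memory_set.n_neurons, height, width)
    lines = []
    for p in memory_set:
        if any(ch.isspace() for ch in p.label):
            raise ValueError(f"label {p.label!r} contains whitespace")
        lines.append(f">{p.label} {h} {w}")
        bits = (p.values.reshape(h, w) > 0).astype(np.uint8)
        lines.extend("".join("1" if b else "0" for b in row) for row in bits)
    Path(path).write_text("\n".join(lines) + "\n")


def read_patterns(path, source: str = "candidate_pool") -> MemorySet:
    """Read a memory set written by :func:`write_patterns`."""
    text = Path(path).read_text().splitlines()
    pats = []
    i = 0
    while i < len(text):
        line = text[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise ValueError(f"expected header line at line {i + 1}, got {line!r}")
        label, h_s, w_s = line[1:].rsplit(maxsplit=2)
        h, w = int(h_s), int(w_s)
        rows = text[i + 1:i + 1 + h]
        if len(rows) != h or any(len(r.strip()) != w for r in rows):
            raise ValueError(f"malformed record for pattern {label!r}")
        bits = np.array([[int(c) for c in r.strip()] for r in rows], dtype=np.int8)
        if not np.isin(bits, (0, 1)).all():
            raise ValueError(f"record {label!r} contains characters outside {{0,1}}")
        vals = (2 * bits - 1).reshape(-1)
        pats.append(MemoryPattern(vals, label=label,
                                  degenerate=bool(np.all(vals == vals[0]))))
        i += 1 + h
    return MemorySet(tuple(pats), source=source)


def write_pbm(pattern: MemoryPattern, path, height: int | None = None,
              width: int | None = None) -> None:
    """Export one pattern as plain PBM (P1); −1 maps to black (1)."""
    h, w = _tile_shape(pattern.n_neurons, height, width)
    bits = (pattern.values.reshape(h, w) < 0).astype(np.uint8)
    body = "\n".join(" ".join(str(b) for b in row) for row in bits)
    Path(path).write_text(f"P1\n{w} {h}\n{body}\n")
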