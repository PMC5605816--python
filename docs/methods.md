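# Methods

## Model

The original network is a classical binary Hopfield network: N neurons
with spins S_i ∈ {−1, +1}, Hebbian storage W = M Mᵀ over the memory matrix
M (one ±1 memory per column), zero diagonal, and hard-threshold dynamics
S_i(t+1) = g(Σ_{j≠i} w_ij S_j) with g(x) = +1 for x ≥ 0, −1 otherwise.  No
1/N normalisation is applied to W: the threshold depends only on the sign
of the input potential, so the dynamics are invariant to positive
rescalings of the weights (a property test locks this in).

The coupled system augments every memory with an auxiliary code,
m̃^μ = [m_o^μ; m_a^μ], and works with the block matrix
W̃ = [[A, B], [C, D]].  Calibration proceeds in five stages, each
activating a subset of blocks:

1. **A** — the original network stores the 20 memories;
2. **A, C** — a sparse random interface C is inserted and the auxiliary
   code evoked by each memory is recorded: m_a^μ = g(C m_o^μ), a single
   feedforward pass with the original network clamped at the memory;
3. **A, C, D** — the codes are stored Hebbian-style in D;
4. **A, D** — each code is checked to be a fixed point of the auxiliary
   dynamics alone; codes that are not are *reported* (they are data about
   auxiliary capacity, not an error);
5. **A, B, D** — the feedback block B is built.

Recovery repeats the staging with A replaced by the lesioned A_inj: the
damaged original converges on the cue (stage 1), the auxiliary is
initialised from the read-out g(C s_orig) (stage 2), converges under D
with the read-out as a standing field (stage 3), then under D alone
(stage 4), and finally the original re-converges under
h = A_inj S + B s_aux (stage 5).

## Interface weight conventions

The interface C carries independent ±1 weights on a seeded uniform mask.
Sign-balanced random read-out weights give distinct memories
near-orthogonal auxiliary codes, which is what the auxiliary network needs
to store them reliably.  A Hebbian variant of C would be circular — the
auxiliary codes are *derived from* C — so no such option exists.

The feedback block B defaults to the masked Hebbian cross-term
Σ_μ m_o^μ (m_a^μ)ᵀ, consistent with the outer-product structure of the
augmented weight matrix; a retrieved code m_a^μ then contributes a field
proportional to m_o^μ at every connected original neuron.  A purely random
±1 convention is available (`weights="random"`) as a control; it cannot
steer retrieval.

## Clamping

The stage arrows define sequential phases but not what the idle population
does.  Default: the population not being updated is clamped (original
during stages 2–4, auxiliary during stage 5).  An unclamped mode
(`clamped=False`) lets both populations co-evolve under each stage's full
block matrix; it is provided for sensitivity analysis and exercised in the
tests only as a smoke check.

## Dynamics, convergence, ties

* Default update mode is synchronous — the form the dynamical map is
  written in — with detection of the period-2 limit cycles that map can
  enter (reported as non-converged).  An asynchronous random-order sweep
  mode exists; with symmetric zero-diagonal weights it descends the energy
  E = −½ SᵀWS at every single-spin update, which the test suite verifies
  across > 10³ seeded trajectories.
* g(0) = +1 exactly; there is no stochastic tie-break.
* Convergence means a sweep reproduced the previous state; the cap is
  `max_sweeps = 50`, generous for 1000-neuron networks, which settle or
  cycle within a handful of sweeps.
* Full retrieval is an exact state match.  Convergence to the negated
  memory (a symmetry-related attractor) counts as failure; with biased
  feedback and low-noise cues it is essentially never reached.

## Lesions and sparse masks

A *connection* is an unordered neuron pair {i, j}; damage at level p
zeroes exactly round(p · n_pairs) of the currently nonzero off-diagonal
pairs, both directions together, seeded-uniform.  (An asymmetric option
severs directed entries instead.)  Counting only nonzero pairs matters in
principle — Hebbian entries can be exactly zero — though for 20 random
memories nearly every pair is nonzero.  Sparse masks place exactly
round(density · rows · cols) entries, so stated densities are exact to one
entry.

## Synthetic memory sets

The study conditions are: 20 memories over 1000 neurons drawn from a
30-candidate pool; an *optimal* subset chosen for mutual orthogonality and
a *nonoptimal* control sharing 15 of its 20 members.  Character bitmaps
are one natural candidate pool (a glyph rasteriser is included), but the
canonical test input is synthetic:

* `generate_synthetic_patterns` draws ±1 vectors by rejection sampling
  under a pairwise bound |m^μ·m^ν|/N ≤ 0.2 (random 1000-bit vectors have
  overlap s.d. ≈ 0.03, so the bound binds rarely and generation is fast).
* `make_candidate_pool` emulates the *heterogeneous* correlation structure
  of a character collection: 20 near-orthogonal base patterns plus 10
  correlated "relatives", each a base pattern with 25 % of pixels flipped
  (overlap 0.5 with its parent).  Without the relatives, every 20-subset
  of the pool would be equally orthogonal and subset optimisation — and
  the optimal/nonoptimal contrast — would be vacuous.

Subset selection minimises the collective correlation score
Σ_{μ<ν} |overlap| by greedy elimination (drop the pattern with the largest
summed |overlap|, lowest index on ties).  Greedy single elimination is
provably optimal; deeper eliminations are near-optimal and always at least
as good as random subsets (both tested), but can differ from exhaustive
search on unstructured pools — acceptable here, since the pools it serves
have strong structure and the exhaustive alternative over C(30, 20) ≈
3·10⁷ subsets buys little.

Cue noise flips exactly round(ε·N) uniformly chosen pixels (not per-pixel
Bernoulli), so the cue-memory overlap at a given noise level is
deterministic: 1 − 2·round(εN)/N.

What the generator does **not** emulate: the spatial coherence of glyph
strokes (synthetic patterns are pixel-wise exchangeable), unequal on/off
pixel fractions, and any semantic relation between a memory and its
auxiliary code.  Passing tests therefore demonstrate the attractor-level
mechanics — storage, lesion tolerance, staged rescue, set-quality effects —
not performance on any particular character set.

## Trials, failure rate, performance

A failure-rate estimate at a grid cell runs `n_repeats` *realisations*,
each drawing one fresh lesion of the original network and probing it with
all K memories under fresh cue noise (one injured brain, every memory).
Failure rate is failures/(K·n_repeats) with a binomial standard error.
Lesions are redrawn per realisation rather than fixed per cell, so rates
average over lesion topologies.  The interface C and feedback B are
calibrated once per memory set and auxiliary size — before any damage, as
a preventive prosthesis would be — and reused across all damage levels;
B is re-masked per feedback-density value with a seed fixed by the master
seed.

*Performance* is not uniquely pinned down by a failure count; this package
defines it as the mean fraction of correctly recovered pixels,
(1 + overlap)/2 averaged over trials, and keeps the metric swappable
(`metric="exact"` gives the fraction of full retrievals instead).

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical master seeds give byte-identical
sweep CSVs (float formatting is pinned to 8 decimals).

## Parameters

| parameter | default | meaning |
|---|---|---|
| N_orig | 1000 | original-network neurons (40×25 bitmap pixels) |
| K | 20 | stored memories, from a 30-candidate pool |
| N_aux | 200 or 400 | auxiliary neurons (20 % / 40 % of original) |
| density_C | 0.05 | fraction of nonzero read-out connections |
| density_B | 0–0.5, step 0.05 | fraction of nonzero feedback connections |
| noise ε | 0–0.5, step 0.05 | fraction of cue pixels flipped |
| damage p | 0–0.8, step 0.1 | fraction of connections severed |
| max_sweeps | 50 | convergence cap per stage |
| repeats | 10 | lesion/noise realisations per cell (sweep default) |

## Problem sizes in the test suite

The trend checks run the full-size networks (N_orig = 1000,
N_aux ∈ {200, 400}) on a coarsened grid — damage {0.6, 0.8}, feedback
density {0, 0.25, 0.5}, noise {0, 0.1, 0.4} — with 5 independent seed
streams of 5 realisations × 20 memories per cell; directional claims use
one-sided paired comparisons across the streams, with strict significance
required only where the effect is expected nonzero (equality is legitimate
when, e.g., the optimal set simply never fails at moderate damage).  The
byte-determinism check uses a reduced network (300 original / 60 auxiliary
neurons), since determinism is a property of the seeding discipline, not
of scale.  Brute-force oracle comparisons run on ≤ 12-neuron networks and
an 8 + 4-neuron coupled toy system.

## Known limitations

* Storage is the plain outer-product rule; no iterative/pseudo-inverse
  learning, no stochastic (finite-temperature) dynamics.
* The auxiliary network at N_aux = 200 holds 20 codes at load 0.1, near
  the classical capacity limit; occasional stage-4 instabilities are
  expected, reported, and are one mechanism behind the smaller auxiliary
  network's weaker rescue.
* No plasticity after injury: A_inj is never retrained, and the auxiliary
  is calibrated strictly pre-damage.
* The glyph rasteriser depends on the bundled default font; it is a
  convenience input, not a reference bitmap set, and pixel-level parity
  with any particular character rendering is out of scope.
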