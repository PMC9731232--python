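# Methods

## Model

Eight identical cells live in a 2-D plane.  Cell *i* has

* an **internal state** `i_i ∈ R^8`, a belief vector over the eight
  target slots; its softmax `σ(i_i)` is a categorical distribution
  ("which slot am I?");
* **active states**: its planar position `x_i` and its secretion
  profile `c_i ∈ R^4` over four signalling channels;
* **sensory states** `s_i = [s_c; s_x; s_λ] + ω`: its own secretion,
  its own position, and the extracellular concentration at its position
  produced by every cell's secretion under isotropic exponential decay,

  `λ_i = τ · Σ_j g_j c_j exp(−k‖x_i − x_j‖)`,

  including the self term (`exp(0)=1`); `g_j` is a per-cell secretion
  gain (1 except under the rescue intervention).

The shared generative model is place-coded: slot `j` carries an expected
expression column `ec*_j`, a position `ex*_j`, and the field `λ*_j`
that column-wise self-consistently follows from evaluating the
diffusion kernel at the slot positions.  The prediction is
`g(i) = [ec*; ex*; λ*]·σ(i)` and the prediction error is
`ε = s − g(i)`.

With Gaussian assumptions and a Laplace approximation the variational
free energy of the collective is

```
F = Σ_i ½ ε_iᵀ Π⁽¹⁾ ε_i + ½ π⁽²⁾ ‖i_i − μ‖²
```

with sensory precision Π⁽¹⁾ = 1 (separately scalable for the
own-secretion, own-position, and field blocks, per cell) and prior
precision π⁽²⁾ = e⁻² about the undifferentiated mean μ = 0.  Action
and perception are the gradient flows in generalized coordinates

```
f_a = D a − ∇_a F,      f_i = D i − ∇_i F,
```

where `D` shifts derivative orders and the free energy is evaluated on
the lowest order (higher-order contributions suppressed; with
zero-initialised higher orders the generalized dynamics reduce exactly
to the first-order flow, which the compiled kernel exploits).  The
action gradient is analytic and runs through the chain rule of the
field: a cell's secretion and movement affect every cell's `s_λ`.  A
finite-difference oracle validates the gradients to ~1e−9.

## Defaults and units

| quantity | default | meaning |
| --- | --- | --- |
| slots | head, pharynx, 4 × intestine, pharynx, tail at y = ±0.5 … ±3.5, x = 0 | planarian-like anterior–posterior axis; the gut is the central, plurality tissue |
| `ec*` | one-hot by type, amplitude 4 | each type predominantly secretes its own channel |
| τ, k | 2, 0.5 | secretion gain; diffusion decay (inverse length) |
| Π⁽¹⁾, π⁽²⁾ | 1, e⁻² | sensory and prior precision |
| horizon | 32 macro-steps × 32 Euler sub-steps (dt = 1/32) | simulation length / resolution |
| init | positions ~ centroid + N(0, 0.5²), beliefs ~ N(0, 0.1²), secretion 0 | "undifferentiated cells near the centre" |
| noise | sd 0.01, correlation length 1 macro-step | smooth sensory fluctuations |

The expression amplitude, τ and k were chosen (jointly, before the test
suite was frozen) as the smallest order of magnitude at which the
unperturbed collective reliably self-organises within the horizon: at
order-unity amplitudes the sensory drive cannot overcome the prior's
pull toward undifferentiated beliefs and the collective remains a
centred cluster.

## Numerical behaviour of the integrator

The fixed-step explicit Euler scheme at dt = 1/32 is part of the model
definition, not merely a solver choice.  The field coupling at the
default amplitudes is marginally stiff at this resolution, and the
resulting bounded fluctuations act as the symmetry-breaking agitation
that lets identical cells commit to distinct slots.  When the same
equations are integrated much more finely, the exact gradient flow
settles instead into a diffuse, contracted collective state — a deeper
free-energy minimum than the fully sorted morphology for centred
initial conditions (measured: F ≈ 5.7 contracted vs ≈ 7.0 sorted at
amplitude 16).  Both states are genuine fixed points; the sorted state
is stable once reached.  Sub-steps are increased beyond 32 only when a
precision-scaled block would violate the hard Euler stability bound
(`π_max·dt < 2`).  Consequences of this choice are stated honestly:
outcomes are reproducible per seed but not invariant to refining dt.

## Scenarios

Perturbations are multiplicative on the per-cell precisions; the
magnitude for "excessive" is e⁴ (none are published).  Position-sense
precision is never scaled — the pathologies are biochemical.

* **high_sensory_precision** — the self-generated chemical signal
  (own-secretion block) gets precision e⁴: a failure of the sensory
  attenuation that normally accompanies action.  Secretion becomes
  slaved to the currently believed expression profile, the collective
  over-produces signal, and development fails (no seed converges).
* **high_prior_identity** — prior mean set to the intestinal-slot
  indicator with π⁽²⁾ × e⁴: every cell rigidly believes it is
  intestinal.  The collective shows an early intestinal phase whose
  summed probability exceeds the final value (a partial, incomplete
  recovery), ends all-intestinal and non-converged.
* **low_sensory_precision** — both chemical blocks × e⁻⁴
  (hyporeactivity): cells barely react to the signals they sense,
  remain incompletely differentiated (typed by the plurality gut
  tissue) and mis-placed.
* **rescue** — cells 0 and 1 carry the high-precision defect; the
  intervention halves their secretion gain (0.5) and quarters their
  field-block precision (0.25).  The dose was calibrated so the
  simulated intervention reproduces the reported cure; with it the
  defect (which never converges untreated) is cured in roughly half of
  the seeds, including the default seed.  The penetrance is partial —
  a single published cured run cannot constrain it.
* **sweeps** — the first `count` cells are perturbed.  The
  prior-identity sweep shows a clean monotone rise of the mean
  intestinal count from the baseline 4 to 8 (Spearman ρ ≈ +0.93).  The
  sensory-precision sweep *decreases* the intestinal count in this
  implementation (ρ ≈ −0.76): over-precise cells scramble their
  neighbours' differentiation rather than recruiting them into an
  intestinal mass.  Both trends are computed and reported.

## Outcome classification

Final cell types are the argmax of the *type-aggregated* softmax
beliefs (the modal type of the differentiation profile); an
incompletely differentiated cell is typed by the tissue holding the
largest probability share.  Cells are matched to slots greedily by
ascending distance (one-to-one, index tie-break).  Convergence requires
every positional error < 1.0 length unit (one slot spacing) with
matching modal types.  The tumor flag (≥ 75 % intestinal-typed and a
radius of gyration below half the target's) is an artifact definition
for test stability.

## What the synthetic conditions do and do not show

The simulator generates all of its own data; nothing is fitted to
measurements.  The packaged morphology stands in for the original
place-code matrices, which were never published, so agreement with the
published simulation figures is qualitative, never numeric.  Real
morphogenesis involves cell division, death, mechanics and 3-D
geometry, all outside this model.  The defect-count table is a
transcription of a published six-trial screening experiment; its
analysis (pooled percentages, per-trial SEM, Welch t-tests on per-trial
percentages with a documented zero-variance rule: equal means → t = 0,
p = 1; unequal → t = ±∞, p = 0) treats the trial as the independent
unit.  The significance test behind the published asterisks is not
named there; Welch's t is this package's documented choice.

## Degenerate inputs and edge cases

Softmax is computed shift-invariantly and rejects non-finite input.
Coincident cells (distance 0) contribute no kernel gradient (the
direction is undefined; the kernel value itself is smooth).  A state
norm exceeding 1e6 aborts the run with the offending cell named and a
smaller-dt suggestion.  Horizon 0 returns only the initial state.  All
randomness (initial jitter and sensory noise) derives from a single
seed per run; equal seeds give bit-identical trajectories.
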