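# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind `petrilearn`, and the rationale for the design
decisions that were genuinely open.

## Model class and assumptions

**Continuous Petri nets with mass-action kinetics.** Places are species,
transitions are reactions. The kinetic order of each input species equals
its stoichiometric coefficient, so a homodimerisation `2 A -> A|A` consumes
`A` at rate `2 k [A]^2`. Rate constants are strictly positive; a species may
not appear on both sides of one reaction.

**Component patterns.** Structural search never edits individual arcs; it
adds and removes *components*, each a one-reaction net from one of two
patterns:

- *binding*: `X + Y -> X|Y` (or `2 X -> X|X`);
- *unbinding*: either *reverse* (`X|Y -> X + Y`) or *convert*
  (`X|Y -> XP + Y`, releasing a converted first constituent and the intact
  second one).

Complex identity is the multiset of constituents: `RKIP|Raf1` and
`Raf1|RKIP` are the same species, canonically labelled with constituents
sorted. The constituent *order* is retained internally because the convert
pattern converts the first constituent. An enzymatic conversion decomposes
into exactly three components (binding, reverse unbinding, converting
unbinding), and the component library over substrate set `S` and enzyme set
`E` contains `3·|S|·|E|` components in lexicographic order.

**Composition semantics.** `add_component` merges shared places (keeping
existing initial concentrations) and skips a transition whose canonical
input/output multisets already occur (duplicate rule). `subtract_component`
removes one transition and prunes places that no longer touch any
transition. Every edit is logged in the model's history.

## Qualitative semantics

Each species gets a qualitative value (magnitude, derivative) with magnitude
in `{zer, pos}` (concentrations cannot be negative) and derivative in
`{neg, zer, pos}`. A transition contributes `sign(Δstoichiometry)` to a
species' derivative when *all* of its input species have magnitude `pos`,
and `zer` otherwise; contributions combine by qualitative addition, where a
`pos`/`neg` conflict permits any derivative sign. This is per-variable
constraint filtering only — no cross-variable consistency or temporal
(transition-ordering) filtering is applied. The consequence is that
`generate_states` may admit globally infeasible states; those inflate `f2`
and are therefore penalised, not excluded.

`generate_states` enumerates magnitudes only over the *relevant* variables
(projection targets plus the variables their constraints mention), then
takes the product of permitted derivative sets. This is exact (verified
against a brute-force assignment checker in the tests) and keeps
pathway-scale projections tractable. The universe `QS_C` over `n` variables
has `6^n` states and is never materialised: the fitness calculus accepts its
size as an integer.

**Abstraction of trajectories.** A numerical trajectory is abstracted by
thresholding: magnitude `zer` below `eps_mag` (default `1e-6 ×` the species'
maximum), derivative sign via `numpy.gradient` thresholded at `eps_der`
(same default), with consecutive duplicate states collapsed. Because the
endpoint derivative estimates are one-sided finite differences, abstraction
of the very first/last samples can produce states the sign semantics does
not admit (for example, at `t = 0` a downstream product can show a positive
numerical derivative while its producing complex still abstracts to zero
magnitude). The soundness property — every abstracted state of a noiseless
simulation is in `generate_states` of the generating model — therefore
holds, and is tested, for the single-reaction binding model; for multi-step
cascades the initial sample can fall outside the generated set. This is
harmless for learning: target states are matched by intersection, and a
target state missing from a candidate's generated set simply lowers `f1`.

## Fitness calculus

```
f1 = |QS_G ∩ QS_T| / |QS_T|
f2 = |QS_G| / |QS_C|            (QS_G ⊆ QS_C by construction)
F  = 1 − 1 / (1 + f1 + 1/(1 + f2))
```

`F` is strictly increasing in `f1`, strictly decreasing in `f2`, and ranges
over `[1/3, 2/3]`: `F(1,0) = 2/3`, `F(0,0) = 1/2`, `F(0,1) = 1/3`. The
quantitative behaviour distance between two trajectory bundles is the mean
over shared species of the Euclidean distance between their sampled
trajectories.

## Structure search: (1+1) evolution strategy

Defaults: 20 independent chains, 100 generations, component addition every
generation, subtraction every second generation (addition applied first).
Survivor selection uses `F` with a `>=` tie-break favouring the offspring,
which lets the search drift across fitness plateaus.

Open choices and their rationale:

- **Partial models.** A candidate may lack some comparison variables.
  Variables absent from the model are padded with `(zer, zer)` — an absent
  species has zero concentration and no dynamics. A candidate containing
  *no* comparison variable is discarded without evaluation.
- **Promotion.** A chain is promoted to rate fitting when `f1 = 1`, or —
  when the true topology is supplied, for benchmarking — when its
  interaction coverage reaches 0.8. A promoted chain stops evolving.
  Because promotion can occur at the seed (generation 0) evaluation, the
  archive holds at most `n_seeds × (generations + 1)` records.
- **Seeding.** Each chain starts from one uniformly drawn library
  component; seeds violating the comparison-variable rule are redrawn.

On the toy problem (3-component library, 68 target states) all 20 chains
reach `f1 = 1`, with a median of about 10 generations.

## Rate fitting: simulated annealing

Defaults: geometric cooling from `t_init = 10` to `t_min = 1e-3` at
`alpha = 0.9` (88 temperatures — the ladder length is
`floor(ln(t_min/t_init)/ln(alpha)) + 1`, i.e. the natural `while t >= t_min`
loop), 50 proposals per temperature (4 400 energy evaluations per run).
Proposals multiply every rate by `exp(0.2 · N(0,1))`, clipped to
`[1e-6, 1e3]`; acceptance is Metropolis (`exp(−ΔE/t)` for uphill moves).
The energy is the behaviour distance of the candidate's simulation against
the target series; a failed integration rejects the proposal. The best
visited rate vector, not the final one, is returned.

On the toy fixture, starting from the true rates × 10, the distance drops by
≥ 99 % in typical runs and each rate is recovered within a factor of two in
roughly 60–75 % of runs depending on the seed set; a fixed-seed batch of 20
runs achieving 75 % joint success is asserted in the acceptance tests. The
hardest rate to pin down is the reverse-unbinding constant, whose effect on
the observed trajectories is partially compensable by the binding constant.

## Numerical choices

- **Integrator.** `scipy.integrate.odeint` (LSODA) with an analytic
  Jacobian. Default tolerances `rtol 1e-8 / atol 1e-10` for plain
  simulation; the annealing energy uses `rtol 1e-4 / atol 1e-7` since ~3 ms
  per evaluation matters at 4 400 evaluations per run and the energy is only
  compared, not reported. Closed-form accuracy at defaults: max error
  ~2e-9 against `1/(1+t)` for equal-concentration binding.
- **Negativity guard.** Trajectory values below `−max(1e-9, 100·atol)`
  raise an integration error; smaller undershoots are clipped to zero. The
  right-hand side and Jacobian clip negative states to zero, which keeps
  LSODA stable near the axes.
- **Determinism.** One global seed; each stage draws from
  `default_rng(sha256(f"{seed}:{stage}")[:4])`, so the qualitative and
  quantitative stages are independently replayable and all derived seeds fit
  in 31 bits. Repeated `learn` runs are byte-identical (asserted).

## Fixtures and what they emulate

- **Toy enzymatic target**: `A + E <-> A|E -> AP + E`, rates
  `(1.0, 0.5, 0.8)`, initials `A=4, E=5`, simulated to `t=10` with 100
  samples. The rates/horizon are package choices giving visible transient
  and near-saturated conversion. Its qualitative target set is
  `generate_states` of its own topology (68 states), which makes full
  coverage achievable exactly.
- **RKIP pathway**: 11 species / 11 reactions of the RKIP-regulated ERK
  pathway. The rate constants and initial concentrations are *documented
  synthetic fixture values* in the conventional literature range for this
  pathway, not measurements; the fixture emulates the pathway's topology
  and qualitative behaviour, not any specific experimental dataset. Its
  qualitative target set is obtained by *abstracting* simulated trajectories
  of the 8 observed species (the `6^8` universe makes enumeration-based
  targets impractical there).
- **Reference tables**: 14 qualitative states over a two-substrate system,
  and 11 candidate reactions with occurrence frequencies of which exactly 2
  (rows 1 and 4) occur in the RKIP topology.

All fixtures are plain text, packaged with the library and verified against
embedded SHA-256 checksums at load time.

## Problem sizes exercised

Unit and acceptance tests run on: the 3-component toy library (4 places),
pattern-built models with ≤ 4 places for oracle equivalence, the 11-species
RKIP fixture for simulation/conservation/membership, 20 × 100-generation ES
runs (< 1 s) and 20 default-configuration annealing runs (~4 min, the bulk
of the suite's runtime).
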