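"""Qualitative semantics: sign-algebra states, abstraction and fitness.

Every model induces a qualitative differential equation over the signs
quantity space: each species gets a (magnitude, derivative) pair with
magnitude in {zer, pos} and derivative in {neg, zer, pos}.  generate_states
enumerates exactly the assignments consistent with the reaction structure.
Numerical trajectories are abstracted into the same state space, which is
what makes qualitative target/candidate comparison possible.
"""

import petrilearn as pl

# irreversible binding admits 8 qualitative states; adding the reverse
# reaction raises that to 34
binding = pl.model_from_components([pl.make_binding_component("A", "E", 1.0)])
reversible = pl.model_from_components([
    pl.make_binding_component("A", "E", 1.0),
    pl.make_unbinding_component("A|E", "reverse", 0.5),
])
qs_bind = pl.generate_states(pl.model_to_qde(binding))
qs_rev = pl.generate_states(pl.model_to_qde(reversible))
print(f"A + E -> A|E          : {len(qs_bind)} qualitative states")
print(f"A + E <-> A|E         : {len(qs_rev)} qualitative states")
print(f"universe over 3 vars  : {pl.universe_size(3)} states")

# abstract a simulated trajectory into qualitative states
toy = pl.toy_enzymatic_target()
abstracted = pl.abstract_states(toy.series)
print(f"\ntoy trajectory abstracts into {len(abstracted)} distinct states, eg:")
for state in sorted(abstracted.states)[:3]:
    print("  " + ", ".join(f"{v}={s}" for v, s in
                           zip(abstracted.variables, state)))

# qualitative fitness: overlap with the target vs spuriousness in the universe
qs_t = toy.qs_t
qs_g = pl.generate_states(pl.model_to_qde(toy.model))
fit = pl.qualitative_fitness(qs_g, qs_t, pl.universe_size(len(qs_t.variables)))
print(f"\nself-fitness of the toy model: f1={fit.f1:.3f} "
      f"f2={fit.f2:.6f} F={fit.F:.6f}")
print(f"extreme values: F(1,0)={pl.fitness_F(1, 0):.4f}  "
      f"F(0,0)={pl.fitness_F(0, 0):.4f}  F(0,1)={pl.fitness_F(0, 1):.4f}")
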