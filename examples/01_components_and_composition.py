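"""Building blocks: component patterns and model composition.

A model is assembled from atomic one-reaction "components" instantiated from
two patterns: binding (two reactants join into a complex) and unbinding (a
complex releases either its constituents or a converted product).  This
script decomposes an enzymatic conversion, builds the full component library
over one substrate and one enzyme, and composes/edits a model.
"""

import petrilearn as pl

# an enzymatic conversion A --E--> AP decomposes into three components
components = pl.decompose_enzymatic("A", "E")
print("enzymatic decomposition of (A, E):")
for c in components:
    print(f"  {c.transition.reaction_string()}   [{c.pattern}]")

# the full library over substrate set {A} and enzyme set {E}
library = pl.build_component_library(["A"], ["E"], default_k=1.0)
print(f"\nlibrary over ({{A}}, {{E}}): {len(library)} components")

# compose a model one component at a time; composition merges shared places
# and skips duplicate reactions
model = pl.PetriNetModel()
for c in library:
    model = pl.add_component(model, c)
model = pl.add_component(model, library[0])  # duplicate: no-op on structure
print(f"\ncomposed model: {len(model.places)} places, "
      f"{len(model.transitions)} transitions")
for t in model.transitions:
    print(f"  {t.reaction_string()} @ {t.rate_constant}")

# subtracting a component prunes places that no longer touch any reaction
smaller = pl.subtract_component(model, 2)
print(f"\nafter subtracting the conversion reaction: "
      f"{len(smaller.places)} places, {len(smaller.transitions)} transitions")
print("composition history:", *model.history, sep="\n  ")
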