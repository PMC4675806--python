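from itertools import product

import pytest

import petrilearn as pl
from petrilearn.qualitative import (MAGNITUDES, SIGNS, QualitativeState,
                                    QualitativeValue, StateSet)


@pytest.fixture(scope="session")
def toy_bundle():
    return pl.toy_enzymatic_target()


@pytest.fixture(scope="session")
def rkip_bundle():
    return pl.rkip_target()


@pytest.fixture(scope="session")
def toy_library():
    return pl.build_component_library(["A"], ["E"], 1.0)


def brute_force_states(model, project_onto=None):
    """Independent oracle: enumerate every raw (magnitude, derivative)
    assignment over all places and keep those satisfying the sign constraints,
    recomputed here directly from the transition list."""
    variables = tuple(sorted(model.place_labels()))
    proj = tuple(project_onto) if project_onto else variables

    def permitted(var, mags):
        contributions = []
        for t in model.transitions:
            ins = t.input_multiset
            outs = t.output_multiset
            delta = outs.get(var, 0) - ins.get(var, 0)
            if delta == 0:
                continue
            fires = all(mags[u] == "pos" for u in ins)
            if not fires:
                contributions.append("zer")
            else:
                contributions.append("pos" if delta > 0 else "neg")
        has_pos = "pos" in contributions
        has_neg = "neg" in contributions
        if has_pos and has_neg:
            return {"neg", "zer", "pos"}
        if has_pos:
            return {"pos"}
        if has_neg:
            return {"neg"}
        return {"zer"}

    states = set()
    for combo in product(
            [QualitativeValue(m, d) for m in MAGNITUDES for d in SIGNS],
            repeat=len(variables)):
        mags = {v: combo[i].magnitude for i, v in enumerate(variables)}
        if all(combo[i].derivative in permitted(v, mags)
               for i, v in enumerate(variables)):
            idx = {v: i for i, v in enumerate(variables)}
            states.add(QualitativeState(combo[idx[v]] for v in proj))
    return StateSet(variables=proj, states=frozenset(states))
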