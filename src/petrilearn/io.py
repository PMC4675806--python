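"""Readers and writers for the plain-text exchange formats.

* Reaction-list model files: one reaction per line
  (``A + E -> A|E @ 0.53``, coefficients as prefixes ``2 A -> A|A @ 0.1``),
  ``#`` comments, and an optional ``[init]`` section of
  ``species = concentration`` lines.
* State-set TSV: header of variable labels, one state per row, cells written
  ``<mag,der>`` with tokens neg/zer/pos.
* Time-series CSV: ``time`` column followed by one column per species.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .petri import (PetriNetModel, Species, Transition, species_key,
                    validate_model)
from .qualitative import QualitativeState, QualitativeValue, StateSet
from .quantitative import TimeSeries

__all__ = ["ParseError", "parse_model_text", "parse_model_file",
           "model_to_text", "write_model_file", "read_state_tsv",
           "parse_state_tsv", "write_state_tsv", "read_timeseries_csv",
           "write_timeseries_csv"]

_TERM_RE = re.compile(r"^(?:(\d+)\s+)?([A-Za-z0-9_*|]+)$")
_CELL_RE = re.compile(r"^<\s*(neg|zer|pos)\s*,\s*(neg|zer|pos)\s*>$")


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _parse_side(text: str, lineno: int) -> tuple[tuple[str, int], ...]:
    terms: dict[str, int] = {}
    for raw in text.split("+"):
        m = _TERM_RE.match(raw.strip())
        if not m:
            raise ParseError(f"line {lineno}: malformed species term {raw.strip()!r}")
        coeff = int(m.group(1)) if m.group(1) else 1
        label = m.group(2)
        terms[label] = terms.get(label, 0) + coeff
    return tuple(terms.items())


def parse_model_text(text: str, name: str = "<string>") -> PetriNetModel:
    model = PetriNetModel()
    places: dict[tuple[str, ...], Species] = {}
    transitions: list[Transition] = []
    in_init = False
    inits: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line == "[init]":
            in_init = True
            continue
        if in_init:
            if "=" not in line:
                raise ParseError(f"line {lineno}: expected 'species = value'")
            label, value = (p.strip() for p in line.split("=", 1))
            try:
                inits[label] = float(value)
            except ValueError:
                raise ParseError(f"line {lineno}: bad concentration {value!r}")
            continue
        if "->" not in line or "@" not in line:
            raise ParseError(f"line {lineno}: expected 'lhs -> rhs @ rate'")
        body, rate_text = line.rsplit("@", 1)
        lhs, rhs = body.split("->", 1)
        if not lhs.strip() or not rhs.strip():
            raise ParseError(f"line {lineno}: empty reaction side")
        try:
            rate = float(rate_text.strip())
        except ValueError:
            raise ParseError(f"line {lineno}: bad rate {rate_text.strip()!r}")
        inputs = _parse_side(lhs, lineno)
        outputs = _parse_side(rhs, lineno)
        t = Transition(id=f"T{len(transitions) + 1}", inputs=inputs,
                       outputs=outputs, rate_constant=rate)
        transitions.append(t)
        for label, _ in inputs + outputs:
            key = species_key(label)
            if key not in places:
                places[key] = Species.make(label)
    model.places = places
    model.transitions = transitions
    for label, value in inits.items():
        if species_key(label) not in places:
            raise ParseError(f"[init] names unknown species {label!r} ({name})")
        model.set_initial(label, value)
    validate_model(model)
    return model


def parse_model_file(path: str | Path) -> PetriNetModel:
    path = Path(path)
    return parse_model_text(path.read_text(), name=str(path))


def model_to_text(model: PetriNetModel) -> str:
    def side(pairs) -> str:
        return " + ".join(
            (f"{c} {l}" if c > 1 else l) for l, c in sorted(pairs.items())
        )

    lines = []
    for t in model.transitions:
        lines.append(
            f"{side(t.input_multiset)} -> {side(t.output_multiset)}"
            f" @ {t.rate_constant!r}"
        )
    inits = {l: v for l, v in sorted(model.initial_concentrations().items())
             if v != 0.0}
    if inits:
        lines.append("[init]")
        for label, value in inits.items():
            lines.append(f"{label} = {value!r}")
    return "\n".join(lines) + "\n"


def write_model_file(model: PetriNetModel, path: str | Path) -> None:
    Path(path).write_text(model_to_text(model))


def read_state_tsv(path: str | Path) -> StateSet:
    """Read a state-set TSV file (header = variable labels, cells ``<mag,der>``)."""
    return parse_state_tsv(Path(path).read_text())


def parse_state_tsv(text: str) -> StateSet:
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        raise ParseError("empty state-set file")
    variables = tuple(lines[0].rstrip("\n").split("\t"))
    states = set()
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(variables):
            raise ParseError(f"line {lineno}: expected {len(variables)} cells")
        vals = []
        for cell in cells:
            m = _CELL_RE.match(cell.strip())
            if not m:
                raise ParseError(f"line {lineno}: malformed cell {cell!r}")
            vals.append(QualitativeValue(m.group(1), m.group(2)))
        states.add(QualitativeState(vals))
    return StateSet(variables=variables, states=frozenset(states))


def write_state_tsv(ss: StateSet, path: str | Path) -> None:
    lines = ["\t".join(ss.variables)]
    for st in sorted(ss, key=lambda s: tuple(str(v) for v in s)):
        lines.append("\t".join(f"<{v.magnitude},{v.derivative}>" for v in st))
    Path(path).write_text("\n".join(lines) + "\n")


def read_timeseries_csv(path: str | Path) -> TimeSeries:
    df = pd.read_csv(path)
    if df.columns[0] != "time":
        raise ParseError("first column must be 'time'")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ParseError("need at least two time points")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
        raise ParseError("time grid is not uniform")
    species = tuple(df.columns[1:])
    return TimeSeries(species=species, t0=float(t[0]), dt=float(dts[0]),
                      values=df[list(species)].to_numpy(dtype=float).T)


def write_timeseries_csv(ts: TimeSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time": ts.times})
    for i, s in enumerate(ts.species):
        df[s] = ts.values[i]
    df.to_csv(path, index=False, float_format="%.12g")
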