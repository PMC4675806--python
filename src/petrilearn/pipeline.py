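"""End-to-end learning pipeline and report writers.

The flow: build a component library from two label sets, seed a population,
evolve structures against the target qualitative states with the (1+1)-ES,
then fit the rate constants of every promoted model against the target time
series with simulated annealing.  All randomness derives deterministically
from one global seed, with an independent stream per stage, so the
qualitative and quantitative stages are independently replayable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .petri import PetriNetModel, build_component_library
from .qualitative import StateSet
from .quantitative import TimeSeries, model_to_odes, simulate
from .fitness import behaviour_distance
from .es import ESConfig, RunArchive, component_frequencies, run_es
from .annealing import SAConfig, SATraceRow, run_sa
from .targets import TargetBundle
from . import io as plio

__all__ = ["RunConfig", "LearnResult", "stage_rng", "run_learn",
           "write_report", "load_config"]


@dataclass
class RunConfig:
    """Everything one learning run needs; serialisable to/from YAML."""

    s_species: tuple[str, ...] = ("A",)
    s_enzymes: tuple[str, ...] = ("E",)
    default_k: float = 1.0
    es: ESConfig = field(default_factory=ESConfig)
    sa: SAConfig = field(default_factory=SAConfig)
    seed: int = 0
    target_model_path: str | None = None
    target_states_path: str | None = None
    target_series_path: str | None = None
    out_dir: str = "learn_out"
    max_promoted_for_sa: int = 3  # fit this many distinct promoted structures

    def __post_init__(self) -> None:
        self.s_species = tuple(self.s_species)
        self.s_enzymes = tuple(self.s_enzymes)
        if isinstance(self.es, dict):
            self.es = ESConfig(**self.es)
        if isinstance(self.sa, dict):
            self.sa = SAConfig(**self.sa)


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**data)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


@dataclass
class LearnResult:
    archive: RunArchive
    fitted_models: dict[int, PetriNetModel]
    traces: dict[int, list[SATraceRow]]
    artifacts: dict[str, str]  # file name -> sha256


def run_learn(config: RunConfig,
              bundle: TargetBundle | None = None) -> LearnResult:
    """Execute the full qualitative-then-quantitative learning flow.

    The target may be given as a pre-built bundle or through the file paths
    in the config.  Artifacts written to ``config.out_dir``: evaluation
    archive (JSON lines), component-frequency TSV, fitness-trajectory CSV,
    fitted models (reaction lists), behaviour-comparison CSV, and a manifest
    with checksums.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    target_model = None
    if bundle is not None:
        qs_t, series, target_model = bundle.qs_t, bundle.series, bundle.model
    else:
        if not config.target_states_path or not config.target_series_path:
            raise ValueError("need a bundle or target state/series paths")
        qs_t = plio.read_state_tsv(config.target_states_path)
        series = plio.read_timeseries_csv(config.target_series_path)
        if config.target_model_path:
            target_model = plio.parse_model_file(config.target_model_path)

    library = build_component_library(config.s_species, config.s_enzymes,
                                      config.default_k)
    es_cfg = config.es
    if not es_cfg.comparison_variables:
        es_cfg.comparison_variables = tuple(qs_t.variables)

    archive = run_es(library, qs_t, es_cfg,
                     rng=stage_rng(config.seed, "es"),
                     target_model=target_model)

    # fit distinct promoted structures (deterministic order by seed index)
    fitted: dict[int, PetriNetModel] = {}
    traces: dict[int, list[SATraceRow]] = {}
    seen_structures: set = set()
    for s in sorted(archive.promoted_models):
        model = archive.promoted_models[s]
        key = frozenset(t.signature for t in model.transitions)
        if key in seen_structures:
            continue
        seen_structures.add(key)
        # seed initial concentrations from the target series where known
        for lbl in model.place_labels():
            if lbl in series.species:
                model.set_initial(lbl, float(series.get(lbl)[0]))
        fitted[s], traces[s] = run_sa(
            model, series, config.sa,
            rng=stage_rng(config.seed, f"sa:{s}"))
        if len(fitted) >= config.max_promoted_for_sa:
            break

    artifacts = _write_artifacts(out_dir, archive, fitted, traces, series,
                                 target_model)
    return LearnResult(archive=archive, fitted_models=fitted, traces=traces,
                       artifacts=artifacts)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_report(archive: RunArchive, traces: dict[int, list[SATraceRow]],
                 out_dir: str | Path,
                 target_model: PetriNetModel | None = None) -> dict[str, str]:
    """Frequency TSV, fitness-trajectory CSV and SA-trace CSV; returns
    name -> checksum."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    freq_path = out_dir / "component_frequencies.tsv"
    lines = ["no\treaction\tfrequency\ttarget"]
    if archive.records:
        for i, (reaction, count, member) in enumerate(
                component_frequencies(archive, target_model), start=1):
            flag = "" if member is None else ("Yes" if member else "No")
            lines.append(f"{i}\t{reaction}\t{count}\t{flag}")
    freq_path.write_text("\n".join(lines) + "\n")
    files[freq_path.name] = _sha256(freq_path)

    fit_path = out_dir / "fitness_trajectory.csv"
    rows = ["seed,generation,f1,f2,F,accepted,promoted"]

    def fmt(x):
        return "" if x is None else f"{x:.10g}"

    for r in archive.records:
        rows.append(f"{r.seed_index},{r.generation},{fmt(r.f1)},{fmt(r.f2)},"
                    f"{fmt(r.F)},{int(r.accepted)},{int(r.promoted)}")
    fit_path.write_text("\n".join(rows) + "\n")
    files[fit_path.name] = _sha256(fit_path)

    for s, trace in sorted(traces.items()):
        p = out_dir / f"sa_trace_seed{s}.csv"
        rows = ["temperature,iteration,energy,accepted"]
        for row in trace:
            rows.append(f"{row.temperature:.10g},{row.iteration},"
                        f"{row.energy:.10g},{int(row.accepted)}")
        p.write_text("\n".join(rows) + "\n")
        files[p.name] = _sha256(p)
    return files


def _write_artifacts(out_dir: Path, archive: RunArchive,
                     fitted: dict[int, PetriNetModel],
                     traces: dict[int, list[SATraceRow]],
                     series: TimeSeries,
                     target_model: PetriNetModel | None) -> dict[str, str]:
    files: dict[str, str] = {}

    arch_path = out_dir / "archive.jsonl"
    with arch_path.open("w") as fh:
        for r in archive.records:
            fh.write(json.dumps(asdict(r), sort_keys=True) + "\n")
    files[arch_path.name] = _sha256(arch_path)

    files.update(write_report(archive, traces, out_dir, target_model))

    for s, model in sorted(fitted.items()):
        p = out_dir / f"fitted_model_seed{s}.model"
        plio.write_model_file(model, p)
        files[p.name] = _sha256(p)

        # behaviour comparison: target vs learned trajectories per species
        t_end = series.t0 + series.dt * (series.n_points - 1)
        learned = simulate(model_to_odes(model),
                           model.initial_concentrations(),
                           t_end=t_end, P=series.n_points)
        shared = [sp for sp in series.species if sp in learned.species]
        comp_path = out_dir / f"behaviour_comparison_seed{s}.csv"
        header = ["time"]
        cols = [series.times]
        for sp in shared:
            header += [f"{sp}_target", f"{sp}_learned"]
            cols += [series.get(sp), learned.get(sp)]
        rows = [",".join(header)]
        for i in range(series.n_points):
            rows.append(",".join(f"{c[i]:.10g}" for c in cols))
        comp_path.write_text("\n".join(rows) + "\n")
        files[comp_path.name] = _sha256(comp_path)

        d = behaviour_distance(series, learned).d
        summary_path = out_dir / f"fit_summary_seed{s}.json"
        summary_path.write_text(json.dumps(
            {"seed": s, "distance": d,
             "rates": [t.rate_constant for t in model.transitions],
             "reactions": [t.reaction_string() for t in model.transitions]},
            sort_keys=True, indent=2) + "\n")
        files[summary_path.name] = _sha256(summary_path)

    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(files, sort_keys=True, indent=2) + "\n")
    return files
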