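"""Run configuration: plain-text schema, validation, and result writers.

A run is described by a YAML (or JSON) document with the top-level keys

.. code-block:: yaml

    model: full            # full | reduced | spatial
    allow_out_of_range: false
    params:                # ParameterSet overrides by symbol
      k3: 0.012
    treatments:            # applied in order to the parameter set
      - kind: depletion
        target: Mad2
        magnitude: 0.05
    solver:                # SolverSettings fields
      mode: deterministic
      t_end: 6000.0
    spatial:               # SpatialConfig fields (spatial model only)
      timestep: 0.1
    outputs:
      directory: results

Every unknown key is an error, not a warning; an empty file yields the
wild-type full model with reference parameters.  Writers emit deterministic
CSV/JSON, and every result directory carries a metadata record with the
seed and the parameter-set hash so any file can be traced to its inputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .assays import Thresholds, Treatment
from .parameters import ConfigurationError, ParameterSet
from .simulate import SolverSettings, TimeCourse

__all__ = ["RunConfig", "load_config", "save_config", "write_results"]

_MODELS = ("full", "reduced", "spatial")


@dataclass
class RunConfig:
    """Validated description of one simulation run."""

    model: str = "full"
    params: ParameterSet = field(default_factory=ParameterSet)
    treatments: list = field(default_factory=list)
    solver: SolverSettings = field(default_factory=SolverSettings)
    spatial: dict = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    output_directory: str = "results"
    allow_out_of_range: bool = False

    def treated_params(self) -> ParameterSet:
        from .assays import apply_treatment
        p = self.params
        for t in self.treatments:
            p = apply_treatment(p, t)
        return p


def _check_keys(mapping: dict, allowed, context: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigurationError(
                f"unknown key {key!r} in {context} "
                f"(allowed: {', '.join(sorted(allowed))})")


def load_config(path: str | Path) -> RunConfig:
    """Read and fully validate a run configuration file."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    _check_keys(doc, {"model", "params", "treatments", "solver", "spatial",
                      "thresholds", "outputs", "allow_out_of_range"},
                str(path))
    model = doc.get("model", "full")
    if model not in _MODELS:
        raise ConfigurationError(
            f"model must be one of {_MODELS}, got {model!r}")
    allow = bool(doc.get("allow_out_of_range", False))
    params = ParameterSet.from_dict(doc.get("params") or {},
                                    allow_out_of_range=allow)

    treatments = []
    for i, t in enumerate(doc.get("treatments") or []):
        _check_keys(t, {"kind", "target", "magnitude", "dose", "c50"},
                    f"treatments[{i}]")
        treatments.append(Treatment(**t))

    sset = doc.get("solver") or {}
    _check_keys(sset, {f.name for f in dataclasses.fields(SolverSettings)},
                "solver")
    solver = SolverSettings(**sset)

    th = doc.get("thresholds") or {}
    _check_keys(th, {f.name for f in dataclasses.fields(Thresholds)},
                "thresholds")
    thresholds = Thresholds(**th)

    spatial = doc.get("spatial") or {}
    from .spatial import SpatialConfig
    _check_keys(spatial,
                {f.name for f in dataclasses.fields(SpatialConfig)},
                "spatial")

    out = doc.get("outputs") or {}
    _check_keys(out, {"directory"}, "outputs")
    return RunConfig(model=model, params=params, treatments=treatments,
                     solver=solver, spatial=dict(spatial),
                     thresholds=thresholds,
                     output_directory=out.get("directory", "results"),
                     allow_out_of_range=allow)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Serialise a RunConfig so that load(save(x)) == x."""
    doc = {
        "model": config.model,
        "allow_out_of_range": config.allow_out_of_range,
        "params": config.params.to_dict(),
        "treatments": [dataclasses.asdict(t) for t in config.treatments],
        "solver": dataclasses.asdict(config.solver),
        "spatial": config.spatial,
        "thresholds": dataclasses.asdict(config.thresholds),
        "outputs": {"directory": config.output_directory},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def write_results(directory: str | Path, *, timecourse: TimeCourse = None,
                  screen: pd.DataFrame = None,
                  bifurcation=None, config: RunConfig = None,
                  seed: int | None = None, extra_meta: dict = None) -> dict:
    """Write run artefacts with a deterministic layout.

    Time courses become tidy CSV (time, species, value) plus an
    attachment-event CSV; screens become CSV and a Table-style Markdown;
    bifurcation results become a branch CSV plus a fold-point JSON.  A
    ``metadata.json`` with the seed and parameter hash is always written.
    Returns the mapping of artefact name to path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}

    meta = {"seed": seed, **(extra_meta or {})}
    if config is not None:
        meta["model"] = config.model
        meta["params_hash"] = config.params.hash()

    if timecourse is not None:
        p = directory / "timecourse.csv"
        timecourse.to_frame().to_csv(p, index=False, float_format="%.10g")
        written["timecourse"] = p
        p = directory / "attachment_events.csv"
        timecourse.events_frame().to_csv(p, index=False,
                                         float_format="%.10g")
        written["attachment_events"] = p
        meta.setdefault("t_last_attach", float(timecourse.t_last_attach))
        meta.setdefault("params_hash",
                        timecourse.meta.get("params_hash"))
        if timecourse.seed is not None:
            meta["seed"] = timecourse.seed

    if screen is not None:
        p = directory / "screen.csv"
        screen.to_csv(p, index=False, float_format="%.6g")
        written["screen"] = p
        p = directory / "screen.md"
        p.write_text(screen[["mutation", "classification"]]
                     .to_markdown(index=False) + "\n")
        written["screen_md"] = p

    if bifurcation is not None:
        rows = []
        for i, kin_u in enumerate(bifurcation.kin_grid):
            for mcct, stable in bifurcation.branches[i]:
                rows.append({"Kin_U": kin_u, "MCCT": mcct,
                             "stable": stable})
        p = directory / "bifurcation_branches.csv"
        pd.DataFrame(rows).to_csv(p, index=False, float_format="%.10g")
        written["bifurcation_branches"] = p
        p = directory / "bifurcation_folds.json"
        p.write_text(json.dumps(
            {"fold_points": bifurcation.fold_points,
             "bistable_range": bifurcation.bistable_range}, indent=2))
        written["bifurcation_folds"] = p

    p = directory / "metadata.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    written["metadata"] = p
    return written
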