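"""Structured-text configs, CSV table writers and run manifests.

Chain specification files are YAML with two top-level layouts:

* an explicit chain — ``states`` (ordered list of ``{name, absorbing}``) plus
  ``transitions`` (mapping from state name to ``{state name: probability}``,
  omitted entries defaulting to 0; an absorbing state's row may be omitted and
  is filled with its unit self-loop);
* an evidence bundle — an ``evidence`` block of the literature statistics and
  an optional ``model`` block (row3_return, row4_split_mode, rounding), from
  which the current-state AMI chain is derived.

If both are present, the explicit ``transitions`` override the derivation.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ami_model import AmiChainConfig, LiteratureEvidence, build_current_state
from .chain_core import AbsorbingChain, AbsorptionResult
from .scenarios import ScenarioResult
from .simulate import CohortRun

__all__ = [
    "ConfigError",
    "ConfigBundle",
    "read_chain_config",
    "write_chain_config",
    "default_config_path",
    "write_results_tables",
    "write_matrix_csv",
    "RunManifest",
]

_EVIDENCE_FIELDS = {f.name for f in dataclasses.fields(LiteratureEvidence)}
_MODEL_FIELDS = {f.name for f in dataclasses.fields(AmiChainConfig)}
_TOP_KEYS = {"states", "transitions", "evidence", "model"}


class ConfigError(ValueError):
    """Config file is unparsable or semantically invalid; message says where."""


@dataclass(frozen=True)
class ConfigBundle:
    """What a config file yielded: a chain, plus evidence/model if derived."""

    chain: AbsorbingChain
    evidence: LiteratureEvidence | None = None
    model: AmiChainConfig | None = None


def default_config_path() -> Path:
    """Path of the packaged default (current-state AMI evidence) config."""
    return Path(str(resources.files("carechain").joinpath("data/default_chain.yaml")))


def read_chain_config(path: str | Path) -> ConfigBundle:
    """Parse and validate a chain or evidence config file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as err:
        raise ConfigError(f"{path}: cannot read config: {err}") from err
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"{path}: YAML parse error: {err}") from err
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(doc).__name__}")

    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s) {sorted(unknown)}; expected {sorted(_TOP_KEYS)}")

    evidence = model = None
    if "evidence" in doc:
        evidence = _parse_block(path, "evidence", doc["evidence"], _EVIDENCE_FIELDS, LiteratureEvidence)
    if "model" in doc:
        model = _parse_block(path, "model", doc["model"], _MODEL_FIELDS, AmiChainConfig)

    if "states" in doc or "transitions" in doc:
        chain = _parse_explicit_chain(path, doc)
    elif evidence is not None:
        try:
            chain = build_current_state(evidence, model or AmiChainConfig())
        except ValueError as err:
            raise ConfigError(f"{path}: evidence-derived chain invalid: {err}") from err
    else:
        raise ConfigError(f"{path}: config needs either 'states'+'transitions' or an 'evidence' block")

    violations = chain.validate()
    if violations:
        raise ConfigError(f"{path}: chain fails validation:\n  - " + "\n  - ".join(violations))
    return ConfigBundle(chain=chain, evidence=evidence, model=model)


def _parse_block(path, name, block, allowed, cls):
    if not isinstance(block, dict):
        raise ConfigError(f"{path}: '{name}' must be a mapping")
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)} in '{name}'; expected {sorted(allowed)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"{path}: invalid '{name}' block: {err}") from err


def _parse_explicit_chain(path: Path, doc: dict) -> AbsorbingChain:
    if "states" not in doc or "transitions" not in doc:
        raise ConfigError(f"{path}: explicit chains need both 'states' and 'transitions'")
    states = doc["states"]
    if not isinstance(states, list) or not states:
        raise ConfigError(f"{path}: 'states' must be a non-empty list")
    names, flags = [], []
    for i, entry in enumerate(states):
        if not isinstance(entry, dict) or "name" not in entry:
            raise ConfigError(f"{path}: states[{i}] must be a mapping with a 'name'")
        extra = set(entry) - {"name", "absorbing"}
        if extra:
            raise ConfigError(f"{path}: states[{i}] has unknown key(s) {sorted(extra)}")
        names.append(str(entry["name"]))
        flags.append(bool(entry.get("absorbing", False)))
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigError(f"{path}: duplicate state name(s) {dupes}")

    transitions = doc["transitions"]
    if not isinstance(transitions, dict):
        raise ConfigError(f"{path}: 'transitions' must be a mapping of state name -> row")
    index = {n: i for i, n in enumerate(names)}
    unknown_rows = set(transitions) - set(names)
    if unknown_rows:
        raise ConfigError(f"{path}: 'transitions' defines unknown state(s) {sorted(unknown_rows)}")

    P = np.zeros((len(names), len(names)))
    for src, row in transitions.items():
        if not isinstance(row, dict):
            raise ConfigError(f"{path}: transitions[{src!r}] must be a mapping of state name -> probability")
        unknown_cols = set(row) - set(names)
        if unknown_cols:
            raise ConfigError(f"{path}: transitions[{src!r}] targets unknown state(s) {sorted(unknown_cols)}")
        for dst, p in row.items():
            P[index[src], index[dst]] = float(p)
    # an omitted absorbing row is its unit self-loop
    for i, absorbing in enumerate(flags):
        if absorbing and names[i] not in transitions:
            P[i, i] = 1.0
    return AbsorbingChain(names, P, flags)


def write_chain_config(chain: AbsorbingChain, path: str | Path) -> Path:
    """Serialize a chain back to the YAML layout ``read_chain_config`` accepts."""
    path = Path(path)
    doc = {
        "states": [
            {"name": n, "absorbing": bool(f)}
            for n, f in zip(chain.state_names, chain.absorbing_flags)
        ],
        "transitions": {
            chain.state_names[i]: {
                chain.state_names[j]: float(chain.transition[i, j])
                for j in range(chain.n_states)
                if chain.transition[i, j] != 0.0
            }
            for i in range(chain.n_states)
        },
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def write_matrix_csv(result: AbsorptionResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the absorption and fundamental matrices as headed CSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    absorption = pd.DataFrame(
        result.absorption, index=list(result.transient_names), columns=list(result.absorbing_names)
    )
    fundamental = pd.DataFrame(
        result.fundamental, index=list(result.transient_names), columns=list(result.transient_names)
    )
    paths = {
        "absorption": out_dir / "absorption_matrix.csv",
        "fundamental": out_dir / "fundamental_matrix.csv",
    }
    absorption.to_csv(paths["absorption"], index_label="state", float_format="%.10g")
    fundamental.to_csv(paths["fundamental"], index_label="state", float_format="%.10g")
    return paths


def write_results_tables(
    results: ScenarioResult | list[ScenarioResult], out_dir: str | Path
) -> list[Path]:
    """Write scenario tables as CSV (values in %, 4 decimals, fixed column order)."""
    if isinstance(results, ScenarioResult):
        results = [results]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for res in results:
        path = out_dir / f"scenario_{res.mode}.csv"
        res.table.round(4).to_csv(path, index=False, float_format="%.4f")
        paths.append(path)
    return paths


def write_cohort_csv(run: CohortRun, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    run.to_frame().to_csv(path, index=False, float_format="%.10g")
    return path


@dataclass
class RunManifest:
    """Provenance record emitted alongside every CLI run's outputs."""

    command: str
    parameters: dict
    seed: int | None
    version: str
    timestamp: str
    outputs: list[str]

    @classmethod
    def create(cls, command: str, parameters: dict, seed: int | None, outputs: list[Path]) -> "RunManifest":
        return cls(
            command=command,
            parameters=parameters,
            seed=seed,
            version=__version__,
            timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
            outputs=[str(p) for p in outputs],
        )

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "run_manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
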