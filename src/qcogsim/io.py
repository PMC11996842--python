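"""Config loading, validation and result serialization.

Scenario configs are YAML (or JSON, a YAML subset) mappings::

    kind: linda_collapse
    seed: 7
    parameters:
      lam: [1.2, 0.7, 0.2]
      gamma: [0.1, 0.3, 0.6]

Validation is fail-closed: unknown scenario kinds and unknown parameter
keys are rejected (see :class:`qcogsim.scenarios.ScenarioConfig`).

Complex matrices (Kraus instruments) serialize to JSON with each entry as
an ``[re, im]`` pair.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .hilbert import LinearOperator
from .qbism import KrausInstrument
from .scenarios import ConfigError, ScenarioConfig

__all__ = [
    "load_scenario_file",
    "config_hash",
    "instrument_to_json",
    "instrument_from_json",
]


def load_scenario_file(path: str | Path) -> ScenarioConfig:
    """Parse and validate a YAML/JSON scenario file.

    Raises :class:`qcogsim.scenarios.ConfigError` on malformed YAML, a
    non-mapping document, unknown top-level keys, or schema violations.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"{path}: malformed YAML{where}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    allowed = {"kind", "parameters", "seed"}
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(
            f"{path}: unknown top-level key(s) {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )
    if "kind" not in doc:
        raise ConfigError(f"{path}: missing required key 'kind'")
    params = doc.get("parameters", {}) or {}
    if not isinstance(params, dict):
        raise ConfigError(f"{path}: 'parameters' must be a mapping")
    return ScenarioConfig(
        kind=str(doc["kind"]),
        parameters=params,
        seed=int(doc.get("seed", 0)),
    )


def config_hash(cfg: ScenarioConfig) -> str:
    """Stable sha256 of the resolved config, for run metadata."""
    payload = json.dumps(
        {"kind": cfg.kind, "parameters": cfg.resolved(), "seed": cfg.seed},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _matrix_to_pairs(m: np.ndarray) -> list[list[list[float]]]:
    return [[[float(z.real), float(z.imag)] for z in row] for row in m]


def _pairs_to_matrix(pairs: Any) -> np.ndarray:
    return np.array(
        [[complex(re, im) for re, im in row] for row in pairs], dtype=complex
    )


def instrument_to_json(instrument: KrausInstrument) -> str:
    doc = {
        "basis": list(instrument.basis),
        "outcome_labels": list(instrument.outcome_labels),
        "subnormalized": instrument.subnormalized,
        "operators": [
            [_matrix_to_pairs(K.matrix) for K in group]
            for group in instrument.operators
        ],
    }
    return json.dumps(doc)


def instrument_from_json(text: str) -> KrausInstrument:
    doc = json.loads(text)
    basis = tuple(doc["basis"])
    ops = tuple(
        tuple(LinearOperator(basis, _pairs_to_matrix(p)) for p in group)
        for group in doc["operators"]
    )
    return KrausInstrument(
        operators=ops,
        outcome_labels=tuple(doc["outcome_labels"]),
        subnormalized=bool(doc["subnormalized"]),
    )
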