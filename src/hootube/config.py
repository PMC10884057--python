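"""YAML/JSON configuration loading for constants, grids and corpus specs.

Each loader accepts a mapping whose keys mirror the dataclass fields;
unknown keys are rejected so typos fail loudly.  Files may be YAML or
JSON (YAML is a superset, so one parser handles both).
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from hootube.chimp_tract import ParamGrid, TractParams
from hootube.synthetic_data import CorpusSpec
from hootube.tube_acoustics import AcousticConstants


def _load_mapping(path) -> dict:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return data


def _build(cls, data: dict, source: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{source}: unknown keys {sorted(unknown)} for {cls.__name__}")
    listy = {"protrusion_lengths", "sac_lengths", "sac_areas", "lip_opening_areas"}
    coerced = {k: tuple(v) if k in listy and isinstance(v, list) else v for k, v in data.items()}
    return cls(**coerced)


def load_acoustic_constants(path) -> AcousticConstants:
    return _build(AcousticConstants, _load_mapping(path), str(path))


def load_param_grid(path) -> ParamGrid:
    return _build(ParamGrid, _load_mapping(path), str(path))


def load_tract_params(path) -> TractParams:
    return _build(TractParams, _load_mapping(path), str(path))


def load_corpus_spec(path) -> CorpusSpec:
    return _build(CorpusSpec, _load_mapping(path), str(path))
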