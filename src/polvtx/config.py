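"""Strict YAML run configuration with the published analysis defaults.

The printed parameter set of the reimplemented analyses is the contract:
bin 200, states 6, umi 8, min-len 10, win 500, step 500, mincov 4,
diff 25, qvalue 0.01, groups 4, min-reads 10, shuffles 3.  Unknown keys
are rejected (with a close-match suggestion) rather than silently
ignored, since silent defaults are the main reproducibility hazard.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields as dc_fields
from typing import Any, Dict, List, Optional

import yaml

from .simulate import SimulationConfig


class SchemaError(ValueError):
    """Configuration violates the schema (missing/unknown key, bad type)."""


SECTION_DEFAULTS: Dict[str, Dict[str, Any]] = {
    "segment": {
        "bin": 200,
        "states": 6,
        "pthresh": 1e-4,
        "max_iter": 200,
        "tol": 1e-4,
        "decode": "posterior",
    },
    "ripseq": {
        "umi_len": 8,
        "min_len": 10,
        "tag": "TATAGGG",
        "tag_mismatch": 1,
        "strand_aware": True,
    },
    "slicing": {
        "groups": 4,
        "min_reads": 10,
        "shuffles": 3,
        "position": 10,
        "filter_mode": "both",
    },
    "dmr": {
        "win": 500,
        "step": 500,
        "mincov": 4,
        "diff": 25.0,
        "qvalue": 0.01,
    },
}

INPUT_KEYS = (
    "genome", "genes", "marks", "peaks", "ip", "mutant_ip", "control",
    "reference", "fastq", "test_report", "ref_report",
)

TOP_KEYS = ("seed", "out_dir", "log_level", "simulate", "inputs") + tuple(
    SECTION_DEFAULTS
)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "polvtx_out"
    log_level: str = "INFO"
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    inputs: Dict[str, Any] = field(default_factory=dict)
    segment: Dict[str, Any] = field(default_factory=lambda: dict(SECTION_DEFAULTS["segment"]))
    ripseq: Dict[str, Any] = field(default_factory=lambda: dict(SECTION_DEFAULTS["ripseq"]))
    slicing: Dict[str, Any] = field(default_factory=lambda: dict(SECTION_DEFAULTS["slicing"]))
    dmr: Dict[str, Any] = field(default_factory=lambda: dict(SECTION_DEFAULTS["dmr"]))


def _reject_unknown(given: dict, allowed, where: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, list(allowed), n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise SchemaError(f"unknown key {key!r} in {where}{suffix}")


def _typed(value, default, key: str, where: str):
    if default is None or value is None:
        return value
    want = type(default)
    if want is float and isinstance(value, int):
        return float(value)
    if want is bool and not isinstance(value, bool):
        raise SchemaError(f"{where}.{key}: expected bool, got {value!r}")
    if not isinstance(value, want):
        raise SchemaError(
            f"{where}.{key}: expected {want.__name__}, got {type(value).__name__}"
        )
    return value


def load_config(path, required: Optional[List[str]] = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``required`` lists dotted keys (e.g. ``inputs.genome``) that must be
    present; a missing one raises a SchemaError naming the key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config root must be a mapping")
    _reject_unknown(raw, TOP_KEYS, "config")
    cfg = RunConfig()
    if "seed" in raw:
        cfg.seed = _typed(raw["seed"], 0, "seed", "config")
    if "out_dir" in raw:
        cfg.out_dir = _typed(raw["out_dir"], "", "out_dir", "config")
    if "log_level" in raw:
        cfg.log_level = _typed(raw["log_level"], "", "log_level", "config")
    sim_fields = {f.name: f for f in dc_fields(SimulationConfig)}
    sim_raw = raw.get("simulate") or {}
    _reject_unknown(sim_raw, sim_fields, "simulate")
    sim_kwargs = dict(sim_raw)
    for key in ("chrom_lengths", "baseline_levels", "reads_per_peak",
                "read_length_mean"):
        if key in sim_kwargs and not isinstance(sim_kwargs[key], dict):
            raise SchemaError(f"simulate.{key}: expected mapping")
    for key in ("sliced_fractions", "gene_length", "peak_width", "polya_range",
                "methylome_chroms"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    cfg.simulate = SimulationConfig(seed=cfg.seed, **{k: v for k, v in
                                                      sim_kwargs.items() if k != "seed"})
    inputs = raw.get("inputs") or {}
    _reject_unknown(inputs, INPUT_KEYS, "inputs")
    cfg.inputs = dict(inputs)
    for section, defaults in SECTION_DEFAULTS.items():
        given = raw.get(section) or {}
        _reject_unknown(given, defaults, section)
        merged = dict(defaults)
        for key, value in given.items():
            merged[key] = _typed(value, defaults[key], key, section)
        setattr(cfg, section, merged)
    for dotted in required or []:
        node: Any = {"inputs": cfg.inputs, **{s: getattr(cfg, s) for s in
                                              SECTION_DEFAULTS}}
        ok = True
        for part in dotted.split("."):
            if isinstance(node, dict) and part in node:
                node = node[part]
            else:
                ok = False
                break
        if not ok or node is None:
            raise SchemaError(f"missing required key {dotted!r}")
    return cfg
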