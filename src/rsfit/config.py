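"""Configuration loading and machine-readable run manifests.

Precedence: explicit function/CLI arguments > config file > built-in
defaults.  The config file is TOML; any subset of keys may be given.
A RunManifest records enough (command, parameters, seeds, input/output
digests) to reproduce a CLI run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import chemdata
from .refine import RefinementConfig
from .restraints import DEFAULT_GM_ALPHA, DEFAULT_GM_LIMIT, DEFAULT_GM_SIGMA

__all__ = ["Settings", "load_settings", "RunManifest", "default_settings_dict"]


def default_settings_dict() -> dict:
    cfg = RefinementConfig()
    return {
        "refine": {
            "map_weight": cfg.map_weight,
            "max_iter": cfg.max_iter,
            "gtol": cfg.gtol,
            "weights": dict(cfg.weights),
        },
        "gm": {
            "alpha": DEFAULT_GM_ALPHA,
            "sigma": DEFAULT_GM_SIGMA,
            "limit": DEFAULT_GM_LIMIT,
        },
        "metal_bonds": {
            f"{m}-{l}": d for (m, l), d in sorted(chemdata.METAL_BOND_TABLE.items())
        },
        "backrub": {
            "angle_range": 10.0,
            "n_steps": 21,
            "w_density": 1.0,
            "w_clash": 1.0,
        },
    }


@dataclass
class Settings:
    data: dict = field(default_factory=default_settings_dict)

    def get(self, *keys, default=None):
        node = self.data
        for k in keys:
            if not isinstance(node, dict) or k not in node:
                return default
            node = node[k]
        return node

    def refinement_config(self, seed: int = 0) -> RefinementConfig:
        r = self.data["refine"]
        return RefinementConfig(
            map_weight=r["map_weight"], max_iter=r["max_iter"],
            gtol=r["gtol"], rng_seed=seed, weights=dict(r["weights"]))

    def metal_table(self) -> dict:
        out = dict(chemdata.METAL_BOND_TABLE)
        for key, dist in self.data.get("metal_bonds", {}).items():
            metal, ligand = key.split("-")
            out[(metal.upper(), ligand.upper())] = float(dist)
        return out


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_settings(path=None) -> Settings:
    data = default_settings_dict()
    if path is not None:
        with open(path, "rb") as fh:
            _deep_update(data, tomllib.load(fh))
    return Settings(data)


def _digest(path) -> str | None:
    p = Path(path)
    if not p.is_file():
        return None
    h = hashlib.sha256()
    with open(p, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)

    def record_input(self, label: str, path) -> None:
        self.inputs[label] = {"path": str(path), "sha256": _digest(path)}

    def record_output(self, label: str, path) -> None:
        self.outputs[label] = {"path": str(path), "sha256": _digest(path)}

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "parameters": self.parameters,
            "seed": self.seed,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "scores": self.scores,
        }

    def write(self, path=None) -> None:
        text = json.dumps(self.to_dict(), indent=2, default=str)
        if path is None:
            print(text, file=sys.stderr)
        else:
            Path(path).write_text(text + "\n")
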