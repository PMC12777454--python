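"""YAML run configuration.

A run config names the input tables, the similarity method, the K grid,
fold counts, seed and the affinity weighting scheme. Anything omitted
falls back to the defaults below, which reproduce the primary analysis
settings.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .affinity import WeightScheme, variant_schemes
from .similarity import CF_COSINE

DEFAULTS = {
    "method": CF_COSINE,
    "k_grid": {"start": 5, "stop": 60, "step": 5},
    "n_outer": 5,
    "n_inner": 5,
    "seed": 42,
    "scheme": "equal",
    "weighted": True,
    "single_visit_policy": "best",
    "fixed_k": 7,
    "output_dir": "run",
}


def load_config(path: str | Path) -> dict:
    cfg = dict(DEFAULTS)
    loaded = yaml.safe_load(Path(path).read_text()) or {}
    cfg.update(loaded)
    return cfg


def k_grid_from_config(cfg: dict) -> tuple[int, ...]:
    kg = cfg["k_grid"]
    if isinstance(kg, dict):
        return tuple(range(kg["start"], kg["stop"] + 1, kg["step"]))
    return tuple(int(k) for k in kg)


def scheme_from_config(cfg: dict) -> WeightScheme:
    name = cfg["scheme"]
    schemes = variant_schemes()
    if name in schemes:
        return schemes[name]
    if isinstance(name, dict):  # fully custom scheme block
        return WeightScheme(
            name.get("name", "custom"),
            name["w_t"], name["w_s"], name["w_l"], name["w_v"],
            penalty_map={int(k): float(v) for k, v in name["penalty_map"].items()},
        )
    raise ValueError(f"unknown affinity scheme {name!r}")
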