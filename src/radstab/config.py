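"""Run configuration: defaults, YAML loading, provenance snapshot."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from radstab.discretize import DEFAULT_NG
from radstab.stability import MCNEMAR_EXACT_MAX, STABILITY_THRESHOLD


@dataclass
class RunConfig:
    ng: int = DEFAULT_NG
    wavelet_family: str = "haar"
    stability_threshold: float = STABILITY_THRESHOLD
    mcnemar_exact_max: int = MCNEMAR_EXACT_MAX
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stability_threshold < 1:
            raise ValueError(f"stability threshold must be in (0,1), got {self.stability_threshold}")
        if self.n_boot < 100:
            raise ValueError(f"bootstrap reps must be >= 100, got {self.n_boot}")
        if self.ng < 2:
            raise ValueError(f"ng must be >= 2, got {self.ng}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        # accept both flat keys and dotted sections (discretization.ng etc.)
        flat = {}
        for k, v in raw.items():
            if isinstance(v, dict):
                for kk, vv in v.items():
                    flat[f"{k}.{kk}"] = vv
            else:
                flat[k] = v
        mapping = {
            "discretization.ng": "ng",
            "wavelet.family": "wavelet_family",
            "stability.threshold": "stability_threshold",
            "stability.mcnemar_exact_max": "mcnemar_exact_max",
            "bootstrap.reps": "n_boot",
            "bootstrap.seed": "seed",
        }
        kwargs = {}
        for key, val in flat.items():
            field = mapping.get(key, key)
            if field in cls.__dataclass_fields__:
                kwargs[field] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)
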