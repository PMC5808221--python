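"""Run configuration shared by the library pipeline and the CLI."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass


@dataclass
class RunConfig:
    """Pipeline parameters.

    Defaults follow the method's standard operating point: 40 SFF prototypes
    for the dissimilarity embedding and a candidate superset built from the
    union of each example streamline's 500 nearest neighbors.
    """

    n_prototypes: int = 40
    n_neighbors: int = 500
    mode: str = "lap"
    seed: int = 0
    subset_factor: int = 25
    mam_rerank: int = 0
    voxel_step_fraction: float = 0.5

    def __post_init__(self):
        if self.mode not in ("lap", "nn"):
            raise ValueError(f"mode must be 'lap' or 'nn', got {self.mode!r}")
        for name in ("n_prototypes", "n_neighbors", "subset_factor"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.voxel_step_fraction <= 0:
            raise ValueError("voxel_step_fraction must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str, **overrides) -> "RunConfig":
        data = json.loads(text)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
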