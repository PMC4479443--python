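"""Run configuration: one JSON document with per-stage namespaces.

Every tunable of the pipeline lives under its stage's namespace so a single
config file (plus the global seed) reproduces a full run; artifacts are
stamped with the config's hash.  Unknown keys are rejected rather than
ignored, so typos fail loudly.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "DEFAULTS"]

DEFAULTS: dict[str, dict] = {
    "color": {"k_L": 3, "k_b": 3, "restarts": 10, "seed": 0},
    "texture": {"window": 16, "amplitude_threshold": 10.0, "max_evanescent_lines": 4},
    "mrf": {"beta": 1.5, "max_sweeps": 20, "min_object": 50, "max_hole": 200, "min_contrast": 10.0},
    "rules": {
        "min_area": 50.0,
        "max_area": 6000.0,
        "circ_max": 1.5,
        "ecc_max": 0.95,
        "containment_min": 0.95,
    },
    "separation": {"depth_min": 3.0, "min_area": 50, "step_deg": 1.0},
    "classify": {"learner": "rf", "folds": 10, "subset": None},
    "diagnosis": {"min_margin": 1e-9, "scheme": "fused"},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with a global seed."""

    sections: dict[str, dict] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))
    seed: int = 0

    def __post_init__(self) -> None:
        merged = copy.deepcopy(DEFAULTS)
        for section, values in self.sections.items():
            if section not in merged:
                raise ValueError(f"unknown config section {section!r}")
            for key, val in values.items():
                if key not in merged[section]:
                    raise ValueError(f"unknown config key {section}.{key}")
                merged[section][key] = val
        self.sections = merged

    def __getitem__(self, section: str) -> dict:
        return self.sections[section]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        seed = doc.pop("seed", 0)
        return cls(sections=doc, seed=seed)

    def to_dict(self) -> dict:
        doc = copy.deepcopy(self.sections)
        doc["seed"] = self.seed
        return doc

    def hash(self) -> str:
        """Stable short hash of the full config, stamped into artifacts."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stamp(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed}
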