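"""Stack configuration: encoder, base learners, metaclassifier, folds, seeds.

Serialisable to/from YAML or JSON so the whole experiment grid can be
changed without code edits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

DEFAULT_BASE_LEARNERS: list[tuple[str, dict]] = [
    ("bayesnet", {}),
    ("nb_multinomial", {}),
    ("svm", {}),
    ("voted_perceptron", {}),
]


@dataclass
class StackConfig:
    """Full recipe for one stacked-ensemble experiment.

    Attributes
    ----------
    encoder, encoder_params
        Encoding scheme name (registry key) and keyword overrides.
    base_learners
        Ordered (name, hyperparams) pairs — the meta-matrix column order.
    meta_learner, meta_params
        Metaclassifier name and hyperparams.
    k
        Number of stacking folds.
    seed
        Fold/learner seed (every source of randomness derives from it).
    threshold
        Decision threshold on the meta score; ties count positive.
    """

    encoder: str = "multifeature"
    encoder_params: dict = field(default_factory=dict)
    base_learners: list[tuple[str, dict]] = field(
        default_factory=lambda: [(n, dict(h)) for n, h in DEFAULT_BASE_LEARNERS]
    )
    meta_learner: str = "logistic"
    meta_params: dict = field(default_factory=dict)
    k: int = 10
    seed: int = 1
    threshold: float = 0.5

    def to_dict(self) -> dict[str, Any]:
        return {
            "encoder": self.encoder,
            "encoder_params": dict(self.encoder_params),
            "base_learners": [[n, dict(h)] for n, h in self.base_learners],
            "meta_learner": self.meta_learner,
            "meta_params": dict(self.meta_params),
            "k": self.k,
            "seed": self.seed,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StackConfig":
        d = dict(d)
        if "base_learners" in d:
            d["base_learners"] = [(n, dict(h)) for n, h in d["base_learners"]]
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "StackConfig":
        """Load from .json or .yaml/.yml."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))
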