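"""Run configuration shared by the indexing, search and evaluation layers.

Defaults encode the engine's operating constants: result caps of 100
studies per page and 5 shown images per study, evaluation cut-off k=10,
text scope restricted to the report body (anamnesis excluded), negation
filtering on.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .features import DescriptorConfig
from .textproc import DEFAULT_NEGATION_CUES, SCOPES

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    # feature extraction / vocabulary
    descriptor: DescriptorConfig = field(default_factory=DescriptorConfig)
    vocab_k: int = 256
    vocab_seed: int = 0
    vocab_max_samples: int = 100_000
    # text processing
    stemmer: str = "porter"
    text_scope: str = "report_only"
    negation: bool = True
    negation_cues: frozenset[str] = DEFAULT_NEGATION_CUES
    # search
    max_studies: int = 100  # result-page cap, studies
    max_images_per_study: int = 5  # shown images per study
    min_shared: int = 1  # "enough" shared visual words
    # evaluation
    eval_k: int = 10

    def __post_init__(self) -> None:
        if self.text_scope not in SCOPES:
            raise ValueError(f"text_scope must be one of {SCOPES}")
        if self.vocab_k < 1 or self.max_studies < 1 or self.max_images_per_study < 1:
            raise ValueError("vocab_k and result caps must be >= 1")
        if self.min_shared < 1 or self.eval_k < 1:
            raise ValueError("min_shared and eval_k must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["negation_cues"] = sorted(self.negation_cues)
        return d


def load_config(path: str | Path | None = None, **overrides: Any) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    The YAML file may contain any RunConfig field; ``descriptor`` is a
    nested mapping of DescriptorConfig fields. Overrides win over the file.
    """
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    if isinstance(data.get("descriptor"), dict):
        data["descriptor"] = DescriptorConfig(**data["descriptor"])
    if "negation_cues_file" in data:
        from .textproc import load_cue_lexicon

        data["negation_cues"] = load_cue_lexicon(data.pop("negation_cues_file"))
    if "negation_cues" in data:
        data["negation_cues"] = frozenset(data["negation_cues"])
    return RunConfig(**data)
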