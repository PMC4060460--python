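"""Pipeline configuration with method-standard defaults, YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .rules import DEFAULT_ALPHA_GRID, MIN_RULES_PER_CONCLUSION


@dataclass
class PipelineConfig:
    """All tunables of the train/predict/evaluate pipeline.

    Defaults are the values used throughout the package's analyses; see
    docs/methods.md for rationale.
    """

    mode: str = "present_all"  # or "all_probesets"
    median_domain: str = "retained"  # or "all"
    m: float = 2.0
    fcm_tol: float = 1e-8
    fcm_max_iter: int = 300
    alpha: float | None = None  # None -> automatic grid selection
    alpha_grid: list = field(default_factory=lambda: list(DEFAULT_ALPHA_GRID))
    ci_method: str = "clopper_pearson"
    min_rules: int = 4
    max_rules_factor: int = 2
    min_rules_for_alpha: int = MIN_RULES_PER_CONCLUSION
    prune: bool = True
    normalize_votes: bool = False
    missing_gene: str = "error"  # or "zero"
    random_control: bool = False
    n_permutations: int = 100
    seed: int = 0

    def classifier_kwargs(self) -> dict:
        return dict(
            alpha=self.alpha,
            alpha_grid=tuple(self.alpha_grid),
            m=self.m,
            fcm_tol=self.fcm_tol,
            fcm_max_iter=self.fcm_max_iter,
            ci_method=self.ci_method,
            prune=self.prune,
            min_rules=self.min_rules,
            max_rules_factor=self.max_rules_factor,
            min_rules_for_alpha=self.min_rules_for_alpha,
            normalize_votes=self.normalize_votes,
            missing_gene=self.missing_gene,
            random_control=self.random_control,
            n_permutations=self.n_permutations,
            random_state=self.seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**obj)
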