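"""Configuration objects for the stratification pipeline.

All stage-level randomness is derived from a single integer seed through
:func:`derive_seeds`, so a pipeline run is reproducible end-to-end from one
number.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    The defaults describe the study conditions used throughout the test
    suite: a reference group of 200, a clinical group of 300 split into five
    planted subtypes (three with decreased and two with increased thickness),
    six acquisition sites, and deviations of 1.5 SD planted on 10% of
    features.
    """

    n_reference: int = 200
    n_clinical: int = 300
    n_features: int = 200
    n_parcels: int = 34
    n_sites: int = 6
    k_true: int = 5
    subtype_proportions: Optional[Sequence[float]] = None
    deviation_amplitude: float = 1.5
    deviation_sparsity: float = 0.1
    age_range: tuple[float, float] = (6.0, 31.0)
    noise_sd: float = 0.1
    symptom_link_strength: float = 0.5
    symptom_cluster_offset: float = 0.3
    symptom_link_mode: str = "shared"  # or "subtype_signed"
    missing_rate: float = 0.03
    missing_mechanism: str = "mcar"  # or "mar"
    quadratic_age: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ConfigurationError("k_true must be >= 1")
        for name in ("n_reference", "n_clinical", "n_features", "n_parcels",
                     "n_sites"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_parcels > self.n_features:
            raise ConfigurationError("n_parcels must be <= n_features")
        props = self.subtype_proportions
        if props is None:
            props = tuple(1.0 / self.k_true for _ in range(self.k_true))
            object.__setattr__(self, "subtype_proportions", props)
        else:
            props = tuple(float(p) for p in props)
            object.__setattr__(self, "subtype_proportions", props)
        if len(props) != self.k_true:
            raise ConfigurationError(
                "subtype_proportions must have length k_true")
        if any(p < 0 for p in props):
            raise ConfigurationError("subtype_proportions must be nonnegative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError(
                "subtype_proportions must sum to 1 within 1e-9")
        if not (0.0 < self.deviation_sparsity <= 1.0):
            raise ConfigurationError("deviation_sparsity must be in (0, 1]")
        if self.deviation_amplitude < 0:
            raise ConfigurationError("deviation_amplitude must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if not (0.0 <= self.symptom_link_strength <= 1.0):
            raise ConfigurationError(
                "symptom_link_strength must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1] or self.age_range[0] <= 0:
            raise ConfigurationError("age_range must be (min, max), min > 0")
        if self.symptom_link_mode not in ("shared", "subtype_signed"):
            raise ConfigurationError("unknown symptom_link_mode")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ConfigurationError("unknown missing_mechanism")


@dataclass(frozen=True)
class KernelConfig:
    """Kernel and optimizer settings for the per-feature exact GP.

    The covariance is a sum of a linear kernel over all encoded covariates, a
    squared-exponential kernel over standardized continuous covariates, and
    white noise. Either structured term can be disabled; with both disabled
    the model degenerates to classical z-scoring against the training
    mean/SD.
    """

    use_linear: bool = True
    use_rbf: bool = True
    n_restarts: int = 5
    max_iter: int = 60
    jitter: float = 1e-6
    max_jitter: float = 1e-2
    seed: int = 0


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and SVM settings shared by separability analyses."""

    n_splits: int = 10
    C: float = 1.0


@dataclass
class PipelineConfig:
    """Top-level configuration for an end-to-end run.

    Exactly one of ``simulate`` or the three input paths must be provided.
    ``k`` fixes the number of clusters; if None, model order is selected on a
    grid of 2..k_max by cross-validated mean pairwise AUROC.
    """

    seed: int = 0
    simulate: Optional[SimulationConfig] = None
    covariates_path: Optional[str] = None
    features_path: Optional[str] = None
    clinical_path: Optional[str] = None
    parcels_path: Optional[str] = None
    k: Optional[int] = 5
    k_min: int = 2
    k_max: int = 10
    kernel: KernelConfig = field(default_factory=KernelConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    n_permutations: int = 99
    atypicality_fraction: float = 0.01
    q_level: float = 0.05
    run_stability: bool = True
    run_model_order: bool = False
    run_associations: bool = True
    run_clinical_classifier: bool = True
    run_demographics: bool = True
    impute: str = "listwise"  # or "median"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate") is not None and not isinstance(
                d["simulate"], SimulationConfig):
            d["simulate"] = SimulationConfig(**d["simulate"])
        if d.get("kernel") is not None and not isinstance(
                d["kernel"], KernelConfig):
            d["kernel"] = KernelConfig(**d["kernel"])
        if d.get("cv") is not None and not isinstance(d["cv"], CVConfig):
            d["cv"] = CVConfig(**d["cv"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent stage seeds (< 2**31) from a global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def demo_config(seed: int = 0) -> PipelineConfig:
    """The demonstration configuration: simulated cohort, fixed k=5."""
    return PipelineConfig(seed=seed, simulate=SimulationConfig(seed=seed))
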