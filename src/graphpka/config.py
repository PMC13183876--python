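"""Model and run configuration objects."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from graphpka.chemgraph import MODES, FeatureToggles
from graphpka.registry import ConfigurationError

__all__ = ["ModelConfig"]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the masked graph-attention pKa regressor.

    ``n_gat_layers`` (L) attention layers run on the full graph; the readout
    pools only atoms within ``mask_size`` (m) bonds of the ionization
    center, so the effective receptive radius is L + m bonds.
    """

    n_gat_layers: int = 3
    mask_size: int = 4
    n_heads: int = 4
    hidden_dim: int = 64
    dropout: float = 0.1
    learning_rate: float = 1e-3
    batch_size: int = 32
    n_epochs: int = 200
    loss: str = "L1"
    mode: str = "full"
    feature_toggles: FeatureToggles = field(default_factory=FeatureToggles)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gat_layers < 1:
            raise ConfigurationError("n_gat_layers must be >= 1")
        if self.mask_size < 0:
            raise ConfigurationError("mask_size must be >= 0")
        if self.loss not in ("L1", "MSE"):
            raise ConfigurationError("loss must be 'L1' or 'MSE'")
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}")
        if self.hidden_dim % self.n_heads != 0:
            raise ConfigurationError("hidden_dim must be divisible by n_heads")

    @property
    def receptive_radius(self) -> int:
        return self.n_gat_layers + self.mask_size

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_toggles"] = asdict(self.feature_toggles)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        toggles = d.pop("feature_toggles", None)
        if isinstance(toggles, dict):
            toggles = (FeatureToggles(**toggles)
                       if all("." not in k for k in toggles)
                       else FeatureToggles.from_mapping(toggles))
        return cls(feature_toggles=toggles or FeatureToggles(), **d)
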