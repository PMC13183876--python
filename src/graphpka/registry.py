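"""Per-element property registry and interval-feature normalization.

Atomic electronegativity (Pauling), absolute hardness (eV) and atomic
diameter (2x the single-bond covalent radius) are the property-based atom
descriptors that carry inductive-effect information into the graph
featurization.  They are read from a versioned CSV shipped with the package
so that features are reproducible and dataset-independent: normalization
bounds are fixed (min, max) over the shipped registry, never refit on a
user's dataset.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "REGISTRY_VERSION",
    "ConfigurationError",
    "UnsupportedElementError",
    "PropertyRegistry",
    "default_registry",
    "normalize_feature",
]

REGISTRY_VERSION = 1

#: interval features whose normalization bounds come from the registry table
_TABLE_FEATURES = ("electronegativity", "hardness", "atomic_diameter")

#: interval features with fixed structural bounds (not element properties)
_STRUCTURAL_BOUNDS = {
    "ring_size": (0.0, 8.0),
    "n_hydrogens": (0.0, 4.0),
}


class ConfigurationError(ValueError):
    """Raised for unknown feature names or malformed configuration."""


class UnsupportedElementError(KeyError):
    """Raised when an element is absent from the property registry.

    Featurization must never silently emit zeros for an unknown element.
    """


@dataclass(frozen=True)
class PropertyRegistry:
    """Immutable table of per-element properties with normalization bounds.

    Parameters
    ----------
    properties
        Mapping ``symbol -> {feature_name: raw value}``.  ``atomic_diameter``
        is stored directly (Angstrom).
    version
        Integer registry version, embedded in model checkpoints so a trained
        model refuses to run against drifted features.
    """

    properties: dict[str, dict[str, float]]
    version: int = REGISTRY_VERSION
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bounds = dict(_STRUCTURAL_BOUNDS)
        for name in _TABLE_FEATURES:
            vals = [p[name] for p in self.properties.values()]
            bounds[name] = (min(vals), max(vals))
        object.__setattr__(self, "bounds", bounds)

    @property
    def elements(self) -> list[str]:
        return list(self.properties)

    def get(self, symbol: str, feature_name: str) -> float:
        try:
            props = self.properties[symbol]
        except KeyError:
            raise UnsupportedElementError(
                f"element {symbol!r} is not in the property registry "
                f"(supported: {', '.join(self.properties)})"
            ) from None
        return props[feature_name]

    def normalize(self, value: float, feature_name: str) -> float:
        """Min-max normalize ``value`` to [0, 1] for a registered feature."""
        try:
            lo, hi = self.bounds[feature_name]
        except KeyError:
            raise ConfigurationError(
                f"no normalization bounds registered for feature "
                f"{feature_name!r} (known: {', '.join(sorted(self.bounds))})"
            ) from None
        x = (value - lo) / (hi - lo)
        return min(1.0, max(0.0, x))

    def normalized(self, symbol: str, feature_name: str) -> float:
        return self.normalize(self.get(symbol, feature_name), feature_name)

    def subset(self, symbols: list[str]) -> "PropertyRegistry":
        """Registry restricted to ``symbols``, with bounds recomputed."""
        missing = [s for s in symbols if s not in self.properties]
        if missing:
            raise UnsupportedElementError(
                f"elements {missing} are not in the property registry"
            )
        return PropertyRegistry(
            {s: self.properties[s] for s in symbols}, version=self.version
        )


def _load_default() -> PropertyRegistry:
    path = resources.files("graphpka.data").joinpath("element_properties.csv")
    props: dict[str, dict[str, float]] = {}
    with path.open() as fh:
        rows = (r for r in fh if not r.startswith("#"))
        for rec in csv.DictReader(rows):
            props[rec["symbol"]] = {
                "electronegativity": float(rec["electronegativity"]),
                "hardness": float(rec["hardness"]),
                "atomic_diameter": 2.0 * float(rec["covalent_radius"]),
            }
    return PropertyRegistry(props)


_DEFAULT: PropertyRegistry | None = None


def default_registry() -> PropertyRegistry:
    """The shipped registry (H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _load_default()
    return _DEFAULT


def normalize_feature(
    value: float, feature_name: str, registry: PropertyRegistry | None = None
) -> float:
    """Normalize a raw scalar to [0, 1] using the registry's fixed bounds."""
    reg = registry if registry is not None else default_registry()
    return reg.normalize(value, feature_name)
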