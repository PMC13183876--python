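"""Fingerprint / descriptor baseline regressors (random forest and
gradient-boosted trees).

These models see only a whole-molecule encoding, so they are trained to
predict a single global macro-pKa per molecule — they have no notion of an
ionization center and are never fed per-site tasks.  They exist as the
comparison surface against which the graph model's site-resolved
predictions are judged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.EState import Fingerprinter as EStateFingerprinter
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from xgboost import XGBRegressor

from graphpka.registry import ConfigurationError

__all__ = [
    "FingerprintSpec",
    "DESCRIPTOR_NAMES",
    "featurize_fingerprint",
    "FingerprintPkaRegressor",
    "train_baseline",
]

FINGERPRINT_KINDS = (
    "2D-descriptors", "MACCS", "Estate", "EstateSum", "2D+MACCS", "Morgan",
)

#: the shipped 2D molecular descriptor set (documented, fixed order)
DESCRIPTOR_NAMES = (
    "MolWt", "MolLogP", "TPSA", "NumHDonors", "NumHAcceptors",
    "NumRotatableBonds", "NumAromaticRings", "NumAliphaticRings",
    "RingCount", "FractionCSP3", "HeavyAtomCount", "NHOHCount",
    "NOCount", "NumHeteroatoms", "MaxPartialCharge", "MinPartialCharge",
    "MaxAbsPartialCharge", "LabuteASA", "BalabanJ", "BertzCT",
)


@dataclass(frozen=True)
class FingerprintSpec:
    """Which whole-molecule encoding to use.

    ``n_bits`` and ``radius`` apply to Morgan fingerprints only
    (e.g. Morgan 1024-2 = radius 2, 1024 bits).
    """

    kind: str = "Morgan"
    n_bits: int = 1024
    radius: int = 2

    def __post_init__(self) -> None:
        if self.kind not in FINGERPRINT_KINDS:
            raise ConfigurationError(
                f"unsupported fingerprint kind {self.kind!r}; "
                f"expected one of {FINGERPRINT_KINDS}"
            )


def _descriptors_2d(mol: Chem.Mol) -> np.ndarray:
    vals = []
    for name in DESCRIPTOR_NAMES:
        v = getattr(Descriptors, name)(mol)
        vals.append(0.0 if v is None or not np.isfinite(v) else float(v))
    return np.asarray(vals)


def featurize_fingerprint(mol: Chem.Mol | str, spec: FingerprintSpec) -> np.ndarray:
    """Deterministic numeric vector for one molecule (canonicalized, so two
    SMILES spellings of the same molecule featurize identically)."""
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable SMILES: {mol!r}")
        mol = parsed
    # canonical atom order, so any SMILES spelling featurizes bit-identically
    # (some 2D descriptors accumulate in atom order)
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    if spec.kind == "2D-descriptors":
        return _descriptors_2d(mol)
    if spec.kind == "MACCS":
        return np.asarray(MACCSkeys.GenMACCSKeys(mol), dtype=np.float64)
    if spec.kind == "Estate":
        counts, _ = EStateFingerprinter.FingerprintMol(mol)
        return np.asarray(counts, dtype=np.float64)
    if spec.kind == "EstateSum":
        _, sums = EStateFingerprinter.FingerprintMol(mol)
        return np.asarray(sums, dtype=np.float64)
    if spec.kind == "2D+MACCS":
        return np.concatenate([
            _descriptors_2d(mol),
            np.asarray(MACCSkeys.GenMACCSKeys(mol), dtype=np.float64),
        ])
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=spec.radius, fpSize=spec.n_bits
    )
    return np.asarray(gen.GetFingerprint(mol), dtype=np.float64)


class FingerprintPkaRegressor(BaseEstimator, RegressorMixin):
    """Macro-pKa regressor on a fixed whole-molecule encoding.

    ``X`` is a sequence of SMILES strings; featurization is part of the
    estimator so it composes with sklearn model selection directly.
    """

    def __init__(
        self,
        algo: str = "random-forest",
        kind: str = "Morgan",
        n_bits: int = 1024,
        radius: int = 2,
        n_estimators: int = 500,
        random_state: int = 0,
    ):
        self.algo = algo
        self.kind = kind
        self.n_bits = n_bits
        self.radius = radius
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _spec(self) -> FingerprintSpec:
        return FingerprintSpec(self.kind, self.n_bits, self.radius)

    def _featurize(self, X: Sequence[str]) -> np.ndarray:
        spec = self._spec()
        return np.stack([featurize_fingerprint(s, spec) for s in X])

    def fit(self, X, y):
        if self.algo == "random-forest":
            self.model_ = RandomForestRegressor(
                n_estimators=self.n_estimators, random_state=self.random_state
            )
        elif self.algo == "gradient-boosted-trees":
            self.model_ = XGBRegressor(
                n_estimators=self.n_estimators, random_state=self.random_state,
                verbosity=0,
            )
        else:
            raise ConfigurationError(
                f"unknown algo {self.algo!r}; expected 'random-forest' or "
                f"'gradient-boosted-trees'"
            )
        self.model_.fit(self._featurize(X), np.asarray(y, dtype=np.float64))
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.model_.predict(self._featurize(X)),
                          dtype=np.float64)


def train_baseline(
    records, algo: str = "random-forest",
    spec: FingerprintSpec | None = None, seed: int = 0,
) -> FingerprintPkaRegressor:
    """Fit a baseline on DatasetRecords (macro label = the record's pKa)."""
    spec = spec or FingerprintSpec()
    est = FingerprintPkaRegressor(
        algo=algo, kind=spec.kind, n_bits=spec.n_bits, radius=spec.radius,
        random_state=seed,
    )
    smiles = [r.smiles for r in records]
    y = [r.pka for r in records]
    return est.fit(smiles, y)
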