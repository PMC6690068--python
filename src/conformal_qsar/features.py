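"""Molecular featurization: 2048-bit Morgan fingerprints plus six scaled
physicochemical descriptors (2054 features per compound).

Feature layout is fixed: columns 0-2047 are the radius-2 Morgan bits, columns
2048-2053 are MolWt, NumHDonors, NumHAcceptors, NumRotatableBonds, MolLogP and
TPSA (in that order), min-max scaled on the designated fitting set.  Structures
are reduced to non-stereospecific canonical SMILES first, so stereoisomers
collapse to one compound.

Two backends cover the modelling stack: the RDKit backend computes everything
from SMILES; the "precomputed" path reads feature matrices written by
:func:`write_feature_matrix` (or produced by the synthetic generator), which
lets the models run without any chemistry input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

N_BITS = 2048
PHYSCHEM_NAMES = (
    "MolWt",
    "NumHDonors",
    "NumHAcceptors",
    "NumRotatableBonds",
    "MolLogP",
    "TPSA",
)
N_FEATURES = N_BITS + len(PHYSCHEM_NAMES)

_MORGAN_RADIUS = 2


class StructureParseError(ValueError):
    """A SMILES string that RDKit cannot parse."""

    def __init__(self, smiles: str):
        super().__init__(f"unparsable SMILES: {smiles!r}")
        self.smiles = smiles


def _mol_from_smiles(smiles: str):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles)
    return mol


def canonicalize_structure(smiles: str) -> str:
    """Non-stereospecific canonical SMILES.

    Stereoisomers map to the same output string; the operation is idempotent
    and representation-invariant.
    """
    from rdkit import Chem

    return Chem.MolToSmiles(_mol_from_smiles(smiles), isomericSmiles=False)


def compute_raw_descriptors(smiles: str) -> tuple[np.ndarray, np.ndarray]:
    """Fingerprint bits and native-unit physicochemical descriptors.

    Returns ``(bits, physchem)`` with ``bits`` a length-2048 0/1 vector and
    ``physchem`` the six descriptor values in :data:`PHYSCHEM_NAMES` order.
    """
    from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

    mol = _mol_from_smiles(smiles)
    gen = _fingerprint_generator()
    bits = np.zeros(N_BITS, dtype=np.uint8)
    on = gen.GetFingerprint(mol).GetOnBits()
    bits[list(on)] = 1
    physchem = np.array(
        [
            Descriptors.MolWt(mol),
            Lipinski.NumHDonors(mol),
            Lipinski.NumHAcceptors(mol),
            Lipinski.NumRotatableBonds(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcTPSA(mol),
        ],
        dtype=float,
    )
    return bits, physchem


_GENERATOR = None


def _fingerprint_generator():
    global _GENERATOR
    if _GENERATOR is None:
        from rdkit.Chem import rdFingerprintGenerator

        _GENERATOR = rdFingerprintGenerator.GetMorganGenerator(
            radius=_MORGAN_RADIUS, fpSize=N_BITS
        )
    return _GENERATOR


def compute_feature_matrix(smiles_list) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`compute_raw_descriptors` over a list of SMILES."""
    bits = np.empty((len(smiles_list), N_BITS), dtype=np.uint8)
    phys = np.empty((len(smiles_list), len(PHYSCHEM_NAMES)), dtype=float)
    for i, smi in enumerate(smiles_list):
        bits[i], phys[i] = compute_raw_descriptors(smi)
    return bits, phys


@dataclass
class PhyschemScaler:
    """Min-max scaling of the six physicochemical descriptors to [0, 1].

    Fitted on a designated set only (by default each model's training
    portion); transformed values of out-of-range compounds are *not* clipped
    and may fall outside [0, 1].  A constant column maps to 0.
    """

    _scaler: MinMaxScaler | None = None

    def fit(self, physchem: np.ndarray) -> "PhyschemScaler":
        self._scaler = MinMaxScaler(clip=False).fit(np.asarray(physchem, dtype=float))
        return self

    def transform(self, physchem: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return self._scaler.transform(np.asarray(physchem, dtype=float))

    def fit_transform(self, physchem: np.ndarray) -> np.ndarray:
        return self.fit(physchem).transform(physchem)

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return self._scaler.inverse_transform(np.asarray(scaled, dtype=float))

    @property
    def data_min_(self) -> np.ndarray:
        self._check_fitted()
        return self._scaler.data_min_

    @property
    def data_max_(self) -> np.ndarray:
        self._check_fitted()
        return self._scaler.data_max_

    def _check_fitted(self):
        if self._scaler is None:
            raise RuntimeError("PhyschemScaler used before fit()")

    # sidecar JSON round-trip
    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "descriptors": list(PHYSCHEM_NAMES),
            "min": self.data_min_.tolist(),
            "max": self.data_max_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhyschemScaler":
        obj = cls()
        obj._scaler = MinMaxScaler(clip=False)
        obj._scaler.fit(np.vstack([d["min"], d["max"]]))
        return obj


def assemble_features(bits: np.ndarray, physchem_scaled: np.ndarray) -> np.ndarray:
    """Stack bits then scaled descriptors into the 2054-column matrix."""
    bits = np.atleast_2d(bits)
    physchem_scaled = np.atleast_2d(physchem_scaled)
    if bits.shape[1] != N_BITS or physchem_scaled.shape[1] != len(PHYSCHEM_NAMES):
        raise ValueError("feature blocks have wrong widths")
    return np.hstack([bits.astype(float), physchem_scaled.astype(float)])


def write_feature_matrix(
    path, compound_ids, bits: np.ndarray, physchem: np.ndarray, scaler: PhyschemScaler | None = None
) -> None:
    """Dense CSV of raw features plus an optional sidecar JSON of scaler params."""
    cols = [f"bit_{i}" for i in range(N_BITS)] + list(PHYSCHEM_NAMES)
    df = pd.DataFrame(
        np.hstack([np.atleast_2d(bits), np.atleast_2d(physchem)]),
        columns=cols,
    )
    df.insert(0, "compound_id", list(compound_ids))
    df.to_csv(path, index=False)
    if scaler is not None:
        Path(path).with_suffix(".scaler.json").write_text(json.dumps(scaler.to_dict()))


def read_feature_matrix(path) -> tuple[list, np.ndarray, np.ndarray, PhyschemScaler | None]:
    """Inverse of :func:`write_feature_matrix`."""
    df = pd.read_csv(path)
    ids = df["compound_id"].tolist()
    bits = df[[f"bit_{i}" for i in range(N_BITS)]].to_numpy(dtype=np.uint8)
    phys = df[list(PHYSCHEM_NAMES)].to_numpy(dtype=float)
    sidecar = Path(path).with_suffix(".scaler.json")
    scaler = PhyschemScaler.from_dict(json.loads(sidecar.read_text())) if sidecar.exists() else None
    return ids, bits, phys, scaler
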