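"""Molecular representations: fingerprints, descriptors, SELFIES vectors.

Three views of each molecule feed the pipeline:

* a 1024-bit Morgan (circular/ECFP) fingerprint, radius 2, hashing
  atom-centred neighbourhoods;
* a fixed-order vector of six physicochemical descriptors
  ``[MolLogP, MolWt, NumRotatableBonds, TPSA, NumHAcceptors, NumHDonors]``;
* a bag-of-tokens count vector over a SELFIES vocabulary built from the
  training set, with a trailing unknown-token bin.

Fingerprint and descriptor blocks are concatenated into the QSAR feature
matrix; standardisation is z-scoring with training-set statistics only
(constant columns are set to zero and flagged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator, rdMolDescriptors

from ._selfies import SelfiesEncodingError, smiles_to_selfies_tokens
from .chem_io import LigandTable

DESCRIPTOR_NAMES = ("MolLogP", "MolWt", "NumRotatableBonds", "TPSA", "NumHAcceptors", "NumHDonors")
DESCRIPTOR_DIM = len(DESCRIPTOR_NAMES)
DEFAULT_FP_DIM = 1024
DEFAULT_RADIUS = 2

UNKNOWN_TOKEN = "<unk>"


class InvalidMoleculeError(ValueError):
    """A SMILES string failed to parse where a valid molecule was required."""


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"invalid SMILES: {smiles!r}")
    return mol


def morgan_fingerprint(smiles: str, radius: int = DEFAULT_RADIUS, nbits: int = DEFAULT_FP_DIM) -> np.ndarray:
    """Binary Morgan fingerprint of length ``nbits`` (uint8 0/1 vector)."""
    mol = _mol(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(nbits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def compute_descriptors(smiles: str) -> np.ndarray:
    """The six descriptors in :data:`DESCRIPTOR_NAMES` order (float64)."""
    mol = _mol(smiles)
    return np.array(
        [
            Crippen.MolLogP(mol),
            Descriptors.MolWt(mol),
            Lipinski.NumRotatableBonds(mol),
            rdMolDescriptors.CalcTPSA(mol),
            Lipinski.NumHAcceptors(mol),
            Lipinski.NumHDonors(mol),
        ],
        dtype=np.float64,
    )


def exact_mass(smiles: str) -> float:
    """Monoisotopic mass in Da (most-abundant-isotope atom masses)."""
    return float(Descriptors.ExactMolWt(_mol(smiles)))


def build_selfies_vocab(table: LigandTable) -> list[str]:
    """Sorted unique SELFIES tokens over the table's molecules.

    The vocabulary is serialised alongside any trained model so that
    screening-time encoding uses exactly the training inventory.
    """
    if len(table) == 0:
        raise ValueError("cannot build a vocabulary from an empty table")
    tokens: set[str] = set()
    for rec in table:
        try:
            tokens.update(smiles_to_selfies_tokens(rec.smiles))
        except SelfiesEncodingError:
            continue
    if not tokens:
        raise ValueError("no molecule in the table could be SELFIES-encoded")
    return sorted(tokens)


def encode_selfies(smiles: str, vocab: list[str]) -> np.ndarray:
    """Token-count vector over ``vocab`` plus a final unknown-token bin.

    The vector sums to the molecule's SELFIES token count; tokens absent
    from the vocabulary land in the last bin rather than erroring.
    """
    tokens = smiles_to_selfies_tokens(smiles)
    index = {t: i for i, t in enumerate(vocab)}
    vec = np.zeros(len(vocab) + 1, dtype=np.float64)
    for t in tokens:
        vec[index.get(t, len(vocab))] += 1
    return vec


@dataclass
class FeatureBundle:
    """Per-molecule feature triple used by the fusion similarity model."""

    fp: np.ndarray
    desc: np.ndarray
    selfies_vec: np.ndarray


def bundle_molecule(smiles: str, vocab: list[str], radius: int = DEFAULT_RADIUS, fp_dim: int = DEFAULT_FP_DIM) -> FeatureBundle:
    return FeatureBundle(
        fp=morgan_fingerprint(smiles, radius=radius, nbits=fp_dim),
        desc=compute_descriptors(smiles),
        selfies_vec=encode_selfies(smiles, vocab),
    )


@dataclass
class FeatureMatrix:
    """Concatenated fingerprint+descriptor matrix in table row order."""

    X: np.ndarray
    fp_dim: int
    radius: int
    ids: list[str] = field(default_factory=list)
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_stds: np.ndarray | None = None
    constant_columns: np.ndarray | None = None

    @property
    def descriptor_block(self) -> np.ndarray:
        return self.X[:, self.fp_dim :]

    @property
    def fingerprint_block(self) -> np.ndarray:
        return self.X[:, : self.fp_dim]


def build_feature_matrix(table: LigandTable, fp_dim: int = DEFAULT_FP_DIM, radius: int = DEFAULT_RADIUS) -> FeatureMatrix:
    """Stack fingerprints and descriptors for every record, in table order."""
    rows = [
        np.concatenate(
            [morgan_fingerprint(r.smiles, radius=radius, nbits=fp_dim).astype(np.float64), compute_descriptors(r.smiles)]
        )
        for r in table
    ]
    return FeatureMatrix(X=np.vstack(rows), fp_dim=fp_dim, radius=radius, ids=list(table.ids))


@dataclass
class Standardizer:
    """Column z-scoring with training-set statistics.

    Constant training columns get mean equal to their value and std 1 so
    they transform to exactly 0; they are flagged rather than producing
    divisions by zero.
    """

    means: np.ndarray
    stds: np.ndarray
    constant: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        means = X.mean(axis=0)
        stds = X.std(axis=0)
        constant = stds < 1e-12
        safe = stds.copy()
        safe[constant] = 1.0
        return cls(means=means, stds=safe, constant=constant)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.means) / self.stds
        Z[:, self.constant] = 0.0
        return Z


def standardize_matrix(matrix: FeatureMatrix, scaler: Standardizer | None = None) -> tuple[FeatureMatrix, Standardizer]:
    """Return a standardized copy of the matrix and the fitted scaler."""
    if scaler is None:
        scaler = Standardizer.fit(matrix.X)
    Z = scaler.transform(matrix.X)
    return (
        FeatureMatrix(
            X=Z,
            fp_dim=matrix.fp_dim,
            radius=matrix.radius,
            ids=list(matrix.ids),
            standardized=True,
            column_means=scaler.means,
            column_stds=scaler.stds,
            constant_columns=scaler.constant,
        ),
        scaler,
    )
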