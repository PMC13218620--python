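"""K-means SAR analytics: cluster selection, PCA, bit profiles, MCS.

Clustering runs on Morgan fingerprint bits with a standardized pIC50
column appended (mean 0, sd 1) so activity and structure contribute on
comparable scales.  The cluster count is chosen by silhouette argmax
over a candidate range, with the SSE (elbow) curve reported alongside
for inspection.  Per-cluster analytics cover fingerprint-bit frequency
profiles, Pearson correlations of each descriptor with pIC50, and the
maximum common substructure of the cluster members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .featurize import DESCRIPTOR_NAMES


@dataclass
class ClusterReport:
    k: int
    assignments: np.ndarray
    sse_curve: dict[int, float]
    silhouette_curve: dict[int, float]
    selection_rationale: str = "silhouette argmax"
    pca_coords: np.ndarray | None = None
    pca_explained: np.ndarray | None = None
    bit_frequency: dict[int, np.ndarray] = field(default_factory=dict)
    sar: dict[int, dict] = field(default_factory=dict)
    mcs: dict[int, dict] = field(default_factory=dict)


def clustering_features(fingerprints: np.ndarray, pic50: np.ndarray) -> np.ndarray:
    """Fingerprint bits + a standardized pIC50 column (population z-score)."""
    fingerprints = np.asarray(fingerprints, dtype=float)
    pic50 = np.asarray(pic50, dtype=float)
    if fingerprints.shape[0] != pic50.shape[0]:
        raise ValueError("fingerprints and pIC50 must align")
    sd = pic50.std()
    if sd == 0:
        z = np.zeros_like(pic50)
    else:
        z = (pic50 - pic50.mean()) / sd
    return np.column_stack([fingerprints, z])


def kmeans_select(
    features: np.ndarray,
    k_range: Sequence[int] = range(2, 7),
    n_init: int = 20,
    seed: int = 0,
) -> ClusterReport:
    """Best-of-``n_init`` K-means per k; chosen k maximises silhouette."""
    features = np.asarray(features, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) < 2:
        raise ValueError("k_range must contain at least two candidate values")
    n = features.shape[0]
    if n < max(ks):
        raise ValueError(f"need at least {max(ks)} samples for k_range up to {max(ks)}")
    sse_curve: dict[int, float] = {}
    sil_curve: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(features)
        sse_curve[k] = float(km.inertia_)
        n_labels = len(np.unique(labels))
        if 1 < n_labels < n:
            sil_curve[k] = float(silhouette_score(features, labels))
        else:  # silhouette undefined for singleton-only or one-cluster fits
            sil_curve[k] = -1.0
        fits[k] = labels
    chosen = max(sil_curve, key=lambda k: (sil_curve[k], -k))
    return ClusterReport(
        k=chosen,
        assignments=fits[chosen],
        sse_curve=sse_curve,
        silhouette_curve=sil_curve,
    )


def pca_project(features: np.ndarray, dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """PCA coordinates and explained-variance fractions (non-increasing)."""
    X = np.asarray(features, dtype=float)
    if X.shape[0] < dims:
        raise ValueError("need at least as many samples as requested dimensions")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("input has zero variance in every column")
    pca = PCA(n_components=dims, svd_solver="full")
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_


def bit_frequency_profile(assignments: np.ndarray, fingerprints: np.ndarray) -> dict[int, np.ndarray]:
    """Per-cluster fraction of members with each fingerprint bit set."""
    assignments = np.asarray(assignments)
    fingerprints = np.asarray(fingerprints, dtype=float)
    if assignments.shape[0] != fingerprints.shape[0]:
        raise ValueError("assignments and fingerprints must align")
    out: dict[int, np.ndarray] = {}
    for c in np.unique(assignments):
        members = fingerprints[assignments == c]
        if members.shape[0] == 0:
            raise ValueError(f"cluster {c} is empty")
        out[int(c)] = members.mean(axis=0)
    return out


def sar_correlations(
    descriptors: np.ndarray,
    pic50: np.ndarray,
    min_n: int = 3,
) -> dict:
    """Pearson r of each descriptor against pIC50 within one cluster.

    Descriptors with zero variance (or clusters below ``min_n``) are
    flagged undefined rather than yielding NaN.  The hydrogen-bond
    acceptor count is the headline correlation in SAR summaries.
    """
    D = np.atleast_2d(np.asarray(descriptors, dtype=float))
    y = np.asarray(pic50, dtype=float)
    if D.shape[0] != y.shape[0]:
        raise ValueError("descriptors and pIC50 must align")
    n = D.shape[0]
    result: dict = {"n": n, "small_sample": n < min_n, "per_descriptor": {}}
    for j, name in enumerate(DESCRIPTOR_NAMES):
        col = D[:, j]
        if n < min_n or col.std() == 0 or y.std() == 0:
            result["per_descriptor"][name] = {"r": None, "undefined": True}
        else:
            r, p = stats.pearsonr(col, y)
            result["per_descriptor"][name] = {"r": float(r), "p": float(p), "undefined": False}
    return result


def mcs_for_cluster(
    smiles: Sequence[str],
    min_fraction: float = 1.0,
    timeout: int = 10,
) -> dict:
    """Maximum common substructure across cluster members.

    Atoms match by element, bonds by order, and ring bonds only match
    ring bonds.  Returns the SMARTS pattern with atom/bond counts, or an
    empty-pattern flag; a solver timeout is reported distinctly.
    """
    mols = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"invalid SMILES {s!r}")
        mols.append(mol)
    if len(mols) < 2:
        raise ValueError("MCS needs at least 2 members")
    params = rdFMCS.MCSParameters()
    params.AtomTyper = rdFMCS.AtomCompare.CompareElements
    params.BondTyper = rdFMCS.BondCompare.CompareOrder
    params.BondCompareParameters.RingMatchesRingOnly = True
    params.Timeout = timeout
    if min_fraction < 1.0:
        params.Threshold = min_fraction
    res = rdFMCS.FindMCS(mols, params)
    out = {
        "smarts": res.smartsString or "",
        "atom_count": int(res.numAtoms),
        "bond_count": int(res.numBonds),
        "timed_out": bool(res.canceled),
        "empty": res.numAtoms == 0,
    }
    return out


def mcs_contains_hydroxyl(mcs_smarts: str, member_smiles: Sequence[str]) -> bool:
    """Whether the MCS pattern covers an -OH (oxygen bearing a hydrogen).

    The SMARTS itself carries no hydrogen counts, so the pattern is
    matched back onto each member and the matched oxygen atoms are
    checked for an attached hydrogen in every member.
    """
    if not mcs_smarts:
        return False
    query = Chem.MolFromSmarts(mcs_smarts)
    if query is None:
        return False
    o_positions = [a.GetIdx() for a in query.GetAtoms() if a.GetAtomicNum() == 8]
    if not o_positions:
        return False
    for pos in o_positions:
        ok_everywhere = True
        for s in member_smiles:
            mol = Chem.MolFromSmiles(s)
            match = mol.GetSubstructMatch(query)
            if not match or mol.GetAtomWithIdx(match[pos]).GetTotalNumHs() == 0:
                ok_everywhere = False
                break
        if ok_everywhere:
            return True
    return False
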