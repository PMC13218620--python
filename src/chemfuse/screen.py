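"""Candidate-library diversity reduction, similarity screening and export.

Diversity reduction embeds candidate fingerprints into 2-D with UMAP
(Jaccard metric on bits), overlays a square grid sized so the number of
occupied cells approaches the requested count, and keeps the candidate
nearest each occupied cell's centroid.  Screening scores every candidate
against every ligand anchor with the trained fusion model, attaches the
Tanimoto to the best anchor, a predicted pIC50/IC50 from the trained
regressor, and Lipinski violations, then ranks by best fusion score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .activity_rules import lipinski
from .chem_io import LigandTable, pic50_to_ic50_nM
from .featurize import build_feature_matrix, bundle_molecule, morgan_fingerprint
from .fusion_similarity import FusionModel, _bundles_to_arrays, tanimoto

DEFAULT_HIT_THRESHOLD = 0.8


@dataclass
class DiversitySelection:
    embedding: np.ndarray          # per-candidate 2-vector, input order
    kept_ids: list[str]
    method: dict = field(default_factory=dict)


@dataclass
class ScreenResult:
    id: str
    smiles: str
    best_fusion_score: float
    best_anchor_id: str
    tanimoto_to_best_anchor: float
    predicted_pic50: float
    predicted_ic50_nM: float
    lipinski_violations: int
    hit: bool


def _umap_embed(fps: np.ndarray, n_neighbors: int, min_dist: float, seed: int) -> np.ndarray:
    import umap  # deferred: import is slow

    n = fps.shape[0]
    nn = int(min(n_neighbors, max(2, n - 1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=nn,
            min_dist=min_dist,
            n_components=2,
            metric="jaccard",
            random_state=seed,
            n_jobs=1,
        )
        return np.asarray(reducer.fit_transform(fps.astype(bool)))


def _occupied_cells(emb: np.ndarray, g: int) -> dict[tuple[int, int], np.ndarray]:
    lo = emb.min(axis=0)
    span = emb.max(axis=0) - lo
    span[span == 0] = 1.0
    cells = np.minimum((g * (emb - lo) / span).astype(int), g - 1)
    groups: dict[tuple[int, int], list[int]] = {}
    for i, (cx, cy) in enumerate(cells):
        groups.setdefault((int(cx), int(cy)), []).append(i)
    return {k: np.array(v) for k, v in groups.items()}


def diversity_reduce(
    candidates: LigandTable,
    target_count: int,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
    fp_dim: int = 1024,
    radius: int = 2,
) -> DiversitySelection:
    """Keep ≈``target_count`` structurally diverse candidates.

    Exact fingerprint duplicates collapse to one representative before
    embedding.  The grid resolution is chosen as the finest square grid
    whose occupied-cell count does not exceed the target, which makes
    the selection idempotent: re-reducing the kept set with the same
    target keeps everything.
    """
    n = len(candidates)
    if not 1 <= target_count <= n:
        raise ValueError(f"target_count must be in 1..{n}, got {target_count}")
    fps = np.vstack([morgan_fingerprint(s, radius=radius, nbits=fp_dim) for s in candidates.smiles])
    # collapse exact duplicates, keeping the first occurrence
    _, uniq_first = np.unique(fps, axis=0, return_index=True)
    uniq_idx = np.sort(uniq_first)
    ids = candidates.ids

    if len(uniq_idx) <= target_count:
        kept = [ids[i] for i in uniq_idx]
        emb = np.zeros((n, 2))
        return DiversitySelection(
            embedding=emb,
            kept_ids=kept,
            method={"n_neighbors": n_neighbors, "min_dist": min_dist, "grid": None, "seed": seed,
                    "note": "unique fingerprints <= target; kept all unique"},
        )

    emb_u = _umap_embed(fps[uniq_idx], n_neighbors, min_dist, seed)
    # finest grid with occupied cells <= target (occupancy is monotone in g)
    lo_g, hi_g = 1, max(2, int(4 * np.sqrt(target_count)) + 2)
    while len(_occupied_cells(emb_u, hi_g)) <= target_count and hi_g < 4096:
        hi_g *= 2
    best_g = lo_g
    while lo_g <= hi_g:
        mid = (lo_g + hi_g) // 2
        if len(_occupied_cells(emb_u, mid)) <= target_count:
            best_g = mid
            lo_g = mid + 1
        else:
            hi_g = mid - 1
    groups = _occupied_cells(emb_u, best_g)

    kept_positions = []
    for _, members in sorted(groups.items()):
        centroid = emb_u[members].mean(axis=0)
        d = np.linalg.norm(emb_u[members] - centroid, axis=1)
        kept_positions.append(int(uniq_idx[members[int(np.argmin(d))]]))
    kept_positions.sort()
    embedding = np.zeros((n, 2))
    embedding[uniq_idx] = emb_u
    return DiversitySelection(
        embedding=embedding,
        kept_ids=[ids[i] for i in kept_positions],
        method={"n_neighbors": n_neighbors, "min_dist": min_dist, "grid": best_g, "seed": seed,
                "occupied_cells": len(groups)},
    )


def screen_library(
    model: FusionModel,
    regressor,
    ligands: LigandTable,
    candidates: LigandTable,
    hit_threshold: float = DEFAULT_HIT_THRESHOLD,
    anchor_policy: str = "high",
    anchor_ids: Sequence[str] | None = None,
) -> list[ScreenResult]:
    """Score every candidate against the ligand anchors; rank by best score.

    The fusion score estimates the probability that both pair members are
    high-activity, so with the default ``anchor_policy="high"`` only the
    high-activity ligands (pIC50 > 7) serve as anchors — a score against
    a weak ligand carries no evidence of candidate potency.  Pass
    ``anchor_policy="all"`` (or explicit ``anchor_ids``) to screen
    against the full ligand set; the policy in force is visible through
    the anchors actually referenced in the results.  The regressor must
    have been fitted on the concatenated fingerprint+descriptor matrix
    with the model's fp_dim/radius.
    """
    if model.vocab is None:
        raise ValueError("model has no SELFIES vocabulary; train or load a checkpoint first")
    if anchor_policy not in ("high", "all"):
        raise ValueError(f"unknown anchor_policy {anchor_policy!r}")
    anchors = ligands.records
    if anchor_ids is not None:
        wanted = set(anchor_ids)
        anchors = [r for r in ligands.records if r.id in wanted]
    elif anchor_policy == "high":
        from .activity_rules import classify_activity

        high = [r for r in anchors if r.pic50 is not None and classify_activity(r.pic50).klass == "high"]
        if high:  # fall back to all anchors for unlabelled ligand sets
            anchors = high
    if not anchors:
        raise ValueError("anchor selection matched no ligand")

    anchor_bundles = [bundle_molecule(r.smiles, model.vocab, radius=model.radius, fp_dim=model.fp_dim) for r in anchors]
    cand_bundles = [bundle_molecule(r.smiles, model.vocab, radius=model.radius, fp_dim=model.fp_dim) for r in candidates.records]
    fa, da, sa = _bundles_to_arrays(anchor_bundles)
    fc, dc, sc = _bundles_to_arrays(cand_bundles)

    # score candidates against anchors in anchor-sized batches
    n_anchor = len(anchors)
    best_score = np.full(len(candidates), -np.inf)
    best_anchor = np.zeros(len(candidates), dtype=int)
    for ai in range(n_anchor):
        rep = lambda arr: np.repeat(arr[ai : ai + 1], len(candidates), axis=0)
        s = model.score_pairs_raw(fc, dc, sc, rep(fa), rep(da), rep(sa)).data.ravel()
        better = s > best_score
        best_score[better] = s[better]
        best_anchor[better] = ai

    fm = build_feature_matrix(candidates, fp_dim=model.fp_dim, radius=model.radius)
    pred_pic50 = np.asarray(regressor.predict(fm.X), dtype=float)

    results = []
    for i, rec in enumerate(candidates.records):
        results.append(
            ScreenResult(
                id=rec.id,
                smiles=rec.smiles,
                best_fusion_score=float(best_score[i]),
                best_anchor_id=anchors[best_anchor[i]].id,
                tanimoto_to_best_anchor=tanimoto(fc[i] > 0, fa[best_anchor[i]] > 0),
                predicted_pic50=float(pred_pic50[i]),
                predicted_ic50_nM=pic50_to_ic50_nM(float(pred_pic50[i])),
                lipinski_violations=lipinski(dc[i]).violations,
                hit=bool(best_score[i] > hit_threshold),
            )
        )
    results.sort(key=lambda r: (-r.best_fusion_score, r.id))
    return results


def results_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def export_top_candidates(results: Sequence[ScreenResult], n: int, out_dir: str | Path, prefix: str = "hits") -> dict:
    """Write the top-n ranked table plus one SDF record per hit for docking."""
    if n > len(results):
        raise ValueError(f"asked for {n} of {len(results)} results")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    top = list(results[:n])
    table_path = out_dir / f"{prefix}.csv"
    results_frame(top).to_csv(table_path, index=False, float_format="%.9g")
    sdf_path = out_dir / f"{prefix}.sdf"
    writer = Chem.SDWriter(str(sdf_path))
    writer.SetKekulize(True)
    for r in top:
        mol = Chem.MolFromSmiles(r.smiles)
        mol.SetProp("_Name", r.id)
        mol.SetProp("best_fusion_score", f"{r.best_fusion_score:.6f}")
        mol.SetProp("predicted_pic50", f"{r.predicted_pic50:.6f}")
        writer.write(mol)
    writer.close()
    return {"table": str(table_path), "sdf": str(sdf_path), "n": n}
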