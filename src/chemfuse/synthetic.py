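"""Synthetic ligand sets and candidate libraries with planted SAR.

The generator emulates a target-focused ligand activity table: molecules
are scaffold + substituent combinations, and pIC50 follows a known linear
model on interpretable structural features

    pIC50 = b0 + b1*[boost fragment present] + b2*(TPSA/100)
            + b3*(rotatable bonds) + eps,   eps ~ Normal(0, sigma)

(with an optional boost x TPSA interaction in nonlinear mode).  The
"boost" fragment is hydroxymethyl (-CH2OH): it carries a hydroxyl so the
maximum-common-substructure stage has a planted, recoverable motif in the
high-activity stratum.  True coefficients and per-molecule feature flags
are returned alongside the table, giving every downstream stage a ground
truth to test against.

Candidate libraries mix "analogs" (single-substituent edits of ligand
molecules, which a similarity screen should rank highly) with decoys
drawn from structurally disjoint scaffolds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem_io import LigandTable, MoleculeRecord
from .featurize import compute_descriptors

#: Ligand scaffolds, each with two substitution points.
LIGAND_SCAFFOLDS = (
    "c1cc({a})ccc1{b}",            # benzene
    "c1cc2c(cc1{b})c({a})c[nH]2",  # indole
    "C1CC({a})CCN1{b}",            # piperidine
    "c1nc({a})ncc1{b}",            # pyrimidine
)

#: Decoy scaffolds for candidate libraries — ring systems disjoint from the
#: ligand scaffolds (checked by Murcko scaffold hashing in tests).
DECOY_SCAFFOLDS = (
    "c1ccc2cc({a})c({b})cc2c1",    # naphthalene
    "c1cc({a})c(s1){b}",           # thiophene
    "c1cc({a})c(o1){b}",           # furan
    "C1CC({a})CCC1{b}",            # cyclohexane
)

#: The activity-boosting substituent: hydroxymethyl, -CH2OH.
BOOST_FRAGMENT = "CO"

#: Plain substituent alphabet (SMILES suffixes; never the boost fragment).
FRAGMENTS = ("C", "CC", "O", "OC", "N", "F", "Cl", "C#N", "C(=O)O", "C(=O)N", "C(C)C", "OCC")

#: Optional linkers prepended to a fragment to enlarge the combinatorial
#: space; "" means direct attachment.
LINKERS = ("", "C", "CC", "N", "O", "CCO")


@dataclass
class SyntheticSpec:
    """Generator configuration; the defaults define the study conditions."""

    n_ligands: int = 2000
    scaffolds: tuple[str, ...] = LIGAND_SCAFFOLDS
    fragments: tuple[str, ...] = FRAGMENTS
    boost_fragment: str = BOOST_FRAGMENT
    boost_prob: float = 0.45
    beta: tuple[float, float, float, float] = (4.7, 2.8, 0.5, 0.05)  # b0, b1, b2, b3
    beta_interaction: float = 2.0   # used only in nonlinear mode
    nonlinear: bool = False
    sigma: float = 0.4
    seed: int = 0
    max_retries_factor: int = 200


@dataclass
class GroundTruth:
    """Planted coefficients plus the per-molecule design used to draw pIC50."""

    beta: tuple[float, float, float, float]
    beta_interaction: float
    nonlinear: bool
    sigma: float
    seed: int
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # per-molecule generation metadata used for analog construction
    recipes: list[dict] = field(default_factory=list)

    def design_matrix(self) -> np.ndarray:
        """[1, boost, TPSA/100, rot_bonds] (+ interaction column in nonlinear mode)."""
        cols = [
            np.ones(len(self.table)),
            self.table["boost"].to_numpy(dtype=float),
            self.table["tpsa"].to_numpy() / 100.0,
            self.table["rot_bonds"].to_numpy(dtype=float),
        ]
        if self.nonlinear:
            cols.append(cols[1] * cols[2])
        return np.column_stack(cols)


def _substituent(rng: np.random.Generator, fragments: tuple[str, ...]) -> str:
    linker = LINKERS[rng.integers(len(LINKERS))]
    frag = fragments[rng.integers(len(fragments))]
    # avoid accidentally synthesising the boost motif (a terminal C-OH)
    # from linker+fragment, which would decouple structure from the flag
    if frag == "O" and linker.endswith("C"):
        linker = ""
    return linker + frag


def _assemble(template: str, sub_a: str, sub_b: str) -> str | None:
    smi = template.format(a=sub_a, b=sub_b)
    mol = Chem.MolFromSmiles(smi)
    return Chem.MolToSmiles(mol) if mol is not None else None


def _true_pic50(spec: SyntheticSpec, boost: bool, tpsa: float, rot: float) -> float:
    b0, b1, b2, b3 = spec.beta
    mu = b0 + b1 * float(boost) + b2 * (tpsa / 100.0) + b3 * rot
    if spec.nonlinear:
        mu += spec.beta_interaction * float(boost) * (tpsa / 100.0)
    return mu


def generate_ligand_set(spec: SyntheticSpec) -> tuple[LigandTable, GroundTruth]:
    """Generate ``spec.n_ligands`` unique molecules with planted activities."""
    if not spec.fragments:
        raise ValueError("fragment alphabet is empty")
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    rows: list[dict] = []
    recipes: list[dict] = []
    attempts = 0
    cap = spec.max_retries_factor * spec.n_ligands
    while len(records) < spec.n_ligands:
        attempts += 1
        if attempts > cap:
            raise RuntimeError(
                f"could not generate {spec.n_ligands} unique molecules in {cap} attempts; "
                "enlarge the scaffold/fragment space"
            )
        s_idx = int(rng.integers(len(spec.scaffolds)))
        boost = bool(rng.random() < spec.boost_prob)
        sub_a = _substituent(rng, spec.fragments)
        sub_b = _substituent(rng, spec.fragments)
        if boost:
            # the boost slot keeps its terminal -CH2OH motif but may sit on a
            # linker, which keeps the unique boost-bearing space large enough
            # that deduplication does not depress boost prevalence
            linker = LINKERS[int(rng.integers(len(LINKERS)))]
            if rng.random() < 0.5:
                sub_a = linker + spec.boost_fragment
            else:
                sub_b = linker + spec.boost_fragment
        can = _assemble(spec.scaffolds[s_idx], sub_a, sub_b)
        if can is None or can in seen:
            continue
        desc = compute_descriptors(can)
        tpsa, rot = float(desc[3]), float(desc[2])
        mu = _true_pic50(spec, boost, tpsa, rot)
        pic50 = mu + float(rng.normal(0.0, spec.sigma)) if spec.sigma > 0 else mu
        seen.add(can)
        idx = len(records)
        ic50_nm = 10.0 ** (9.0 - pic50)
        records.append(
            MoleculeRecord(id=f"SYN-{idx:05d}", smiles=can, ic50_nM=ic50_nm, pic50=pic50, source="synthetic")
        )
        rows.append({"id": f"SYN-{idx:05d}", "smiles": can, "boost": boost, "tpsa": tpsa, "rot_bonds": rot, "mu": mu, "pic50": pic50})
        recipes.append({"scaffold": s_idx, "sub_a": sub_a, "sub_b": sub_b, "boost": boost})
    truth = GroundTruth(
        beta=spec.beta,
        beta_interaction=spec.beta_interaction,
        nonlinear=spec.nonlinear,
        sigma=spec.sigma,
        seed=spec.seed,
        table=pd.DataFrame(rows),
        recipes=recipes,
    )
    return LigandTable(records=records), truth


def murcko_scaffold(smiles: str) -> str:
    """Canonical Murcko scaffold SMILES (ring systems + linkers)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    return Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol))


def generate_candidate_library(
    spec: SyntheticSpec,
    n_candidates: int = 500,
    analog_fraction: float = 0.25,
) -> tuple[LigandTable, pd.DataFrame]:
    """Candidate library: ligand analogs plus disjoint-scaffold decoys.

    Analogs are single-substituent edits of molecules from the ligand set
    implied by ``spec`` (regenerated deterministically from the same
    seed), so a similarity screen against that ligand set should enrich
    them.  Returns the library and a sidecar frame with columns
    ``id, smiles, is_analog, parent_id``.
    """
    if not 0.0 <= analog_fraction <= 1.0:
        raise ValueError("analog_fraction must lie in [0, 1]")
    ligands, truth = generate_ligand_set(spec)
    rng = np.random.default_rng(spec.seed + 104729)
    n_analogs = int(round(n_candidates * analog_fraction))
    ligand_smiles = set(ligands.smiles)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    rows: list[dict] = []
    attempts, cap = 0, spec.max_retries_factor * max(n_candidates, 1)

    while len(records) < n_analogs:
        attempts += 1
        if attempts > cap:
            raise RuntimeError("analog generation exhausted retries")
        j = int(rng.integers(len(truth.recipes)))
        recipe = dict(truth.recipes[j])
        # edit exactly one substitution point, never touching a boost slot
        editable = [k for k in ("sub_a", "sub_b") if not recipe[k].endswith(spec.boost_fragment)]
        if not editable:
            continue
        point = editable[int(rng.integers(len(editable)))]
        recipe[point] = _substituent(rng, spec.fragments)
        can = _assemble(spec.scaffolds[recipe["scaffold"]], recipe["sub_a"], recipe["sub_b"])
        if can is None or can in seen or can in ligand_smiles:
            continue
        seen.add(can)
        cid = f"CAND-A{len(records):05d}"
        records.append(MoleculeRecord(id=cid, smiles=can, source="synthetic-analog"))
        rows.append({"id": cid, "smiles": can, "is_analog": True, "parent_id": ligands.records[j].id})

    attempts = 0
    while len(records) < n_candidates:
        attempts += 1
        if attempts > cap:
            raise RuntimeError("decoy generation exhausted retries")
        template = DECOY_SCAFFOLDS[int(rng.integers(len(DECOY_SCAFFOLDS)))]
        sub_a = _substituent(rng, spec.fragments)
        sub_b = _substituent(rng, spec.fragments)
        can = _assemble(template, sub_a, sub_b)
        if can is None or can in seen or can in ligand_smiles:
            continue
        seen.add(can)
        cid = f"CAND-D{len(records):05d}"
        records.append(MoleculeRecord(id=cid, smiles=can, source="synthetic-decoy"))
        rows.append({"id": cid, "smiles": can, "is_analog": False, "parent_id": None})

    return LigandTable(records=records), pd.DataFrame(rows)


def analytic_pic50_sd(spec: SyntheticSpec, truth: GroundTruth) -> float:
    """Closed-form sd of generated pIC50: mixture-of-means variance + sigma^2.

    Uses the realised per-molecule means (the deterministic part of the
    model), so it is exact for the generated set rather than an
    approximation over the scaffold distribution.
    """
    mu = truth.table["mu"].to_numpy()
    return float(math.sqrt(mu.var() + spec.sigma**2))
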