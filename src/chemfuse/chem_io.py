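"""Reading, validation and normalisation of ligand activity tables.

All unit conventions live here: IC50 values are stored in nanomolar, and
pIC50 is the negative base-10 logarithm of the IC50 expressed in molar
(so 100 nM corresponds to pIC50 = 7).  Structures are kept as RDKit
canonical SMILES; anything RDKit cannot parse is rejected, never silently
kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Multiplicative factors taking an IC50 in the given unit to nanomolar.
_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "M": 1e9}

#: Plausible IC50 window in nM; values outside are treated as anomalous.
DEFAULT_IC50_BOUNDS_NM = (1e-3, 1e12)


class ChemIOError(Exception):
    """Base class for ligand-table I/O problems."""


class MissingColumnError(ChemIOError):
    """A required column is absent from the input table."""


class EmptyTableError(ChemIOError):
    """Every input row was rejected during validation."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound: identifier, canonical SMILES and optional activity."""

    id: str
    smiles: str
    ic50_nM: float | None = None
    pic50: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.ic50_nM is not None and self.ic50_nM <= 0:
            raise ValueError(f"ic50_nM must be positive, got {self.ic50_nM}")
        if self.ic50_nM is not None and self.pic50 is not None:
            expected = 9.0 - math.log10(self.ic50_nM)
            if abs(expected - self.pic50) > 1e-6:
                raise ValueError(
                    f"inconsistent activity for {self.id!r}: "
                    f"ic50_nM={self.ic50_nM} implies pIC50={expected:.6f}, "
                    f"got {self.pic50}"
                )


@dataclass
class LigandTable:
    """An ordered set of validated molecule records plus filter accounting.

    ``rejected_count + dedup_count + len(records)`` always equals the raw
    input row count, so no row can disappear unaccounted for.
    """

    records: list[MoleculeRecord] = field(default_factory=list)
    rejected_count: int = 0
    dedup_count: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def pic50(self) -> list[float | None]:
        return [r.pic50 for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "ic50_nM": [r.ic50_nM for r in self.records],
                "pic50": [r.pic50 for r in self.records],
            }
        )


def ic50_to_pic50(ic50: float, unit: str = "nM") -> float:
    """Convert an IC50 in the given unit to pIC50 (-log10 of molar IC50)."""
    if unit not in _UNIT_TO_NM:
        raise ValueError(f"unknown IC50 unit {unit!r}; expected one of {sorted(_UNIT_TO_NM)}")
    if not (isinstance(ic50, (int, float)) and math.isfinite(ic50)) or ic50 <= 0:
        raise ValueError(f"IC50 must be a positive finite number, got {ic50!r}")
    ic50_nm = ic50 * _UNIT_TO_NM[unit]
    return 9.0 - math.log10(ic50_nm)


def pic50_to_ic50_nM(pic50: float) -> float:
    """Inverse of :func:`ic50_to_pic50` for the nanomolar scale."""
    if not math.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50!r}")
    return 10.0 ** (9.0 - pic50)


def canonicalize_smiles(smiles: str, keep_largest_fragment: bool = True) -> str | None:
    """Return the RDKit canonical SMILES, or ``None`` for unparsable input.

    Multi-fragment inputs (salts, mixtures) are reduced to their largest
    organic fragment before canonicalisation, so e.g. a hydrochloride salt
    and its free base map to the same record.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    mol = Chem.MolFromSmiles(smiles.strip())
    if mol is None:
        return None
    if keep_largest_fragment and len(Chem.GetMolFrags(mol)) > 1:
        chooser = rdMolStandardize.LargestFragmentChooser()
        mol = chooser.choose(mol)
        if mol is None:
            return None
    return Chem.MolToSmiles(mol)


def _coerce_ic50(value, bounds_nm: tuple[float, float], unit: str) -> float | None:
    """Parse one raw IC50 cell to nM, returning None for anomalous values."""
    try:
        x = float(value)
    except (TypeError, ValueError):
        return None
    if not math.isfinite(x) or x <= 0:
        return None
    x_nm = x * _UNIT_TO_NM[unit]
    lo, hi = bounds_nm
    if not (lo <= x_nm <= hi):
        return None
    return x_nm


def load_ligand_table(
    path: str | Path,
    ic50_unit: str = "nM",
    ic50_column: str = "ic50",
    smiles_column: str = "smiles",
    id_column: str | None = "id",
    pic50_column: str | None = None,
    sep: str = ",",
    ic50_bounds_nM: tuple[float, float] = DEFAULT_IC50_BOUNDS_NM,
    require_activity: bool = True,
) -> LigandTable:
    """Load and validate a delimited ligand activity table.

    Every row is structure-validated with RDKit; rows with unparsable
    SMILES or (when ``require_activity``) missing/non-positive/anomalous
    IC50 values are dropped and counted in ``rejected_count``.  Rows whose
    canonical SMILES collide are collapsed to a single record using the
    median IC50 and counted in ``dedup_count``.

    When ``pic50_column`` is given it takes precedence over the IC50
    column and is converted back to a nanomolar IC50.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if ic50_unit not in _UNIT_TO_NM:
        raise ValueError(f"unknown IC50 unit {ic50_unit!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col, needed in ((smiles_column, True), (ic50_column, require_activity and not pic50_column)):
        if needed and col not in df.columns:
            raise MissingColumnError(f"column {col!r} not found in {path} (columns: {list(df.columns)})")
    if pic50_column and pic50_column not in df.columns:
        raise MissingColumnError(f"column {pic50_column!r} not found in {path}")

    raw_count = len(df)
    rejected = 0
    # canonical smiles -> (first id, list of ic50_nM)
    by_smiles: dict[str, dict] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        can = canonicalize_smiles(rowd[smiles_column])
        if can is None:
            rejected += 1
            continue
        ic50_nm: float | None = None
        if pic50_column:
            try:
                pic = float(rowd[pic50_column])
                if not math.isfinite(pic):
                    raise ValueError
                ic50_nm = pic50_to_ic50_nM(pic)
            except (TypeError, ValueError):
                ic50_nm = None
        elif ic50_column in df.columns:
            ic50_nm = _coerce_ic50(rowd.get(ic50_column), ic50_bounds_nM, ic50_unit)
        if require_activity and ic50_nm is None:
            rejected += 1
            continue
        if can not in by_smiles:
            rid = rowd.get(id_column, "") if id_column else ""
            if not rid:
                rid = f"mol_{i}"
            by_smiles[can] = {"id": rid, "ic50s": []}
            order.append(can)
        if ic50_nm is not None:
            by_smiles[can]["ic50s"].append(ic50_nm)

    records: list[MoleculeRecord] = []
    seen_ids: set[str] = set()
    dedup = raw_count - rejected - len(order)
    for can in order:
        entry = by_smiles[can]
        rid = entry["id"]
        while rid in seen_ids:  # enforce id uniqueness after collapsing
            rid = rid + "_dup"
        seen_ids.add(rid)
        ic50s = sorted(entry["ic50s"])
        ic50_nm = float(pd.Series(ic50s).median()) if ic50s else None
        pic50 = 9.0 - math.log10(ic50_nm) if ic50_nm is not None else None
        records.append(MoleculeRecord(id=rid, smiles=can, ic50_nM=ic50_nm, pic50=pic50, source=str(path)))

    if not records:
        raise EmptyTableError(f"no valid records remained after filtering {path} ({raw_count} raw rows)")
    return LigandTable(records=records, rejected_count=rejected, dedup_count=dedup)


def load_sdf_library(path: str | Path) -> LigandTable:
    """Load a candidate library from SDF; the molecule title is the id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    records: list[MoleculeRecord] = []
    rejected = 0
    seen: dict[str, int] = {}
    seen_ids: set[str] = set()
    for i, mol in enumerate(supplier):
        if mol is None:
            rejected += 1
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen[can] = i
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i}"
        while rid in seen_ids:
            rid = rid + "_dup"
        seen_ids.add(rid)
        records.append(MoleculeRecord(id=rid, smiles=can, source=str(path)))
    dedup = (i + 1 if records or rejected else 0) - rejected - len(records)
    if not records:
        raise EmptyTableError(f"no valid molecules in {path}")
    return LigandTable(records=records, rejected_count=rejected, dedup_count=dedup)


def save_ligand_table(table: LigandTable, path: str | Path, sep: str = ",") -> None:
    """Write a normalised table with columns id, smiles, ic50_nM, pic50."""
    df = table.to_frame()
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def table_from_records(records: Iterable[MoleculeRecord]) -> LigandTable:
    """Build an in-memory table from already-validated records."""
    recs = list(records)
    if len({r.id for r in recs}) != len(recs):
        raise ValueError("duplicate ids in records")
    return LigandTable(records=recs)
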