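"""Activity classification and Lipinski drug-likeness rules.

Three-level activity scheme on pIC50 (−log10 molar IC50):
low < 5, medium in [5, 7] (boundaries inclusive), high > 7.  The binary
discretisation used for classification metrics is high = pIC50 > 7
versus low = pIC50 ≤ 7.  Lipinski's Rule of Five uses the four strict
inequalities LogP < 5, MW < 500 Da, HBD < 5, HBA < 10, evaluated on the
average molecular weight descriptor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LOW_THRESHOLD = 5.0
HIGH_THRESHOLD = 7.0

LIPINSKI_LOGP_MAX = 5.0
LIPINSKI_MW_MAX = 500.0
LIPINSKI_HBD_MAX = 5
LIPINSKI_HBA_MAX = 10


@dataclass(frozen=True)
class ActivityLabel:
    klass: str  # "low" | "medium" | "high"
    binary_high: bool


@dataclass(frozen=True)
class LipinskiReport:
    logp_ok: bool
    mw_ok: bool
    hbd_ok: bool
    hba_ok: bool

    @property
    def violations(self) -> int:
        return sum(not ok for ok in (self.logp_ok, self.mw_ok, self.hbd_ok, self.hba_ok))


def classify_activity(pic50: float, low: float = LOW_THRESHOLD, high: float = HIGH_THRESHOLD) -> ActivityLabel:
    """Partition a finite pIC50 into low/medium/high; boundaries are medium."""
    if not (isinstance(pic50, (int, float)) and math.isfinite(pic50)):
        raise ValueError(f"pIC50 must be finite, got {pic50!r}")
    if pic50 < low:
        klass = "low"
    elif pic50 > high:
        klass = "high"
    else:
        klass = "medium"
    return ActivityLabel(klass=klass, binary_high=pic50 > high)


def lipinski(desc: np.ndarray) -> LipinskiReport:
    """Rule-of-five report from a 6-descriptor vector.

    Expects :data:`chemfuse.featurize.DESCRIPTOR_NAMES` ordering:
    [MolLogP, MolWt, NumRotatableBonds, TPSA, NumHAcceptors, NumHDonors].
    """
    desc = np.asarray(desc, dtype=float)
    if desc.shape != (6,):
        raise ValueError(f"expected a 6-descriptor vector, got shape {desc.shape}")
    logp, mw, _rot, _tpsa, hba, hbd = desc
    return LipinskiReport(
        logp_ok=logp < LIPINSKI_LOGP_MAX,
        mw_ok=mw < LIPINSKI_MW_MAX,
        hbd_ok=hbd < LIPINSKI_HBD_MAX,
        hba_ok=hba < LIPINSKI_HBA_MAX,
    )
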