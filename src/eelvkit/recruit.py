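"""PEEP-induced alveolar recruitment from EELV and static compliance.

Raising PEEP inflates the already-open lung by roughly compliance x dPEEP;
any EELV gain beyond that minimum predicted volume is attributed to newly
recruited lung:

    Vrec = (EELV_high - EELV_low) - C_stat(lower PEEP) * (PEEP_high - PEEP_low)

Compliance is taken at the lower PEEP step and total PEEP (including the
intrinsic component) is preferred over set PEEP when available. The result
may be negative (derecruitment). Note the estimator is *not* antisymmetric
under swapping the steps, because compliance is anchored at the lower one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .errors import InsufficientDataError, InvalidMechanicsError

__all__ = ["PeepStepRecord", "static_compliance", "vrec_mbnw", "recruitment_table"]


@dataclass
class PeepStepRecord:
    """One subject's measurements at one PEEP step."""

    subject: str
    peep_set: float
    peep_tot: Optional[float] = None
    pplat: Optional[float] = None
    vt_ml: Optional[float] = None
    eelv_ml: Optional[float] = None
    compliance_mlcmh2o: Optional[float] = None

    @property
    def peep(self) -> float:
        """Total PEEP when measured, else set PEEP."""
        return self.peep_tot if self.peep_tot is not None else self.peep_set

    @property
    def peep_source(self) -> str:
        return "total" if self.peep_tot is not None else "set"

    def compliance(self) -> float:
        """Stated compliance, or computed from this step's VT/Pplat/PEEPtot."""
        if self.compliance_mlcmh2o is not None:
            return self.compliance_mlcmh2o
        if self.vt_ml is None or self.pplat is None:
            raise InsufficientDataError(
                f"step {self.subject}@{self.peep_set}: no compliance and no "
                "vt/pplat to compute it"
            )
        return static_compliance(self.vt_ml, self.pplat, self.peep)


def static_compliance(vt_ml: float, pplat: float, peep_tot: float) -> float:
    """Static respiratory-system compliance VT / (Pplat - total PEEP), mL/cmH2O."""
    if pplat <= peep_tot:
        raise InvalidMechanicsError(
            f"plateau pressure ({pplat}) must exceed total PEEP ({peep_tot})"
        )
    return vt_ml / (pplat - peep_tot)


def vrec_mbnw(lower: PeepStepRecord, higher: PeepStepRecord) -> float:
    """EELV-derived recruited volume (mL) between two consecutive PEEP steps."""
    if higher.peep <= lower.peep:
        raise InvalidMechanicsError(
            "higher-PEEP record must have a larger PEEP than the lower one"
        )
    if lower.eelv_ml is None or higher.eelv_ml is None:
        raise InsufficientDataError("both steps need an EELV measurement")
    c = lower.compliance()
    return (higher.eelv_ml - lower.eelv_ml) - c * (higher.peep - lower.peep)


def recruitment_table(steps: pd.DataFrame) -> pd.DataFrame:
    """Per-subject recruitment between consecutive PEEP steps.

    ``steps`` needs columns ``subject, peep_set, eelv_ml`` and either
    ``compliance_mlcmh2o`` or ``vt_ml`` + ``pplat``; ``peep_tot`` is used
    when present. Rows are paired in ascending PEEP order within subject.
    """
    def _opt(row, key):
        v = row.get(key)
        if v is None or pd.isna(v):
            return None
        return float(v)

    rows = []
    for subject, grp in steps.groupby("subject", sort=False):
        recs = [
            PeepStepRecord(
                subject=str(subject),
                peep_set=float(row["peep_set"]),
                peep_tot=_opt(row, "peep_tot"),
                pplat=_opt(row, "pplat"),
                vt_ml=_opt(row, "vt_ml"),
                eelv_ml=_opt(row, "eelv_ml"),
                compliance_mlcmh2o=_opt(row, "compliance_mlcmh2o"),
            )
            for _, row in grp.iterrows()
        ]
        recs.sort(key=lambda r: r.peep)
        for lo, hi in zip(recs, recs[1:]):
            rows.append(
                {
                    "subject": subject,
                    "peep_low": lo.peep,
                    "peep_high": hi.peep,
                    "peep_source": lo.peep_source,
                    "compliance_mlcmh2o": lo.compliance(),
                    "vrec_ml": vrec_mbnw(lo, hi),
                }
            )
    return pd.DataFrame(rows)
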