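"""Cognitive-impairment labelling from CDR, clinical diagnosis and MMSE.

Brain donors are labelled cognitively impaired (CI) or not (NCI) from up to
three antemortem measures: the Clinical Dementia Rating (CDR, positive at
>= 0.5), a clinical diagnosis of impairment, and the Mini-Mental State
Examination (MMSE, positive at <= 24).  Donors with no available measure are
excluded.  CDR values above 3 are capped at 3 for cross-center consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import pandas as pd

from .config import ConfigError, LabelPolicy

__all__ = ["DonorRecord", "cap_cdr", "assign_label", "label_cohort"]

CI, NCI, EXCLUDED = "CI", "NCI", "excluded"
_DX_CODES = ("impaired", "not_impaired")


@dataclass
class DonorRecord:
    """Covariates, cognitive measures and derived label for one donor.

    ``true_state`` exists only for simulated donors; real cohorts leave it
    ``None``.  ``label`` is derived exclusively through :func:`assign_label`.
    """

    donor_id: str
    age: float
    sex: str
    cdr: Optional[float] = None
    mmse: Optional[int] = None
    clinical_dx: Optional[str] = None
    braak: int = 0
    cerad: int = 0
    artag: int = 0
    cvd: int = 0
    true_state: Optional[str] = None
    label: Optional[str] = None


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def cap_cdr(cdr: Optional[float]) -> Optional[float]:
    """Cap a CDR score at 3; missing passes through.

    Raises
    ------
    ConfigError
        If ``cdr`` is negative.
    """
    if _is_missing(cdr):
        return cdr
    if cdr < 0:
        raise ConfigError(f"CDR must be non-negative, got {cdr!r}")
    return min(float(cdr), 3.0)


def assign_label(donor: DonorRecord, policy: LabelPolicy = LabelPolicy()) -> str:
    """Derive the CI / NCI / excluded label for one donor.

    In ``any_evidence`` mode, CI iff any available measure is positive, NCI
    iff at least one measure is available and all available ones are
    negative, excluded when none is available.  In ``hierarchical`` mode the
    first available measure in the order CDR -> diagnosis -> MMSE decides
    alone.
    """
    cdr = cap_cdr(donor.cdr)
    dx = donor.clinical_dx
    if not _is_missing(dx) and dx not in _DX_CODES:
        raise ConfigError(f"unknown clinical_dx code {dx!r}")
    mmse = donor.mmse

    verdicts: list[bool] = []  # True = positive evidence of impairment
    if not _is_missing(cdr):
        verdicts.append(cdr >= policy.cdr_threshold)
    if not _is_missing(dx):
        verdicts.append(dx == "impaired")
    if not _is_missing(mmse):
        verdicts.append(mmse <= policy.mmse_threshold)

    if not verdicts:
        return EXCLUDED
    if policy.mode == "hierarchical":
        return CI if verdicts[0] else NCI
    return CI if any(verdicts) else NCI


def label_cohort(cohort: pd.DataFrame, policy: LabelPolicy = LabelPolicy()) -> pd.DataFrame:
    """Return a copy of the cohort table with capped ``cdr`` and a ``label`` column."""
    out = cohort.copy()
    out["cdr"] = [cap_cdr(v) for v in out["cdr"]]
    labels = []
    for _, row in out.iterrows():
        donor = DonorRecord(
            donor_id=str(row["donor_id"]),
            age=row.get("age", float("nan")),
            sex=str(row.get("sex", "")),
            cdr=row["cdr"],
            mmse=None if pd.isna(row["mmse"]) else int(row["mmse"]),
            clinical_dx=None if pd.isna(row["clinical_dx"]) else str(row["clinical_dx"]),
        )
        labels.append(assign_label(donor, policy))
    out["label"] = labels
    return out
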