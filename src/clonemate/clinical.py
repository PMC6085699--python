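"""Histopathological concordance and clinical group assignment.

A patient's two tumours are compared feature by feature (histological
subtype, ER status, HER2 status, molecular subtype). A feature with a
missing (``ND``) value on either side is not evaluable and excluded from
the concordance denominator; a patient is *discordant* overall when at
least one evaluable feature differs.

Patients are stratified into four clinical groups by laterality and the
time between diagnoses: BM / BS (bilateral metachronous / synchronous)
and IM / IS (ipsilateral). Metachronous means an interval of more than
six months (operationalised as > 183 days).

A bundled example cohort — 37 breast cancer patients, each with paired
invasive tumours — ships with the package and is loaded with
:func:`load_example_clinical`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .datatypes import ClinicalRecord

__all__ = [
    "ConcordanceReport",
    "assign_group",
    "feature_concordance",
    "cohort_concordance_summary",
    "her2_from_cn",
    "load_example_clinical",
]

FEATURES = ("histology", "er", "her2", "subtype")
METACHRONOUS_DAYS = 183  # six months
_ND = "ND"


@dataclass
class ConcordanceReport:
    """Feature-level concordance between one patient's two tumours."""

    patient_id: str
    status: dict[str, str]  # feature -> concordant | discordant | not_evaluable

    @property
    def n_discordant(self) -> int:
        return sum(1 for s in self.status.values() if s == "discordant")

    @property
    def overall(self) -> str:
        return "discordant" if self.n_discordant >= 1 else "concordant"

    @property
    def discordant_features(self) -> list[str]:
        return [f for f in FEATURES if self.status[f] == "discordant"]


def assign_group(record: ClinicalRecord) -> str:
    """BM/BS/IM/IS from laterality and the >6-month metachronicity rule."""
    metachronous = record.interval_days > METACHRONOUS_DAYS
    return record.laterality[0].upper() + ("M" if metachronous else "S")


def feature_concordance(record: ClinicalRecord) -> ConcordanceReport:
    """Compare histology, ER, HER2 and molecular subtype between tumours."""
    status = {}
    for feat in FEATURES:
        v1, v2 = getattr(record, feat)
        if v1 == _ND or v2 == _ND:
            status[feat] = "not_evaluable"
        elif v1 == v2:
            status[feat] = "concordant"
        else:
            status[feat] = "discordant"
    return ConcordanceReport(record.patient_id, status)


def cohort_concordance_summary(records: list[ClinicalRecord]) -> dict:
    """Cohort-level concordance counts.

    Returns per-feature ``(n_discordant, n_evaluable)``, the number of
    discordant patients out of the cohort, and the number of patients
    with exactly two discordant features.
    """
    if not records:
        raise ValueError("need at least one clinical record")
    reports = [feature_concordance(r) for r in records]
    per_feature = {}
    for feat in FEATURES:
        n_eval = sum(1 for r in reports if r.status[feat] != "not_evaluable")
        n_disc = sum(1 for r in reports if r.status[feat] == "discordant")
        per_feature[feat] = (n_disc, n_eval)
    return {
        "per_feature": per_feature,
        "n_patients": len(records),
        "n_discordant_patients": sum(1 for r in reports if r.overall == "discordant"),
        "n_two_discordant": sum(1 for r in reports if r.n_discordant == 2),
        "reports": reports,
    }


def her2_from_cn(log2_ratio_at_locus: float) -> str:
    """HER2 status from the copy-number log2 ratio at the ERBB2 locus.

    Positive at log2 ratio >= +0.5 (inclusive), negative below.
    """
    import math

    if not math.isfinite(log2_ratio_at_locus):
        raise ValueError("log2 ratio must be finite")
    return "pos" if log2_ratio_at_locus >= 0.5 else "neg"


def load_example_clinical() -> list[ClinicalRecord]:
    """Load the bundled 37-patient paired-breast-tumour clinical table."""
    from . import io as cio

    ref = resources.files("clonemate.data").joinpath("breast_pair_clinical.csv")
    with resources.as_file(ref) as path:
        return cio.read_clinical(path)
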