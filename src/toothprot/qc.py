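"""Identification-quality filtering and batch intersection.

Each acquisition batch is filtered independently: a protein survives
only if its identification q-value is at most ``q_max``, it is
represented by at least ``min_peptides`` distinct peptides and at least
``min_psms`` peptide-spectrum matches.  The combined group (CG) is the
set of accessions surviving QC in *both* batches.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .io_formats import GroupDataset, QuantRecord, ValidationError

__all__ = ["QcThresholds", "apply_qc", "qc_reasons", "intersect_groups"]


@dataclass(frozen=True)
class QcThresholds:
    """Inclusive retention thresholds.

    Defaults encode the conventional exclusion rules "q-value greater
    than 0.05", "fewer than two peptides" and "three or fewer PSMs":
    a record with q = 0.05, 2 peptides and 4 PSMs is kept.
    """

    q_max: float = 0.05
    min_peptides: int = 2
    min_psms: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.q_max <= 1.0):
            raise ValidationError(f"q_max must be in (0, 1], got {self.q_max}")
        if self.min_peptides < 0 or self.min_psms < 0:
            raise ValidationError("min_peptides and min_psms must be >= 0")

    def passes(self, rec: QuantRecord) -> bool:
        return (
            rec.q_value <= self.q_max
            and rec.n_peptides >= self.min_peptides
            and rec.n_psms >= self.min_psms
        )


def apply_qc(dataset: GroupDataset, thresholds: QcThresholds) -> GroupDataset:
    """Return a new dataset holding exactly the records passing QC.

    Record order is preserved and the input is left untouched.
    """
    kept = [rec for rec in dataset.records if thresholds.passes(rec)]
    return GroupDataset(batch=dataset.batch, records=kept, design=list(dataset.design))


def qc_reasons(dataset: GroupDataset, thresholds: QcThresholds) -> Counter:
    """Count removal reasons (a record may fail several filters)."""
    reasons: Counter = Counter()
    for rec in dataset.records:
        if rec.q_value > thresholds.q_max:
            reasons["q_value"] += 1
        if rec.n_peptides < thresholds.min_peptides:
            reasons["n_peptides"] += 1
        if rec.n_psms < thresholds.min_psms:
            reasons["n_psms"] += 1
    return reasons


def intersect_groups(a: GroupDataset, b: GroupDataset) -> list[str]:
    """Accessions present in both batches (the CG), sorted lexicographically."""
    return sorted(set(a.accessions()) & set(b.accessions()))
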