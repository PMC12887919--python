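"""Pairwise abundance ratios, censoring, significance and CGSig selection.

Every treatment specimen is compared against every control specimen of
the same batch (a 2+2 batch yields 4 comparisons; the two-batch design
yields 8).  For each protein and comparison the abundance ratio is

    raw_ratio = abundance(treatment) / abundance(control)

on normalized intensities, log2-transformed and censored at +/-cap
(default 3.32 = log2 10, i.e. raw ratios clamped to [0.1, 10]).  The
per-comparison p-value is a two-sided one-sample t-test of the protein's
peptide-level log2 ratios against 0, Benjamini-Hochberg adjusted across
proteins within the comparison.

A CG protein enters CGSig when at least one comparison is significant
(adj p <= alpha) in *each* batch and its ratio is missing in fewer than
two of the comparisons (pooled over both batches).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GroupDataset, QuantRecord, SpecimenDesign, ValidationError

__all__ = [
    "DEFAULT_CAP",
    "ComparisonSpec",
    "RatioResult",
    "build_comparisons",
    "normalize_abundances",
    "censored_log2",
    "comparison_pvalues",
    "compute_ratio_results",
    "select_cgsig",
    "ratios_to_frame",
    "volcano_frame",
]

#: log2 censoring bound; +/-3.32 = log2(10) caps raw ratios at [0.1, 10].
DEFAULT_CAP = 3.32


@dataclass(frozen=True)
class ComparisonSpec:
    """One treatment-over-control pairing within a batch."""

    comparison_id: str
    batch: str
    treatment: str
    control: str


@dataclass(frozen=True)
class RatioResult:
    """One protein x one comparison.

    A missing ``raw_ratio`` (either specimen unobserved) forces every
    downstream field to be missing as well.
    """

    accession: str
    comparison_id: str
    raw_ratio: Optional[float]
    log2_ratio: Optional[float]
    censored: bool
    p_value: Optional[float]
    adj_p_value: Optional[float]

    @property
    def missing(self) -> bool:
        return self.raw_ratio is None

    def significant(self, alpha: float) -> bool:
        return self.adj_p_value is not None and self.adj_p_value <= alpha


def build_comparisons(design: Sequence[SpecimenDesign]) -> list[ComparisonSpec]:
    """Full treatment x control cross within each batch.

    Specimens are ordered by id within arm, so comparison ids are stable
    across runs.
    """
    specs: list[ComparisonSpec] = []
    batches = sorted({d.batch for d in design})
    for batch in batches:
        treatments = sorted(
            d.specimen_id for d in design if d.batch == batch and d.arm == "treatment"
        )
        controls = sorted(
            d.specimen_id for d in design if d.batch == batch and d.arm == "control"
        )
        if not treatments or not controls:
            raise ValidationError(f"batch {batch} lacks a treatment or control arm")
        for t in treatments:
            for c in controls:
                specs.append(
                    ComparisonSpec(
                        comparison_id=f"{batch}:{t}/{c}",
                        batch=batch,
                        treatment=t,
                        control=c,
                    )
                )
    return specs


def normalize_abundances(dataset: GroupDataset) -> GroupDataset:
    """Rescale each specimen so all share the same total intensity.

    The common total is the median of the per-specimen totals (computed
    over observed protein-level abundances); peptide-level abundances
    are scaled by the same per-specimen factor so protein and peptide
    ratios stay consistent.  Missing values are untouched.
    """
    sids = dataset.specimen_ids
    totals = {}
    for sid in sids:
        total = sum(
            rec.abundances.get(sid) or 0.0
            for rec in dataset.records
            if rec.abundances.get(sid) is not None
        )
        if total <= 0:
            raise ValidationError(f"specimen {sid} has no observed abundances")
        totals[sid] = total
    target = float(np.median(list(totals.values())))
    factors = {sid: target / totals[sid] for sid in sids}

    def scale(mapping, factor_lookup):
        return {
            sid: (None if v is None else v * factor_lookup[sid])
            for sid, v in mapping.items()
        }

    records = []
    for rec in dataset.records:
        peptides = None
        if rec.peptide_abundances is not None:
            peptides = {
                pid: scale(per_spec, factors)
                for pid, per_spec in rec.peptide_abundances.items()
            }
        records.append(
            replace(
                rec,
                abundances=scale(rec.abundances, factors),
                peptide_abundances=peptides,
            )
        )
    return GroupDataset(batch=dataset.batch, records=records, design=list(dataset.design))


def censored_log2(
    raw_ratio: Optional[float], cap: float = DEFAULT_CAP
) -> tuple[Optional[float], bool]:
    """Log2-transform and clamp a raw abundance ratio to [-cap, +cap].

    Returns ``(log2_ratio, censored)``; a missing ratio propagates.
    """
    if raw_ratio is None:
        return None, False
    if not (raw_ratio > 0 and math.isfinite(raw_ratio)):
        raise ValidationError(f"raw ratio must be positive, got {raw_ratio!r}")
    value = math.log2(raw_ratio)
    if value > cap:
        return cap, True
    if value < -cap:
        return -cap, True
    return value, False


def _one_sample_t(log_ratios: np.ndarray) -> Optional[float]:
    """Two-sided one-sample t-test of log2 peptide ratios against 0.

    Zero-variance convention: all ratios exactly at the null value give
    p = 1; all at a common non-null value give no p (the statistic is
    undefined, not infinitely significant).
    """
    n = log_ratios.size
    if n < 2:
        return None
    sd = float(np.std(log_ratios, ddof=1))
    mean = float(np.mean(log_ratios))
    if sd == 0.0:
        return 1.0 if mean == 0.0 else None
    t = mean / (sd / math.sqrt(n))
    return 2.0 * float(stats.t.sf(abs(t), n - 1))


def comparison_pvalues(
    dataset: GroupDataset,
    spec: ComparisonSpec,
    adjust: str = "bh",
) -> dict[str, tuple[Optional[float], Optional[float]]]:
    """Per-protein (p, adjusted p) for one treatment/control comparison.

    Peptides missing on either side are excluded; proteins with fewer
    than two usable peptide ratios get a missing p.  ``adjust`` is one
    of ``bh`` (Benjamini-Hochberg, default), ``bonferroni`` or ``none``;
    adjustment runs across all proteins within the comparison.
    """
    known = set(dataset.specimen_ids)
    for sid in (spec.treatment, spec.control):
        if sid not in known:
            raise ValidationError(f"specimen {sid} absent from dataset {dataset.batch}")
    pvals: dict[str, Optional[float]] = {}
    for rec in dataset.records:
        if not rec.peptide_abundances:
            pvals[rec.accession] = None
            continue
        ratios = []
        for per_spec in rec.peptide_abundances.values():
            a_t = per_spec.get(spec.treatment)
            a_c = per_spec.get(spec.control)
            if a_t is not None and a_c is not None:
                ratios.append(math.log2(a_t / a_c))
        pvals[rec.accession] = _one_sample_t(np.array(ratios, dtype=float))

    accs = [a for a, p in pvals.items() if p is not None]
    out: dict[str, tuple[Optional[float], Optional[float]]] = {
        a: (None, None) for a in pvals
    }
    if accs:
        raw = np.array([pvals[a] for a in accs], dtype=float)
        if adjust == "bh":
            adj = multipletests(raw, method="fdr_bh")[1]
        elif adjust == "bonferroni":
            adj = np.minimum(raw * raw.size, 1.0)
        elif adjust == "none":
            adj = raw
        else:
            raise ValidationError(f"unknown adjustment {adjust!r}")
        for a, p, ap in zip(accs, raw, adj):
            out[a] = (float(p), float(ap))
    return out


def compute_ratio_results(
    dataset: GroupDataset,
    comparisons: Sequence[ComparisonSpec],
    cap: float = DEFAULT_CAP,
    adjust: str = "bh",
    restrict_to: Optional[Iterable[str]] = None,
) -> list[RatioResult]:
    """Ratio, censored log2 ratio and (adjusted) p for every protein and
    comparison of one batch.

    ``restrict_to`` optionally limits output to a set of accessions
    (e.g. the CG) — p-value adjustment still runs across the full table
    so adjusted values do not depend on the restriction.
    """
    keep = set(restrict_to) if restrict_to is not None else None
    results: list[RatioResult] = []
    for spec in comparisons:
        if spec.batch != dataset.batch:
            continue
        pmap = comparison_pvalues(dataset, spec, adjust=adjust)
        for rec in dataset.records:
            if keep is not None and rec.accession not in keep:
                continue
            a_t = rec.abundances.get(spec.treatment)
            a_c = rec.abundances.get(spec.control)
            if a_t is None or a_c is None:
                results.append(
                    RatioResult(rec.accession, spec.comparison_id, None, None,
                                False, None, None)
                )
                continue
            raw = a_t / a_c
            log2_ratio, censored = censored_log2(raw, cap=cap)
            p, adj_p = pmap[rec.accession]
            results.append(
                RatioResult(rec.accession, spec.comparison_id, raw, log2_ratio,
                            censored, p, adj_p)
            )
    return results


def select_cgsig(
    ratios_g1: Sequence[RatioResult],
    ratios_g2: Sequence[RatioResult],
    alpha: float = 0.05,
    max_missing: int = 1,
) -> list[str]:
    """Select significantly differentially expressed CG proteins (CGSig).

    A protein is batch-significant when at least one of its comparisons
    in that batch has adjusted p <= ``alpha``; it is discarded when its
    ratio is missing in more than ``max_missing`` comparisons pooled
    over both batches.  CGSig holds the proteins batch-significant in
    both batches and not discarded, sorted lexicographically.  At the
    limiting ``alpha = 1.0`` every protein with a computable p in each
    batch survives the significance step.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")

    def batch_significant(results: Sequence[RatioResult]) -> set[str]:
        sig: set[str] = set()
        for r in results:
            if r.significant(alpha):
                sig.add(r.accession)
        return sig

    sig_both = batch_significant(ratios_g1) & batch_significant(ratios_g2)
    missing_counts: dict[str, int] = {}
    for r in list(ratios_g1) + list(ratios_g2):
        if r.missing:
            missing_counts[r.accession] = missing_counts.get(r.accession, 0) + 1
    return sorted(
        a for a in sig_both if missing_counts.get(a, 0) <= max_missing
    )


def ratios_to_frame(results: Sequence[RatioResult]) -> pd.DataFrame:
    """Long-format DataFrame of ratio results (one row per protein x comparison)."""
    return pd.DataFrame(
        {
            "accession": [r.accession for r in results],
            "comparison_id": [r.comparison_id for r in results],
            "raw_ratio": [r.raw_ratio for r in results],
            "log2_ratio": [r.log2_ratio for r in results],
            "censored": [r.censored for r in results],
            "p_value": [r.p_value for r in results],
            "adj_p_value": [r.adj_p_value for r in results],
            "missing": [r.missing for r in results],
        }
    )


def volcano_frame(
    results: Sequence[RatioResult], comparison_id: str
) -> pd.DataFrame:
    """(log2 ratio, -log10 adjusted p) pairs for one comparison's volcano plot."""
    rows = [
        r
        for r in results
        if r.comparison_id == comparison_id
        and r.log2_ratio is not None
        and r.adj_p_value is not None
    ]
    neglog = [
        -math.log10(r.adj_p_value) if r.adj_p_value > 0 else math.inf for r in rows
    ]
    return pd.DataFrame(
        {
            "accession": [r.accession for r in rows],
            "log2_ratio": [r.log2_ratio for r in rows],
            "neg_log10_adj_p": neglog,
        }
    )
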