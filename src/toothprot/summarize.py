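"""Per-protein summarization of significant comparisons.

The report mean is the average of the *uncensored* significant log2
ratios: comparisons pinned at the +/-cap sentinels carry no usable
magnitude, so they contribute only to the up/down counts.  A mean is
withheld (the record is "unstable") when no uncensored significant
value exists, when the mean is too close to zero (|mean| < epsilon), or
when removing any single value would flip the mean's sign; unstable
records report the up/down counts instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .differential import DEFAULT_CAP, RatioResult
from .io_formats import ValidationError

__all__ = ["CgSigRecord", "summarize_protein", "build_table1"]


@dataclass(frozen=True)
class CgSigRecord:
    """Table-1-style summary for one CGSig protein."""

    accession: str
    mean_log2fc: Optional[float]
    direction: str  # "Up" | "Down" | "Mixed"
    n_up: int
    n_down: int
    n_censored: int
    stable: bool
    gene: Optional[str] = None

    @property
    def updown_label(self) -> str:
        """Rendering for the Up/down column: mean direction or ``xU/yD``."""
        if self.stable:
            return self.direction
        return f"{self.n_up}U/{self.n_down}D"


def summarize_protein(
    results: Sequence[RatioResult],
    alpha: float = 0.05,
    epsilon: float = 0.3,
    cap: float = DEFAULT_CAP,
    gene: Optional[str] = None,
) -> CgSigRecord:
    """Collapse one protein's per-comparison results into a summary record.

    ``results`` must all belong to a single accession and contain at
    least one significant comparison (CGSig membership guarantees
    this).  The result is independent of comparison order.
    """
    accessions = {r.accession for r in results}
    if len(accessions) != 1:
        raise ValidationError(f"results span several accessions: {sorted(accessions)}")
    accession = accessions.pop()

    significant = [
        r for r in results if r.significant(alpha) and r.log2_ratio is not None
    ]
    if not significant:
        raise ValidationError(
            f"{accession}: no significant comparisons — not a CGSig member"
        )
    n_up = sum(1 for r in significant if r.log2_ratio > 0)
    n_down = sum(1 for r in significant if r.log2_ratio < 0)
    n_censored = sum(1 for r in significant if r.censored)

    uncensored = sorted(r.log2_ratio for r in significant if not r.censored)
    stable = bool(uncensored)
    mean: Optional[float] = None
    if uncensored:
        mean = sum(uncensored) / len(uncensored)
        if abs(mean) < epsilon:
            stable = False
        elif len(uncensored) > 1:
            # leave-one-out sign check
            total = sum(uncensored)
            for v in uncensored:
                loo = (total - v) / (len(uncensored) - 1)
                if loo == 0.0 or (loo > 0) != (mean > 0):
                    stable = False
                    break

    if stable:
        direction = "Up" if mean > 0 else "Down"
    else:
        if n_up > n_down:
            direction = "Up"
        elif n_down > n_up:
            direction = "Down"
        else:
            direction = "Mixed"
        mean = None
    return CgSigRecord(
        accession=accession,
        mean_log2fc=mean,
        direction=direction,
        n_up=n_up,
        n_down=n_down,
        n_censored=n_censored,
        stable=stable,
        gene=gene,
    )


def build_table1(
    records: Sequence[CgSigRecord],
    category_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Assemble the differential-expression report.

    Rows are grouped by functional category (proteins without a label
    fall under "Unknown") and ordered by mean log2 fold change within a
    category; unstable records render an empty mean and an ``xU/yD``
    up/down label.
    """
    category_map = category_map or {}
    rows = []
    for rec in records:
        rows.append(
            {
                "accession": rec.accession,
                "gene": rec.gene or "",
                "category": category_map.get(rec.accession, "Unknown"),
                "mean_log2fc": rec.mean_log2fc,
                "up_down": rec.updown_label,
                "n_up": rec.n_up,
                "n_down": rec.n_down,
                "n_censored": rec.n_censored,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "accession", "gene", "category", "mean_log2fc", "up_down",
            "n_up", "n_down", "n_censored",
        ],
    )
    if not frame.empty:
        frame = frame.sort_values(
            ["category", "mean_log2fc", "accession"], na_position="last"
        ).reset_index(drop=True)
    return frame
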