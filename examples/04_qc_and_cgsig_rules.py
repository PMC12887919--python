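"""The selection rules on a miniature hand-built experiment.

A handful of proteins illustrate the decision boundaries: QC keeps a
protein with q = 0.05, 2 peptides and 4 PSMs but drops one with 3 PSMs;
the combined group (CG) needs presence in both batches; CGSig needs a
significant comparison in each batch and fewer than two missing
comparisons; censored ratios sit exactly at +/-3.32.
"""

import numpy as np

from toothprot.differential import (
    build_comparisons,
    censored_log2,
    compute_ratio_results,
    select_cgsig,
)
from toothprot.io_formats import GroupDataset, QuantRecord, SpecimenDesign
from toothprot.qc import QcThresholds, apply_qc, intersect_groups

rng = np.random.default_rng(0)


def record(acc, q, n_pep, n_psm, shift, sids):
    """A protein whose treatment specimens are shifted by `shift` log2 units."""
    peptides = {}
    for j in range(max(n_pep, 2)):
        base = float(rng.lognormal(5, 0.3))
        per_spec = {}
        for sid in sids:
            noise = 2.0 ** rng.normal(0.0, 0.2)
            level = base * (2.0 ** shift if sid.startswith("T") else 1.0)
            per_spec[sid] = level * noise
        peptides[f"pep{j + 1}"] = per_spec
    abundances = {
        sid: sum(per_spec[sid] for per_spec in peptides.values()) for sid in sids
    }
    return QuantRecord(accession=acc, q_value=q, n_peptides=n_pep, n_psms=n_psm,
                       abundances=abundances, peptide_abundances=peptides)


def batch(name, sids):
    design = [
        SpecimenDesign(s, name, "treatment" if s.startswith("T") else "control",
                       f"L{i}")
        for i, s in enumerate(sids)
    ]
    records = [
        record("UP_BOTH", 0.01, 6, 18, +2.0, sids),  # real effect, both batches
        record("Q_BOUND", 0.05, 2, 4, 0.0, sids),    # QC boundary values: kept
        record("PSM_FAIL", 0.01, 5, 3, +2.0, sids),  # 3 PSMs: removed by QC
        record("G1_ONLY", 0.01, 6, 18, +2.0 if name == "group1" else 0.0, sids),
    ]
    # null proteins give the within-comparison BH adjustment a family
    records += [
        record(f"NULL_{i:02d}", 0.01, 6, 18, 0.0, sids) for i in range(20)
    ]
    return GroupDataset(batch=name, records=records, design=design)


g1 = batch("group1", ["T1", "T2", "C1", "C2"])
g2 = batch("group2", ["T3", "T4", "C3", "C4"])

kept1, kept2 = (apply_qc(g, QcThresholds()) for g in (g1, g2))
named = [a for a in kept1.accessions() if not a.startswith("NULL")]
print("after QC (q <= 0.05, >= 2 peptides, >= 4 PSMs):")
print(f"  each batch keeps {named} + 20 null proteins")
print("  PSM_FAIL is gone (3 PSMs); Q_BOUND survives at q exactly 0.05")

cg = intersect_groups(kept1, kept2)
print(f"CG: {len(cg)} proteins present in both batches")

# the toy data are generated on a common intensity scale already, and
# with so few proteins total-intensity normalization would itself be
# biased by the planted 4-fold protein, so it is skipped here
comparisons = build_comparisons(kept1.design + kept2.design)
r1 = compute_ratio_results(kept1, comparisons, restrict_to=cg)
r2 = compute_ratio_results(kept2, comparisons, restrict_to=cg)
cgsig = select_cgsig(r1, r2, alpha=0.05)
print(f"CGSig (adj p <= 0.05 in >= 1 comparison of EACH batch, < 2 missing): {cgsig}")
if "G1_ONLY" not in cgsig:
    print("  G1_ONLY is excluded: its effect exists only in batch 1")

print("\ncensoring at the +/-3.32 sentinels (a 10-fold cap on raw ratios):")
for raw in (1.0, 0.5, 12.0, 1 / 4000):
    value, censored = censored_log2(raw)
    print(f"  raw ratio {raw:>9.4g} -> log2 {value:+.2f} censored={censored}")
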