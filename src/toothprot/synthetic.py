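"""Ground-truth synthetic data emulating a two-batch label-free study.

The generator mirrors the statistical structure of a dual-batch tooth
proteomics experiment: two acquisition batches ("group1", "group2"),
each with its own treatment and control specimens, a shared protein
universe detected per batch with different probabilities (so the two
tables overlap only partially), planted signed log2 effects on a small
fraction of proteins, peptide-level multiplicative noise, and
intensity-dependent (missing-not-at-random) dropout: an observation
goes missing with probability ``logistic(mnar_slope * (mnar_threshold -
log2 abundance))``, so faint proteins vanish more often.

Identification metadata (q-value, peptide count, PSM count) is drawn so
a configurable fraction of proteins fails each QC filter.  Pathway
annotations and landmark sets with known effects complete the inputs
needed to exercise every pipeline stage.  All generators are pure
functions of their configuration, including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.special import expit

from .io_formats import (
    GroupDataset,
    LandmarkSet,
    PathwaySet,
    QuantRecord,
    SpecimenDesign,
    ValidationError,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_quant_experiment",
    "generate_pathway_sets",
    "generate_landmark_sets",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic two-batch experiment.

    Defaults are sized to the emulated study: a ~2,400-protein
    universe with per-batch detection probabilities chosen so the two
    mapped tables hold roughly 2,200 and 1,600 proteins with ~1,500
    shared.  Effects are log2 fold changes; ``peptide_noise_sd`` is the
    standard deviation of per-peptide, per-specimen log2 noise.
    """

    n_proteins: int = 2400
    detect_prob_g1: float = 0.95
    detect_prob_g2: float = 0.70
    n_treatment: int = 2
    n_control: int = 2
    frac_de: float = 0.05
    effect_range: tuple[float, float] = (1.0, 2.5)
    peptide_noise_sd: float = 0.4
    peptide_offset_sd: float = 1.0
    n_peptides_range: tuple[int, int] = (2, 12)
    baseline_mean: float = 20.0
    baseline_sd: float = 2.5
    mnar_threshold: float = 15.0
    mnar_slope: float = 1.0
    frac_fail_q: float = 0.02
    frac_fail_peptides: float = 0.02
    frac_fail_psms: float = 0.02
    ratio_cap: float = 3.32
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("detect_prob_g1", "detect_prob_g2", "frac_de",
                     "frac_fail_q", "frac_fail_peptides", "frac_fail_psms"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be positive")
        lo, hi = self.effect_range
        if not (0.0 < lo <= hi):
            raise ValidationError("effect_range must be a positive interval")
        if self.ratio_cap <= 0:
            raise ValidationError("ratio_cap must be positive")
        if self.peptide_noise_sd < 0:
            raise ValidationError("peptide_noise_sd must be >= 0")
        k_lo, k_hi = self.n_peptides_range
        if not (1 <= k_lo <= k_hi):
            raise ValidationError("n_peptides_range must be a positive interval")
        if self.n_treatment < 1 or self.n_control < 1:
            raise ValidationError("each batch needs >=1 treatment and control")


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside generated data."""

    planted: dict[str, float] = field(default_factory=dict)
    enriched_pathways: set[str] = field(default_factory=set)
    landmark_effects: dict[str, float] = field(default_factory=dict)


def _accessions(n: int) -> list[str]:
    return [f"SYN{i:05d}" for i in range(1, n + 1)]


def _batch_design(
    batch: str, t_start: int, c_start: int, n_t: int, n_c: int
) -> list[SpecimenDesign]:
    design = []
    for j in range(n_t):
        idx = t_start + j
        design.append(
            SpecimenDesign(f"T{idx}", batch, "treatment", litter_id=f"L{idx}")
        )
    for j in range(n_c):
        idx = c_start + j
        design.append(
            SpecimenDesign(f"C{idx}", batch, "control", litter_id=f"L{idx + 100}")
        )
    return design


def _fail_mask(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    n_fail = int(round(frac * n))
    if n_fail:
        mask[rng.choice(n, size=n_fail, replace=False)] = True
    return mask


def _generate_batch(
    rng: np.random.Generator,
    config: SyntheticConfig,
    batch: str,
    design: list[SpecimenDesign],
    accessions: list[str],
    baseline: np.ndarray,
    effects: np.ndarray,
    detected: np.ndarray,
) -> GroupDataset:
    idx_detected = np.flatnonzero(detected)
    m = idx_detected.size
    k_lo, k_hi = config.n_peptides_range
    k_counts = rng.integers(k_lo, k_hi + 1, size=m)
    fail_q = _fail_mask(rng, m, config.frac_fail_q)
    fail_pep = _fail_mask(rng, m, config.frac_fail_peptides)
    fail_psm = _fail_mask(rng, m, config.frac_fail_psms)
    k_counts[fail_pep] = 1
    q_ok = rng.uniform(0.0, 0.045, size=m)
    q_bad = rng.uniform(0.051, 0.3, size=m)
    psm_mult = rng.integers(2, 6, size=m)
    psm_bad = rng.integers(0, 4, size=m)

    arms = np.array([1.0 if d.arm == "treatment" else 0.0 for d in design])
    sids = [d.specimen_id for d in design]
    n_spec = len(sids)

    records = []
    for row, i in enumerate(idx_detected):
        k = int(k_counts[row])
        true_log2 = baseline[i] + effects[i] * arms  # per specimen
        offsets = rng.normal(0.0, config.peptide_offset_sd, size=k)
        noise = rng.normal(0.0, config.peptide_noise_sd, size=(k, n_spec))
        pep_log2 = true_log2[None, :] + offsets[:, None] + noise
        pep_linear = np.exp2(pep_log2)
        protein_linear = pep_linear.sum(axis=0)
        drop_p = expit(config.mnar_slope * (config.mnar_threshold - np.log2(protein_linear)))
        dropped = rng.random(n_spec) < drop_p

        abundances: dict[str, Optional[float]] = {}
        peptides: dict[str, dict[str, Optional[float]]] = {
            f"pep{j + 1}": {} for j in range(k)
        }
        for s, sid in enumerate(sids):
            if dropped[s]:
                abundances[sid] = None
                for j in range(k):
                    peptides[f"pep{j + 1}"][sid] = None
            else:
                abundances[sid] = float(protein_linear[s])
                for j in range(k):
                    peptides[f"pep{j + 1}"][sid] = float(pep_linear[j, s])

        fully_missing = bool(dropped.all())
        # A protein identified but never quantified carries no peptide
        # evidence in this batch; it is kept in the mapped table and
        # later removed by the QC peptide filter.
        n_peptides = 0 if fully_missing else k
        n_psms = 0 if fully_missing else int(
            psm_bad[row] if fail_psm[row] else k * psm_mult[row]
        )
        records.append(
            QuantRecord(
                accession=accessions[i],
                q_value=float(q_bad[row] if fail_q[row] else q_ok[row]),
                n_peptides=n_peptides,
                n_psms=n_psms,
                abundances=abundances,
                peptide_abundances=None if fully_missing else peptides,
            )
        )
    return GroupDataset(batch=batch, records=records, design=design)


def generate_quant_experiment(
    config: SyntheticConfig,
) -> tuple[GroupDataset, GroupDataset, SyntheticTruth]:
    """Generate both batches' quantification tables plus ground truth.

    Per protein, a baseline log2 abundance is drawn from
    N(baseline_mean, baseline_sd); treatment specimens are shifted by
    the planted signed effect (0 for null proteins).  Peptide-level
    abundances multiply the protein abundance by a per-peptide offset
    and per-observation noise (all lognormal); the protein intensity is
    the sum of its peptide intensities, so protein-level ratios track
    the planted effects.  Dropout and QC metadata follow the module
    docstring.  Reproducible bit-for-bit from the seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    accessions = _accessions(n)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    detected_g1 = rng.random(n) < config.detect_prob_g1
    detected_g2 = rng.random(n) < config.detect_prob_g2

    # plant effects only on proteins mapped in at least one batch, so the
    # ground-truth bookkeeping (every planted accession appears in some
    # table) holds by construction
    detectable = np.flatnonzero(detected_g1 | detected_g2)
    n_de = min(int(round(config.frac_de * n)), detectable.size)
    effects = np.zeros(n)
    planted_idx = (
        rng.choice(detectable, size=n_de, replace=False)
        if n_de
        else np.array([], dtype=int)
    )
    if n_de:
        lo, hi = config.effect_range
        magnitudes = rng.uniform(lo, hi, size=n_de)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        effects[planted_idx] = signs * magnitudes
    truth = SyntheticTruth(
        planted={accessions[i]: float(effects[i]) for i in planted_idx}
    )

    design_g1 = _batch_design("group1", 1, 1, config.n_treatment, config.n_control)
    design_g2 = _batch_design(
        "group2",
        config.n_treatment + 1,
        config.n_control + 1,
        config.n_treatment,
        config.n_control,
    )
    g1 = _generate_batch(
        rng, config, "group1", design_g1, accessions, baseline, effects,
        detected_g1,
    )
    g2 = _generate_batch(
        rng, config, "group2", design_g2, accessions, baseline, effects,
        detected_g2,
    )
    return g1, g2, truth


def generate_pathway_sets(
    universe: Sequence[str],
    truth: SyntheticTruth,
    n_pathways: int,
    sizes: tuple[int, int] = (20, 400),
    seed: int = 0,
    n_enriched: int = 0,
    enriched_fraction: float = 0.8,
) -> list[PathwaySet]:
    """Annotation sets with optional planted over-representation.

    The first ``n_enriched`` pathways draw ``enriched_fraction`` of
    their members from the planted accessions (capped at the number of
    planted proteins) and the rest uniformly from the remainder of the
    universe; null pathways draw uniformly from the whole universe.
    Ids of enriched pathways are added to ``truth.enriched_pathways``.
    """
    if not universe:
        raise ValidationError("universe is empty")
    lo, hi = sizes
    if not (1 <= lo <= hi):
        raise ValidationError("sizes must be a positive interval")
    if hi > len(universe):
        raise ValidationError(
            f"requested pathway size {hi} exceeds universe {len(universe)}"
        )
    if n_enriched > n_pathways:
        raise ValidationError("n_enriched exceeds n_pathways")
    planted = sorted(set(truth.planted) & set(universe))
    if n_enriched and not planted:
        raise ValidationError("cannot plant enriched pathways without planted proteins")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    others = sorted(set(universe) - set(planted))
    pathways = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        pid = f"SYNPW{i + 1:04d}"
        if i < n_enriched:
            n_planted = min(int(round(enriched_fraction * size)), len(planted))
            chosen = list(rng.choice(planted, size=n_planted, replace=False))
            n_rest = size - n_planted
            if n_rest:
                chosen += list(rng.choice(others, size=n_rest, replace=False))
            truth.enriched_pathways.add(pid)
            name = "planted enriched pathway"
        else:
            chosen = list(rng.choice(universe, size=size, replace=False))
            name = "null pathway"
        pathways.append(PathwaySet(pid, name, frozenset(chosen)))
    return pathways


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _molar_outline(area: float, n_points: int = 25, aspect: float = 1.6) -> np.ndarray:
    """25 planar points on an ellipse whose inscribed polygon has the
    requested convex-hull area exactly."""
    theta = 2.0 * math.pi * np.arange(n_points) / n_points
    # polygon area of the inscribed ellipse polygon: (n/2) a b sin(2 pi / n)
    ab = 2.0 * area / (n_points * math.sin(2.0 * math.pi / n_points))
    a = math.sqrt(ab * aspect)
    b = math.sqrt(ab / aspect)
    return np.column_stack(
        [a * np.cos(theta), b * np.sin(theta), np.zeros(n_points)]
    )


def generate_landmark_sets(
    n_per_group: int,
    effects: Optional[Mapping[str, float]] = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    base_length: float = 19.0,
    base_area: float = 1.02,
    molar_noise_sd: Optional[float] = None,
) -> tuple[list[LandmarkSet], list[SpecimenDesign], SyntheticTruth]:
    """Skull and molar landmark sets with known group effects.

    ``effects`` maps trait name (``skull_length_mm``, ``crown_area_mm2``)
    to the true treatment-minus-control mean difference; controls sit at
    the base values.  Each specimen's landmarks receive isotropic
    Gaussian coordinate noise and a random rigid rotation plus
    translation, which the derived phenotypes ignore.  ``noise_sd``
    (mm) applies to the skull landmarks; crown-outline landmarks use
    ``molar_noise_sd``, by default a tenth of it, because the molar is
    an order of magnitude smaller than the skull.
    """
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if molar_noise_sd is None:
        molar_noise_sd = noise_sd / 10.0
    if molar_noise_sd < 0:
        raise ValidationError("molar_noise_sd must be >= 0")
    effects = dict(effects or {})
    d_length = float(effects.get("skull_length_mm", 0.0))
    d_area = float(effects.get("crown_area_mm2", 0.0))
    rng = np.random.default_rng(seed)
    landmark_sets: list[LandmarkSet] = []
    design: list[SpecimenDesign] = []
    for arm, prefix, dl, da in (
        ("control", "C", 0.0, 0.0),
        ("treatment", "T", d_length, d_area),
    ):
        for j in range(1, n_per_group + 1):
            sid = f"PH_{prefix}{j:02d}"
            design.append(
                SpecimenDesign(sid, "phenotyping", arm, litter_id=f"PL{j}")
            )
            length = base_length + dl
            skull_pts = np.array(
                [[-length / 2.0, 0.0, 0.0], [length / 2.0, 0.0, 0.0]]
            )
            molar_pts = _molar_outline(base_area + da)
            for role, pts, labels, sd in (
                ("skull", skull_pts,
                 ["foramen_magnum_apex", "maxillae_junction"], noise_sd),
                ("molar", molar_pts,
                 [f"crown_{k + 1:02d}" for k in range(25)], molar_noise_sd),
            ):
                noisy = pts + rng.normal(0.0, sd, size=pts.shape)
                rot = _random_rotation(rng)
                shift = rng.uniform(-10.0, 10.0, size=3)
                placed = noisy @ rot.T + shift
                landmark_sets.append(
                    LandmarkSet(
                        specimen_id=sid,
                        landmarks=tuple(
                            (label, float(p[0]), float(p[1]), float(p[2]))
                            for label, p in zip(labels, placed)
                        ),
                        role=role,
                    )
                )
    truth = SyntheticTruth(
        landmark_effects={"skull_length_mm": d_length, "crown_area_mm2": d_area}
    )
    return landmark_sets, design, truth
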