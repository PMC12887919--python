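"""End-to-end orchestration: QC -> CG -> ratios -> CGSig -> reports.

A single :class:`PipelineConfig` drives the run.  Inputs are either
files (two quantification tables, a design table, optionally a GMT
annotation, a category map and a landmark directory) or a synthetic
experiment generated in place.  Outputs are CSV/JSON files plus a
manifest recording the configuration hash, derived stage seeds and
stage-by-stage record counts.

One top-level seed derives all stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so partial re-runs of a
stage see the same stream as the full pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .differential import (
    DEFAULT_CAP,
    build_comparisons,
    compute_ratio_results,
    normalize_abundances,
    ratios_to_frame,
    select_cgsig,
    volcano_frame,
)
from .enrichment import enrich, enrichment_to_frame
from .io_formats import (
    GroupDataset,
    ValidationError,
    read_design,
    read_gmt,
    read_landmarks,
    read_quant_table,
    write_design,
    write_landmarks,
    write_quant_table,
)
from .morphometrics import phenotype_table
from .qc import QcThresholds, apply_qc, intersect_groups, qc_reasons
from .reference import DEFAULT_BACKGROUND
from .summarize import build_table1, summarize_protein
from .synthetic import (
    SyntheticConfig,
    generate_landmark_sets,
    generate_pathway_sets,
    generate_quant_experiment,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a run needs, in one place.

    File-mode fields (``group1_table`` ...) and synthetic mode
    (``synthetic=True``) are mutually exclusive ways to obtain inputs;
    all thresholds live here and are echoed into the manifest.
    """

    output_dir: str = "toothprot_run"
    group1_table: Optional[str] = None
    group2_table: Optional[str] = None
    design_table: Optional[str] = None
    gmt_file: Optional[str] = None
    category_map: Optional[str] = None  # JSON accession -> category label
    landmark_dir: Optional[str] = None  # holds <specimen>_<role>.fcsv files
    synthetic: bool = False
    synthetic_config: dict = field(default_factory=dict)
    synthetic_pathways: int = 100
    synthetic_enriched: int = 1
    synthetic_landmarks_per_group: int = 10
    q_max: float = 0.05
    min_peptides: int = 2
    min_psms: int = 4
    alpha: float = 0.05
    cap: float = DEFAULT_CAP
    epsilon: float = 0.3
    max_missing: int = 1
    background: int = DEFAULT_BACKGROUND
    alternative: str = "a_greater"
    adjust: str = "bh"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _load_inputs(config: PipelineConfig, outdir: Path, seeds: list[int]):
    if config.synthetic:
        syn = SyntheticConfig(**{**config.synthetic_config, "seed": seeds[0]})
        g1, g2, truth = generate_quant_experiment(syn)
        size_hi = min(400, max(2, syn.n_proteins // 5))
        pathways = generate_pathway_sets(
            [f"SYN{i:05d}" for i in range(1, syn.n_proteins + 1)],
            truth,
            n_pathways=config.synthetic_pathways,
            sizes=(min(20, size_hi), size_hi),
            seed=seeds[1],
            n_enriched=config.synthetic_enriched,
        )
        landmark_sets, lm_design, lm_truth = generate_landmark_sets(
            n_per_group=config.synthetic_landmarks_per_group,
            effects=None,
            seed=seeds[2],
        )
        truth.landmark_effects = lm_truth.landmark_effects
        inputs = outdir / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        with open(inputs / "group1.tsv", "w") as fh:
            write_quant_table(g1, fh)
        with open(inputs / "group2.tsv", "w") as fh:
            write_quant_table(g2, fh)
        with open(inputs / "design.tsv", "w") as fh:
            write_design(g1.design + g2.design + lm_design, fh)
        from .io_formats import write_gmt

        with open(inputs / "pathways.gmt", "w") as fh:
            write_gmt(pathways, fh)
        for lm in landmark_sets:
            with open(inputs / f"{lm.specimen_id}_{lm.role}.fcsv", "w") as fh:
                write_landmarks(lm, fh)
        with open(inputs / "truth.json", "w") as fh:
            json.dump(
                {
                    "planted": truth.planted,
                    "enriched_pathways": sorted(truth.enriched_pathways),
                    "landmark_effects": truth.landmark_effects,
                },
                fh,
                indent=1,
            )
        category_map: dict[str, str] = {}
        # the synthetic universe, not the organism proteome, is the
        # enrichment background
        return g1, g2, pathways, category_map, landmark_sets, lm_design, syn.n_proteins

    if not (config.group1_table and config.group2_table and config.design_table):
        raise ValidationError(
            "file mode needs group1_table, group2_table and design_table"
        )
    with open(config.design_table) as fh:
        design = read_design(fh)
    batches = sorted({d.batch for d in design if d.batch in ("group1", "group2")})
    if batches != ["group1", "group2"]:
        raise ValidationError("design must cover batches 'group1' and 'group2'")
    with open(config.group1_table) as fh:
        g1 = read_quant_table(fh, [d for d in design if d.batch == "group1"])
    with open(config.group2_table) as fh:
        g2 = read_quant_table(fh, [d for d in design if d.batch == "group2"])
    pathways = []
    if config.gmt_file:
        with open(config.gmt_file) as fh:
            pathways = read_gmt(fh)
    category_map = {}
    if config.category_map:
        with open(config.category_map) as fh:
            category_map = json.load(fh)
    landmark_sets = []
    lm_design = [d for d in design if d.batch not in ("group1", "group2")]
    if config.landmark_dir:
        for path in sorted(Path(config.landmark_dir).glob("*.fcsv")):
            stem = path.stem
            sid, _, role = stem.rpartition("_")
            with open(path) as fh:
                landmark_sets.append(
                    read_landmarks(fh, specimen_id=sid, role=role or None)
                )
    return g1, g2, pathways, category_map, landmark_sets, lm_design, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``<output_dir>/manifest.json``)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    (g1_raw, g2_raw, pathways, category_map, landmark_sets, lm_design,
     background_override) = _load_inputs(config, outdir, seeds)

    thresholds = QcThresholds(
        q_max=config.q_max,
        min_peptides=config.min_peptides,
        min_psms=config.min_psms,
    )
    g1 = apply_qc(g1_raw, thresholds)
    g2 = apply_qc(g2_raw, thresholds)
    cg = intersect_groups(g1, g2)
    (outdir / "cg.txt").write_text("\n".join(cg) + ("\n" if cg else ""))

    g1n = normalize_abundances(g1)
    g2n = normalize_abundances(g2)
    comparisons = build_comparisons(g1.design + g2.design)
    ratios_g1 = compute_ratio_results(
        g1n, comparisons, cap=config.cap, adjust=config.adjust, restrict_to=cg
    )
    ratios_g2 = compute_ratio_results(
        g2n, comparisons, cap=config.cap, adjust=config.adjust, restrict_to=cg
    )
    all_ratios = ratios_g1 + ratios_g2
    ratios_to_frame(all_ratios).to_csv(outdir / "ratios.csv", index=False)
    for spec in comparisons:
        frame = volcano_frame(all_ratios, spec.comparison_id)
        safe = spec.comparison_id.replace(":", "_").replace("/", "_over_")
        frame.to_csv(outdir / f"volcano_{safe}.csv", index=False)

    # counts feeding the manifest: batch-significant sets and the
    # missingness discard rule, surfaced separately so either reading
    # (per-batch or pooled) of the retained/discarded counts can be
    # checked
    def batch_sig(results):
        return {r.accession for r in results if r.significant(config.alpha)}

    retained = sorted(batch_sig(ratios_g1) & batch_sig(ratios_g2))
    cgsig = select_cgsig(
        ratios_g1, ratios_g2, alpha=config.alpha, max_missing=config.max_missing
    )
    discarded = sorted(set(retained) - set(cgsig))
    (outdir / "cgsig.txt").write_text("\n".join(cgsig) + ("\n" if cgsig else ""))

    by_acc: dict[str, list] = {}
    for r in all_ratios:
        by_acc.setdefault(r.accession, []).append(r)
    genes = {rec.accession: rec.gene for rec in g1.records}
    summaries = [
        summarize_protein(
            by_acc[a],
            alpha=config.alpha,
            epsilon=config.epsilon,
            cap=config.cap,
            gene=genes.get(a),
        )
        for a in cgsig
    ]
    table1 = build_table1(summaries, category_map)
    table1.to_csv(outdir / "table1.csv", index=False)

    n_enriched_sig = 0
    if pathways and cgsig:
        background = background_override or config.background
        results = enrich(cgsig, pathways, N=background, alpha=config.alpha)
        enrichment_to_frame(results).to_csv(outdir / "table2.csv", index=False)
        n_enriched_sig = sum(1 for r in results if r.significant)

    phenotypes = []
    if landmark_sets:
        phenotypes = phenotype_table(
            landmark_sets, lm_design, alternative=config.alternative
        )
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "trait": p.trait,
                    "mean_control": p.control_mean,
                    "mean_treatment": p.treatment_mean,
                    "t": p.welch.t,
                    "df": p.welch.df,
                    "p": p.welch.p,
                    "alternative": p.welch.alternative,
                    "ci_lower": p.welch.ci_lower,
                }
                for p in phenotypes
            ]
        ).to_csv(outdir / "table3.csv", index=False)

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "counts": {
            "mapped_group1": len(g1_raw.records),
            "mapped_group2": len(g2_raw.records),
            "post_qc_group1": len(g1.records),
            "post_qc_group2": len(g2.records),
            "qc_reasons_group1": dict(qc_reasons(g1_raw, thresholds)),
            "qc_reasons_group2": dict(qc_reasons(g2_raw, thresholds)),
            "cg": len(cg),
            "retained": len(retained),
            "discarded": len(discarded),
            "cgsig": len(cgsig),
            "comparisons": len(comparisons),
            "enriched_pathways": n_enriched_sig,
            "phenotyped_traits": len(phenotypes),
        },
        "parameters": {
            "q_max": config.q_max,
            "min_peptides": config.min_peptides,
            "min_psms": config.min_psms,
            "alpha": config.alpha,
            "cap": config.cap,
            "epsilon": config.epsilon,
            "max_missing": config.max_missing,
            "background": config.background,
            "alternative": config.alternative,
            "adjust": config.adjust,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
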