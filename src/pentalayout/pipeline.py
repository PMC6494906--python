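"""End-to-end orchestration: synthetic (or pre-parsed) inputs through
preprocess, clustering, stoichiometry and layout, with per-stage outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clustering import ward_cluster, run_sweep
from .config import RunConfig, validate_config
from .expression_io import (
    ExpressionMatrix,
    SampleRecord,
    aggregate_substructures,
    read_expression_table,
)
from .layout import (
    compare_to_reference,
    layout_dendrogram,
    pair_distance_consensus,
    pair_distance_individual,
    reference_similarity,
    stereotypy,
    whole_brain_profiles,
)
from .ontology import default_ontology
from .panel import default_panel
from .preprocess import (
    classify_profiles,
    fold_enrichment,
    global_contribution,
    probe_consistency,
    proportional_contribution,
    select_probes,
)
from .stoichiometry import (
    HIGH_EXPRESSION_GENES,
    consensus_pairs,
    convergence_curve,
    pairwise_correlations,
    profiles_from_composition,
    stoichiometric_gate,
)
from .synthetic import (
    default_nuclei_truth,
    default_regional_truth,
    simulate_nuclei,
    simulate_probes,
    simulate_regional,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _child_seeds(seed: int, n: int) -> List[int]:
    """Deterministic per-stage seed fan-out from the global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def _mean_matrix(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Across-subject mean on the stored scale; columns must align."""
    cols = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != cols:
            shared = [c for c in cols if c in m.sample_ids]
            matrices = [mm.select_samples(
                [mm.sample_ids.index(c) for c in shared]) for mm in matrices]
            cols = shared
            break
    stack = np.stack([m.values for m in matrices])
    records = [
        SampleRecord(sample_id=s.sample_id, subject_id="group",
                     substructure=s.substructure)
        for s in matrices[0].samples
    ]
    return ExpressionMatrix(
        matrices[0].row_ids, records, stack.mean(axis=0),
        matrices[0].scale, matrices[0].unit,
    )


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the configured stages and write the report bundle.

    Returns a dict of in-memory results keyed by stage. Identical
    ``(config, seed)`` produce identical bundles; partial outputs are kept
    when a stage fails.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = default_panel()
    ontology = default_ontology()
    seeds = dict(zip(
        ("regional", "probes", "nuclei", "sweep", "dunnett"),
        _child_seeds(config.seed, 5),
    ))
    meta = {
        "run_id": f"run-{config.config_hash()}-s{config.seed}",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "counts": {},
    }
    results: Dict[str, object] = {"meta": meta}

    def _write_meta() -> None:
        with open(out_dir / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True, default=str)

    # ----- inputs ---------------------------------------------------------
    stage = "inputs"
    try:
        if config.inputs:
            m = read_expression_table(
                config.inputs["expression"],
                config.inputs["annotation"],
                config.inputs.get("dialect", "allen_microarray"),
            )
            subjects = m.subjects()
            subject_matrices = [
                aggregate_substructures(m, ontology, s) for s in subjects
            ]
            probe_matrices, truth_map = None, None
            nuclei_matrix, nuclei_records = None, None
        else:
            syn = config.synthetic
            truth = default_regional_truth(
                n_subjects=int(syn.get("n_subjects", 6)),
                subject_sd=float(syn.get("subject_sd", 0.3)),
                regional_sd=float(syn.get("regional_sd", 1.0)),
            )
            subject_matrices, ontology = simulate_regional(truth, seeds["regional"])
            probe_matrices, truth_map = simulate_probes(
                subject_matrices,
                probes_per_gene=int(syn.get("probes_per_gene", 4)),
                noise_sd=float(syn.get("probe_noise_sd", 0.2)),
                seed=seeds["probes"],
            )
            nuclei_truth = default_nuclei_truth(
                n_nuclei=int(syn.get("nuclei_per_type", 100)),
                tradeoff_pairs=(("GABRB2", "GABRB3", -1, 0.9),),
            )
            nuclei_matrix, nuclei_records = simulate_nuclei(
                nuclei_truth, seeds["nuclei"]
            )
        meta["counts"]["subjects"] = len(subject_matrices)
        meta["counts"]["substructures"] = subject_matrices[0].shape[1]
    except Exception as exc:  # noqa: BLE001
        _write_meta()
        raise PipelineError(stage, exc) from exc

    group = _mean_matrix(subject_matrices)
    composition = proportional_contribution(group, panel)

    # ----- preprocess -----------------------------------------------------
    if "preprocess" in config.stages:
        stage = "preprocess"
        t0 = time.time()
        try:
            if probe_matrices is not None:
                probe_to_gene = {
                    pid: pid.rsplit("_p", 1)[0]
                    for pid in probe_matrices[0].row_ids
                }
                concat = ExpressionMatrix(
                    probe_matrices[0].row_ids,
                    [s for m in probe_matrices for s in m.samples],
                    np.concatenate([m.values for m in probe_matrices], axis=1),
                    probe_matrices[0].scale,
                    probe_matrices[0].unit,
                )
                selected = select_probes(concat, probe_to_gene)
                scores = probe_consistency(probe_matrices, probe_to_gene)
                pd.DataFrame(
                    [
                        {"probe_id": s.probe_id, "gene": s.gene,
                         "loading": s.loading, "consistency": s.consistency}
                        for s in scores
                    ]
                ).to_csv(out_dir / "probe_scores.csv", index=False)
                with open(out_dir / "selected_probes.json", "w") as fh:
                    json.dump(selected, fh, indent=1, sort_keys=True)
                results["selected_probes"] = selected
                if truth_map is not None:
                    recovered = sum(
                        selected.get(g) == p for g, p in truth_map.items()
                    )
                    meta["counts"]["faithful_probes_recovered"] = recovered

            enrich = fold_enrichment(group, panel, ontology)
            profiles = classify_profiles(
                group, enrich, config.noise_log2, config.enrich_fold
            )
            contrib = global_contribution(group, panel)
            enrich.to_frame(ontology).to_csv(out_dir / "enrichment.csv", index=False)
            enrich.summary_frame(ontology).to_csv(
                out_dir / "enrichment_summary.csv", index=False
            )
            composition.to_frame().to_csv(out_dir / "composition.csv")
            with open(out_dir / "global_contribution.json", "w") as fh:
                json.dump(contrib, fh, indent=1, sort_keys=True)
            with open(out_dir / "expression_profiles.json", "w") as fh:
                json.dump(profiles, fh, indent=1, sort_keys=True)
            results.update(
                enrichment=enrich, profiles=profiles,
                global_contribution=contrib, composition=composition,
            )
        except Exception as exc:  # noqa: BLE001
            _write_meta()
            raise PipelineError(stage, exc) from exc
        log.info("stage %s finished in %.2fs", stage, time.time() - t0)

    # ----- clustering -----------------------------------------------------
    if "cluster" in config.stages:
        stage = "cluster"
        t0 = time.time()
        try:
            subs = group.sample_ids
            genes = list(group.row_ids)
            log2_matrix = group.values.T  # substructures x genes
            prop_matrix = composition.values.T
            dend_rows = ward_cluster(log2_matrix, subs, axis="rows")
            dend_cols = ward_cluster(log2_matrix, genes, axis="columns")
            (out_dir / "dendrogram_substructures.nwk").write_text(
                dend_rows.to_newick() + "\n"
            )
            (out_dir / "dendrogram_genes.nwk").write_text(
                dend_cols.to_newick() + "\n"
            )
            matrices = {
                "log2": (log2_matrix, subs, genes),
                "proportional": (prop_matrix, composition.sample_ids, genes),
            }
            sweep_cfg = config.sweep_config()
            consensus, partitions = run_sweep(
                matrices, sweep_cfg, axis="rows", seed=seeds["sweep"]
            )
            pd.DataFrame(
                consensus.values, index=consensus.items, columns=consensus.items
            ).to_csv(out_dir / "consensus_substructures.csv")
            pd.DataFrame(
                [
                    {"method": p.method, "parameter": p.parameter,
                     "transform": p.transform,
                     **{f"item:{k}": v for k, v in p.assignment.items()}}
                    for p in partitions
                ]
            ).to_csv(out_dir / "sweep_partitions.csv", index=False)
            meta["counts"]["sweep_partitions"] = len(partitions)
            results.update(consensus=consensus, partitions=partitions,
                           dendrograms=(dend_rows, dend_cols))
        except Exception as exc:  # noqa: BLE001
            _write_meta()
            raise PipelineError(stage, exc) from exc
        log.info("stage %s finished in %.2fs", stage, time.time() - t0)

    # ----- stoichiometry --------------------------------------------------
    if "stoich" in config.stages:
        stage = "stoich"
        t0 = time.time()
        try:
            reports = []
            comp_frame = composition.to_frame().T  # substructures x genes
            reports.append(
                pairwise_correlations(comp_frame, HIGH_EXPRESSION_GENES,
                                      tag="A", unit="substructures")
            )
            per_subject = [
                proportional_contribution(m, panel).to_frame().T
                for m in subject_matrices
            ]
            pooled = pd.concat(per_subject, axis=0, ignore_index=True)
            reports.append(
                pairwise_correlations(pooled, HIGH_EXPRESSION_GENES,
                                      tag="B", unit="samples")
            )
            gate_summary = {}
            if nuclei_matrix is not None:
                comp_nuclei = proportional_contribution(nuclei_matrix, panel)
                profiles_n = profiles_from_composition(comp_nuclei)
                gated, gate_counts = stoichiometric_gate(
                    profiles_n, config.gate_windows()
                )
                gate_summary = {
                    "kept": sum(c["kept"] for c in gate_counts.values()),
                    "dropped": sum(c["dropped"] for c in gate_counts.values()),
                    "per_type": gate_counts,
                }
                meta["counts"]["nuclei_gated"] = gate_summary["kept"]
                by_type: Dict[str, List] = {}
                for nuc in gated:
                    by_type.setdefault(nuc.cell_type, []).append(nuc)
                type_means = {
                    t: np.mean([n.composition for n in nucs], axis=0)
                    for t, nucs in by_type.items()
                }
                means_frame = pd.DataFrame(
                    type_means, index=list(panel.symbols)
                ).T
                if len(means_frame) >= 3:
                    reports.append(
                        pairwise_correlations(means_frame, HIGH_EXPRESSION_GENES,
                                              tag="C", unit="cell_type_means")
                    )
                for t, nucs in sorted(by_type.items()):
                    if len(nucs) < 20:
                        continue
                    frame = pd.DataFrame(
                        [n.composition for n in nucs], columns=list(panel.symbols)
                    )
                    reports.append(
                        pairwise_correlations(
                            frame, HIGH_EXPRESSION_GENES, tag="D",
                            unit="nuclei", cell_type=t,
                            cell_class=nucs[0].cell_class,
                        )
                    )
                sizes = sorted({
                    s for s in (5, 10, 20, 50, len(profiles_n) // len(by_type))
                    if 0 < s <= min(len(v) for v in by_type.values())
                })
                if sizes and by_type:
                    first_type = sorted(by_type)[0]
                    convergence_curve(
                        by_type[first_type], sizes, n_draws=50,
                        seed=seeds["nuclei"],
                    ).to_csv(out_dir / "convergence_curve.csv", index=False)
            table = consensus_pairs(
                reports, alpha=config.alpha, min_support=config.min_support
            )
            pd.concat([r.to_frame() for r in reports], ignore_index=True).to_csv(
                out_dir / "correlation_reports.csv", index=False
            )
            table.to_frame().to_csv(out_dir / "consensus_pairs.csv", index=False)
            with open(out_dir / "gate_summary.json", "w") as fh:
                json.dump(
                    {"windows": config.gate, **gate_summary,
                     "rule": f"two-tailed p < {config.alpha}, "
                             f">= {config.min_support} supporting reports"},
                    fh, indent=1, sort_keys=True, default=str,
                )
            meta["counts"]["pairs_reported"] = len(table.rows)
            results.update(correlation_reports=reports, consensus_table=table)
        except Exception as exc:  # noqa: BLE001
            _write_meta()
            raise PipelineError(stage, exc) from exc
        log.info("stage %s finished in %.2fs", stage, time.time() - t0)

    # ----- layout ---------------------------------------------------------
    if "layout" in config.stages:
        stage = "layout"
        t0 = time.time()
        try:
            profiles = whole_brain_profiles(subject_matrices, panel)
            d_c = pair_distance_consensus(profiles, panel)
            r_values = [
                stereotypy(pair_distance_individual(p, panel), d_c)
                for p in profiles
            ]
            (out_dir / "dendrogram_layout.nwk").write_text(
                layout_dendrogram(d_c).to_newick() + "\n"
            )
            whole_brain = {
                "mean_R": float(np.mean(r_values)),
                "sem_R": float(np.std(r_values, ddof=1) / np.sqrt(len(r_values)))
                if len(r_values) > 1 else 0.0,
                "per_subject": r_values,
            }
            frames = []
            anova = {}
            for transform in config.transforms:
                if transform == "log2":
                    mats = subject_matrices
                else:
                    mats = []
                    for m in subject_matrices:
                        comp = proportional_contribution(m, panel)
                        mats.append(ExpressionMatrix(
                            list(panel.symbols), comp.samples, comp.values,
                            "linear", "percent",
                        ))
                report = reference_similarity(
                    mats, panel, ontology, config.reference, transform=transform
                )
                frames.append(report.to_frame())
                dunnett = compare_to_reference(
                    report,
                    reference_group=ontology[config.reference].structure,
                    n_sim=20_000,
                    seed=seeds["dunnett"],
                )
                anova[transform] = {
                    "F": dunnett.f_statistic,
                    "p": dunnett.anova_p,
                    "significant_vs_reference": dunnett.significant(config.alpha),
                }
            pd.concat(frames, ignore_index=True).to_csv(
                out_dir / "stereotypy.csv", index=False
            )
            with open(out_dir / "layout_summary.json", "w") as fh:
                json.dump(
                    {"whole_brain": whole_brain, "anova": anova,
                     "reference": config.reference},
                    fh, indent=1, sort_keys=True,
                )
            results.update(whole_brain_stereotypy=whole_brain, anova=anova)
        except Exception as exc:  # noqa: BLE001
            _write_meta()
            raise PipelineError(stage, exc) from exc
        log.info("stage %s finished in %.2fs", stage, time.time() - t0)

    _write_meta()
    return results
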