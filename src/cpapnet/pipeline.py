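"""Stage functions chaining the library into the two-step study design.

Stage one (network analysis): discretize the CPAP-titration cohort,
build the risk-compatibility network, detect communities, cross-
tabulate treatment response, and label response classes. Stage two
(statistical analysis): ROC/Youden cutoff analysis of neck
circumference on the screening cohorts, then evaluation of the chosen
cutoff back on the network's response classes.

Reports are plain CSV/JSON named ``table2`` … ``table7`` after the
cross-tabulations they contain; graph exports are GEXF.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .cohort import DEFAULT_RULES, PatientRecord, discretize_patient
from .communities import (
    CommunityPartition,
    detect_communities,
    force_layout,
    layout_community_agreement,
)
from .config import PipelineConfig
from .diagnostics import (
    cutoff_metrics_table,
    mann_whitney_u,
    roc_auc,
    spearman_rho,
    youden_optimal_cutoff,
)
from .io import (
    export_graph,
    write_edgelist_csv,
    write_layout_csv,
    write_partition_csv,
    write_patients,
)
from .network import build_network, summarize_network, threshold_sweep
from .response import (
    ResponseClassLabeling,
    evaluate_nc_threshold,
    improvements_by_community,
    label_response_classes,
    parameter_community_map,
    severity_transition_table,
)
from .synth import (
    ResponseModelSpec,
    generate_clustered_cohort,
    generate_screening_cohorts,
)

logger = logging.getLogger(__name__)

__all__ = [
    "simulate_stage",
    "network_stage",
    "response_stage",
    "roc_stage",
    "cutoff_stage",
    "run_all",
]


def _outdir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out


def simulate_stage(outdir, seed: int = 0, config: Optional[PipelineConfig] = None):
    """Write a synthetic titration cohort (with planted communities and
    CPAP response) and labeled screening cohorts."""
    out = _outdir(outdir)
    cohort = generate_clustered_cohort(seed=seed, response=ResponseModelSpec())
    write_patients(cohort.records, out / "d1_patients.csv")
    pd.DataFrame(
        sorted(cohort.labels.items()), columns=["id", "true_community"]
    ).to_csv(out / "d1_true_communities.csv", index=False)
    screening = generate_screening_cohorts(seed=seed + 1)
    write_patients(screening, out / "screening_patients.csv")
    logger.info(
        "simulated %d titration and %d screening records",
        len(cohort.records),
        len(screening),
    )
    return cohort, screening


def network_stage(
    records: Iterable[PatientRecord],
    outdir,
    config: Optional[PipelineConfig] = None,
    seed: Optional[int] = None,
):
    """Build the compatibility network, detect communities, lay it out."""
    cfg = config or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    out = _outdir(outdir)
    records = list(records)
    profiles = {r.id: discretize_patient(r, cfg.rules) for r in records}
    G = build_network(profiles, threshold=cfg.compatibility_threshold)
    partition = detect_communities(
        G, seed=seed, weighted=cfg.weighted_modularity
    )
    layout = force_layout(G, seed=seed)
    sweep = threshold_sweep(
        profiles, seed=seed, weighted=cfg.weighted_modularity
    )
    pd.DataFrame(
        [
            {
                "threshold": s.threshold,
                "n_nodes": s.n_nodes,
                "n_edges": s.n_edges,
                "density": s.density,
                "n_components": s.n_components,
                "giant_component_size": s.giant_component_size,
                "n_communities": m,
            }
            for s, m in sweep
        ]
    ).to_csv(out / "threshold_sweep.csv", index=False)
    write_partition_csv(partition, out / "partition.csv")
    write_layout_csv(layout, out / "layout.csv")
    write_edgelist_csv(G, out / "edges.csv")
    export_graph(G, out / "network.gexf", partition=partition, layout=layout)
    summary = summarize_network(G)
    try:
        agreement = layout_community_agreement(layout, partition)
    except ValueError:
        agreement = None
    (out / "network_summary.json").write_text(
        json.dumps(
            {
                "n_nodes": summary.n_nodes,
                "n_edges": summary.n_edges,
                "density": summary.density,
                "n_components": summary.n_components,
                "giant_component_size": summary.giant_component_size,
                "threshold": summary.threshold,
                "modularity": partition.modularity,
                "n_communities": partition.m,
                "layout_agreement_ratio": agreement,
            },
            indent=2,
        )
    )
    return G, partition, layout, profiles


def response_stage(
    records: Iterable[PatientRecord],
    profiles: Mapping,
    partition: CommunityPartition,
    outdir,
    config: Optional[PipelineConfig] = None,
) -> ResponseClassLabeling:
    """Tables 2–4 analogues: severity transitions, improvement labels,
    parameter representation per community."""
    cfg = config or PipelineConfig()
    out = _outdir(outdir)
    records = list(records)
    assign = partition.assignment
    table2 = severity_transition_table(records, assign)
    table2.to_csv(out / "table2.csv")
    improvements = improvements_by_community(records, assign)
    labeling = label_response_classes(improvements, cfg.best_threshold)
    pd.DataFrame(
        [
            {
                "community": c,
                "ahi_improvement": improvements[c],
                "response_class": labeling.labels[c],
            }
            for c in sorted(improvements)
        ]
    ).to_csv(out / "table3.csv", index=False)
    parameter_community_map(
        profiles, assign, cfg.representative_threshold
    ).to_csv(out / "table4.csv", index=False)
    return labeling


def roc_stage(
    screening: Iterable[PatientRecord],
    outdir,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Table 5 analogue plus AUC/CI, Youden cutoff, and rank tests."""
    cfg = config or PipelineConfig()
    out = _outdir(outdir)
    screening = list(screening)
    scores = [r.neck_circumference for r in screening]
    labels = [bool(r.osa_label) for r in screening]
    roc = roc_auc(scores, labels)
    table5 = cutoff_metrics_table(scores, labels, cfg.roc_cutoffs)
    pd.DataFrame(
        [
            {
                "cutoff": m.cutoff,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "ppv": m.ppv,
                "npv": m.npv,
                "lr_pos": m.lr_pos,
                "lr_neg": m.lr_neg,
            }
            for m in table5
        ]
    ).to_csv(out / "table5.csv", index=False)
    youden = youden_optimal_cutoff(scores, labels, cfg.roc_cutoffs)
    osa = [r for r in screening if r.osa_label]
    rho = spearman_rho(
        [r.neck_circumference for r in osa], [r.ahi_before for r in osa]
    )
    low = [r.ahi_before for r in screening if r.neck_circumference <= youden]
    high = [r.ahi_before for r in screening if r.neck_circumference > youden]
    mw = mann_whitney_u(high, low)
    pd.DataFrame(
        [
            {
                "characteristic": "ahi_before",
                "median_nc_le_cutoff": pd.Series(low).median(),
                "median_nc_gt_cutoff": pd.Series(high).median(),
                "u_statistic": mw.statistic,
                "p_value": mw.p_value,
            }
        ]
    ).to_csv(out / "table6.csv", index=False)
    result = {
        "auc": roc.auc,
        "ci_low": roc.ci_low,
        "ci_high": roc.ci_high,
        "level": roc.level,
        "n_positive": roc.n_positive,
        "n_negative": roc.n_negative,
        "youden_cutoff": youden,
        "spearman_nc_ahi": rho.statistic,
        "spearman_p": rho.p_value,
        "mann_whitney_u": mw.statistic,
        "mann_whitney_p": mw.p_value,
    }
    (out / "roc.json").write_text(json.dumps(result, indent=2))
    return result


def cutoff_stage(
    records: Iterable[PatientRecord],
    labeling: ResponseClassLabeling,
    partition: CommunityPartition,
    outdir,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Table 7 analogue: per-community counts and contingency rates of
    the NC-threshold classifier at each configured cutoff."""
    cfg = config or PipelineConfig()
    out = _outdir(outdir)
    records = list(records)
    rows = []
    communities = sorted(set(partition.assignment.values()))
    for cutoff in cfg.table7_cutoffs:
        ev = evaluate_nc_threshold(records, labeling, partition.assignment, cutoff)
        for orient, metrics, counts in (
            ("good", ev.good, ev.pred_good_counts),
            ("best", ev.best, ev.pred_best_counts),
        ):
            row = {
                "cutoff": cutoff,
                "orientation": orient,
                "total": sum(counts.values()),
                "tpr": metrics.tpr,
                "tnr": metrics.tnr,
                "ppv": metrics.ppv,
                "npv": metrics.npv,
            }
            for c in communities:
                row[f"C{c}"] = counts.get(c, 0)
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out / "table7.csv", index=False)
    return df


def run_all(outdir, seed: int = 0, config: Optional[PipelineConfig] = None) -> dict:
    """Full pipeline on simulated cohorts; returns the headline numbers."""
    cfg = config or PipelineConfig()
    out = _outdir(outdir)
    cohort, screening = simulate_stage(out, seed=seed, config=cfg)
    G, partition, layout, profiles = network_stage(
        cohort.records, out, config=cfg, seed=seed
    )
    labeling = response_stage(cohort.records, profiles, partition, out, config=cfg)
    roc = roc_stage(screening, out, config=cfg)
    cutoff_stage(cohort.records, labeling, partition, out, config=cfg)
    summary = {
        "seed": seed,
        "n_titration": len(cohort.records),
        "n_screening": len(screening),
        "n_communities": partition.m,
        "modularity": partition.modularity,
        "response_labels": labeling.labels,
        "auc": roc["auc"],
        "youden_cutoff": roc["youden_cutoff"],
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
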