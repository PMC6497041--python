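"""End-to-end orchestration: counts -> DE -> ceRNA network -> module survival."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import cerna_net, diff_expr, survival
from .data_model import (
    STAGES,
    ExpressionMatrix,
    InteractionTable,
    SampleTable,
    compute_fpkm,
    estimate_size_factors,
    log2_normalize,
)

#: FPKM abundance threshold per gene class (lncRNAs are lowly expressed)
ABUNDANCE_THRESHOLDS = {"mRNA": 1.0, "miRNA": 1.0, "lncRNA": 0.1}
ABUNDANCE_MIN_FRACTION = 0.1


@dataclass
class PipelineResult:
    de_tables: dict[str, dict[str, pd.DataFrame]]  # class -> stage -> DETable
    common: dict[str, diff_expr.CommonDEGSet]
    correlations: pd.DataFrame
    modules: list[cerna_net.CeRNAModule]
    network: nx.Graph
    module_survival: list[survival.ModuleSurvival] = field(default_factory=list)


def run_differential_expression(
    matrices: dict[str, ExpressionMatrix],
    samples: SampleTable,
    gene_lengths: pd.Series,
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.01,
) -> tuple[dict[str, dict[str, pd.DataFrame]], dict[str, diff_expr.CommonDEGSet]]:
    """Abundance-filter each class, test all four stages, intersect."""
    de_tables: dict[str, dict[str, pd.DataFrame]] = {}
    common: dict[str, diff_expr.CommonDEGSet] = {}
    for cls, counts in matrices.items():
        fpkm = compute_fpkm(counts, gene_lengths)
        retained = diff_expr.abundance_filter(
            fpkm, ABUNDANCE_THRESHOLDS[cls], ABUNDANCE_MIN_FRACTION
        )
        de_tables[cls] = {
            stage: diff_expr.nb_de_test(counts, samples, stage, gene_ids=retained)
            for stage in STAGES
        }
        common[cls] = diff_expr.common_degs(
            de_tables[cls], gene_class=cls, fc_threshold=fc_threshold, fdr_threshold=fdr_threshold
        )
    return de_tables, common


def run_pipeline(
    matrices: dict[str, ExpressionMatrix],
    samples: SampleTable,
    gene_lengths: pd.Series,
    interactions: InteractionTable,
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.01,
    r_threshold: float = 0.8,
    p_threshold: float = 0.05,
    module_fdr: float = 0.05,
    min_shared: int = 1,
    with_survival: bool = True,
) -> PipelineResult:
    """Run the full ceRNA discovery pipeline on one cohort.

    ``matrices`` maps gene class ('mRNA', 'lncRNA', 'miRNA') to a counts
    ExpressionMatrix over the same samples as ``samples``. When
    ``with_survival`` is true, every kept module is expanded into
    lncRNA-miRNA-mRNA triplets (one per shared miRNA) and each triplet is
    evaluated with the risk-score classifier on tumor samples.
    """
    de_tables, common = run_differential_expression(
        matrices, samples, gene_lengths, fc_threshold, fdr_threshold
    )

    log2 = {cls: log2_normalize(em) for cls, em in matrices.items()}
    lnc_de = log2["lncRNA"].subset_genes(sorted(common["lncRNA"].ids()))
    mrna_de = log2["mRNA"].subset_genes(sorted(common["mRNA"].ids()))
    if len(lnc_de.gene_ids) and len(mrna_de.gene_ids):
        correlations = cerna_net.correlate_pairs(lnc_de, mrna_de, r_threshold, p_threshold)
    else:
        correlations = pd.DataFrame(columns=["lncrna_id", "mrna_id", "r", "pvalue"])

    if len(correlations):
        modules, network = cerna_net.build_cerna_network(
            common, interactions, correlations, module_fdr=module_fdr, min_shared=min_shared
        )
    else:
        modules, network = [], nx.Graph()

    module_surv: list[survival.ModuleSurvival] = []
    if with_survival and modules:
        tumor = samples.tumor_ids()
        times, events = samples.survival(tumor)
        for mod in modules:
            for mir in sorted(mod.shared_mirna_ids):
                expr = pd.concat(
                    [
                        log2["lncRNA"].values.loc[[mod.lncrna_id], tumor],
                        log2["mRNA"].values.loc[[mod.mrna_id], tumor],
                        log2["miRNA"].values.loc[[mir], tumor],
                    ]
                )
                module_surv.append(
                    survival.module_risk_score(
                        f"{mod.lncrna_id}|{mir}|{mod.mrna_id}", expr, times, events
                    )
                )

    return PipelineResult(
        de_tables=de_tables,
        common=common,
        correlations=correlations,
        modules=modules,
        network=network,
        module_survival=module_surv,
    )
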