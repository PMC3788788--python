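"""High-level workflows tying the modules together.

These functions are what the command-line interface wraps and what the
example scripts call: align expression with the network, run the
per-patient regressions, aggregate consensus calls, and validate against
miRNA measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .consensus import ConsensusCallSet, call_active, permutation_pvalue, validate_calls
from .infer import CohortFit, fit_cohort
from .io import EdgeList, ExpressionMatrix, RunConfig, ValidationError
from .network import SignedTargetMatrix, build_influence_matrix
from .preprocess import NormalizedDEMatrix, normalize_differential

logger = logging.getLogger(__name__)

__all__ = ["InferenceResult", "ValidationResult", "run_inference", "run_validation"]


@dataclass(frozen=True)
class InferenceResult:
    calls: ConsensusCallSet
    cohort: CohortFit
    design: SignedTargetMatrix
    gene_de: NormalizedDEMatrix


@dataclass(frozen=True)
class ValidationResult:
    calls: ConsensusCallSet
    p_value: float
    mirna_de: NormalizedDEMatrix


def align_to_network(
    gene_de: NormalizedDEMatrix, edges: EdgeList
) -> tuple[NormalizedDEMatrix, SignedTargetMatrix]:
    """Intersect the expression gene space with the network's gene space.

    Genes measured but never targeted carry no information about miRNA
    influence under this model, and network genes missing from the platform
    cannot inform the fit; both are dropped (with a log line noting the
    loss) and the design matrix is built over the surviving intersection.
    """
    network_genes = set(edges.genes)
    kept = [g for g in gene_de.feature_ids if g in network_genes]
    if not kept:
        raise ValidationError("no overlap between expression genes and network genes")
    lost_expr = len(gene_de.feature_ids) - len(kept)
    lost_net = len(network_genes) - len(kept)
    logger.info(
        "gene space intersection: %d kept, %d expression-only, %d network-only",
        len(kept),
        lost_expr,
        lost_net,
    )
    design = build_influence_matrix(edges, kept, edges.mirnas)
    sub = NormalizedDEMatrix(gene_de.data.loc[kept])
    return sub, design


def run_inference(
    gene_tumour: ExpressionMatrix,
    gene_healthy: ExpressionMatrix,
    edges: EdgeList,
    config: RunConfig,
) -> InferenceResult:
    """Normalize, align, fit the cohort, and call consensus-active miRNAs."""
    gene_de, _ = normalize_differential(
        gene_tumour, gene_healthy, s0=config.s0, cancer_var_weight=config.cancer_var_weight
    )
    gene_de, design = align_to_network(gene_de, edges)
    cohort = fit_cohort(gene_de, design, config)
    calls = call_active(
        cohort, config.consensus_fraction, not_assessable=design.pruned_mirna_ids
    )
    return InferenceResult(calls=calls, cohort=cohort, design=design, gene_de=gene_de)


def run_validation(
    calls: ConsensusCallSet,
    mirna_tumour: ExpressionMatrix,
    mirna_healthy: ExpressionMatrix,
    config: RunConfig,
) -> ValidationResult:
    """Normalize miRNA measurements, validate call signs, and compute the
    permutation p-value for the call set."""
    if len(calls) == 0:
        raise ValidationError("nothing to validate: empty call set")
    mirna_de, _ = normalize_differential(
        mirna_tumour,
        mirna_healthy,
        s0=config.s0,
        cancer_var_weight=config.cancer_var_weight,
    )
    validated = validate_calls(calls, mirna_de, config.validation_fraction)
    p = permutation_pvalue(
        calls,
        mirna_de,
        config.validation_fraction,
        n_permutations=config.n_permutations,
        seed=config.seed,
    )
    return ValidationResult(calls=validated, p_value=p, mirna_de=mirna_de)
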