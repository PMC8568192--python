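"""Joint multi-trait association testing for de novo mutation counts.

A Poisson mixture model over per-gene de novo mutation (DNM) counts from
one or two trio cohorts.  Each gene carries a latent association class; the
class prior quantifies pleiotropy between traits, functional annotations
enter through an exponential link on the relative risk, parameters are
estimated by EM, and risk genes are called by thresholding the joint local
false discovery rate at a nominal global FDR level.
"""

from .annotations import (
    FeatureSelectionReport,
    collapse_to_gene,
    prune_correlated,
    select_by_effect_size,
    select_features,
    standardize_features,
)
from .em import (
    FitOptions,
    FitResult,
    e_step,
    fit_multi,
    fit_single,
    m_step_beta_closed,
    m_step_pi,
    newton_update_beta,
)
from .inference import fdr_threshold, jlfdr, run_inference
from .io import read_gene_table, write_gene_table
from .model import (
    AnnotationDesign,
    CohortInfo,
    GeneTable,
    MixtureParams,
    class_loglik,
    expected_count,
    gene_relative_risk,
    marginal_loglik,
)
from .simulate import (
    METHODS,
    ReplicateMetrics,
    SimulationConfig,
    evaluate_replicate,
    pi_from_margins,
    run_grid,
    run_replicate,
    sample_mutabilities,
    simulate_misspecified,
    simulate_true_model,
)

__version__ = "0.1.0"

__all__ = [
    "AnnotationDesign",
    "CohortInfo",
    "FeatureSelectionReport",
    "FitOptions",
    "FitResult",
    "GeneTable",
    "METHODS",
    "MixtureParams",
    "ReplicateMetrics",
    "SimulationConfig",
    "class_loglik",
    "collapse_to_gene",
    "e_step",
    "evaluate_replicate",
    "expected_count",
    "fdr_threshold",
    "fit_multi",
    "fit_single",
    "gene_relative_risk",
    "jlfdr",
    "m_step_beta_closed",
    "m_step_pi",
    "marginal_loglik",
    "newton_update_beta",
    "pi_from_margins",
    "prune_correlated",
    "read_gene_table",
    "run_grid",
    "run_inference",
    "run_replicate",
    "sample_mutabilities",
    "select_by_effect_size",
    "select_features",
    "simulate_misspecified",
    "simulate_true_model",
    "standardize_features",
    "write_gene_table",
]
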