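"""Shared feature-construction path: associations + DAGs -> weighted features.

Both the model front-end and cross-validation (which may rebuild features per
fold with held-out associations masked) go through this module so that the
similarity -> network -> RWR -> weighting chain exists in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_data import AssociationMatrix, DiseaseDAG, SimilarityMatrix
from .predictor import KnnParams
from .propagation import (
    AdjacencyMatrix,
    AffinityMatrix,
    RwrParams,
    ThresholdParams,
    WeightedFeatures,
    affinity_matrix,
    identity_affinity,
    threshold_adjacency,
    weight_features,
)
from .similarity import (
    GipParams,
    SemanticParams,
    circ_functional_similarity,
    disease_semantic_similarity,
    gip_kernel,
    integrate_circ_similarity,
    integrate_disease_similarity,
)

__all__ = ["PipelineParams", "PipelineState", "compute_similarities", "build_features"]


@dataclass(frozen=True)
class PipelineParams:
    """Every tunable of the method, defaulting to its chosen operating point
    (Δ=0.5, σ*=1, α=0.6, β=0.8, c=0.7, k=5, p=1, RWR-weighted features,
    column-stochastic walk)."""

    semantic: SemanticParams = field(default_factory=SemanticParams)
    gip: GipParams = field(default_factory=GipParams)
    thresholds: ThresholdParams = field(default_factory=ThresholdParams)
    rwr: RwrParams = field(default_factory=RwrParams)
    knn: KnnParams = field(default_factory=KnnParams)
    weighting: str = "rwr"  # "rwr" or "identity" (the raw-KNN ablation)
    normalization: str = "column"  # walk-matrix normalisation: column | row

    def __post_init__(self) -> None:
        if self.weighting not in ("rwr", "identity"):
            raise ValueError(f"weighting must be 'rwr' or 'identity', got {self.weighting!r}")
        if self.normalization not in ("column", "row"):
            raise ValueError(
                f"normalization must be 'column' or 'row', got {self.normalization!r}"
            )

    def with_overrides(self, **kwargs) -> "PipelineParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PipelineState:
    """All intermediate matrices of one feature-construction run."""

    similarities: dict[str, SimilarityMatrix]
    disease_network: AdjacencyMatrix
    circ_network: AdjacencyMatrix
    disease_affinity: AffinityMatrix
    circ_affinity: AffinityMatrix
    wsd: WeightedFeatures
    wsc: WeightedFeatures


def compute_similarities(
    assoc: AssociationMatrix,
    dags: dict[str, DiseaseDAG],
    params: PipelineParams,
) -> dict[str, SimilarityMatrix]:
    """All six similarity matrices keyed by role (DSS, DGS, SD, CFS, CGS, SC)."""
    dss = disease_semantic_similarity(
        dags, params.semantic, registry=assoc.disease_registry
    )
    dgs = gip_kernel(
        assoc.values.T, assoc.disease_registry, params.gip, role="DGS"
    )
    sd = integrate_disease_similarity(dss, dgs)
    cgs = gip_kernel(assoc.values, assoc.circ_registry, params.gip, role="CGS")
    cfs = circ_functional_similarity(assoc, dss)
    sc = integrate_circ_similarity(cfs, cgs)
    return {"DSS": dss, "DGS": dgs, "SD": sd, "CGS": cgs, "CFS": cfs, "SC": sc}


def build_features(
    assoc: AssociationMatrix,
    dags: dict[str, DiseaseDAG],
    params: PipelineParams | None = None,
) -> PipelineState:
    """Run similarity -> thresholded networks -> RWR -> weighted features."""
    params = params or PipelineParams()
    sims = compute_similarities(assoc, dags, params)
    da = threshold_adjacency(sims["SD"], params.thresholds.alpha, "DA")
    ca = threshold_adjacency(sims["SC"], params.thresholds.beta, "CA")
    if params.weighting == "rwr":
        fd = affinity_matrix(da, params.rwr, params.normalization)
        fc = affinity_matrix(ca, params.rwr, params.normalization)
    else:
        fd = identity_affinity(assoc.disease_registry)
        fc = identity_affinity(assoc.circ_registry)
    wsd = weight_features(fd, sims["SD"])
    wsc = weight_features(fc, sims["SC"])
    return PipelineState(
        similarities=sims,
        disease_network=da,
        circ_network=ca,
        disease_affinity=fd,
        circ_affinity=fc,
        wsd=wsd,
        wsc=wsc,
    )
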