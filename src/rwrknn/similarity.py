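"""Similarity matrices over diseases and circRNAs.

Six matrices feed the downstream network construction:

* ``DSS`` — disease semantic similarity from ontology DAGs (Wang's measure):
  each ancestor term ``t`` of disease ``d`` contributes
  ``D_d(t) = Δ · max{D_d(t') : t' child of t in DAG(d)}`` with ``D_d(d) = 1``;
  two diseases are similar in proportion to the contributions of their shared
  ancestors, normalised by their total semantic values.
* ``DGS`` / ``CGS`` — Gaussian interaction-profile (GIP) kernels over the
  binary association profiles of diseases (columns of A) and circRNAs
  (rows of A), with bandwidth ``σ = σ*/ mean(‖IP‖²)``.
* ``SD`` / ``SC`` — integrated similarities: the mean of the semantic
  (functional) and GIP values where the former is non-zero, the GIP value
  otherwise.
* ``CFS`` — circRNA functional similarity: best-match average of disease
  semantic similarity between the two circRNAs' disease sets.

Entities with no defining information (empty profile, singleton DAG with no
counterpart overlap) get off-diagonal similarity 0 and self-similarity 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .core_data import (
    AssociationMatrix,
    DiseaseDAG,
    EntityRegistry,
    SimilarityMatrix,
)

__all__ = [
    "SemanticParams",
    "GipParams",
    "semantic_contributions",
    "semantic_value",
    "disease_semantic_similarity",
    "gip_kernel",
    "integrate_disease_similarity",
    "circ_functional_similarity",
    "integrate_circ_similarity",
]


@dataclass(frozen=True)
class SemanticParams:
    """Semantic contribution decay factor Δ ∈ (0, 1]; default 0.5."""

    delta: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.delta <= 1:
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")


@dataclass(frozen=True)
class GipParams:
    """GIP bandwidth normaliser σ* > 0 (dimensionless); default 1."""

    sigma_star: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_star <= 0:
            raise ValueError(f"sigma_star must be positive, got {self.sigma_star}")


def semantic_contributions(
    dag: DiseaseDAG, params: SemanticParams | None = None
) -> dict[str, float]:
    """Per-term decayed contributions D_d(t) for every ancestor term of the
    disease.

    The disease's own term contributes 1; every other ancestor contributes
    ``Δ`` times the maximum contribution of its children *within the DAG*.
    Terms not reachable from the disease along child -> parent edges are not
    ancestors and are excluded.
    """
    params = params or SemanticParams()
    g = dag.graph()
    terms = dag.ancestor_terms()
    sub = g.subgraph(terms)
    contributions: dict[str, float] = {}
    # child -> parent edges: topological order yields children before parents
    for term in nx.topological_sort(sub):
        if term == dag.root:
            contributions[term] = 1.0
        else:
            child_vals = [
                contributions[c] for c in sub.predecessors(term) if c in contributions
            ]
            contributions[term] = params.delta * max(child_vals)
    return contributions


def semantic_value(dag: DiseaseDAG, params: SemanticParams | None = None) -> float:
    """DSV(d): the sum of all ancestor contributions; >= 1 for any DAG."""
    return float(sum(semantic_contributions(dag, params).values()))


def disease_semantic_similarity(
    dags: dict[str, DiseaseDAG],
    params: SemanticParams | None = None,
    registry: EntityRegistry | None = None,
) -> SimilarityMatrix:
    """Disease semantic similarity matrix DSS.

    ``DSS(i, j) = Σ_{t ∈ T(i) ∩ T(j)} (D_i(t) + D_j(t)) / (DSV(i) + DSV(j))``.
    Diseases with disjoint ancestor sets get 0; the diagonal is exactly 1.
    """
    registry = registry or EntityRegistry.from_iterable(dags)
    contribs = [semantic_contributions(dags[d], params) for d in registry]
    dsv = np.array([sum(c.values()) for c in contribs])
    n = len(registry)
    values = np.eye(n)
    for i in range(n):
        ci = contribs[i]
        for j in range(i + 1, n):
            cj = contribs[j]
            shared = ci.keys() & cj.keys()
            if shared:
                num = sum(ci[t] + cj[t] for t in shared)
                values[i, j] = values[j, i] = num / (dsv[i] + dsv[j])
    return SimilarityMatrix(values, registry, "DSS")


def gip_kernel(
    profiles: np.ndarray,
    registry: EntityRegistry,
    params: GipParams | None = None,
    role: str = "DGS",
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over binary profiles (one row per
    entity).

    Bandwidth ``σ = σ* / ((1/N) Σ_i ‖IP_i‖²)``; the kernel is
    ``K(i, j) = exp(−σ ‖IP_i − IP_j‖²)``. Raises if every profile is all-zero
    (the bandwidth is then undefined).
    """
    params = params or GipParams()
    profiles = np.asarray(profiles, dtype=np.float64)
    if profiles.ndim != 2 or profiles.shape[0] != len(registry):
        raise ValueError("profiles must be a 2-D array with one row per entity")
    mean_sq_norm = float(np.square(profiles).sum()) / profiles.shape[0]
    if mean_sq_norm == 0:
        raise ValueError("all interaction profiles are zero: GIP bandwidth undefined")
    sigma = params.sigma_star / mean_sq_norm
    sq_dists = cdist(profiles, profiles, "sqeuclidean")
    values = np.exp(-sigma * sq_dists)
    values = (values + values.T) / 2.0  # exact symmetry
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, registry, role)


def _integrate(primary: np.ndarray, gip: np.ndarray) -> np.ndarray:
    # mean of the two where the semantic/functional entry is informative,
    # GIP alone otherwise
    return np.where(primary != 0, (primary + gip) / 2.0, gip)


def integrate_disease_similarity(
    dss: SimilarityMatrix, dgs: SimilarityMatrix
) -> SimilarityMatrix:
    """Integrated disease similarity SD: mean of DSS and DGS where DSS ≠ 0,
    DGS otherwise."""
    if dss.registry != dgs.registry:
        raise ValueError("DSS and DGS registries differ")
    return SimilarityMatrix(_integrate(dss.values, dgs.values), dss.registry, "SD")


def circ_functional_similarity(
    assoc: AssociationMatrix, dss: SimilarityMatrix
) -> SimilarityMatrix:
    """circRNA functional similarity CFS via best-match averaging.

    With ``Du``, ``Dv`` the disease sets of circRNAs U and V and
    ``SS(d, D) = max_{d' ∈ D} DSS(d, d')``:

    ``CFS(U, V) = [Σ_{d∈Du} SS(d, Dv) + Σ_{d∈Dv} SS(d, Du)] / (|Du| + |Dv|)``

    A circRNA with no known diseases has off-diagonal similarity 0 and
    self-similarity 1.
    """
    if dss.registry != assoc.disease_registry:
        raise ValueError("DSS registry does not match the association's diseases")
    M = dss.values
    disease_sets = [np.nonzero(row)[0] for row in assoc.values]
    n = assoc.n_circ
    values = np.eye(n)
    for i in range(n):
        du = disease_sets[i]
        if du.size == 0:
            continue
        for j in range(i + 1, n):
            dv = disease_sets[j]
            if dv.size == 0:
                continue
            block = M[np.ix_(du, dv)]
            score = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (
                du.size + dv.size
            )
            values[i, j] = values[j, i] = score
    return SimilarityMatrix(values, assoc.circ_registry, "CFS")


def integrate_circ_similarity(
    cfs: SimilarityMatrix, cgs: SimilarityMatrix
) -> SimilarityMatrix:
    """Integrated circRNA similarity SC: mean of CFS and CGS where CFS ≠ 0,
    CGS otherwise."""
    if cfs.registry != cgs.registry:
        raise ValueError("CFS and CGS registries differ")
    return SimilarityMatrix(_integrate(cfs.values, cgs.values), cfs.registry, "SC")
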