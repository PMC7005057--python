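"""Synthetic benchmark data: layered disease DAGs and planted-block
association matrices.

The generator emulates the two real inputs — an association edge list and a
per-disease ontology DAG file — with a *planted block model*: diseases and
circRNAs belong to latent blocks, within-block association probability
exceeds the cross-block (noise) probability, and diseases of the same block
share a block-root ancestor term so both the GIP kernels and the DAG
semantic similarity can detect the block structure. Cross-block disease
pairs share no ancestor at all, which exercises the "otherwise" branch of
the similarity integration rules.

Default parameters are the package's reference study condition: 60 circRNAs,
20 diseases, 4 blocks, within-block link probability 0.6 against noise 0.02,
ancestor chains up to depth 3. Everything is deterministic in ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .core_data import (
    AssociationMatrix,
    DiseaseDAG,
    EntityRegistry,
    write_matrix,
)

__all__ = ["SyntheticSpec", "generate_dags", "generate_associations", "generate_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block generator."""

    n_circ: int = 60
    n_disease: int = 20
    n_terms: int = 40
    n_blocks: int = 4
    within_block_assoc_prob: float = 0.6
    noise_assoc_prob: float = 0.02
    dag_depth: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_circ, self.n_disease, self.n_blocks) < 1:
            raise ValueError("entity and block counts must be positive")
        for name in ("within_block_assoc_prob", "noise_assoc_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dag_depth < 0:
            raise ValueError("dag_depth must be >= 0")

    @property
    def circ_names(self) -> tuple[str, ...]:
        return tuple(f"C{i:03d}" for i in range(self.n_circ))

    @property
    def disease_names(self) -> tuple[str, ...]:
        return tuple(f"D{i:03d}" for i in range(self.n_disease))

    def disease_block(self, i: int) -> int:
        """Deterministic block label of disease i (round-robin)."""
        return i % self.n_blocks


def _block_terms(spec: SyntheticSpec, block: int) -> list[str]:
    """Intermediate ontology terms of one block, in fixed depth order."""
    return [f"T{t:03d}" for t in range(spec.n_terms) if t % spec.n_blocks == block]


def generate_dags(spec: SyntheticSpec) -> dict[str, DiseaseDAG]:
    """One ancestor DAG per disease.

    With ``dag_depth == 0`` every DAG is a singleton. Otherwise each disease
    gets an ancestor chain of random length <= dag_depth through its block's
    intermediate terms (in a fixed order, so edge sets are always acyclic),
    ending at the block-root term shared by all diseases of the block.
    """
    rng = np.random.default_rng([spec.rng_seed, 1])
    dags: dict[str, DiseaseDAG] = {}
    for i, name in enumerate(spec.disease_names):
        if spec.dag_depth == 0:
            dags[name] = DiseaseDAG(disease=name, edges=frozenset())
            continue
        block = spec.disease_block(i)
        root = f"B{block}"
        depth = int(rng.integers(1, spec.dag_depth + 1))
        pool = _block_terms(spec, block)
        n_mid = min(depth - 1, len(pool))
        if n_mid > 0:
            picked = sorted(rng.choice(len(pool), size=n_mid, replace=False).tolist())
            chain = [name] + [pool[j] for j in picked] + [root]
        else:
            chain = [name, root]
        edges = frozenset(zip(chain, chain[1:]))
        dags[name] = DiseaseDAG(disease=name, edges=edges)
    return dags


def generate_associations(spec: SyntheticSpec) -> AssociationMatrix:
    """Planted-block binary association matrix.

    Each circRNA is assigned one block uniformly at random; links are
    Bernoulli(within_block_assoc_prob) to same-block diseases and
    Bernoulli(noise_assoc_prob) otherwise. Entities that end up with zero
    links are retained (they exercise the degenerate-profile conventions
    downstream).
    """
    rng = np.random.default_rng([spec.rng_seed, 2])
    circ_blocks = rng.integers(spec.n_blocks, size=spec.n_circ)
    disease_blocks = np.array(
        [spec.disease_block(j) for j in range(spec.n_disease)]
    )
    same_block = circ_blocks[:, None] == disease_blocks[None, :]
    probs = np.where(same_block, spec.within_block_assoc_prob, spec.noise_assoc_prob)
    values = (rng.random((spec.n_circ, spec.n_disease)) < probs).astype(np.int8)
    return AssociationMatrix(
        values,
        EntityRegistry(spec.circ_names),
        EntityRegistry(spec.disease_names),
    )


def generate_fixture(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete on-disk fixture and return the paths.

    Files: ``associations.tsv`` (edge list; zero-degree entities have no
    lines there), ``association_matrix.tsv`` (full matrix incl. zero-degree
    entities), ``dags.tsv``, and ``spec.json`` recording the generator
    parameters. All round-trip through the package's readers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assoc = generate_associations(spec)
    dags = generate_dags(spec)

    edge_path = out_dir / "associations.tsv"
    with edge_path.open("w", encoding="utf-8") as fh:
        fh.write("# circRNA\tdisease\n")
        for ci, di in assoc.positive_pairs():
            fh.write(f"{assoc.circ_registry[ci]}\t{assoc.disease_registry[di]}\n")

    matrix_path = out_dir / "association_matrix.tsv"
    write_matrix(assoc, matrix_path)

    dag_path = out_dir / "dags.tsv"
    with dag_path.open("w", encoding="utf-8") as fh:
        fh.write("# disease\tchild_term\tparent_term\n")
        for name in assoc.disease_registry:
            dag = dags[name]
            if not dag.edges:
                fh.write(f"{name}\t{name}\t{name}\n")  # isolated-root convention
            for child, parent in sorted(dag.edges):
                fh.write(f"{name}\t{child}\t{parent}\n")

    spec_path = out_dir / "spec.json"
    spec_path.write_text(json.dumps(asdict(spec), indent=2) + "\n", encoding="utf-8")

    return {
        "associations": edge_path,
        "association_matrix": matrix_path,
        "dags": dag_path,
        "spec": spec_path,
    }
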