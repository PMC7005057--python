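"""Model front-end: :class:`RWRKNN` and :class:`RWRKNNResults`.

The model bundles the full method — similarity construction, network
thresholding, random walk with restart feature weighting, balanced negative
sampling and inverse-distance KNN scoring — behind a fit/results interface:

>>> from rwrknn import RWRKNN, SyntheticSpec, generate_associations, generate_dags
>>> spec = SyntheticSpec(rng_seed=7)
>>> model = RWRKNN(generate_associations(spec), generate_dags(spec))
>>> res = model.fit(negative_seed=7)
>>> print(res.summary())                       # doctest: +SKIP
>>> res.top_candidates("D003", n=5)            # doctest: +SKIP

``fit`` trains on all known positives plus an equal number of sampled
negatives and scores every (circRNA, disease) pair;
``cross_validate`` reports held-out performance instead.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import (
    AssociationMatrix,
    DiseaseDAG,
    EntityRegistry,
    read_associations,
    read_disease_dags,
    write_matrix,
)
from .evaluation import CVConfig, MetricReport, run_cv
from .pipeline import PipelineParams, PipelineState, build_features
from .predictor import (
    PairSample,
    build_pair_features,
    predict_all_pairs,
    sample_negatives,
)

__all__ = ["RWRKNN", "RWRKNNResults"]

_FLOAT_FMT = "%.17g"


def _write_named_matrix(
    values: np.ndarray,
    row_names: Sequence[str],
    col_names: Sequence[str],
    path: Path,
    role: str,
    fmt: str = _FLOAT_FMT,
) -> None:
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# role: {role}\n")
        fh.write("id\t" + "\t".join(col_names) + "\n")
        for name, row in zip(row_names, values):
            fh.write(name + "\t" + "\t".join(fmt % v for v in row) + "\n")


class RWRKNN:
    """Bipartite association predictor with RWR-weighted similarity features.

    Parameters
    ----------
    assoc
        Binary circRNA x disease association matrix (the supervision signal
        and the source of the GIP interaction profiles).
    dags
        Ancestor DAG per disease, for semantic similarity. Diseases without
        ontology information may map to singleton DAGs.
    params
        All pipeline tunables; defaults are the method's operating point
        (alpha=0.6, beta=0.8, k=5, p=1, c=0.7, delta=0.5, sigma*=1).
    """

    def __init__(
        self,
        assoc: AssociationMatrix,
        dags: dict[str, DiseaseDAG],
        params: PipelineParams | None = None,
    ) -> None:
        missing = [d for d in assoc.disease_registry if d not in dags]
        if missing:
            # diseases without ontology rows fall back to singleton DAGs
            dags = dict(dags)
            for d in missing:
                dags[d] = DiseaseDAG(disease=d, edges=frozenset())
        self.assoc = assoc
        self.dags = dags
        self.params = params or PipelineParams()

    @classmethod
    def from_files(
        cls,
        associations: str | Path,
        dag_file: str | Path | None = None,
        params: PipelineParams | None = None,
    ) -> "RWRKNN":
        """Build a model from an association edge list and a DAG TSV."""
        assoc = read_associations(associations)
        if dag_file is not None:
            dags = read_disease_dags(dag_file, assoc.disease_registry)
        else:
            dags = {}
        return cls(assoc, dags, params)

    # -- estimation ---------------------------------------------------------

    def fit(self, negative_seed: int = 0) -> "RWRKNNResults":
        """Train on all positives + balanced sampled negatives and score
        every pair. Deterministic given ``negative_seed``."""
        state = build_features(self.assoc, self.dags, self.params)
        positives = self.assoc.positive_pairs()
        negatives = sample_negatives(self.assoc, negative_seed)
        pairs = positives + negatives
        labels = [1] * len(positives) + [0] * len(negatives)
        train = build_pair_features(state.wsd, state.wsc, pairs, labels)
        scores = predict_all_pairs(state.wsd, state.wsc, train, self.params.knn)
        return RWRKNNResults(
            model=self,
            state=state,
            train_samples=train,
            negative_pairs=negatives,
            negative_seed=negative_seed,
            score_matrix=scores,
        )

    def cross_validate(
        self, config: CVConfig | None = None, negative_seed: int = 0
    ) -> MetricReport:
        """Held-out performance (LOOCV or k-fold over positives)."""
        return run_cv(self.assoc, self.dags, self.params, config, negative_seed)


@dataclass
class RWRKNNResults:
    """Fitted artefacts: intermediate matrices, training set, and the full
    Nc x Nd score matrix."""

    model: RWRKNN
    state: PipelineState
    train_samples: list[PairSample]
    negative_pairs: list[tuple[int, int]]
    negative_seed: int
    score_matrix: np.ndarray = field(repr=False)

    # -- accessors ----------------------------------------------------------

    @property
    def circ_registry(self) -> EntityRegistry:
        return self.model.assoc.circ_registry

    @property
    def disease_registry(self) -> EntityRegistry:
        return self.model.assoc.disease_registry

    def scores_frame(self) -> pd.DataFrame:
        """Score matrix as a DataFrame (rows circRNAs, columns diseases)."""
        return pd.DataFrame(
            self.score_matrix,
            index=list(self.circ_registry),
            columns=list(self.disease_registry),
        )

    def scored_pairs(self) -> pd.DataFrame:
        """Long-format table: circRNA, disease, score, known label."""
        records = []
        for ci, cname in enumerate(self.circ_registry):
            for di, dname in enumerate(self.disease_registry):
                records.append(
                    (
                        cname,
                        dname,
                        float(self.score_matrix[ci, di]),
                        int(self.model.assoc.values[ci, di]),
                    )
                )
        return pd.DataFrame(records, columns=["circRNA", "disease", "score", "label"])

    def top_candidates(
        self, disease: str, n: int = 10, exclude_known: bool = True
    ) -> pd.DataFrame:
        """Top-n circRNAs for one disease by predicted score (case-study
        style ranking). Known associations are excluded unless requested."""
        di = self.disease_registry.position(disease)
        scores = self.score_matrix[:, di]
        known = self.model.assoc.values[:, di].astype(bool)
        order = np.argsort(-scores, kind="stable")
        rows = []
        for ci in order:
            if exclude_known and known[ci]:
                continue
            rows.append((self.circ_registry[ci], float(scores[ci]), bool(known[ci])))
            if len(rows) == n:
                break
        return pd.DataFrame(rows, columns=["circRNA", "score", "known"])

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text block)."""
        a = self.model.assoc
        p = self.model.params
        n_pos = len(a.positive_pairs())
        width = 58
        lines = [
            "RWRKNN association model".center(width),
            "=" * width,
            f"{'circRNAs:':<28}{a.n_circ:>10}",
            f"{'diseases:':<28}{a.n_disease:>10}",
            f"{'known associations:':<28}{n_pos:>10}",
            f"{'sampled negatives:':<28}{len(self.negative_pairs):>10}",
            f"{'pair feature dimension:':<28}{a.n_disease + a.n_circ:>10}",
            "-" * width,
            f"{'decay delta:':<28}{p.semantic.delta:>10}",
            f"{'GIP sigma*:':<28}{p.gip.sigma_star:>10}",
            f"{'alpha (disease net):':<28}{p.thresholds.alpha:>10}",
            f"{'beta (circRNA net):':<28}{p.thresholds.beta:>10}",
            f"{'restart prob c:':<28}{p.rwr.restart_prob:>10}",
            f"{'k neighbours:':<28}{p.knn.k:>10}",
            f"{'Minkowski p:':<28}{p.knn.p:>10}",
            f"{'feature weighting:':<28}{p.weighting:>10}",
            f"{'negative seed:':<28}{self.negative_seed:>10}",
            "-" * width,
            f"{'disease net edges:':<28}{int(self.state.disease_network.values.sum()):>10}",
            f"{'circRNA net edges:':<28}{int(self.state.circ_network.values.sum()):>10}",
            f"{'score range:':<28}"
            f"{self.score_matrix.min():>.3f} .. {self.score_matrix.max():.3f}".rjust(10),
            "=" * width,
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every intermediate and final artefact as TSV/JSON.

        Files: the six similarity matrices, the thresholded networks (DA,
        CA), affinity matrices, weighted feature matrices, the scored-pair
        table, and a provenance record (parameters, seeds, library
        versions). Numeric content is bit-reproducible across runs with the
        same inputs and seeds.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        for role, sim in self.state.similarities.items():
            paths[role] = out / f"similarity_{role}.tsv"
            write_matrix(sim, paths[role])

        d_names = list(self.disease_registry)
        c_names = list(self.circ_registry)
        for key, values, names, role, fmt in [
            ("DA", self.state.disease_network.values, d_names, "DA", "%d"),
            ("CA", self.state.circ_network.values, c_names, "CA", "%d"),
            ("Fd", self.state.disease_affinity.values, d_names, "affinity_d", _FLOAT_FMT),
            ("Fc", self.state.circ_affinity.values, c_names, "affinity_c", _FLOAT_FMT),
            ("WSD", self.state.wsd.values, d_names, "WSD", _FLOAT_FMT),
            ("WSC", self.state.wsc.values, c_names, "WSC", _FLOAT_FMT),
        ]:
            paths[key] = out / f"{key}.tsv"
            _write_named_matrix(values, names, names, paths[key], role, fmt)

        paths["scores"] = out / "scored_pairs.tsv"
        with paths["scores"].open("w", encoding="utf-8") as fh:
            fh.write("circRNA\tdisease\tscore\tlabel\n")
            for _, row in self.scored_pairs().iterrows():
                fh.write(
                    f"{row['circRNA']}\t{row['disease']}\t"
                    f"{_FLOAT_FMT % row['score']}\t{row['label']}\n"
                )

        paths["provenance"] = out / "provenance.json"
        paths["provenance"].write_text(
            json.dumps(self.provenance(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        return paths

    def provenance(self) -> dict:
        import datetime
        import sklearn
        import scipy

        return {
            "params": asdict(self.model.params),
            "negative_seed": self.negative_seed,
            "n_circ": self.model.assoc.n_circ,
            "n_disease": self.model.assoc.n_disease,
            "n_positive": len(self.model.assoc.positive_pairs()),
            "versions": {
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            },
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }
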