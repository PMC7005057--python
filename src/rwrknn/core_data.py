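"""Domain containers and on-disk formats for bipartite association data.

The package works on two entity classes — circRNAs and diseases in the
original application, but nothing here is specific to RNA biology — linked by
a binary association matrix ``A`` (rows = circRNAs, columns = diseases).
Diseases additionally carry a directed acyclic graph of ontology ancestors
used for semantic similarity.

All on-disk formats are plain TSV (UTF-8, ``#``-prefixed comment lines):

* association edge list: ``circRNA<TAB>disease``
* disease DAG file: ``disease<TAB>child_term<TAB>parent_term``
* matrix file: first row = column identifiers, first column = row identifiers
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "DataFormatError",
    "CycleError",
    "EntityRegistry",
    "AssociationMatrix",
    "DiseaseDAG",
    "SimilarityMatrix",
    "SIMILARITY_ROLES",
    "read_associations",
    "read_disease_dags",
    "write_matrix",
    "read_matrix",
]

#: Recognised similarity-matrix roles: disease semantic (DSS), disease GIP
#: (DGS), integrated disease (SD), circRNA functional (CFS), circRNA GIP
#: (CGS), integrated circRNA (SC).
SIMILARITY_ROLES = frozenset({"DSS", "DGS", "SD", "CFS", "CGS", "SC"})

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


class DataFormatError(ValueError):
    """Malformed input file (wrong column count, empty file, bad headers)."""


class CycleError(ValueError):
    """A disease's ancestor edge set contains a directed cycle."""


@dataclass(frozen=True)
class EntityRegistry:
    """Ordered, unique entity identifiers with O(1) name -> index lookup."""

    names: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index: dict[str, int] = {}
        for i, name in enumerate(self.names):
            if not isinstance(name, str) or not name:
                raise ValueError(f"entity name at position {i} is empty or not a string")
            if name in index:
                raise ValueError(f"duplicate entity name: {name!r}")
            index[name] = i
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_iterable(cls, names: Iterable[str]) -> "EntityRegistry":
        """Build a registry preserving first-appearance order."""
        seen: dict[str, None] = {}
        for name in names:
            seen.setdefault(name, None)
        return cls(tuple(seen))

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def __getitem__(self, position: int) -> str:
        return self.names[position]

    def position(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown entity: {name!r}") from None


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary circRNA x disease adjacency; rows = circRNAs, columns = diseases.

    The orientation follows the stated Nc x Nd shape of the association
    matrix: row ``i`` is the interaction profile of circRNA ``i`` over all
    diseases, and column ``j`` the profile of disease ``j`` over all circRNAs.
    """

    values: np.ndarray
    circ_registry: EntityRegistry
    disease_registry: EntityRegistry

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("association matrix must be 2-dimensional")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        if values.shape != (len(self.circ_registry), len(self.disease_registry)):
            raise ValueError(
                f"shape {values.shape} does not match registries "
                f"({len(self.circ_registry)}, {len(self.disease_registry)})"
            )
        object.__setattr__(self, "values", values.astype(np.int8, copy=False))

    @property
    def n_circ(self) -> int:
        return len(self.circ_registry)

    @property
    def n_disease(self) -> int:
        return len(self.disease_registry)

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Known associations as (circ_index, disease_index), row-major order."""
        rows, cols = np.nonzero(self.values)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass(frozen=True)
class DiseaseDAG:
    """One disease's ancestor DAG: the disease's own term plus its ontology
    ancestors, with edges directed child -> parent.

    ``root`` is the disease's own term (conventionally equal to ``disease``).
    An acyclic edge set is enforced at construction.
    """

    disease: str
    edges: frozenset[tuple[str, str]]
    root: str = ""
    extra_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.root:
            object.__setattr__(self, "root", self.disease)
        # the root is always a term; listing it again adds nothing
        object.__setattr__(self, "extra_terms", frozenset(self.extra_terms) - {self.root})
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise CycleError(f"cyclic ancestor edges for disease {self.disease!r}")

    def graph(self) -> nx.DiGraph:
        """child -> parent digraph over all declared terms."""
        g = nx.DiGraph()
        g.add_node(self.root)
        g.add_nodes_from(self.extra_terms)
        g.add_edges_from(self.edges)
        return g

    def ancestor_terms(self) -> set[str]:
        """T(d): the disease's own term plus every term reachable from it
        along child -> parent edges."""
        g = self.graph()
        return {self.root} | nx.descendants(g, self.root)

    @property
    def is_singleton(self) -> bool:
        return len(self.ancestor_terms()) == 1


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] over one entity class."""

    values: np.ndarray
    registry: EntityRegistry
    role: str

    _TOL = 1e-12

    def __post_init__(self) -> None:
        if self.role not in SIMILARITY_ROLES:
            raise ValueError(f"unknown similarity role: {self.role!r}")
        values = np.asarray(self.values, dtype=np.float64)
        n = len(self.registry)
        if values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {values.shape} != ({n}, {n})")
        if not np.allclose(values, values.T, rtol=0, atol=self._TOL):
            raise ValueError("similarity matrix is not symmetric")
        if values.min() < -self._TOL or values.max() > 1 + self._TOL:
            raise ValueError("similarity entries outside [0, 1]")
        object.__setattr__(self, "values", values)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path: Path) -> Iterator[tuple[int, str]]:
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_associations(path: str | Path) -> AssociationMatrix:
    """Read a 2-column TSV edge list ``circRNA<TAB>disease``.

    Registries follow first-appearance order; duplicate lines collapse to a
    single association. Raises :class:`DataFormatError` on malformed lines or
    an empty file.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 2 or not all(fields):
            raise DataFormatError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
            )
        pairs.append((fields[0], fields[1]))
    if not pairs:
        raise DataFormatError(f"{path}: no association records found")
    circ_registry = EntityRegistry.from_iterable(c for c, _ in pairs)
    disease_registry = EntityRegistry.from_iterable(d for _, d in pairs)
    values = np.zeros((len(circ_registry), len(disease_registry)), dtype=np.int8)
    for c, d in pairs:
        values[circ_registry.position(c), disease_registry.position(d)] = 1
    return AssociationMatrix(values, circ_registry, disease_registry)


def read_disease_dags(
    path: str | Path, registry: EntityRegistry
) -> dict[str, DiseaseDAG]:
    """Read a 3-column TSV ``disease<TAB>child_term<TAB>parent_term``.

    A self-edge row ``(disease, term, term)`` declares an isolated term
    without adding an edge. Diseases in ``registry`` that have no rows map to
    a singleton DAG of their own term. Rows naming diseases outside the
    registry are skipped with a warning; a cyclic edge set raises
    :class:`CycleError` naming the disease.
    """
    path = Path(path)
    edges: dict[str, set[tuple[str, str]]] = {}
    loners: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 3 or not all(fields):
            raise DataFormatError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
            )
        disease, child, parent = fields
        if disease not in registry:
            warnings.warn(
                f"{path}:{lineno}: disease {disease!r} not in registry; row skipped",
                stacklevel=2,
            )
            continue
        if child == parent:
            loners.setdefault(disease, set()).add(child)
        else:
            edges.setdefault(disease, set()).add((child, parent))

    dags: dict[str, DiseaseDAG] = {}
    for disease in registry:
        dags[disease] = DiseaseDAG(
            disease=disease,
            edges=frozenset(edges.get(disease, set())),
            extra_terms=frozenset(loners.get(disease, set())),
        )
    return dags


def write_matrix(
    m: SimilarityMatrix | AssociationMatrix, path: str | Path
) -> None:
    """Write a matrix as TSV with identifier headers and a role comment."""
    path = Path(path)
    if isinstance(m, SimilarityMatrix):
        role = m.role
        row_names = col_names = m.registry.names
        values = m.values
        fmt = _FLOAT_FMT
    elif isinstance(m, AssociationMatrix):
        role = "association"
        row_names = m.circ_registry.names
        col_names = m.disease_registry.names
        values = m.values
        fmt = "%d"
    else:
        raise TypeError(f"cannot write object of type {type(m).__name__}")

    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# role: {role}\n")
        fh.write("id\t" + "\t".join(col_names) + "\n")
        for name, row in zip(row_names, values):
            fh.write(name + "\t" + "\t".join(fmt % v for v in row) + "\n")


def read_matrix(
    path: str | Path, role: str | None = None
) -> SimilarityMatrix | AssociationMatrix:
    """Read a matrix written by :func:`write_matrix`.

    The role is taken from the ``# role:`` header comment unless overridden.
    Similarity roles require a square matrix with identical row and column
    identifiers.
    """
    path = Path(path)
    file_role: str | None = None
    header: list[str] | None = None
    row_names: list[str] = []
    rows: list[list[str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if line.lstrip().startswith("#"):
                stripped = line.lstrip("# ").strip()
                if stripped.startswith("role:"):
                    file_role = stripped.split(":", 1)[1].strip()
                continue
            if not line.strip():
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
            else:
                row_names.append(fields[0])
                rows.append(fields[1:])
    if header is None or not rows:
        raise DataFormatError(f"{path}: no matrix data found")

    role = role or file_role
    if role is None:
        raise DataFormatError(f"{path}: no role header and no role argument given")

    if role in SIMILARITY_ROLES:
        if list(header) != row_names:
            raise DataFormatError(
                f"{path}: role {role} requires identical row/column identifiers"
            )
        values = np.array([[float(v) for v in row] for row in rows])
        return SimilarityMatrix(values, EntityRegistry(tuple(row_names)), role)
    if role == "association":
        values = np.array([[int(v) for v in row] for row in rows], dtype=np.int8)
        return AssociationMatrix(
            values,
            EntityRegistry(tuple(row_names)),
            EntityRegistry(tuple(header)),
        )
    raise DataFormatError(f"{path}: unknown matrix role {role!r}")
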