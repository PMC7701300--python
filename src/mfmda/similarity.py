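"""Disease and miRNA similarity matrices.

Three constructions are provided:

* **Semantic similarity** between diseases, computed on the directed acyclic
  graph (DAG) each disease spans in a MeSH-style hierarchy.  Every ancestor
  heading ``t`` of a disease ``d`` contributes ``D_d(t)``, equal to 1 for the
  disease itself and decaying by a factor ``delta`` per hierarchy level below
  it.  The similarity of two diseases is the summed contribution of their
  shared ancestors, normalized by the total contributions of both DAGs — so
  identical DAGs score 1 and disjoint DAGs score 0.

* **Gaussian interaction-profile (GIP) kernels** for both axes of a binary
  association matrix: the similarity of two entities is a Gaussian of the
  squared distance between their association profiles, with the bandwidth
  normalized by the mean squared profile norm so that it adapts to the
  density of the network.

* **Piecewise integration**: the semantic (or externally supplied functional)
  similarity is used wherever both entities have one; the GIP kernel fills in
  for entities without curated annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

if TYPE_CHECKING:  # pragma: no cover
    from .io import MeshTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "DiseaseDAG",
    "KernelBandwidth",
    "build_disease_dag",
    "semantic_contributions",
    "semantic_similarity",
    "semantic_similarity_matrix",
    "gip_bandwidth",
    "gip_kernel",
    "integrate_similarity",
    "disease_similarity",
    "mirna_similarity",
]


def _norm_label(name: str) -> str:
    return name.strip().lower()


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with per-entry provenance.

    ``primary_mask[i, j]`` is True where the value came from a curated
    source (semantic or functional similarity) and False where it is a
    Gaussian interaction-profile kernel value.
    """

    labels: list[str]
    values: np.ndarray
    primary_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if self.primary_mask is None:
            self.primary_mask = np.zeros((n, n), dtype=bool)
        else:
            self.primary_mask = np.asarray(self.primary_mask, dtype=bool)
            if self.primary_mask.shape != (n, n):
                raise ValueError("primary_mask shape does not match matrix")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self) -> dict[str, int]:
        """Map of normalized label -> position."""
        return {_norm_label(l): i for i, l in enumerate(self.labels)}

    def validate(self, atol: float = 1e-12) -> None:
        """Check symmetry, unit diagonal and the [0, 1] range."""
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("similarity diagonal is not 1")
        if v.min() < -atol or v.max() > 1 + atol:
            raise ValueError("similarity values outside [0, 1]")


@dataclass(frozen=True)
class DiseaseDAG:
    """The sub-hierarchy a disease spans in the MeSH tree.

    ``nodes`` are tree-number prefixes (each prefix is an ancestor heading,
    e.g. ``C04`` and ``C04.588`` for tree number ``C04.588``); ``edges`` are
    parent -> child links between consecutive prefixes; ``self_nodes`` are
    the full tree numbers, i.e. the positions of the disease itself.
    """

    disease: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    self_nodes: frozenset[str]


@dataclass(frozen=True)
class KernelBandwidth:
    """Raw (``gamma_prime``) and profile-normalized (``gamma``) GIP bandwidth."""

    gamma_prime: float
    gamma: float


def build_disease_dag(disease: str, mesh_table: "MeshTable") -> DiseaseDAG | None:
    """Expand a disease's MeSH tree numbers into its ancestor DAG.

    Returns None when the disease has no tree number in the table; callers
    then fall back to the Gaussian interaction-profile kernel.
    """
    numbers = mesh_table.tree_numbers(disease)
    if not numbers:
        return None
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for tn in numbers:
        parts = tn.split(".")
        prefixes = [".".join(parts[: i + 1]) for i in range(len(parts))]
        nodes.update(prefixes)
        edges.update(zip(prefixes[:-1], prefixes[1:]))
    return DiseaseDAG(
        disease=disease,
        nodes=frozenset(nodes),
        edges=frozenset(edges),
        self_nodes=frozenset(numbers),
    )


def semantic_contributions(dag: DiseaseDAG, delta: float = 0.5) -> dict[str, float]:
    """Contribution ``D_d(t)`` of each DAG node to the disease.

    The disease's own nodes contribute 1; every other node contributes
    ``max(delta * D_d(child))`` over its children, evaluated in reverse
    topological order.  ``delta`` is the per-level semantic decay in (0, 1).
    """
    if not 0 < delta < 1:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    if not dag.nodes:
        raise ValueError("empty DAG")
    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    g.add_edges_from(dag.edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError(f"cycle detected in DAG of {dag.disease!r}")
    contrib: dict[str, float] = {}
    for t in reversed(list(nx.topological_sort(g))):
        if t in dag.self_nodes:
            contrib[t] = 1.0
        else:
            children = list(g.successors(t))
            if not children:
                raise ValueError(
                    f"node {t!r} in DAG of {dag.disease!r} is a leaf but not "
                    "a position of the disease itself"
                )
            contrib[t] = max(delta * contrib[c] for c in children)
    return contrib


def semantic_similarity(
    dag_i: DiseaseDAG, dag_j: DiseaseDAG, delta: float = 0.5
) -> float:
    """Shared-ancestor semantic similarity of two disease DAGs, in [0, 1]."""
    ci = semantic_contributions(dag_i, delta)
    cj = semantic_contributions(dag_j, delta)
    return _semantic_similarity_from_contribs(ci, cj)


def _semantic_similarity_from_contribs(
    ci: Mapping[str, float], cj: Mapping[str, float]
) -> float:
    shared = ci.keys() & cj.keys()
    if not shared:
        return 0.0
    num = sum(ci[t] + cj[t] for t in shared)
    den = sum(ci.values()) + sum(cj.values())
    return num / den


def semantic_similarity_matrix(
    disease_names: Sequence[str],
    mesh_table: "MeshTable",
    delta: float = 0.5,
) -> SimilarityMatrix:
    """Pairwise semantic similarity for an ordered list of diseases.

    Entries for pairs where either disease lacks a DAG are left at 0 with
    ``primary_mask`` False; :func:`integrate_similarity` fills those from the
    GIP kernel.  Diseases with a DAG get an exact 1.0 self-similarity.
    """
    n = len(disease_names)
    values = np.zeros((n, n))
    contribs: list[dict[str, float] | None] = []
    for name in disease_names:
        dag = build_disease_dag(name, mesh_table)
        contribs.append(semantic_contributions(dag, delta) if dag else None)
    has_dag = np.array([c is not None for c in contribs], dtype=bool)
    for i in range(n):
        if contribs[i] is None:
            continue
        values[i, i] = 1.0
        for j in range(i + 1, n):
            if contribs[j] is None:
                continue
            s = _semantic_similarity_from_contribs(contribs[i], contribs[j])
            values[i, j] = values[j, i] = s
    mask = np.outer(has_dag, has_dag)
    return SimilarityMatrix(list(disease_names), values, primary_mask=mask)


def gip_bandwidth(
    Y: np.ndarray, axis: str = "mirna", gamma_prime: float = 1.0
) -> KernelBandwidth:
    """Normalized GIP bandwidth: gamma = gamma' / mean squared profile norm."""
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    Y = np.asarray(Y, dtype=float)
    profiles = Y if axis == "mirna" else Y.T
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0:
        raise ValueError(
            "all interaction profiles are zero; GIP bandwidth is undefined"
        )
    return KernelBandwidth(gamma_prime=gamma_prime, gamma=gamma_prime / mean_sq)


def gip_kernel(
    Y: np.ndarray,
    axis: str = "mirna",
    gamma_prime: float = 1.0,
    labels: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over rows (miRNAs) or columns
    (diseases) of a binary association matrix.

    ``K(i, j) = exp(-gamma * ||profile_i - profile_j||^2)`` with gamma
    normalized by the mean squared profile norm.  Symmetric with unit
    diagonal by construction.
    """
    if axis not in ("mirna", "disease"):
        raise ValueError(f"axis must be 'mirna' or 'disease', got {axis!r}")
    Y = np.asarray(Y, dtype=float)
    bw = gip_bandwidth(Y, axis=axis, gamma_prime=gamma_prime)
    profiles = Y if axis == "mirna" else Y.T
    d2 = cdist(profiles, profiles, metric="sqeuclidean")
    K = np.exp(-bw.gamma * d2)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    if labels is None:
        labels = [f"{axis}-{i}" for i in range(profiles.shape[0])]
    return SimilarityMatrix(list(labels), K, primary_mask=None)


def integrate_similarity(
    primary: SimilarityMatrix | None,
    gaussian: SimilarityMatrix,
    has_primary: np.ndarray | None = None,
) -> SimilarityMatrix:
    """Piecewise integration of a curated similarity with the GIP kernel.

    Entry (i, j) takes the primary (semantic/functional) value when BOTH
    entities have a primary similarity defined, and the Gaussian kernel value
    otherwise.  ``has_primary`` marks which entities are covered by the
    primary source; by default it is read off the primary mask diagonal.
    The diagonal is forced to exactly 1.
    """
    if primary is None:
        out = gaussian.values.copy()
        np.fill_diagonal(out, 1.0)
        return SimilarityMatrix(list(gaussian.labels), out, primary_mask=None)
    if len(primary.labels) != len(gaussian.labels) or any(
        _norm_label(a) != _norm_label(b)
        for a, b in zip(primary.labels, gaussian.labels)
    ):
        raise ValueError("primary and gaussian similarity labels do not match")
    if has_primary is None:
        has_primary = np.diag(primary.primary_mask).copy()
    has_primary = np.asarray(has_primary, dtype=bool)
    mask = np.outer(has_primary, has_primary)
    out = np.where(mask, primary.values, gaussian.values)
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(list(primary.labels), out, primary_mask=mask)


def disease_similarity(
    Y: np.ndarray,
    disease_names: Sequence[str],
    mesh_table: "MeshTable | None",
    delta: float = 0.5,
    gamma_prime: float = 1.0,
) -> SimilarityMatrix:
    """Integrated disease similarity: semantic where DAGs exist, GIP elsewhere.

    The GIP kernel is computed from the supplied association matrix ``Y``,
    which in cross-validation must be the *training* matrix so that held-out
    associations cannot leak through the profiles.
    """
    gauss = gip_kernel(Y, axis="disease", gamma_prime=gamma_prime,
                       labels=disease_names)
    if mesh_table is None:
        return integrate_similarity(None, gauss)
    sem = semantic_similarity_matrix(disease_names, mesh_table, delta)
    return integrate_similarity(sem, gauss)


def mirna_similarity(
    Y: np.ndarray,
    mirna_names: Sequence[str],
    fs: SimilarityMatrix | None = None,
    gamma_prime: float = 1.0,
) -> SimilarityMatrix:
    """Integrated miRNA similarity: functional (FS) where available, GIP
    elsewhere.

    ``fs`` is an externally computed functional-similarity matrix; miRNAs
    absent from it fall back to the GIP kernel, matched by trimmed,
    case-insensitive name.
    """
    gauss = gip_kernel(Y, axis="mirna", gamma_prime=gamma_prime,
                       labels=mirna_names)
    if fs is None:
        return integrate_similarity(None, gauss)
    fs_index = fs.index()
    n = len(mirna_names)
    has_fs = np.zeros(n, dtype=bool)
    aligned = np.zeros((n, n))
    pos = [fs_index.get(_norm_label(name)) for name in mirna_names]
    for i, pi in enumerate(pos):
        if pi is None:
            continue
        has_fs[i] = True
        for j, pj in enumerate(pos):
            if pj is not None:
                aligned[i, j] = fs.values[pi, pj]
    primary = SimilarityMatrix(
        list(mirna_names), aligned, primary_mask=np.outer(has_fs, has_fs)
    )
    return integrate_similarity(primary, gauss, has_primary=has_fs)
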