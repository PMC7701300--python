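"""Synthetic miRNA-disease association data with planted low-rank structure.

The generator emulates the statistical assumptions the factorization model
exploits: entities belong to latent groups, associations concentrate where a
miRNA's and a disease's groups align, functionally similar miRNAs share
latent profiles, and same-group diseases sit close together in a MeSH-like
hierarchy.  Concretely it samples cluster-structured nonnegative factors
``W*`` (miRNAs) and ``H*`` (diseases), forms the row-normalized ground-truth
score matrix ``P = W* H*^T``, plants the top-scoring fraction of cells as
known associations, perturbs a small fraction of them, fabricates a
functional-similarity matrix from the cosine similarity of ``W*`` rows, and
embeds disease groups as subtrees of a synthetic MeSH hierarchy.

A deterministic :func:`toy_fixture` bundles the hand-checkable micro-cases
used across the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

from .factorization import Hyperparams
from .io import AssociationDataset, MeshTable
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "SyntheticData", "PRESETS", "generate", "toy_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings.

    n_m, n_d      number of miRNAs / diseases.
    k_true        number of planted latent groups.
    density       fraction of cells planted as known associations.
    noise         fraction of planted positives relocated to random unknown
                  pairs (a 1->0 flip paired with a 0->1 flip; density is
                  preserved).
    dag_depth     number of levels in the synthetic MeSH subtrees.
    fs_noise      sd of the perturbation added to the fabricated functional
                  similarity.
    mesh_missing  fraction of diseases omitted from the MeSH table, to
                  exercise the Gaussian-kernel fallback.
    """

    n_m: int = 200
    n_d: int = 100
    k_true: int = 10
    density: float = 0.05
    noise: float = 0.02
    dag_depth: int = 4
    fs_noise: float = 0.1
    mesh_missing: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_m, self.n_d, self.k_true) < 1:
            raise ValueError("entity counts and k_true must be positive")
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must be in [0, 0.5)")
        if self.dag_depth < 2:
            raise ValueError("dag_depth must be at least 2")
        if not 0 <= self.mesh_missing < 1:
            raise ValueError("mesh_missing must be in [0, 1)")


@dataclass
class SyntheticData:
    """A generated dataset bundle with its ground truth."""

    dataset: AssociationDataset
    mesh_table: MeshTable
    fs: SimilarityMatrix
    truth: np.ndarray
    mirna_groups: np.ndarray
    disease_groups: np.ndarray
    spec: SyntheticSpec


#: Ready-made generator settings.  "small" is the standard benchmark used by
#: the test suite; "medium" approximates the scale and ~2.9% density of a
#: curated human miRNA-disease catalogue.
PRESETS: dict[str, SyntheticSpec] = {
    "small": SyntheticSpec(n_m=200, n_d=100, k_true=10, density=0.05,
                           noise=0.02),
    "medium": SyntheticSpec(n_m=495, n_d=383, k_true=15, density=0.029,
                            noise=0.02),
}


def _group_assignment(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Shuffled round-robin assignment: every group nonempty when n >= k."""
    return rng.permutation(np.arange(n) % k)


def _cluster_factors(
    groups: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Nonnegative factors: strong loading on the own group, weak background."""
    n = len(groups)
    F = 0.2 * rng.random((n, k))
    F[np.arange(n), groups] += 1.0
    return F


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Generate a dataset bundle; byte-for-byte deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_m * spec.n_d
    n_pos = int(round(spec.density * n_cells))
    if not 0 < n_pos < n_cells:
        raise ValueError(
            f"density {spec.density} infeasible for {spec.n_m}x{spec.n_d}"
        )
    if spec.n_d > 999:
        raise ValueError("at most 999 diseases fit the synthetic tree numbers")

    mirna_groups = _group_assignment(spec.n_m, spec.k_true, rng)
    disease_groups = _group_assignment(spec.n_d, spec.k_true, rng)
    W = _cluster_factors(mirna_groups, spec.k_true, rng)
    H = _cluster_factors(disease_groups, spec.k_true, rng)
    P = W @ H.T
    P = P / P.sum(axis=1, keepdims=True)

    # Plant the top `density` fraction of ground-truth scores as positives.
    flat_order = np.argsort(P, axis=None, kind="stable")[::-1]
    Y = np.zeros(n_cells)
    Y[flat_order[:n_pos]] = 1.0
    Y = Y.reshape(spec.n_m, spec.n_d)

    # Relocate a `noise` fraction of positives to random unknown pairs.
    n_flip = int(round(spec.noise * n_pos))
    if n_flip:
        pos_idx = np.flatnonzero(Y.ravel() == 1)
        zero_idx = np.flatnonzero(Y.ravel() == 0)
        drop = rng.choice(pos_idx, size=n_flip, replace=False)
        add = rng.choice(zero_idx, size=n_flip, replace=False)
        Yf = Y.ravel()
        Yf[drop] = 0.0
        Yf[add] = 1.0
        Y = Yf.reshape(spec.n_m, spec.n_d)

    mirna_names = [f"hsa-mir-{i:04d}" for i in range(spec.n_m)]
    disease_names = [f"disease-{j:03d}" for j in range(spec.n_d)]
    dataset = AssociationDataset(mirna_names, disease_names, Y)

    # Fabricated functional similarity: cosine of the miRNA factors plus
    # symmetric noise, clipped to [0, 1].
    FS = cosine_similarity(W)
    if spec.fs_noise:
        E = rng.normal(scale=spec.fs_noise, size=FS.shape)
        FS = FS + (E + E.T) / 2.0
    FS = np.clip(FS, 0.0, 1.0)
    np.fill_diagonal(FS, 1.0)
    fs = SimilarityMatrix(
        mirna_names, FS,
        primary_mask=np.ones((spec.n_m, spec.n_m), dtype=bool),
    )

    # MeSH-like hierarchy: one subtree per disease group, with a shared
    # prefix chain of depth dag_depth - 1 and a unique leaf per disease.
    n_missing = int(round(spec.mesh_missing * spec.n_d))
    missing = set(rng.choice(spec.n_d, size=n_missing, replace=False))
    entries = []
    for j in range(spec.n_d):
        if j in missing:
            continue
        g = disease_groups[j]
        chain = [f"C{g + 1:02d}"] + [f"{500 + g:03d}"] * (spec.dag_depth - 2)
        entries.append((disease_names[j], ".".join(chain + [f"{j:03d}"])))
    mesh_table = MeshTable(entries)

    return SyntheticData(
        dataset=dataset, mesh_table=mesh_table, fs=fs, truth=P,
        mirna_groups=mirna_groups, disease_groups=disease_groups, spec=spec,
    )


def toy_fixture() -> dict:
    """Hand-checkable micro-cases shared by the test suites.

    * two sibling diseases under one root: semantic similarity 1/3 at
      decay 0.5;
    * the 2x2 identity association matrix: GIP off-diagonal exp(-2) at
      gamma' = 1;
    * a rank-1 3x2 instance where (W, H) exactly factor Y, a fixed point of
      the unregularized multiplicative update.
    """
    sibling_mesh = MeshTable([
        ("inflammation-a", "C01.100"),
        ("inflammation-b", "C01.200"),
    ])
    identity_dataset = AssociationDataset(
        ["mir-a", "mir-b"], ["disease-a", "disease-b"], np.eye(2)
    )
    W = np.array([[1.0], [2.0], [3.0]])
    H = np.array([[1.0], [2.0]])
    return {
        "sibling_mesh": sibling_mesh,
        "sibling_diseases": ("inflammation-a", "inflammation-b"),
        "sibling_expected": 1.0 / 3.0,
        "identity_dataset": identity_dataset,
        "gip_offdiag_expected": float(np.exp(-2.0)),
        "stationary_W": W,
        "stationary_H": H,
        "stationary_Y": W @ H.T,
        "stationary_hyper": Hyperparams(
            k=1, lambda_l=0.0, lambda_m=0.0, lambda_d=0.0, eps=0.0
        ),
    }
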