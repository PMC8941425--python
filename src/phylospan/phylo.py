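"""Patristic distances from a Newick tree and the L2-norm phylogenetic
covariance kernel.

The kernel assigns between-species covariance that declines with squared
patristic distance from a maximum at zero distance:

    K_ij = eta_sq * exp(-rho * d_ij^2)        (i != j)
    K_ii = eta_sq + sigma_ind^2

i.e. the squared-exponential Gaussian-process covariance of the hierarchical
modelling literature, with an independent per-species variance on the
diagonal. Distances are rescaled to a maximum of 1 by default so that
priors on the decay rate are free of the arbitrary depth of the source tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloDistanceMatrix",
    "KernelParams",
    "patristic_distances",
    "l2norm_kernel",
    "read_newick",
    "match_species",
]

DEFAULT_JITTER = 1e-9


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of the phylogenetic covariance kernel.

    eta_sq : maximum covariance between infinitesimally close species
    rho : decay rate per squared distance
    sigma_ind : sd of the independent (non-phylogenetic) per-species term
    """

    eta_sq: float
    rho: float
    sigma_ind: float

    def __post_init__(self) -> None:
        if self.eta_sq < 0 or self.rho < 0 or self.sigma_ind < 0:
            raise ValueError("kernel parameters must be nonnegative")


@dataclass(frozen=True)
class PhyloDistanceMatrix:
    species: tuple[str, ...]
    distances: np.ndarray  # symmetric, zero-diagonal

    def __post_init__(self) -> None:
        d = self.distances
        if d.shape != (len(self.species), len(self.species)):
            raise ValueError("distance matrix shape does not match species")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")

    def subset(self, species: list[str]) -> "PhyloDistanceMatrix":
        idx = [self.species.index(s) for s in species]
        return PhyloDistanceMatrix(
            species=tuple(species),
            distances=self.distances[np.ix_(idx, idx)],
        )


def read_newick(path_or_string: str, *, is_path: bool = True) -> dendropy.Tree:
    src = {"path": path_or_string} if is_path else {"data": path_or_string}
    return dendropy.Tree.get(schema="newick", **src)


def patristic_distances(
    tree: dendropy.Tree, *, rescale: bool = True
) -> PhyloDistanceMatrix:
    """Pairwise sums of branch lengths between tips.

    By default distances are rescaled so the maximum pairwise distance is 1
    (tree depth is arbitrary across sources; only relative distances enter
    the kernel). Duplicate tip labels are rejected.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise ValueError("tree must have at least 2 tips")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            d[i, j] = d[j, i] = dij
    if np.any(d < 0):
        raise ValueError("negative branch lengths produce invalid distances")
    if rescale:
        dmax = d.max()
        if dmax > 0:
            d = d / dmax
    return PhyloDistanceMatrix(species=tuple(labels), distances=d)


def l2norm_kernel(
    dist: PhyloDistanceMatrix,
    params: KernelParams,
    *,
    jitter: float = DEFAULT_JITTER,
) -> np.ndarray:
    """Covariance matrix K_ij = eta_sq*exp(-rho*d_ij^2), K_ii += sigma_ind^2.

    A small jitter is added to the diagonal before the positive-definiteness
    check; a matrix that still fails to factorize raises ArithmeticError.
    """
    d = dist.distances
    k = params.eta_sq * np.exp(-params.rho * d ** 2)
    k[np.diag_indices_from(k)] = params.eta_sq + params.sigma_ind ** 2
    k = k + jitter * np.eye(k.shape[0])
    try:
        np.linalg.cholesky(k)
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError(
            "kernel matrix not positive definite after jitter"
        ) from exc
    return k


def match_species(
    tree_species: list[str], table_species: list[str]
) -> list[str]:
    """Intersection of tree tips and trait-table species, preserving table
    order; raises with both unmatched lists if the intersection is empty."""
    tree_set = set(tree_species)
    common = [s for s in table_species if s in tree_set]
    if not common:
        raise ValueError(
            "no overlapping species between tree and trait table; "
            f"tree-only={sorted(tree_set - set(table_species))[:10]}, "
            f"table-only={sorted(set(table_species) - tree_set)[:10]}"
        )
    return common
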