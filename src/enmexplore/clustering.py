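"""Fixed-radius RMSD clustering of conformers.

Implements the spawn-on-overflow k-means variant used by structure
clustering tools that take an RMSD cutoff instead of a cluster count:
each structure joins the nearest existing centroid if it lies within the
radius, otherwise it seeds a new cluster. Centroids are recomputed after
every assignment pass (members are superposed onto the cluster
representative before their C-alpha coordinates are averaged) and the
passes repeat until the assignment is stable. The averaged centroid is
used only for distances; the representative — the real member closest to
the centroid — is what gets promoted downstream.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .structio import Structure, kabsch, kabsch_rmsd_many

__all__ = ["Cluster", "ClusterConfig", "pairwise_rmsd", "kcluster", "select_representatives"]


@dataclasses.dataclass
class Cluster:
    member_ids: list[str]
    centroid_coords: np.ndarray  # (N_ca, 3)
    representative_id: str
    contains_parent: bool
    converged: bool = True


@dataclasses.dataclass(frozen=True)
class ClusterConfig:
    radius: float  # A; set to the deformation RMSD
    max_iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")


def _ca_stack(conformers: Sequence[Structure]) -> np.ndarray:
    cas = [s.ca_coords() for s in conformers]
    n = cas[0].shape[0]
    if any(c.shape[0] != n for c in cas):
        raise ValueError("conformers do not share C-alpha topology")
    return np.stack(cas)


def pairwise_rmsd(conformers: Sequence[Structure]) -> np.ndarray:
    """Symmetric matrix of optimal-fit C-alpha RMSDs (Angstrom)."""
    X = _ca_stack(conformers)
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n - 1):
        block = kabsch_rmsd_many(
            np.broadcast_to(X[i], (n - i - 1,) + X[i].shape), X[i + 1 :]
        )
        out[i, i + 1 :] = block
        out[i + 1 :, i] = block
    return out


def _dist_to_centroid(X: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    return kabsch_rmsd_many(X, np.broadcast_to(centroid, X.shape))


def _recompute_centroid(X: np.ndarray, members: list[int], centroid: np.ndarray) -> tuple[np.ndarray, int]:
    """Average member coordinates after superposing each onto the representative.

    Returns (centroid, representative index into ``members``).
    """
    d = _dist_to_centroid(X[members], centroid)
    rep_local = int(np.argmin(d))
    ref = X[members[rep_local]]
    acc = np.zeros_like(ref)
    for m in members:
        R, t, _ = kabsch(X[m], ref)
        acc += X[m] @ R.T + t
    new_centroid = acc / len(members)
    d = _dist_to_centroid(X[members], new_centroid)
    rep_local = int(np.argmin(d))
    return new_centroid, rep_local


def kcluster(
    conformers: Sequence[Structure],
    config: ClusterConfig,
    ids: Sequence[str] | None = None,
    parent_ids: Sequence[str] | set[str] | None = None,
) -> list[Cluster]:
    """Cluster structures by mutual C-alpha RMSD with a fixed radius.

    Deterministic for a given seed and input order. Non-convergence within
    ``max_iterations`` returns the last assignment with ``converged=False``
    on every cluster.
    """
    if len(conformers) == 0:
        raise ValueError("need at least one conformer")
    if ids is None:
        ids = [str(i) for i in range(len(conformers))]
    ids = list(ids)
    parents = set(parent_ids or ())
    X = _ca_stack(conformers)
    n = X.shape[0]

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)

    centroids: list[np.ndarray] = []
    assignment = np.full(n, -1, dtype=int)
    converged = False
    for it in range(config.max_iterations):
        dists = (
            np.stack([_dist_to_centroid(X, c) for c in centroids], axis=1)
            if centroids
            else np.zeros((n, 0))
        )
        new_assignment = np.full(n, -1, dtype=int)
        pass_order = order if it == 0 else np.arange(n)
        for i in pass_order:
            if dists.shape[1]:
                j = int(np.argmin(dists[i]))
                if dists[i, j] <= config.radius:
                    new_assignment[i] = j
                    continue
            # spawn a new cluster seeded at this structure
            centroids.append(X[i].copy())
            col = _dist_to_centroid(X, centroids[-1])
            dists = np.concatenate([dists, col[:, None]], axis=1)
            new_assignment[i] = dists.shape[1] - 1
        # drop empty clusters, recompute centroids
        used = sorted(set(new_assignment.tolist()))
        remap = {old: k for k, old in enumerate(used)}
        new_assignment = np.array([remap[a] for a in new_assignment])
        members_of = [np.nonzero(new_assignment == k)[0].tolist() for k in range(len(used))]
        new_centroids = []
        for k, members in enumerate(members_of):
            c, _ = _recompute_centroid(X, members, centroids[used[k]])
            new_centroids.append(c)
        stable = np.array_equal(new_assignment, assignment)
        assignment = new_assignment
        centroids = new_centroids
        if stable:
            converged = True
            break

    clusters: list[Cluster] = []
    for k, c in enumerate(centroids):
        members = np.nonzero(assignment == k)[0].tolist()
        _, rep_local = _recompute_centroid(X, members, c)
        member_ids = [ids[m] for m in members]
        clusters.append(
            Cluster(
                member_ids=member_ids,
                centroid_coords=c,
                representative_id=ids[members[rep_local]],
                contains_parent=any(m in parents for m in member_ids),
                converged=converged,
            )
        )
    return clusters


def select_representatives(
    clusters: Sequence[Cluster], parent_ids: Sequence[str] | set[str]
) -> list[str]:
    """Representatives of clusters that contain no parent structure.

    An empty result is valid; the generation engine treats it as a
    termination signal.
    """
    parents = set(parent_ids)
    out = []
    for cluster in clusters:
        if cluster.contains_parent or any(m in parents for m in cluster.member_ids):
            continue
        out.append(cluster.representative_id)
    return out
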