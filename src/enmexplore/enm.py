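"""Contact-weighted anisotropic elastic network model.

Residues are network nodes placed at their heavy-atom centroids. The
spring constant between two residues is proportional to the number of
their heavy-atom pairs within a distance cutoff (10 Angstrom by default),
so well-packed interfaces are stiffer than grazing contacts. The Hessian
is the standard anisotropic-network form built from 3x3 super-elements;
its six near-zero eigenvalues are the rigid-body modes, and the next few
eigenpairs are the slow, collective motions used for deformation.

The base force constant is 1 (arbitrary units): only relative spring
strengths and mode shapes matter downstream because deformation amplitude
is renormalized to a fixed RMSD.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .structio import CoarseModel, Structure

__all__ = [
    "ElasticNetwork",
    "ENMModes",
    "ConnectivityError",
    "build_network",
    "hessian",
    "slow_modes",
    "mode_overlap",
]

RIGID_BODY_TOL = 1e-8  # relative eigenvalue threshold for the 6 zero modes


class ConnectivityError(ValueError):
    """Network with more than six rigid-body modes (disconnected)."""


@dataclasses.dataclass
class ElasticNetwork:
    coarse: CoarseModel
    cutoff: float
    spring_weights: sp.coo_matrix  # symmetric, zero diagonal, integer counts

    @property
    def n_nodes(self) -> int:
        return self.coarse.n_nodes

    def is_connected(self) -> bool:
        n_comp, _ = sp.csgraph.connected_components(
            self.spring_weights.tocsr(), directed=False
        )
        return n_comp == 1


@dataclasses.dataclass
class ENMModes:
    """Slow eigenpairs of the network Hessian, rigid-body modes removed.

    ``eigenvalues`` ascend; ``eigenvectors`` has one orthonormal 3N-vector
    per column, sign-fixed so the first nonzero component is positive.
    """

    eigenvalues: np.ndarray  # (M,)
    eigenvectors: np.ndarray  # (3N, M)
    n_modes_kept: int


def build_network(
    coarse: CoarseModel, structure: Structure, cutoff: float = 10.0
) -> ElasticNetwork:
    """Count heavy-atom contact pairs between residues within ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy_idx = np.nonzero(structure.is_heavy)[0]
    heavy_xyz = structure.coords[heavy_idx]
    heavy_res = structure.atom_residue[heavy_idx]
    tree = cKDTree(heavy_xyz)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    ri = heavy_res[pairs[:, 0]]
    rj = heavy_res[pairs[:, 1]]
    inter = ri != rj
    ri, rj = ri[inter], rj[inter]
    lo = np.minimum(ri, rj)
    hi = np.maximum(ri, rj)
    n = coarse.n_nodes
    flat = lo * n + hi
    uniq, counts = np.unique(flat, return_counts=True)
    i = uniq // n
    j = uniq % n
    w = sp.coo_matrix(
        (
            np.concatenate([counts, counts]).astype(float),
            (np.concatenate([i, j]), np.concatenate([j, i])),
        ),
        shape=(n, n),
    )
    return ElasticNetwork(coarse=coarse, cutoff=float(cutoff), spring_weights=w)


def hessian(network: ElasticNetwork) -> np.ndarray:
    """Assemble the dense 3N x 3N anisotropic-network Hessian.

    Off-diagonal super-element for a connected pair (i, j):
    ``H_ij = -k_ij * d d^T / |d|^2`` with d the centroid difference;
    diagonal blocks are minus the row sums of the off-diagonals.
    """
    xyz = network.coarse.centroids
    n = network.n_nodes
    H = np.zeros((3 * n, 3 * n))
    w = network.spring_weights.tocoo()
    for i, j, k in zip(w.row, w.col, w.data):
        if i >= j:
            continue
        d = xyz[j] - xyz[i]
        d2 = float(d @ d)
        if d2 < 1e-12:
            raise ValueError(f"coincident centroids for connected pair ({i}, {j})")
        block = -k * np.outer(d, d) / d2
        H[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        H[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        H[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        H[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return H


def slow_modes(H: np.ndarray, n_modes: int = 3) -> ENMModes:
    """Extract the ``n_modes`` slowest internal modes of a Hessian.

    The six smallest-magnitude eigenvalues (rigid-body translations and
    rotations) are discarded by a relative threshold; more than six
    near-zero eigenvalues indicate a disconnected network.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    H = np.asarray(H)
    if not np.allclose(H, H.T, atol=1e-10):
        raise ValueError("Hessian must be symmetric")
    evals, evecs = np.linalg.eigh(H)
    lam_max = float(np.abs(evals).max())
    near_zero = np.abs(evals) <= RIGID_BODY_TOL * max(lam_max, 1.0)
    n_zero = int(near_zero.sum())
    if n_zero > 6:
        raise ConnectivityError(
            f"{n_zero} near-zero eigenvalues; network appears disconnected"
        )
    if n_zero < 6:
        raise ConnectivityError(
            f"only {n_zero} near-zero eigenvalues; expected 6 rigid-body modes"
        )
    keep = np.nonzero(~near_zero)[0]
    if n_modes > keep.size:
        raise ValueError(f"requested {n_modes} modes but only {keep.size} available")
    order = keep[np.argsort(evals[keep])][:n_modes]
    lam = evals[order].copy()
    U = evecs[:, order].copy()
    # deterministic sign: first component above tolerance made positive
    for m in range(U.shape[1]):
        nz = np.nonzero(np.abs(U[:, m]) > 1e-10)[0]
        if nz.size and U[nz[0], m] < 0:
            U[:, m] *= -1.0
    return ENMModes(eigenvalues=lam, eigenvectors=U, n_modes_kept=n_modes)


def mode_overlap(mode: np.ndarray, displacement: np.ndarray) -> float:
    """Normalized inner product between a mode and a displacement vector."""
    mode = np.asarray(mode, dtype=float).ravel()
    disp = np.asarray(displacement, dtype=float).ravel()
    if mode.shape != disp.shape:
        raise ValueError("mode and displacement lengths differ")
    nd = np.linalg.norm(disp)
    nm = np.linalg.norm(mode)
    if nd == 0 or nm == 0:
        raise ValueError("zero-norm vector in overlap")
    return float(mode @ disp / (nm * nd))
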