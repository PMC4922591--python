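"""Mode-combination deformations at a fixed deformation RMSD.

Each direction is a linear combination of the M slowest modes with
coefficients a_j drawn from {-1, 0, +1} (the all-zero tuple excluded),
each mode down-weighted by the square root of its eigenvalue so softer
modes contribute larger amplitude:

    V = sum_j a_j u_j / sqrt(lambda_j)

The combined vector is rescaled to norm DF * sqrt(N), which makes the
per-node displacement RMS exactly DF (the deformation RMSD). The
residue-level displacement is applied rigidly to every atom of the
residue; with M = 3 modes this yields 3^3 - 1 = 26 children per parent.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np

from .enm import ENMModes
from .structio import CoarseModel, Structure

__all__ = [
    "DeformationSpec",
    "DeformationDirection",
    "enumerate_directions",
    "apply_deformation",
    "deformation_rmsd",
]


@dataclasses.dataclass(frozen=True)
class DeformationSpec:
    """Deformation RMSD (Angstrom), mode count and coefficient alphabet."""

    DF: float = 2.0
    M: int = 3
    coefficient_alphabet: tuple[float, ...] = (-1.0, 0.0, 1.0)

    def __post_init__(self):
        if self.DF <= 0:
            raise ValueError("DF must be positive")
        if self.M < 1:
            raise ValueError("M must be >= 1")


@dataclasses.dataclass(frozen=True)
class DeformationDirection:
    coefficients: tuple[float, ...]
    raw_vector: np.ndarray  # (3N,)
    scaled_vector: np.ndarray  # (3N,), norm DF * sqrt(N)


def enumerate_directions(
    modes: ENMModes, spec: DeformationSpec
) -> list[DeformationDirection]:
    """All coefficient combinations, scaled to the deformation RMSD."""
    if modes.n_modes_kept < spec.M:
        raise ValueError(
            f"{spec.M} modes requested but only {modes.n_modes_kept} kept"
        )
    lam = modes.eigenvalues[: spec.M]
    if np.any(lam <= 0):
        raise ValueError("non-positive eigenvalue among kept modes")
    U = modes.eigenvectors[:, : spec.M]  # (3N, M)
    n_nodes = U.shape[0] // 3
    weighted = U / np.sqrt(lam)[None, :]
    target_norm = spec.DF * np.sqrt(n_nodes)
    out: list[DeformationDirection] = []
    for coeffs in itertools.product(spec.coefficient_alphabet, repeat=spec.M):
        if all(c == 0 for c in coeffs):
            continue
        raw = weighted @ np.asarray(coeffs)
        norm = np.linalg.norm(raw)
        if norm == 0:
            raise ValueError(f"degenerate direction for coefficients {coeffs}")
        out.append(
            DeformationDirection(
                coefficients=tuple(float(c) for c in coeffs),
                raw_vector=raw,
                scaled_vector=raw * (target_norm / norm),
            )
        )
    return out


def apply_deformation(
    parent: Structure, coarse: CoarseModel, direction: DeformationDirection
) -> Structure:
    """Translate every atom of residue i by the i-th block of the direction.

    The displacement field is defined on residue nodes; atoms of a residue
    move rigidly with their node, so no internal geometry is disturbed.
    """
    n = coarse.n_nodes
    if direction.scaled_vector.size != 3 * n:
        raise ValueError(
            f"direction has {direction.scaled_vector.size // 3} nodes, model has {n}"
        )
    disp = direction.scaled_vector.reshape(n, 3)
    coords = parent.coords.copy()
    for i, atom_idx in enumerate(coarse.membership):
        coords[atom_idx] += disp[i]
    return parent.with_coords(coords)


def deformation_rmsd(parent: Structure, child: Structure) -> float:
    """Raw per-C-alpha displacement RMS, without re-superposition."""
    ia = parent.ca_indices()
    ib = child.ca_indices()
    if ia.size != ib.size or ia.size == 0:
        raise ValueError("topology mismatch between parent and child")
    delta = parent.coords[ia] - child.coords[ib]
    return float(np.sqrt((delta ** 2).sum(axis=1).mean()))
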