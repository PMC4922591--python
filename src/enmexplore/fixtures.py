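"""Synthetic test structures with controlled dynamics.

Real hinge proteins are two well-packed domains joined by a thin flexible
linker; their slowest elastic-network mode is the rigid closure of one
domain over the other. The generators here build a minimal all-atom
caricature of that architecture so every pipeline stage can be exercised
without downloading coordinates:

* a reduced 5-atom residue (N, CA, C, O, CB as small offsets around the
  C-alpha) — enough atoms for contact-count spring weighting and
  per-residue rigid shifts to be nontrivial;
* compact domains laid out as a space-filling snake on a cubic lattice
  (lattice constant 4.2 A keeps all non-bonded heavy atoms outside the
  3 A soft-sphere radius, so fixtures score zero surrogate energy);
* a clamshell architecture: two tower-shaped domains stand on a common
  hinge line, their facing surfaces within the contact cutoff only near
  that line, with the linker residues running along the hinge axis and
  the open state wedged apart by a fixed opening angle. Every relative
  domain motion except rotation about the hinge line stretches contact
  springs at first order, so the hinge bend is the unique soft mode (the
  slowest-mode overlap with the open-to-closed displacement is ~0.99);
* a closed reference state made by rigidly rotating the second domain
  (and the distal half of the linker, which lies on the axis) about the
  hinge line, the angle solved numerically so the open/closed C-alpha
  RMSD hits a requested target.

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq

from .structio import ResidueKey, Structure, rmsd_ca

__all__ = ["HingeFixture", "make_chain", "make_hinge", "perturb"]

# local-frame atom offsets (A) around each C-alpha; small enough that
# non-adjacent residues on the 4.2 A lattice never clash
_ATOM_OFFSETS = {
    "N": np.array([-0.50, 0.20, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([0.50, 0.20, 0.00]),
    "O": np.array([0.45, 0.30, 0.35]),
    "CB": np.array([0.00, -0.35, 0.40]),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}

LATTICE = 4.2  # A, domain lattice constant
LINKER_LENGTH = 4
LINKER_SPACING = 4.0  # A, spacing of linker nodes along the hinge axis
DOMAIN_GAP = 7.5  # A, hinge-line separation of the facing domain surfaces
OPENING_ANGLE_DEG = 45.0  # wedge angle of the open state
HINGE_DROP = 3.0  # A, hinge line sits this far below the domain bases


@dataclasses.dataclass
class HingeFixture:
    open_structure: Structure
    closed_structure: Structure
    hinge_residues: list[int]
    target_open_closed_rmsd: float
    seed: int
    hinge_angle_deg: float = 0.0


def _structure_from_ca(
    ca_positions: np.ndarray, seed: int, chain_id: str = "A"
) -> Structure:
    """Expand C-alpha trace into 5-atom residues with seeded jitter."""
    rng = np.random.default_rng(seed)
    n = ca_positions.shape[0]
    coords, names, elements, serials, atom_residue = [], [], [], [], []
    residue_table = []
    serial = 0
    for i in range(n):
        residue_table.append(ResidueKey(chain_id, i + 1, "", "ALA"))
        jitter = rng.normal(scale=0.03, size=(len(_ATOM_OFFSETS), 3))
        for k, (name, offset) in enumerate(_ATOM_OFFSETS.items()):
            serial += 1
            pos = ca_positions[i] + offset + (jitter[k] if name != "CA" else 0.0)
            coords.append(pos)
            names.append(name)
            elements.append(_ELEMENTS[name])
            serials.append(serial)
            atom_residue.append(i)
    return Structure(
        np.asarray(coords), names, elements, serials,
        np.asarray(atom_residue), residue_table,
    )


def _helix_trace(n: int) -> np.ndarray:
    # ideal alpha-helix: ~3.83 A between consecutive C-alphas
    radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    i = np.arange(n)
    return np.stack(
        [radius * np.cos(twist * i), radius * np.sin(twist * i), rise * i], axis=1
    )


def _extended_trace(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.stack([3.8 * i, 0.4 * (i % 2), np.zeros(n)], axis=1)


def make_chain(n_residues: int, geometry: str = "helix", seed: int = 0) -> Structure:
    """Poly-alanine-like chain with ideal local geometry."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if geometry == "helix":
        trace = _helix_trace(n_residues)
    elif geometry == "extended":
        trace = _extended_trace(n_residues)
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return _structure_from_ca(trace, seed=seed)


def _snake_domain(n: int) -> np.ndarray:
    """Boustrophedon walk through a 2 x 2 x ceil(n/4) lattice tower."""
    nx = ny = 2
    nz = int(np.ceil(n / (nx * ny)))
    pts = []
    for iz in range(nz):
        for iy in range(ny):
            ys = iy if iz % 2 == 0 else ny - 1 - iy
            xs = range(nx) if (iy + iz) % 2 == 0 else range(nx - 1, -1, -1)
            for ix in xs:
                pts.append((ix, ys, iz))
                if len(pts) == n:
                    return LATTICE * np.asarray(pts, dtype=float)
    raise AssertionError("unreachable")


def _hinge_ca_trace(n_per_domain: int) -> tuple[np.ndarray, list[int], np.ndarray, np.ndarray]:
    """Open-state C-alpha trace: tower, hinge-line linker, wedged tower.

    Returns (trace, hinge residue indices, hinge point, hinge axis).
    The second domain is pre-rotated open by ``OPENING_ANGLE_DEG`` about
    the hinge axis; closing rotates it back toward the first.
    """
    d1 = _snake_domain(n_per_domain)
    d1[:, 0] -= d1[:, 0].max()
    d1[:, 1] -= d1[:, 1].mean()
    d1[:, 2] -= d1[:, 2].min()
    # last residue of domain 1 sits at the hinge-facing bottom corner
    order1 = np.lexsort((d1[:, 1], d1[:, 2], -d1[:, 0]))
    d1 = d1[order1][::-1]

    d2 = _snake_domain(n_per_domain)
    d2[:, 0] = -d2[:, 0]
    d2[:, 0] -= d2[:, 0].min() - DOMAIN_GAP
    d2[:, 1] -= d2[:, 1].mean()
    d2[:, 2] -= d2[:, 2].min()
    # first residue of domain 2 starts at its hinge-facing bottom corner
    order2 = np.lexsort((d2[:, 1], d2[:, 2], d2[:, 0]))
    d2 = d2[order2]

    hinge_point = np.array([DOMAIN_GAP / 2.0, 0.0, -HINGE_DROP])
    axis = np.array([0.0, 1.0, 0.0])
    ys = (np.arange(LINKER_LENGTH) - (LINKER_LENGTH - 1) / 2.0) * LINKER_SPACING
    linker = np.stack(
        [np.full(LINKER_LENGTH, hinge_point[0]), ys, np.full(LINKER_LENGTH, hinge_point[2])],
        axis=1,
    )
    d2_open = _rotate_about_axis(d2, hinge_point, axis, np.deg2rad(OPENING_ANGLE_DEG))
    trace = np.vstack([d1, linker, d2_open])
    hinge = list(range(n_per_domain, n_per_domain + LINKER_LENGTH))
    return trace, hinge, hinge_point, axis


def _rotate_about_axis(
    points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle: float
) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return (points - origin) @ R.T + origin


def _close_trace(
    trace: np.ndarray,
    hinge: list[int],
    hinge_point: np.ndarray,
    axis: np.ndarray,
    angle: float,
) -> np.ndarray:
    """Rotate the distal half of the linker and the second domain.

    The linker lies on the hinge axis, so rotating its distal half is a
    geometric no-op; it is included for bookkeeping symmetry.
    """
    pivot_res = hinge[len(hinge) // 2]
    moved = trace.copy()
    moved[pivot_res:] = _rotate_about_axis(trace[pivot_res:], hinge_point, axis, -angle)
    return moved


def make_hinge(
    n_per_domain: int = 28, target_rmsd: float = 5.0, seed: int = 0
) -> HingeFixture:
    """Two-domain hinge fixture with a known open/closed pair.

    The closed state rotates the second domain about the hinge line; the
    angle is solved so the open/closed C-alpha RMSD matches
    ``target_rmsd`` within the 5% contract.
    """
    if n_per_domain < 10:
        raise ValueError("need at least 10 residues per domain")
    if target_rmsd <= 0:
        raise ValueError("target_rmsd must be positive")
    trace, hinge, hinge_point, axis = _hinge_ca_trace(n_per_domain)
    open_structure = _structure_from_ca(trace, seed=seed)

    def rmsd_at(angle: float) -> float:
        closed = _close_trace(trace, hinge, hinge_point, axis, angle)
        moved = _structure_from_ca(closed, seed=seed)
        return rmsd_ca(open_structure, moved)

    hi = np.deg2rad(OPENING_ANGLE_DEG)
    if rmsd_at(hi) < target_rmsd:
        raise ValueError(
            f"target RMSD {target_rmsd} A unreachable within the "
            f"{OPENING_ANGLE_DEG} degree opening of this fixture "
            f"(max {rmsd_at(hi):.2f} A); increase n_per_domain"
        )
    angle = brentq(lambda a: rmsd_at(a) - target_rmsd, 0.0, hi, xtol=1e-6)
    closed_structure = _structure_from_ca(
        _close_trace(trace, hinge, hinge_point, axis, angle), seed=seed
    )
    return HingeFixture(
        open_structure=open_structure,
        closed_structure=closed_structure,
        hinge_residues=hinge,
        target_open_closed_rmsd=target_rmsd,
        seed=seed,
        hinge_angle_deg=float(np.rad2deg(angle)),
    )


def perturb(structure: Structure, magnitude: float, seed: int = 0) -> Structure:
    """Rigid per-residue Gaussian displacement with C-alpha RMS ~ magnitude."""
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude == 0:
        return structure.with_coords(structure.coords)
    rng = np.random.default_rng(seed)
    n_res = structure.n_residues
    shifts = rng.normal(scale=magnitude / np.sqrt(3.0), size=(n_res, 3))
    coords = structure.coords.copy()
    for i in range(n_res):
        coords[structure.atom_residue == i] += shifts[i]
    return structure.with_coords(coords)
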