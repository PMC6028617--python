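"""Solvent-accessible surface area by the Shrake–Rupley method.

Each atom is inflated by the probe radius and sampled with a deterministic
golden-section spiral of test points; the accessible area is the exposed
fraction of the inflated sphere.  Per-residue areas are additionally split
into charged, polar and nonpolar classes so that the charged/polar surface
accounting used in halophilicity analyses can be reproduced.

The spiral is generated in a local frame derived from each atom's
geometric context (direction to the structure centroid and to the nearest
neighbouring atom).  Because those directions co-rotate with the
coordinates, the computed areas are invariant under rigid transforms up to
floating-point roundoff, not merely up to sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import DEFAULT_VDW_RADIUS, VDW_RADII, Structure

__all__ = [
    "SasaParams",
    "ResidueAccessibility",
    "sphere_points",
    "shrake_rupley",
    "residue_asa",
    "compute_accessibility",
]

# Side-chain atoms whose ASA counts as *charged* (carboxylate oxygens of
# Asp/Glu; basic nitrogens of Lys/Arg/His).
CHARGED_SIDECHAIN_ATOMS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "LYS": frozenset({"NZ"}),
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "HIS": frozenset({"ND1", "NE2"}),
}


@dataclass
class SasaParams:
    """Shrake–Rupley parameters.

    probe_radius : solvent probe radius in Å (1.4 = water).
    n_sphere_points : test points per atom; error falls roughly as 1/n.
    radii_table : element → van der Waals radius (Å).
    """

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be non-negative")
        if self.n_sphere_points < 12:
            raise ValueError("n_sphere_points must be at least 12")

    def radius_of(self, element: str) -> float:
        return self.radii_table.get(element.upper(), DEFAULT_VDW_RADIUS)


@dataclass
class ResidueAccessibility:
    """Per-residue ASA (Å²) and its charged/polar/nonpolar decomposition."""

    chain_id: str
    seq_id: int
    insertion_code: str
    res_type: str
    total_asa: float
    polar_asa: float
    charged_asa: float
    nonpolar_asa: float

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.insertion_code)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral on the unit sphere, shape (n, 3)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _local_frames(coords: np.ndarray) -> np.ndarray:
    """Rotation-covariant orthonormal frame per atom, shape (n, 3, 3).

    Axis 1 points to the nearest neighbouring atom, axis 2 toward the
    nearest non-collinear neighbour (orthogonalised).  Because the frame
    depends only on each atom's local neighbourhood, it co-rotates with
    the coordinates, and distant additions to the structure leave it
    unchanged.  Degenerate geometry (single atom, coincident neighbour,
    an exactly collinear neighbourhood) falls back to a fixed frame.
    """
    n = len(coords)
    frames = np.tile(np.eye(3), (n, 1, 1))
    if n < 2:
        return frames
    k = min(n, 8)
    dist, nn = cKDTree(coords).query(coords, k=k)
    dist, nn = np.atleast_2d(dist), np.atleast_2d(nn)
    for i in range(n):
        # ties (symmetric neighbourhoods) broken by index after rounding,
        # so the choice is stable under rigid transforms
        candidates = [j for _, j in sorted(
            (round(float(d), 6), int(j))
            for d, j in zip(dist[i], nn[i]) if j != i)]
        a1 = coords[candidates[0]] - coords[i]
        norm1 = np.linalg.norm(a1)
        if norm1 < 1e-8:
            continue
        e1 = a1 / norm1
        e2 = None
        for j in candidates[1:]:
            b2 = coords[j] - coords[i]
            b2 = b2 - (b2 @ e1) * e1
            norm2 = np.linalg.norm(b2)
            if norm2 > 1e-6:
                e2 = b2 / norm2
                break
        if e2 is None:  # collinear neighbourhood: fixed orthogonal fallback
            axis = np.zeros(3)
            axis[np.argmin(np.abs(e1))] = 1.0
            b2 = axis - (axis @ e1) * e1
            e2 = b2 / np.linalg.norm(b2)
        frames[i] = np.column_stack([e1, e2, np.cross(e1, e2)])
    return frames


def shrake_rupley(structure: Structure, params: SasaParams | None = None,
                  exclude_hydrogens: bool = False) -> np.ndarray:
    """Per-atom ASA in structure atom order, shape (n_atoms,).

    ASA_i = (exposed points / total points) × 4π(r_i + probe)².  A test
    point is occluded when it lies within (r_j + probe) of any other atom
    centre.  Coincident atoms mutually occlude; hydrogens may be dropped
    from the model entirely with ``exclude_hydrogens``.
    """
    params = params or SasaParams()
    atoms = list(structure.atoms())
    if not atoms:
        raise ValueError("structure has no atoms")

    keep = np.array([not (exclude_hydrogens and a.element == "H")
                     for a in atoms])
    coords = np.array([a.position for a in atoms], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite atom coordinates")
    radii = np.array([params.radius_of(a.element) for a in atoms]) \
        + params.probe_radius

    asa = np.zeros(len(atoms))
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return asa
    coords_k = coords[idx]
    radii_k = radii[idx]

    unit = sphere_points(params.n_sphere_points)
    frames = _local_frames(coords_k)
    tree = cKDTree(coords_k)
    max_radius = radii_k.max()

    for local_i in range(len(idx)):
        center = coords_k[local_i]
        r_i = radii_k[local_i]
        neighbours = tree.query_ball_point(center, r_i + max_radius)
        neighbours = [j for j in neighbours if j != local_i]
        pts = center + r_i * (unit @ frames[local_i].T)
        nb = np.asarray(neighbours, dtype=int)
        if nb.size:
            close = np.linalg.norm(coords_k[nb] - center, axis=1) \
                < r_i + radii_k[nb]
            nb = nb[close]
        if nb.size:
            diff = pts[:, None, :] - coords_k[nb][None, :, :]
            d2 = np.einsum("pkj,pkj->pk", diff, diff)
            # small slack so exactly coincident spheres fully occlude
            exposed = np.all(d2 > radii_k[nb] ** 2 + 1e-9, axis=1)
            n_exposed = int(exposed.sum())
        else:
            n_exposed = len(pts)
        asa[idx[local_i]] = (n_exposed / params.n_sphere_points) \
            * 4.0 * np.pi * r_i ** 2
    return asa


def _atom_class(res_type: str, atom_name: str, element: str) -> str:
    """charged | polar | nonpolar for a single atom.

    Carbons (and any hydrogens) are nonpolar; the basic/acidic side-chain
    N/O of Lys/Arg/His/Asp/Glu are charged; every other N, O, S (and any
    unusual element) is polar, including all backbone N/O.
    """
    element = element.upper()
    if element in ("C", "H"):
        return "nonpolar"
    if atom_name in CHARGED_SIDECHAIN_ATOMS.get(res_type, frozenset()):
        return "charged"
    return "polar"


def residue_asa(structure: Structure,
                atom_asa: np.ndarray) -> list[ResidueAccessibility]:
    """Aggregate per-atom ASA to residues with class decomposition.

    ``atom_asa`` must be aligned with ``structure.atoms()`` order, as
    produced by :func:`shrake_rupley`.
    """
    if len(atom_asa) != structure.n_atoms:
        raise ValueError("atom_asa length does not match structure atom count")
    out: list[ResidueAccessibility] = []
    cursor = 0
    for residue in structure.residues():
        sums = {"charged": 0.0, "polar": 0.0, "nonpolar": 0.0}
        for atom in residue.atoms:
            cls = _atom_class(residue.res_type, atom.name, atom.element)
            sums[cls] += float(atom_asa[cursor])
            cursor += 1
        out.append(ResidueAccessibility(
            chain_id=residue.chain_id,
            seq_id=residue.seq_id,
            insertion_code=residue.insertion_code,
            res_type=residue.res_type,
            total_asa=sums["charged"] + sums["polar"] + sums["nonpolar"],
            polar_asa=sums["polar"],
            charged_asa=sums["charged"],
            nonpolar_asa=sums["nonpolar"],
        ))
    return out


def compute_accessibility(structure: Structure,
                          params: SasaParams | None = None,
                          exclude_hydrogens: bool = False,
                          ) -> list[ResidueAccessibility]:
    """Convenience: Shrake–Rupley followed by residue aggregation."""
    return residue_asa(structure,
                       shrake_rupley(structure, params, exclude_hydrogens))
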