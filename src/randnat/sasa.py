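"""Solvent-accessible surface area by Shrake–Rupley sphere-point sampling.

The accessible surface of an atom is the locus traced by the centre of a
probe sphere (default radius 1.4 Å, a water molecule) rolled over the atom's
van der Waals sphere.  Each atom's expanded sphere (r_vdw + r_probe) is
sampled with a quasi-uniform point set; a point is accessible when it lies
outside every other atom's expanded sphere, and the atom's area is the
accessible fraction of 4*pi*(r_vdw + r_probe)^2.

Hydrogens (and deuteriums) are ignored; radii are heavy-atom van der Waals
radii without bound hydrogens folded in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Van der Waals radii in Å (Bondi-style set; heavy atoms only).
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Radius used for elements absent from :data:`VDW_RADII`.
DEFAULT_RADIUS = 1.70


@dataclass(frozen=True)
class SASAResult:
    """Per-atom, per-residue and total accessible area in Å²."""

    atom_area: np.ndarray
    residue_area: np.ndarray
    total: float


def sphere_points(n: int) -> np.ndarray:
    """Return ``n`` quasi-uniform unit vectors (Fibonacci / golden spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack((rho * np.cos(theta), rho * np.sin(theta), z))


def atom_radii(elements) -> np.ndarray:
    """Van der Waals radius per element symbol, with a default for unknowns."""
    return np.array(
        [VDW_RADII.get(str(e).upper(), DEFAULT_RADIUS) for e in elements]
    )


def sasa_from_coords(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Shrake–Rupley accessible area (Å²) for each atom.

    Parameters
    ----------
    coords
        ``(n_atoms, 3)`` Cartesian coordinates in Å.
    radii
        Per-atom van der Waals radii in Å.
    probe_radius
        Probe sphere radius in Å; must be positive.
    n_points
        Number of test points per atom; accuracy is O(1/n_points).
    """
    if probe_radius <= 0:
        raise ValueError(f"probe radius must be positive, got {probe_radius}")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must have shape (n_atoms, 3)")
    if len(radii) != len(coords):
        raise ValueError("radii and coords length mismatch")
    n = len(coords)
    if n == 0:
        raise ValueError("need at least one atom")

    expanded = radii + probe_radius
    unit = sphere_points(n_points)
    areas = np.empty(n)
    # pairwise distances once; neighbour lists keep the inner test small
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    for i in range(n):
        cutoff = expanded[i] + expanded
        nbr = np.where((dist[i] < cutoff) & (np.arange(n) != i))[0]
        pts = coords[i] + expanded[i] * unit
        if nbr.size:
            d2 = ((pts[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(-1)
            buried = (d2 < expanded[nbr] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return areas


def compute_sasa(model, probe_radius: float = 1.4, n_points: int = 960) -> SASAResult:
    """Accessible surface area of a :class:`~randnat.structure_features.StructureModel`.

    Hydrogens are excluded from both the occlusion test and the reported
    areas.  ``residue_area[k]`` sums the areas of residue ``k``'s heavy
    atoms; ``total`` is the sum over residues.
    """
    elements = np.array([str(e).upper() for e in model.atom_elements])
    heavy = ~np.isin(elements, ("H", "D"))
    if not heavy.any():
        raise ValueError("no heavy atoms in model")
    coords = model.atom_coords[heavy]
    radii = atom_radii(elements[heavy])
    areas_heavy = sasa_from_coords(coords, radii, probe_radius, n_points)

    atom_area = np.zeros(len(model.atom_elements))
    atom_area[heavy] = areas_heavy
    residue_area = np.zeros(model.n_residues)
    np.add.at(residue_area, model.atom_res_index, atom_area)
    return SASAResult(atom_area=atom_area, residue_area=residue_area, total=float(residue_area.sum()))
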