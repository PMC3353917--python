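"""Shared fixtures: analytic backbone geometry and toy feature tables.

Backbones are built from canonical internal coordinates (bond lengths,
bond angles, and the requested phi/psi torsions) with the standard
natural-extension frame construction, so secondary-structure tests run
against geometry whose hydrogen-bond pattern is known by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from randnat.structure_features import StructureModel

BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7}


def place_atom(a, b, c, length, angle_deg, torsion_deg):
    """Position atom D given A-B-C, |C-D|, angle(B,C,D) and torsion(A,B,C,D)."""
    ang, tor = np.deg2rad(angle_deg), np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [-length * np.cos(ang), length * np.sin(ang) * np.cos(tor), length * np.sin(ang) * np.sin(tor)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(n_res: int, phi: float, psi: float, omega: float = 180.0):
    """N/CA/C/O coordinates of an ideal backbone with uniform phi/psi."""
    N = [np.zeros(3)]
    CA = [np.array([BOND["N-CA"], 0.0, 0.0])]
    theta = np.deg2rad(180.0 - ANGLE["N-CA-C"])
    C = [CA[0] + BOND["CA-C"] * np.array([np.cos(theta), np.sin(theta), 0.0])]
    for _ in range(1, n_res):
        Nn = place_atom(N[-1], CA[-1], C[-1], BOND["C-N"], ANGLE["CA-C-N"], psi)
        CAn = place_atom(CA[-1], C[-1], Nn, BOND["N-CA"], ANGLE["C-N-CA"], omega)
        Cn = place_atom(C[-1], Nn, CAn, BOND["CA-C"], ANGLE["N-CA-C"], phi)
        N.append(Nn), CA.append(CAn), C.append(Cn)
    N, CA, C = map(np.asarray, (N, CA, C))
    O = np.full((n_res, 3), np.nan)
    for i in range(n_res - 1):
        u = C[i] - CA[i]
        u /= np.linalg.norm(u)
        v = C[i] - N[i + 1]
        v /= np.linalg.norm(v)
        d = u + v
        O[i] = C[i] + 1.231 * d / np.linalg.norm(d)
    return N, CA, C, O


def model_from_backbone(segments, resname="ALA", letter="A") -> StructureModel:
    """Assemble one or more (N, CA, C, O) segments into a single chain."""
    if not isinstance(segments, list):
        segments = [segments]
    names, elements, res_index, coords = [], [], [], []
    k = 0
    for N, CA, C, O in segments:
        for i in range(len(N)):
            for nm, el, xyz in (("N", "N", N[i]), ("CA", "C", CA[i]), ("C", "C", C[i]), ("O", "O", O[i])):
                if np.isnan(xyz[0]):
                    continue
                names.append(nm)
                elements.append(el)
                res_index.append(k)
                coords.append(xyz)
            k += 1
    return StructureModel(
        chain_id="A",
        sequence=letter * k,
        residue_names=[resname] * k,
        atom_elements=elements,
        atom_names=names,
        atom_res_index=np.array(res_index),
        atom_coords=np.array(coords),
    )


def _align_screw_axis_to_x(parts):
    """Rotate a 2-residue-periodic strand so its screw axis is +x."""
    CA = parts[1]
    ax = (CA[2:] - CA[:-2]).mean(axis=0)
    ax /= np.linalg.norm(ax)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(ax, x)
    s, c = np.linalg.norm(v), ax @ x
    if s < 1e-12:
        R = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return tuple(np.where(np.isnan(p), p, p @ R.T) for p in parts)


@pytest.fixture
def helix_model() -> StructureModel:
    """20-residue ideal poly-Ala alpha helix (phi=-57, psi=-47)."""
    return model_from_backbone(build_backbone(20, phi=-57.0, psi=-47.0))


@pytest.fixture
def strand_model() -> StructureModel:
    """One isolated 8-residue extended strand: no H-bond partners exist."""
    return model_from_backbone(build_backbone(8, phi=-139.0, psi=135.0))


@pytest.fixture
def sheet_model() -> StructureModel:
    """Two antiparallel 8-residue strands with paired backbone H-bonds.

    The second strand is the first rotated 180 degrees about the strand
    axis and offset so that the inter-strand N-H...O=C register closes
    (offset found once by scanning and frozen here).
    """
    s1 = _align_screw_axis_to_x(build_backbone(8, phi=-139.0, psi=135.0))
    flip = np.diag([1.0, -1.0, -1.0])
    shift = np.array([-1.0, 1.2, 3.6])
    s2 = tuple(np.where(np.isnan(p), p, p @ flip.T + shift) for p in s1)
    return model_from_backbone([s1, s2])


def pdb_text_from_model(model: StructureModel, het_tail: bool = False) -> str:
    """Serialize a StructureModel back to minimal PDB ATOM records."""
    lines = []
    for s, (nm, el, ri, xyz) in enumerate(
        zip(model.atom_names, model.atom_elements, model.atom_res_index, model.atom_coords), 1
    ):
        resname = model.residue_names[ri]
        lines.append(
            f"ATOM  {s:>5d}  {nm:<3s}{resname:>4s} {model.chain_id}{ri + 1:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}          {el:>2s}"
        )
    if het_tail:
        lines.append(
            "HETATM 9999  O   HOH A 900      99.000  99.000  99.000  1.00  0.00           O"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def toy_table(seed: int, n_per_class: int = 40, shift: float = 5.0, n_noise: int = 3) -> pd.DataFrame:
    """Two-class table where only variable v1 separates the classes."""
    rng = np.random.default_rng(seed)
    frames = []
    for cls, mu in (("natural", 0.0), ("random", shift)):
        block = {"label": [cls] * n_per_class, "v1": rng.normal(mu, 1.0, n_per_class)}
        for j in range(2, n_noise + 2):
            block[f"v{j}"] = rng.normal(0.0, 1.0, n_per_class)
        frames.append(pd.DataFrame(block))
    return pd.concat(frames, ignore_index=True)
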