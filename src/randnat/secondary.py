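"""Backbone hydrogen-bond based secondary-structure assignment.

A simplified Kabsch–Sander scheme over four states:

``H``
    alpha helix — residues covered by two consecutive i -> i+4 backbone
    hydrogen-bond turns.
``E``
    beta strand — residues participating in a parallel or antiparallel
    bridge (the Kabsch–Sander bridge patterns).
``T``
    "other" ordered state — residues inside an isolated 3-, 4- or 5-turn
    (turns/bends that are neither helix nor strand).
``C``
    coil — everything else.

Hydrogen bonds are detected with the Kabsch–Sander electrostatic model: the
amide H is placed 1 Å from N opposite the preceding carbonyl, and the
bond energy between acceptor C=O of residue i and donor N-H of residue j is

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  [kcal/mol]

with an H-bond assigned when E < -0.5 kcal/mol.  Prolines donate no amide
hydrogen.  A missing backbone O is reconstructed in the carbonyl plane when
the next residue's N is available.
"""

from __future__ import annotations

import numpy as np

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_COUPLING = 0.084 * 332.0  # partial charges times electrostatic constant
_MAX_MISSING_FRACTION = 0.20
_MIN_RESIDUES = 5


class SecondaryStructureError(ValueError):
    """Raised when backbone geometry is too incomplete to assign states."""


def _backbone_arrays(model):
    n = model.n_residues
    out = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O")}
    for name, res_idx, xyz in zip(model.atom_names, model.atom_res_index, model.atom_coords):
        if name in out and np.isnan(out[name][res_idx, 0]):
            out[name][res_idx] = xyz
    return out


def _reconstruct_oxygens(bb):
    """Fill missing carbonyl O from C, CA and the next residue's N."""
    n = len(bb["O"])
    for i in range(n - 1):
        if np.isnan(bb["O"][i, 0]) and not (
            np.isnan(bb["C"][i, 0]) or np.isnan(bb["CA"][i, 0]) or np.isnan(bb["N"][i + 1, 0])
        ):
            u = bb["C"][i] - bb["CA"][i]
            v = bb["C"][i] - bb["N"][i + 1]
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            d = u + v
            bb["O"][i] = bb["C"][i] + 1.231 * d / np.linalg.norm(d)


def hydrogen_bond_matrix(model) -> np.ndarray:
    """Boolean matrix ``HB[i, j]``: C=O of residue i accepts from N-H of j."""
    bb = _backbone_arrays(model)
    _reconstruct_oxygens(bb)
    n = model.n_residues

    complete = ~np.isnan(np.concatenate([bb[k] for k in ("N", "CA", "C")], axis=1)).any(axis=1)
    if n < _MIN_RESIDUES or complete.sum() < _MIN_RESIDUES:
        raise SecondaryStructureError(
            f"need at least {_MIN_RESIDUES} residues with complete backbone, have {int(complete.sum())}"
        )
    missing = 1.0 - complete.mean()
    if missing > _MAX_MISSING_FRACTION:
        raise SecondaryStructureError(
            f"{missing:.0%} of residues lack N/CA/C backbone atoms (limit {_MAX_MISSING_FRACTION:.0%})"
        )

    # amide H: 1 Å from N, anti to the previous carbonyl; none on residue 0 or Pro
    H = np.full((n, 3), np.nan)
    for j in range(1, n):
        if model.residue_names[j].upper() == "PRO":
            continue
        d = bb["C"][j - 1] - bb["O"][j - 1]
        if np.isnan(d[0]) or np.isnan(bb["N"][j, 0]):
            continue
        H[j] = bb["N"][j] + d / np.linalg.norm(d)

    def dist(a, b):
        return np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)

    with np.errstate(divide="ignore", invalid="ignore"):
        energy = _COUPLING * (
            1.0 / dist(bb["O"], bb["N"])
            + 1.0 / dist(bb["C"], H)
            - 1.0 / dist(bb["O"], H)
            - 1.0 / dist(bb["C"], bb["N"])
        )
    energy = np.where(np.isnan(energy), np.inf, energy)

    idx = np.arange(n)
    valid = np.abs(idx[:, None] - idx[None, :]) >= 2
    acceptor_ok = ~np.isnan(bb["O"][:, 0]) & ~np.isnan(bb["C"][:, 0])
    donor_ok = ~np.isnan(H[:, 0])
    valid &= acceptor_ok[:, None] & donor_ok[None, :]
    return (energy < HBOND_ENERGY_CUTOFF) & valid


def assign_secondary_structure(model) -> np.ndarray:
    """One state per residue, over ``{'H', 'E', 'T', 'C'}`` (``T`` = other)."""
    hb = hydrogen_bond_matrix(model)
    n = model.n_residues
    labels = np.full(n, "C", dtype="<U1")

    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in turn:
        for i in range(n - k):
            turn[k][i] = hb[i, i + k]

    helix = np.zeros(n, dtype=bool)
    for i in range(1, n - 4):
        if turn[4][i - 1] and turn[4][i]:
            helix[i : i + 4] = True

    bridge = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            antiparallel = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if parallel or antiparallel:
                bridge[i] = bridge[j] = True

    other = np.zeros(n, dtype=bool)
    for k in turn:
        for i in np.where(turn[k])[0]:
            other[i + 1 : i + k] = True

    labels[other] = "T"
    labels[bridge & ~helix] = "E"
    labels[helix] = "H"
    return labels


def state_counts(labels: np.ndarray) -> dict[str, int]:
    """Residue counts of the four states."""
    return {s: int((labels == s).sum()) for s in ("H", "E", "T", "C")}
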