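"""Structural descriptors of a single protein chain.

Eleven structure-related variables are computed per chain: net charge,
volume, surface area, coil / alpha-helix / beta-sheet residue counts, the
corresponding percentages of chain length, percentage of secondary
structure (%alpha + %beta) and surface hydrophobicity (the fraction of the
solvent-accessible surface contributed by hydrophobic residues).

Conventions
-----------
* Net charge: +1 per Lys/Arg, -1 per Asp/Glu; His and the termini are
  neutral (pH ~7, no pKa model).
* Volume: sum of per-residue mean volumes (Zamyatnin 1972), packaged as
  data; structure independent.
* Surface: Shrake–Rupley SASA, probe 1.4 Å, 960 points per atom, heavy
  atoms only (see :mod:`randnat.sasa`).
* Secondary structure: simplified Kabsch–Sander four-state assignment
  (see :mod:`randnat.secondary`); "coil" counts the ``C`` state only, so
  alpha + beta + coil can be smaller than the chain length.
* Hydrophobic residues: {A, V, L, I, M, F, W, C, P}.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1_extended

from .sasa import SASAResult, compute_sasa
from .secondary import assign_secondary_structure, state_counts

__all__ = [
    "StructureModel",
    "FeatureVector",
    "PDBParseError",
    "parse_structure",
    "assign_secondary_structure",
    "compute_sasa",
    "compute_net_charge",
    "compute_volume",
    "surface_hydrophobicity",
    "extract_features",
    "feature_frame",
    "write_feature_table",
    "read_feature_table",
    "VARIABLE_NAMES",
    "HYDROPHOBIC_RESIDUES",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWCP")

#: The 11 variables, in canonical table order.
VARIABLE_NAMES = (
    "Net charge",
    "Volume",
    "Surface",
    "Coil",
    "Beta",
    "Alpha",
    "% Alpha",
    "% Beta",
    "% Coil",
    "% Secondary structure",
    "Surface hydrophobicity",
)

#: Non-variable columns of a feature table.
ID_COLUMN, LABEL_COLUMN = "id", "label"


class PDBParseError(ValueError):
    """Raised when PDB text cannot be turned into a usable chain model."""


@dataclass
class StructureModel:
    """One chain of one model: ordered residues and their atoms.

    Residue serials are 1-based in ATOM-record order; ``atom_res_index``
    maps each atom to its 0-based residue position.
    """

    chain_id: str
    sequence: str
    residue_names: list[str]
    atom_elements: list[str]
    atom_names: list[str]
    atom_res_index: np.ndarray
    atom_coords: np.ndarray
    residue_serials: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.atom_res_index = np.asarray(self.atom_res_index, dtype=int)
        self.atom_coords = np.asarray(self.atom_coords, dtype=float)
        if not self.residue_serials:
            self.residue_serials = list(range(1, len(self.residue_names) + 1))
        if not np.isfinite(self.atom_coords).all():
            raise PDBParseError("non-finite atom coordinates")
        if len(self.sequence) != len(self.residue_names):
            raise PDBParseError("sequence/residue length mismatch")

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_elements)


def _pick_altloc(atoms):
    """Highest occupancy wins; ties prefer altloc 'A', then blank."""

    def key(a):
        occ = a.get_occupancy() if a.get_occupancy() is not None else 0.0
        alt = a.get_altloc()
        return (occ, 2 if alt == "A" else (1 if alt in ("", " ") else 0))

    return max(atoms, key=key)


def parse_structure(pdb_text: str, chain: str | None = None) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the first MODEL is read; HETATM records are ignored; for
    alternate locations the highest-occupancy conformer is kept (ties
    broken towards altloc 'A', then blank).  ``chain`` defaults to the
    first chain containing standard ATOM records.
    """
    if "ATOM" not in pdb_text:
        raise PDBParseError("no ATOM records found")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("chain", io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:  # pragma: no cover - PDBParser always yields one
        raise PDBParseError("no coordinate model found") from None

    chains = {}
    for ch in model:
        residues = [r for r in ch if r.id[0] == " "]
        if residues:
            chains[ch.id] = residues
    if not chains:
        raise PDBParseError("no ATOM records found (HETATM-only input?)")
    if chain is None:
        chain = next(iter(chains))
    elif chain not in chains:
        raise PDBParseError(
            f"chain {chain!r} not present; available chains: {sorted(chains)}"
        )

    seq, residue_names, serials = [], [], []
    elements, names, res_index, coords = [], [], [], []
    for k, residue in enumerate(chains[chain]):
        resname = residue.get_resname().upper()
        residue_names.append(resname)
        serials.append(k + 1)
        seq.append(protein_letters_3to1_extended.get(resname, "X"))
        for atom in residue:
            chosen = (
                _pick_altloc(atom.disordered_get_list())
                if atom.is_disordered()
                else atom
            )
            elements.append(chosen.element or "")
            names.append(chosen.get_name())
            res_index.append(k)
            coords.append(chosen.get_coord())

    return StructureModel(
        chain_id=chain,
        sequence="".join(seq),
        residue_names=residue_names,
        residue_serials=serials,
        atom_elements=elements,
        atom_names=names,
        atom_res_index=np.array(res_index, dtype=int),
        atom_coords=np.array(coords, dtype=float),
    )


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty amino-acid sequence")
    bad = sorted(set(sequence.upper()) - set(STANDARD_AA))
    if bad:
        raise ValueError(f"non-standard amino-acid letter(s): {bad}")
    return sequence.upper()


def compute_net_charge(sequence: str) -> int:
    """Signed charge at neutral pH: +1 per K/R, -1 per D/E; His neutral."""
    seq = _check_sequence(sequence)
    return sum(seq.count(a) for a in "KR") - sum(seq.count(a) for a in "DE")


def _residue_volumes() -> dict[str, float]:
    with resources.files("randnat.data").joinpath("residue_volumes.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["residue"], df["volume_A3"]))


_VOLUMES = None


def compute_volume(sequence: str) -> float:
    """Chain volume in Å³ as the sum of mean residue volumes."""
    global _VOLUMES
    if _VOLUMES is None:
        _VOLUMES = _residue_volumes()
    seq = _check_sequence(sequence)
    return float(sum(_VOLUMES[a] for a in seq))


def surface_hydrophobicity(model: StructureModel, residue_area: np.ndarray) -> float:
    """Fraction of total SASA contributed by hydrophobic residues."""
    residue_area = np.asarray(residue_area, dtype=float)
    if len(residue_area) != model.n_residues:
        raise ValueError("per-residue areas do not match model residues")
    total = residue_area.sum()
    if total <= 0:
        raise ValueError("total SASA is zero; hydrophobic fraction undefined")
    hydro = np.array([a in HYDROPHOBIC_RESIDUES for a in model.sequence])
    return float(residue_area[hydro].sum() / total)


@dataclass(frozen=True)
class FeatureVector:
    """The 11 structural variables of one chain, plus its class label."""

    net_charge: float
    volume: float
    surface: float
    coil: int
    beta: int
    alpha: int
    pct_alpha: float
    pct_beta: float
    pct_coil: float
    pct_secondary: float
    surface_hydrophobicity: float
    label: str = "unknown"

    def to_dict(self) -> dict[str, float]:
        """Variable values keyed by canonical table names."""
        values = (
            self.net_charge,
            self.volume,
            self.surface,
            self.coil,
            self.beta,
            self.alpha,
            self.pct_alpha,
            self.pct_beta,
            self.pct_coil,
            self.pct_secondary,
            self.surface_hydrophobicity,
        )
        return dict(zip(VARIABLE_NAMES, values))


def extract_features(
    model: StructureModel,
    label: str = "unknown",
    probe_radius: float = 1.4,
    n_points: int = 960,
    sasa: SASAResult | None = None,
) -> FeatureVector:
    """Compute all 11 variables for a chain.

    ``sasa`` may be passed to reuse a precomputed surface; otherwise it is
    computed with the given probe radius and point count.
    """
    n = model.n_residues
    labels = assign_secondary_structure(model)
    counts = state_counts(labels)
    if sasa is None:
        sasa = compute_sasa(model, probe_radius=probe_radius, n_points=n_points)
    pct_alpha = 100.0 * counts["H"] / n
    pct_beta = 100.0 * counts["E"] / n
    return FeatureVector(
        net_charge=compute_net_charge(model.sequence),
        volume=compute_volume(model.sequence),
        surface=sasa.total,
        coil=counts["C"],
        beta=counts["E"],
        alpha=counts["H"],
        pct_alpha=pct_alpha,
        pct_beta=pct_beta,
        pct_coil=100.0 * counts["C"] / n,
        pct_secondary=pct_alpha + pct_beta,
        surface_hydrophobicity=surface_hydrophobicity(model, sasa.residue_area),
        label=label,
    )


def feature_frame(records: list[tuple[str, FeatureVector]]) -> pd.DataFrame:
    """Assemble (id, FeatureVector) pairs into a feature table."""
    rows = []
    for rec_id, fv in records:
        row = {ID_COLUMN: rec_id, LABEL_COLUMN: fv.label}
        row.update(fv.to_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=[ID_COLUMN, LABEL_COLUMN, *VARIABLE_NAMES])


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in (ID_COLUMN, LABEL_COLUMN, *VARIABLE_NAMES) if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing column(s): {missing}")
    return table
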