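"""Per-entry physicochemical metadata for peptides and interfaces.

Sequence statistics (molecular weight, aromaticity, Guruprasad
instability index) are computed through ``Bio.SeqUtils.ProtParam``.
The isoelectric point is solved here by bisection of the
Henderson-Hasselbalch net charge using the EMBOSS pKa set
(``data/pka_emboss.tsv``); the hydrophobic fraction uses the
Kyte-Doolittle-positive residue set {A, V, L, I, P, F, M, W} by default.
Buried surface area comes from a Shrake-Rupley solvent-accessible
surface area (SASA) with a deterministic golden-spiral sphere lattice:
BSA = SASA(protein) + SASA(peptide) - SASA(complex).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from scipy.spatial import cKDTree

from .structure_io import Atom, Chain, Structure

__all__ = [
    "PeptideProperties",
    "molecular_weight",
    "aromaticity",
    "instability_index",
    "isoelectric_point",
    "net_charge",
    "hydrophobic_fraction",
    "sasa",
    "binding_area",
    "peptide_properties",
    "write_properties_tsv",
    "HYDROPHOBIC_SET",
    "PKA_SETS",
]

_STANDARD_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

#: Kyte-Doolittle positive-hydropathy residues.
HYDROPHOBIC_SET = frozenset("AVLIPFMW")


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    for i, letter in enumerate(seq):
        if letter not in _STANDARD_LETTERS:
            raise ValueError(f"unknown residue letter {letter!r} at position {i}")


def molecular_weight(seq: str) -> float:
    """Average molecular weight in Da (residue masses + one water)."""
    _check_sequence(seq)
    return float(ProteinAnalysis(seq).molecular_weight())


def aromaticity(seq: str) -> float:
    """Relative frequency of F, W and Y (Lobry-Gautier)."""
    _check_sequence(seq)
    return float(ProteinAnalysis(seq).aromaticity())


def instability_index(seq: str) -> float:
    """Guruprasad dipeptide-weight instability index, (10/L) * sum DIWV."""
    _check_sequence(seq)
    if len(seq) < 2:
        raise ValueError("instability index needs at least 2 residues")
    return float(ProteinAnalysis(seq).instability_index())


def hydrophobic_fraction(
    seq: str, hydrophobic: frozenset[str] = HYDROPHOBIC_SET
) -> float:
    """Fraction of residues in the hydrophobic set."""
    _check_sequence(seq)
    return sum(1 for r in seq if r in hydrophobic) / len(seq)


# ---------------------------------------------------------------------------
# isoelectric point


def _load_pka(name: str = "emboss") -> dict[str, tuple[float, int]]:
    text = (
        resources.files("pepsigna").joinpath(f"data/pka_{name}.tsv").read_text()
    )
    table: dict[str, tuple[float, int]] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        group, pka, sign = line.split("\t")
        table[group] = (float(pka), int(sign))
    return table


PKA_SETS = {"emboss": _load_pka("emboss")}


def net_charge(seq: str, ph: float, pka_set: str = "emboss") -> float:
    """Henderson-Hasselbalch net charge at ``ph``.

    Basic groups (N-terminus, C, H, K, R... sign +1) contribute
    ``+1/(1+10^(pH-pKa))``; acidic groups (C-terminus, D, E, C, Y) ``-1/(1+10^(pKa-pH))``.
    """
    _check_sequence(seq)
    table = PKA_SETS[pka_set]
    charge = 0.0
    groups = [("Nterm", 1), ("Cterm", 1)]
    groups += [(aa, seq.count(aa)) for aa in "CDEHKRY"]
    for group, count in groups:
        if count == 0 or group not in table:
            continue
        pka, sign = table[group]
        if sign > 0:
            charge += count / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= count / (1.0 + 10.0 ** (pka - ph))
    return charge


def isoelectric_point(
    seq: str, pka_set: str = "emboss", tol: float = 1e-3
) -> float:
    """pH of zero net charge, by bisection on [0, 14] to ``tol``."""
    _check_sequence(seq)
    lo, hi = 0.0, 14.0
    # net charge is monotone decreasing in pH
    if net_charge(seq, lo, pka_set) <= 0:
        return lo
    if net_charge(seq, hi, pka_set) >= 0:
        return hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# solvent-accessible surface area (Shrake-Rupley)


def _load_radii() -> dict[str, float]:
    text = (
        resources.files("pepsigna").joinpath("data/vdw_radii.tsv").read_text()
    )
    radii: dict[str, float] = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        element, r = line.split("\t")
        radii[element] = float(r)
    return radii


_RADII = _load_radii()


def _sphere_lattice(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n_points) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa(
    atoms: Structure | Chain | Sequence[Atom],
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-heavy-atom solvent-accessible surface areas in Å².

    Shrake-Rupley: each atom's solvent sphere (vdW radius + probe) is
    sampled on a fixed golden-spiral lattice of ``n_points`` points; a
    point is accessible when outside every neighbour's solvent sphere.
    Deterministic for fixed ``n_points``.
    """
    if isinstance(atoms, Structure):
        atom_list = [a for a in atoms.atoms() if not a.is_hydrogen]
    elif isinstance(atoms, Chain):
        atom_list = atoms.heavy_atoms()
    else:
        atom_list = [a for a in atoms if not a.is_hydrogen]
    if not atom_list:
        raise ValueError("need at least one heavy atom")

    coords = np.array([a.coord for a in atom_list])
    radii = np.array(
        [_RADII.get(a.element, _RADII["default"]) + probe for a in atom_list]
    )
    lattice = _sphere_lattice(n_points)
    tree = cKDTree(coords)
    r_max = radii.max()
    areas = np.empty(len(atom_list))
    for i, (center, r_i) in enumerate(zip(coords, radii)):
        points = center + r_i * lattice
        neighbours = [j for j in tree.query_ball_point(center, r_i + r_max) if j != i]
        if neighbours:
            nb_coords = coords[neighbours]
            nb_radii = radii[neighbours]
            d2 = ((points[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            accessible = (d2 >= nb_radii**2).all(axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * r_i**2
    return areas


def binding_area(
    complex_structure: Structure,
    protein: Chain | str,
    peptide: Chain | str,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[float, float]:
    """Buried surface area upon complex formation.

    Returns ``(bsa_total, bsa_per_side)`` where ``bsa_total =
    SASA(protein alone) + SASA(peptide alone) - SASA(complex)`` and
    ``bsa_per_side`` is half the total.  Chains not in contact give ~0
    (within lattice tolerance).
    """
    if isinstance(protein, str):
        protein = complex_structure.chain(protein)
    if isinstance(peptide, str):
        peptide = complex_structure.chain(peptide)
    both = protein.heavy_atoms() + peptide.heavy_atoms()
    total = (
        sasa(protein, probe, n_points).sum()
        + sasa(peptide, probe, n_points).sum()
        - sasa(both, probe, n_points).sum()
    )
    return float(total), float(total) / 2.0


# ---------------------------------------------------------------------------
# per-entry aggregation


@dataclass
class PeptideProperties:
    entry_id: str
    sequence: str
    length: int
    molecular_weight: float
    aromaticity: float
    instability_index: float
    isoelectric_point: float
    hydrophobic_fraction: float
    bsa_total: float
    bsa_per_side: float


def peptide_properties(
    complex_structure: Structure,
    protein_chain_id: str,
    peptide_chain_id: str,
    entry_id: str | None = None,
) -> PeptideProperties:
    """All reported metadata for one complex entry.

    Non-standard residues contribute coordinates to the SASA terms but
    are skipped in the sequence statistics.
    """
    peptide = complex_structure.chain(peptide_chain_id)
    seq = peptide.sequence()
    _check_sequence(seq)
    bsa_total, bsa_per_side = binding_area(
        complex_structure, protein_chain_id, peptide_chain_id
    )
    if entry_id is None:
        entry_id = (
            f"{complex_structure.pdb_id}_{protein_chain_id}_{peptide_chain_id}"
        )
    return PeptideProperties(
        entry_id=entry_id,
        sequence=seq,
        length=len(seq),
        molecular_weight=molecular_weight(seq),
        aromaticity=aromaticity(seq),
        instability_index=instability_index(seq),
        isoelectric_point=isoelectric_point(seq),
        hydrophobic_fraction=hydrophobic_fraction(seq),
        bsa_total=bsa_total,
        bsa_per_side=bsa_per_side,
    )


def write_properties_tsv(
    rows: Iterable[PeptideProperties], destination: str | Path
) -> None:
    header = (
        "entry_id\tsequence\tlength\tmw\taromaticity\tinstability\tpi"
        "\thydrophobic_frac\tbsa_total\tbsa_per_side"
    )
    lines = [header]
    for p in rows:
        lines.append(
            f"{p.entry_id}\t{p.sequence}\t{p.length}\t{p.molecular_weight:.2f}"
            f"\t{p.aromaticity:.4f}\t{p.instability_index:.2f}"
            f"\t{p.isoelectric_point:.3f}\t{p.hydrophobic_fraction:.4f}"
            f"\t{p.bsa_total:.2f}\t{p.bsa_per_side:.2f}"
        )
    Path(destination).write_text("\n".join(lines) + "\n")
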