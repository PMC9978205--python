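"""Pharmacophore atom typing for the aCSM-ALL signature.

Every heavy atom of a standard residue is mapped to one or more of the
eight aCSM-ALL categories — acceptor, donor, aromatic, hydrophobic,
negative, neutral, positive, sulfide — by a table keyed on
(residue name, atom name).  Typing is a pure function of those two
strings: coordinates, chain and file order play no role.

The default table ships as a human-editable TSV
(``data/typing_table.tsv``).  It is a reconstruction built from standard
pharmacophore chemistry (carboxylate oxygens are negative acceptors,
lysine/arginine/histidine protonatable nitrogens positive donors,
aromatic ring atoms aromatic, aliphatic carbons hydrophobic, thioether
and thiol sulfur sulfide, everything else neutral); the exact table used
to build the published signature datasets is unpublished, so any
single-label or alternative assignment is a data-file swap, not a code
change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .structure_io import Atom, Chain, Structure, STANDARD_RESIDUES

__all__ = [
    "CATEGORIES",
    "TypingTable",
    "TypedAtomSet",
    "load_default_table",
    "assign_types",
    "validate_table",
    "CANONICAL_HEAVY_ATOMS",
]

#: The eight aCSM-ALL categories, alphabetical; this order fixes feature naming.
CATEGORIES: tuple[str, ...] = (
    "acceptor",
    "donor",
    "aromatic",
    "hydrophobic",
    "negative",
    "neutral",
    "positive",
    "sulfide",
)
_CATEGORY_SET = frozenset(CATEGORIES)

# canonical heavy atoms of the 20 standard residues (PDB v3 naming),
# backbone N/CA/C/O plus side chain; terminal OXT is optional
_SIDE_CHAINS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

CANONICAL_HEAVY_ATOMS: dict[str, tuple[str, ...]] = {
    res: ("N", "CA", "C", "O") + _SIDE_CHAINS[res] for res in _SIDE_CHAINS
}


@dataclass
class TypingTable:
    """Mapping (residue_name, atom_name) -> frozenset of categories."""

    entries: dict[tuple[str, str], frozenset[str]]

    def lookup(self, residue_name: str, atom_name: str) -> frozenset[str] | None:
        return self.entries.get((residue_name, atom_name))

    @classmethod
    def from_tsv(cls, text: str) -> "TypingTable":
        entries: dict[tuple[str, str], frozenset[str]] = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            res, atom, cats = line.split("\t")
            categories = frozenset(c.strip() for c in cats.split(","))
            bad = categories - _CATEGORY_SET
            if bad:
                raise ValueError(
                    f"unknown category {sorted(bad)} for {res} {atom}"
                )
            if not categories:
                raise ValueError(f"empty category set for {res} {atom}")
            entries[(res, atom)] = categories
        return cls(entries)

    def to_tsv(self) -> str:
        lines = ["# residue\tatom\tcategories"]
        for (res, atom), cats in sorted(self.entries.items()):
            ordered = [c for c in CATEGORIES if c in cats]
            lines.append(f"{res}\t{atom}\t{','.join(ordered)}")
        return "\n".join(lines) + "\n"


def load_default_table() -> TypingTable:
    """Load the packaged default aCSM-ALL typing table."""
    text = (
        resources.files("pepsigna").joinpath("data/typing_table.tsv").read_text()
    )
    return TypingTable.from_tsv(text)


@dataclass
class TypedAtomSet:
    """Heavy atoms with their pharmacophore category sets, coordinate-aligned."""

    atoms: list[Atom]
    categories: list[frozenset[str]]
    n_untyped: int = 0

    def __post_init__(self) -> None:
        if len(self.atoms) != len(self.categories):
            raise ValueError("atoms and categories must align")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coord for a in self.atoms], dtype=float)

    def category_masks(self) -> dict[str, np.ndarray]:
        """Boolean membership mask per category, aligned with ``coords``."""
        return {
            cat: np.array([cat in cs for cs in self.categories], dtype=bool)
            for cat in CATEGORIES
        }


def assign_types(
    source: Structure | Chain | list[Chain],
    table: TypingTable | None = None,
) -> TypedAtomSet:
    """Type every heavy atom of the amino-acid residues in ``source``.

    Hydrogens are excluded.  Atoms with no table entry degrade to
    ``{neutral}`` and are counted in ``TypedAtomSet.n_untyped`` with a
    single summary warning.
    """
    if table is None:
        table = load_default_table()
    if isinstance(source, Structure):
        chains = source.chains
    elif isinstance(source, Chain):
        chains = [source]
    else:
        chains = list(source)

    atoms: list[Atom] = []
    cats: list[frozenset[str]] = []
    n_untyped = 0
    for chain in chains:
        for res in chain.residues:
            if not res.is_amino_acid:
                continue
            for atom in res.heavy_atoms():
                found = table.lookup(res.name, atom.name)
                if found is None:
                    found = frozenset({"neutral"})
                    n_untyped += 1
                atoms.append(atom)
                cats.append(found)
    if n_untyped:
        warnings.warn(
            f"{n_untyped} atoms had no typing-table entry; assigned neutral"
        )
    return TypedAtomSet(atoms=atoms, categories=cats, n_untyped=n_untyped)


@dataclass
class ValidationReport:
    missing: list[tuple[str, str]] = field(default_factory=list)
    n_entries: int = 0

    @property
    def ok(self) -> bool:
        return not self.missing


def validate_table(table: TypingTable) -> ValidationReport:
    """Check ``table`` against the canonical heavy-atom dictionary.

    Categories outside the 8-member universe raise at load time already;
    a table constructed in memory is re-checked here (hard error).
    """
    for (res, atom), cats in table.entries.items():
        bad = cats - _CATEGORY_SET
        if bad:
            raise ValueError(f"unknown category {sorted(bad)} for {res} {atom}")
    missing = [
        (res, atom)
        for res in sorted(CANONICAL_HEAVY_ATOMS)
        for atom in CANONICAL_HEAVY_ATOMS[res]
        if (res, atom) not in table.entries
    ]
    return ValidationReport(missing=missing, n_entries=len(table.entries))
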