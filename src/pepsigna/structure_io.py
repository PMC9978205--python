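"""Read, write and synthesize PDB-format macromolecular structures.

The in-memory model is a thin chains -> residues -> atoms hierarchy
(:class:`Structure`, :class:`Chain`, :class:`Residue`, :class:`Atom`)
carrying exactly the fields the downstream signature and interface code
needs.  Parsing is delegated to :class:`Bio.PDB.PDBParser` (permissive
mode); writing emits fixed-column PDB v3.3 records directly so that a
chain subset can be written without retaining Biopython entities.

Conventions applied at parse time:

* waters (HOH/DOD/WAT) are dropped;
* hydrogens are retained but flagged (``Atom.is_hydrogen``);
* alternate locations keep altloc ``'A'`` or blank; among other altlocs
  the highest occupancy wins, ties broken alphabetically;
* hetero residues that carry a peptide backbone (N, CA, C) are kept as
  polymer residues (modified amino acids); other HETATM groups are
  dropped;
* NMR ensembles keep every model, but model 1 is the working model for
  everything downstream.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "Experiment",
    "ChainKind",
    "STANDARD_RESIDUES",
    "THREE_TO_ONE",
    "parse_structure",
    "write_structure",
    "make_synthetic_complex",
    "make_chain",
]

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATERS = {"HOH", "DOD", "WAT"}


class Experiment(str, Enum):
    XRAY = "xray"
    NMR = "nmr"
    OTHER = "other"


class ChainKind(str, Enum):
    PEPTIDE = "peptide"
    PROTEIN = "protein"
    OTHER = "other"


@dataclass
class Atom:
    """One atom record with coordinates in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    icode: str
    chain_id: str
    coord: np.ndarray
    altloc: str = " "
    occupancy: float = 1.0
    is_hetatm: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.serial} needs 3 finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.serial} has empty element")


@dataclass
class Residue:
    name: str
    seq: int
    icode: str = " "
    atoms: list[Atom] = field(default_factory=list)
    is_hetero: bool = False

    @property
    def is_amino_acid(self) -> bool:
        """Standard residue, or a hetero group carrying a peptide backbone."""
        if self.name in STANDARD_RESIDUES:
            return True
        names = {a.name for a in self.atoms}
        return {"N", "CA", "C"} <= names

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    kind: ChainKind = ChainKind.OTHER

    def __len__(self) -> int:
        """Number of amino-acid residues (the peptide-length criterion)."""
        return sum(1 for r in self.residues if r.is_amino_acid)

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def heavy_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.heavy_atoms()]

    def sequence(self) -> str:
        """One-letter sequence; non-standard residues are skipped."""
        return "".join(
            THREE_TO_ONE[r.name] for r in self.residues if r.name in THREE_TO_ONE
        )


@dataclass
class Structure:
    pdb_id: str
    models: list[list[Chain]]
    experiment: Experiment = Experiment.OTHER
    resolution: float | None = None

    @property
    def chains(self) -> list[Chain]:
        """Chains of the working model (model 1)."""
        return self.models[0]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.pdb_id}")

    def atoms(self) -> list[Atom]:
        return [a for c in self.chains for a in c.atoms()]


# ---------------------------------------------------------------------------
# parsing


def _prefilter(text: str) -> str:
    """Drop coordinate records too mangled to parse, with a warning each."""
    kept = []
    for i, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                warnings.warn(f"line {i}: truncated {rec.strip()} record skipped")
                continue
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                warnings.warn(f"line {i}: unparseable coordinates, record skipped")
                continue
        kept.append(line)
    return "\n".join(kept) + "\n"


def _pick_altloc(bio_residue) -> list:
    """Resolve disordered atoms: altloc blank or 'A' wins, then occupancy."""
    out = []
    for atom in bio_residue.get_unpacked_list():
        alt = atom.get_altloc()
        if alt in (" ", "A"):
            out.append(atom)
    seen = {a.get_name() for a in out}
    by_name: dict[str, list] = {}
    for atom in bio_residue.get_unpacked_list():
        if atom.get_name() not in seen:
            by_name.setdefault(atom.get_name(), []).append(atom)
    for alts in by_name.values():
        best = sorted(
            alts, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc())
        )[0]
        out.append(best)
    return out


def parse_structure(text: str, pdb_id: str | None = None) -> Structure:
    """Parse a PDB-format string into a :class:`Structure`.

    Malformed coordinate records are skipped with a warning; a file with
    zero parsable atoms raises :class:`ValueError`.
    """
    clean = _prefilter(text)
    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        bio = parser.get_structure("S", io.StringIO(clean))
        header = parser.get_header() or {}

    method = (header.get("structure_method") or "").lower()
    if "x-ray" in method or "xray" in method:
        experiment = Experiment.XRAY
    elif "nmr" in method:
        experiment = Experiment.NMR
    else:
        experiment = Experiment.OTHER
    resolution = header.get("resolution")
    if pdb_id is None:
        pdb_id = "XXXX"
        for line in text.splitlines():
            if line.startswith("HEADER") and len(line) >= 66:
                code = line[62:66].strip()
                if code:
                    pdb_id = code
                break

    models: list[list[Chain]] = []
    n_atoms = 0
    for bio_model in bio:
        chains: list[Chain] = []
        for bio_chain in bio_model:
            chain = Chain(chain_id=bio_chain.id)
            for bio_res in bio_chain:
                hetflag, seq, icode = bio_res.get_id()
                name = bio_res.get_resname().strip()
                if name in _WATERS or hetflag == "W":
                    continue
                is_het = hetflag.startswith("H_")
                res = Residue(name=name, seq=seq, icode=icode, is_hetero=is_het)
                for bio_atom in _pick_altloc(bio_res):
                    element = (bio_atom.element or "").strip().upper()
                    if not element:
                        element = _infer_element(bio_atom.get_name())
                    res.atoms.append(
                        Atom(
                            serial=bio_atom.get_serial_number() or 0,
                            name=bio_atom.get_name(),
                            element=element,
                            residue_name=name,
                            residue_seq=seq,
                            icode=icode,
                            chain_id=chain.chain_id,
                            coord=bio_atom.get_coord(),
                            altloc=bio_atom.get_altloc(),
                            occupancy=bio_atom.get_occupancy() or 1.0,
                            is_hetatm=is_het,
                        )
                    )
                # drop non-polymer HETATM groups (ligands); keep modified aa
                if res.is_hetero and not res.is_amino_acid:
                    continue
                if res.atoms:
                    chain.residues.append(res)
                    n_atoms += len(res.atoms)
            if chain.residues:
                chain.residues.sort(key=lambda r: (r.seq, r.icode))
                chains.append(chain)
        models.append(chains)
    if n_atoms == 0:
        raise ValueError("no parsable ATOM/HETATM records")
    return Structure(
        pdb_id=pdb_id, models=models, experiment=experiment, resolution=resolution
    )


def _infer_element(atom_name: str) -> str:
    """Infer the element from the atom name per PDB naming convention."""
    stripped = atom_name.strip()
    if not stripped:
        return "X"
    if stripped[0].isdigit():  # e.g. 1HG1
        return "H"
    if len(atom_name) >= 2 and atom_name[0] != " " and stripped[:2] in (
        "FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "SE", "CU", "NI", "CO",
    ):
        return stripped[:2]
    return stripped[0]


# ---------------------------------------------------------------------------
# writing


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    # one-letter elements start in column 14
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(
    s: Structure,
    chain_subset: Iterable[str] | None = None,
    model_index: int = 0,
) -> str:
    """Serialize one model as fixed-column PDB v3.3 text.

    Only chains in ``chain_subset`` are emitted (all chains when None);
    a TER record follows each chain and the file ends with END.
    """
    chains = s.models[model_index]
    if chain_subset is not None:
        subset = set(chain_subset)
        if not subset:
            raise ValueError("empty chain selection")
        missing = subset - {c.chain_id for c in chains}
        if missing:
            raise KeyError(f"chains not in structure: {sorted(missing)}")
        chains = [c for c in chains if c.chain_id in subset]

    lines = [
        f"HEADER    PEPTIDE-PROTEIN COMPLEX                 01-JAN-00   {s.pdb_id:<4s}"
    ]
    if s.experiment == Experiment.XRAY:
        lines.append("EXPDTA    X-RAY DIFFRACTION")
        if s.resolution is not None:
            lines.append(
                f"REMARK   2 RESOLUTION. {s.resolution:5.2f} ANGSTROMS."
            )
    elif s.experiment == Experiment.NMR:
        lines.append("EXPDTA    SOLUTION NMR")

    serial = 0
    for chain in chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                record = "HETATM" if atom.is_hetatm else "ATOM  "
                x, y, z = atom.coord
                lines.append(
                    f"{record}{serial:5d} {_format_atom_name(atom.name, atom.element)}"
                    f"{atom.altloc}{res.name:>3s} {chain.chain_id}{res.seq:4d}"
                    f"{res.icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
                )
        last = chain.residues[-1]
        serial += 1
        lines.append(
            f"TER   {serial:5d}      {last.name:>3s} {chain.chain_id}{last.seq:4d}{last.icode}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# synthetic structures

# idealized offsets (Å) from the CA position for an extended backbone
_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.85, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.20, 0.60, 0.0]),
    "O": np.array([1.30, 1.82, 0.0]),
    "CB": np.array([0.0, -0.77, 1.33]),
}

_AA_CODES = sorted(STANDARD_RESIDUES)


def make_chain(
    chain_id: str,
    n_res: int,
    rng: np.random.Generator,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    sequence: Sequence[str] | None = None,
    jitter: float = 0.02,
) -> Chain:
    """Build an extended-backbone chain along +x with CA spacing 3.8 Å.

    Each residue gets N, CA, C, O and (except glycine) CB at idealized
    offsets plus a small coordinate jitter drawn from ``rng``.
    """
    origin = np.asarray(origin, dtype=float)
    if sequence is None:
        sequence = [str(rng.choice(_AA_CODES)) for _ in range(n_res)]
    chain = Chain(chain_id=chain_id)
    serial = 0
    for i in range(n_res):
        resname = sequence[i]
        ca = origin + np.array([3.8 * i, 0.0, 0.0])
        res = Residue(name=resname, seq=i + 1)
        for atom_name, offset in _BACKBONE_OFFSETS.items():
            if atom_name == "CB" and resname == "GLY":
                continue
            serial += 1
            coord = ca + offset + rng.normal(0.0, jitter, size=3)
            res.atoms.append(
                Atom(
                    serial=serial,
                    name=atom_name,
                    element=atom_name[0],
                    residue_name=resname,
                    residue_seq=i + 1,
                    icode=" ",
                    chain_id=chain_id,
                    coord=coord,
                )
            )
        chain.residues.append(res)
    return chain


def make_synthetic_complex(
    n_protein_res: int,
    n_peptide_res: int,
    seed: int,
    min_distance: float = 4.0,
    pdb_id: str = "SYN1",
) -> Structure:
    """Deterministic two-chain toy complex: protein A and peptide B.

    The peptide runs parallel to the protein, offset so the closest
    inter-chain atoms sit near ``min_distance`` Å — close enough to form
    a contact interface at conventional cutoffs.
    """
    if n_protein_res < 1 or n_peptide_res < 1:
        raise ValueError("chains need at least one residue")
    rng = np.random.default_rng(seed)
    protein = make_chain("A", n_protein_res, rng, origin=(0.0, 0.0, 0.0))
    peptide = make_chain(
        "B", n_peptide_res, rng, origin=(1.9, 4.0 + min_distance, 0.0)
    )
    # one corrective translation along y so the closest inter-chain atom
    # pair sits at ~min_distance (the chains are stacked along y)
    pc = np.array([a.coord for a in protein.atoms()])
    qc = np.array([a.coord for a in peptide.atoms()])
    d_min = cdist(pc, qc).min()
    shift = np.array([0.0, min_distance - d_min, 0.0])
    for atom in peptide.atoms():
        atom.coord += shift
    s = Structure(
        pdb_id=pdb_id,
        models=[[protein, peptide]],
        experiment=Experiment.XRAY,
        resolution=1.80,
    )
    return s
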