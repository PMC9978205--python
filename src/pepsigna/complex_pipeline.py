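"""Collection criteria, chain classification, entry enumeration and
contact-interface extraction for peptide-protein complexes.

A *peptide* is a polypeptide chain of 2-50 amino-acid residues inside a
multi-chain structure; a chain longer than the peptide ceiling is a
*protein*.  Every (protein chain, peptide chain) pair that shares at
least one inter-chain heavy-atom contact becomes a complex entry, named
``PDBID_PROTEINCHAIN_PEPTIDECHAIN`` — a four-chain structure with
proteins {A, B} and peptides {C, D} all in mutual contact therefore
yields the four entries A-C, A-D, B-C and B-D.

The admission rules mirror the archive-collection criteria: at least two
chains, at least one chain in the peptide length window, and an
admissible experiment (X-ray subject to a resolution rule, NMR always).
The default resolution rule keeps structures at <= 2.5 Å; the comparator
is explicit configuration because the conventional quality filter keeps
*high*-resolution structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import (
    Chain,
    ChainKind,
    Experiment,
    Structure,
    write_structure,
)

__all__ = [
    "CollectionCriteria",
    "InterfaceRecord",
    "ComplexEntry",
    "passes_criteria",
    "classify_chains",
    "enumerate_entries",
    "extract_interface",
    "write_entry_files",
]


@dataclass(frozen=True)
class CollectionCriteria:
    min_peptide_len: int = 2
    max_peptide_len: int = 50
    min_chains: int = 2
    allowed_experiments: frozenset[Experiment] = frozenset(
        {Experiment.XRAY, Experiment.NMR}
    )
    xray_resolution_threshold: float = 2.5
    # "le": resolution <= threshold (quality filter, default);
    # "ge": resolution >= threshold (the literal printed criterion)
    resolution_comparator: Literal["le", "ge"] = "le"

    def __post_init__(self) -> None:
        if not 1 <= self.min_peptide_len <= self.max_peptide_len:
            raise ValueError("need 1 <= min_peptide_len <= max_peptide_len")
        if self.xray_resolution_threshold <= 0:
            raise ValueError("resolution threshold must be positive")


@dataclass
class InterfaceRecord:
    """Inter-chain heavy-atom contacts within ``contact_cutoff`` Å."""

    contact_pairs: list[tuple[int, int, float]]  # (protein serial, peptide serial, d)
    protein_atoms: set[int]
    peptide_atoms: set[int]
    contact_cutoff: float

    @property
    def n_contacts(self) -> int:
        return len(self.contact_pairs)

    def to_tsv(self) -> str:
        lines = ["protein_atom\tpeptide_atom\tdistance"]
        for pa, qa, d in self.contact_pairs:
            lines.append(f"{pa}\t{qa}\t{d:.3f}")
        return "\n".join(lines) + "\n"


@dataclass
class ComplexEntry:
    entry_id: str  # PDBID_PROTEINCHAIN_PEPTIDECHAIN
    protein_chain: Chain
    peptide_chain: Chain
    interface: InterfaceRecord

    @property
    def n_contacts(self) -> int:
        return self.interface.n_contacts


def passes_criteria(
    s: Structure, c: CollectionCriteria | None = None
) -> tuple[bool, list[str]]:
    """Admission decision plus the list of failed-criterion reasons."""
    if c is None:
        c = CollectionCriteria()
    reasons: list[str] = []
    if len(s.chains) < c.min_chains:
        reasons.append(
            f"chain count {len(s.chains)} < {c.min_chains}"
        )
    lengths = [len(ch) for ch in s.chains]
    if not any(c.min_peptide_len <= L <= c.max_peptide_len for L in lengths):
        reasons.append(
            f"peptide length: no chain in [{c.min_peptide_len}, {c.max_peptide_len}]"
        )
    if s.experiment not in c.allowed_experiments:
        reasons.append(f"experiment {s.experiment.value} not admissible")
    elif s.experiment == Experiment.XRAY:
        if s.resolution is None:
            reasons.append("experiment metadata: X-ray without resolution")
        elif c.resolution_comparator == "le":
            if s.resolution > c.xray_resolution_threshold:
                reasons.append(
                    f"resolution {s.resolution} > {c.xray_resolution_threshold}"
                )
        elif s.resolution < c.xray_resolution_threshold:
            reasons.append(
                f"resolution {s.resolution} < {c.xray_resolution_threshold}"
            )
    return (not reasons, reasons)


def classify_chains(
    s: Structure, c: CollectionCriteria | None = None
) -> dict[str, ChainKind]:
    """Assign peptide/protein/other by amino-acid length.

    Length in [min, max] -> peptide (bounds inclusive); above max ->
    protein; below min or non-polypeptide -> other.  The assignment is
    also written onto each chain's ``kind``.
    """
    if c is None:
        c = CollectionCriteria()
    kinds: dict[str, ChainKind] = {}
    for chain in s.chains:
        L = len(chain)
        if c.min_peptide_len <= L <= c.max_peptide_len:
            kind = ChainKind.PEPTIDE
        elif L > c.max_peptide_len:
            kind = ChainKind.PROTEIN
        else:
            kind = ChainKind.OTHER
        chain.kind = kind
        kinds[chain.chain_id] = kind
    return kinds


def extract_interface(
    protein: Chain, peptide: Chain, contact_cutoff: float = 5.0
) -> InterfaceRecord:
    """All inter-chain heavy-atom pairs within ``contact_cutoff`` Å.

    Per-side interface atom sets are the unions of the contacting atoms'
    serial numbers.
    """
    p_atoms = protein.heavy_atoms()
    q_atoms = peptide.heavy_atoms()
    if not p_atoms or not q_atoms:
        raise ValueError("both chains need at least one heavy atom")
    d = cdist(
        np.array([a.coord for a in p_atoms]),
        np.array([a.coord for a in q_atoms]),
    )
    pairs: list[tuple[int, int, float]] = []
    for i, j in zip(*np.nonzero(d <= contact_cutoff)):
        pairs.append((p_atoms[i].serial, q_atoms[j].serial, float(d[i, j])))
    return InterfaceRecord(
        contact_pairs=pairs,
        protein_atoms={p for p, _, _ in pairs},
        peptide_atoms={q for _, q, _ in pairs},
        contact_cutoff=contact_cutoff,
    )


def enumerate_entries(
    s: Structure,
    c: CollectionCriteria | None = None,
    contact_cutoff: float = 5.0,
) -> list[ComplexEntry]:
    """Cartesian product of protein x peptide chains, kept when in contact.

    Pairs with zero heavy-atom contacts at ``contact_cutoff`` are
    dropped.  Entry order follows (protein chain id, peptide chain id).
    """
    if c is None:
        c = CollectionCriteria()
    kinds = classify_chains(s, c)
    proteins = sorted(
        (ch for ch in s.chains if kinds[ch.chain_id] == ChainKind.PROTEIN),
        key=lambda ch: ch.chain_id,
    )
    peptides = sorted(
        (ch for ch in s.chains if kinds[ch.chain_id] == ChainKind.PEPTIDE),
        key=lambda ch: ch.chain_id,
    )
    entries: list[ComplexEntry] = []
    for prot in proteins:
        for pep in peptides:
            iface = extract_interface(prot, pep, contact_cutoff)
            if iface.n_contacts >= 1:
                entries.append(
                    ComplexEntry(
                        entry_id=f"{s.pdb_id}_{prot.chain_id}_{pep.chain_id}",
                        protein_chain=prot,
                        peptide_chain=pep,
                        interface=iface,
                    )
                )
    return entries


def write_entry_files(
    s: Structure, entries: list[ComplexEntry], outdir: str | Path
) -> list[Path]:
    """Write each entry as a two-chain PDB plus an interface TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for entry in entries:
        pdb_path = outdir / f"{entry.entry_id}.pdb"
        pdb_path.write_text(
            write_structure(
                s,
                chain_subset={
                    entry.protein_chain.chain_id,
                    entry.peptide_chain.chain_id,
                },
            )
        )
        tsv_path = outdir / f"{entry.entry_id}.interface.tsv"
        tsv_path.write_text(entry.interface.to_tsv())
        written.extend([pdb_path, tsv_path])
    return written
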