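"""Synthetic inputs for every pipeline stage.

Provides: labeled signature datasets with controllable class separation
(per-class template conformations perturbed by isotropic Gaussian
coordinate noise), multi-chain contact complexes for entry enumeration,
a boundary-spanning corpus for the collection criteria, and a corpus of
deliberately malformed PDB text for parser robustness.

Class templates are idealized extended backbones whose residue
composition differs per class, so class signal exists both in the
geometry (template coordinates, chain length) and in the atom-type
channel (category composition).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .atom_typing import TypingTable, assign_types, load_default_table
from .ml_harness import LabeledDataset
from .signature import SignatureParams, SignatureVector, compute_signature, feature_schema
from .structure_io import (
    Chain,
    Experiment,
    Structure,
    make_chain,
    make_synthetic_complex,
    write_structure,
)

__all__ = [
    "FixtureSpec",
    "CASE_STUDY_1_SPEC",
    "make_labeled_signature_dataset",
    "make_four_chain_complex",
    "make_criteria_corpus",
    "make_malformed_corpus",
]

# residue palettes biasing each class toward distinct category channels
_CLASS_PALETTES = [
    ["ALA", "VAL", "LEU", "ILE", "MET"],      # hydrophobic / sulfide
    ["PHE", "TYR", "TRP", "HIS", "GLY"],      # aromatic
    ["ASP", "GLU", "SER", "THR", "ASN"],      # negative / polar
    ["LYS", "ARG", "HIS", "GLN", "GLY"],      # positive
    ["CYS", "PRO", "GLY", "SER", "ALA"],      # sulfide / small
    ["TRP", "LYS", "ASP", "MET", "VAL"],      # mixed
]


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for a labeled signature dataset."""

    n_classes: int = 5
    peptides_per_class: tuple[int, ...] = (10, 10, 10, 10, 10)
    peptide_length_range: tuple[int, int] = (8, 16)
    noise_sigma: float = 0.1  # Å, isotropic per-coordinate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        if len(self.peptides_per_class) != self.n_classes:
            raise ValueError("peptides_per_class must list one size per class")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")


#: Desk-scale analogue of the five-cluster sequence case study: class
#: sizes proportional to 503:183:161:142:122, scaled to n = 249.
CASE_STUDY_1_SPEC = FixtureSpec(
    n_classes=5,
    peptides_per_class=(113, 41, 36, 32, 27),
    peptide_length_range=(8, 16),
    noise_sigma=0.1,
    seed=0,
)


def _perturb(chain: Chain, rng: np.random.Generator, sigma: float) -> Chain:
    noisy = copy.deepcopy(chain)
    for atom in noisy.atoms():
        if sigma > 0:
            atom.coord = atom.coord + rng.normal(0.0, sigma, size=3)
    return noisy


def make_labeled_signature_dataset(
    spec: FixtureSpec,
    params: SignatureParams | None = None,
    table: TypingTable | None = None,
    return_structures: bool = False,
):
    """Generate a labeled signature dataset from noisy class templates.

    One template conformation per class (distinct length and residue
    palette); members are the template plus isotropic Gaussian noise of
    ``spec.noise_sigma`` Å on every atom, pushed through the signature
    pipeline.  Deterministic per spec (the seed covers template
    sequences and noise draws).
    """
    if params is None:
        params = SignatureParams()
    if table is None:
        table = load_default_table()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.peptide_length_range
    lengths = np.linspace(lo, hi, spec.n_classes).round().astype(int)

    ids: list[str] = []
    vectors: list[np.ndarray] = []
    labels: list[str] = []
    structures: list[Chain] = []
    for k in range(spec.n_classes):
        palette = _CLASS_PALETTES[k % len(_CLASS_PALETTES)]
        sequence = [palette[i % len(palette)] for i in range(lengths[k])]
        template = make_chain("B", int(lengths[k]), rng, sequence=sequence, jitter=0.0)
        for m in range(spec.peptides_per_class[k]):
            member = _perturb(template, rng, spec.noise_sigma)
            typed = assign_types(member, table)
            pid = f"C{k}P{m:03d}_B"
            sig = compute_signature(typed, params, peptide_id=pid)
            ids.append(pid)
            vectors.append(sig.values)
            labels.append(f"s{k}")
            if return_structures:
                structures.append(member)
    dataset = LabeledDataset(
        ids=ids,
        X=np.array(vectors),
        y=np.array(labels),
        schema=feature_schema(params),
    )
    if return_structures:
        return dataset, structures
    return dataset


def make_four_chain_complex(seed: int = 0, pdb_id: str = "SYN4") -> Structure:
    """Proteins {A, B} and peptides {C, D}, all four pairs in contact.

    The two peptides are sandwiched between the two protein chains so
    every protein-peptide pair shares heavy atoms within ~4.5 Å.
    """
    rng = np.random.default_rng(seed)
    protein_a = make_chain("A", 60, rng, origin=(0.0, 0.0, 0.0))
    protein_b = make_chain("B", 60, rng, origin=(0.0, 9.0, 0.0))
    peptide_c = make_chain("C", 10, rng, origin=(40.0, 4.5, 2.5))
    peptide_d = make_chain("D", 10, rng, origin=(80.0, 4.5, -2.5))
    return Structure(
        pdb_id=pdb_id,
        models=[[protein_a, protein_b, peptide_c, peptide_d]],
        experiment=Experiment.XRAY,
        resolution=1.90,
    )


def make_criteria_corpus(
    seed: int = 0, n_structures: int = 50
) -> list[tuple[Structure, bool, list[str]]]:
    """Structures spanning the collection-criteria boundaries.

    Cycles over chain lengths {1, 2, 50, 51}, chain counts {1, 2},
    experiments (X-ray at 1.8 Å / 3.0 Å, NMR), and records the expected
    admission decision plus the expected failure reasons (as substrings:
    "chain count", "peptide length", "resolution") under the default
    criteria.
    """
    rng = np.random.default_rng(seed)
    pep_lengths = [1, 2, 50, 51]
    chain_counts = [1, 2]
    experiments = [
        (Experiment.XRAY, 1.8),
        (Experiment.XRAY, 3.0),
        (Experiment.NMR, None),
    ]
    corpus: list[tuple[Structure, bool, list[str]]] = []
    i = 0
    while len(corpus) < n_structures:
        pep_len = pep_lengths[i % 4]
        n_chains = chain_counts[(i // 4) % 2]
        experiment, resolution = experiments[(i // 8) % 3]
        i += 1

        chains = [make_chain("B", pep_len, rng)]
        if n_chains == 2:
            chains.insert(0, make_chain("A", 60, rng, origin=(0.0, 8.0, 0.0)))
        s = Structure(
            pdb_id=f"T{len(corpus):03d}",
            models=[chains],
            experiment=experiment,
            resolution=resolution,
        )
        expected_reasons: list[str] = []
        if n_chains < 2:
            expected_reasons.append("chain count")
        # with one chain of 60 residues present, the peptide-window rule
        # hinges on the short chain alone
        if not (2 <= pep_len <= 50) and not (n_chains == 2 and 2 <= 60 <= 50):
            expected_reasons.append("peptide length")
        if experiment == Experiment.XRAY and resolution is not None and resolution > 2.5:
            expected_reasons.append("resolution")
        corpus.append((s, not expected_reasons, expected_reasons))
    return corpus


def make_malformed_corpus(seed: int = 0) -> list[str]:
    """Deterministic corpus of adversarial PDB-format strings.

    Covers truncated ATOM lines, unparseable coordinates, blank element
    columns, altloc duplicates, and multi-model files; every member
    still contains at least one parsable atom.
    """
    base = write_structure(make_synthetic_complex(5, 3, seed=seed))
    lines = base.splitlines()
    atom_lines = [ln for ln in lines if ln.startswith("ATOM")]

    truncated = "\n".join(lines[:3] + [atom_lines[0][:40]] + atom_lines[1:4]) + "\nEND\n"
    bad_coords = "\n".join(
        [atom_lines[0][:30] + "  xx.xxx" + atom_lines[0][38:]] + atom_lines[1:4]
    ) + "\nEND\n"
    no_element = "\n".join(ln[:76].rstrip() for ln in atom_lines[:6]) + "\nEND\n"
    altloc_dup = (
        atom_lines[0][:16] + "A" + atom_lines[0][17:] + "\n"
        + atom_lines[0][:16] + "B" + atom_lines[0][17:] + "\nEND\n"
    )
    multi_model = (
        "MODEL        1\n" + "\n".join(atom_lines[:4]) + "\nENDMDL\n"
        "MODEL        2\n" + "\n".join(atom_lines[:4]) + "\nENDMDL\nEND\n"
    )
    return [truncated, bad_coords, no_element, altloc_dup, multi_model]


def write_case_study_fixture(outdir: str | Path, seed: int = 0) -> Path:
    """Emit the case-study-1 preset as PDB files plus a labels TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = FixtureSpec(
        n_classes=CASE_STUDY_1_SPEC.n_classes,
        peptides_per_class=CASE_STUDY_1_SPEC.peptides_per_class,
        peptide_length_range=CASE_STUDY_1_SPEC.peptide_length_range,
        noise_sigma=CASE_STUDY_1_SPEC.noise_sigma,
        seed=seed,
    )
    dataset, structures = make_labeled_signature_dataset(spec, return_structures=True)
    labels_path = outdir / "labels.tsv"
    rows = []
    for pid, label, chain in zip(dataset.ids, dataset.y, structures):
        s = Structure(
            pdb_id=pid.split("_")[0],
            models=[[chain]],
            experiment=Experiment.XRAY,
            resolution=1.8,
        )
        (outdir / f"{pid}.pdb").write_text(write_structure(s))
        rows.append(f"{pid}\t{label}")
    labels_path.write_text("peptide_id\tclass\n" + "\n".join(rows) + "\n")
    return labels_path
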