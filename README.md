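# pepsigna

Graph-based structural signatures for peptide–protein complexes.

Peptides (chains of 2–50 amino-acid residues bound to a protein
partner) mediate a large share of protein–protein interactions and are
a growing class of therapeutics. Comparing their 3D structures at scale
needs a fixed-length numerical representation. `pepsigna` implements
the **aCSM-ALL cutoff-scanning signature**: each heavy atom is labelled
with one or more of eight pharmacophore categories (acceptor, donor,
aromatic, hydrophobic, negative, neutral, positive, sulfide), and for
every unordered category pair {c₁, c₂} and distance cutoff
c = k·Δ (k = 1 … L/Δ) the feature

&nbsp;&nbsp;&nbsp;&nbsp;x₍c₁,c₂,c₎ = |{ (i, j) : i < j, dᵢⱼ ≤ c, atom i carries c₁ and atom j carries c₂ }|

counts atom pairs within the cutoff. With the defaults Δ = 0.2 Å,
L = 20 Å this yields 36 × 100 = **3,600 features per peptide**. The
toolkit also extracts peptide–protein complex entries from PDB files
(collection criteria, chain classification, pairwise entry enumeration,
contact interfaces), computes per-entry physicochemical metadata
(molecular weight, aromaticity, instability index, isoelectric point,
hydrophobic fraction, buried surface area), and reproduces a stratified
70/30 triplicate evaluation protocol over seven classifier families.

Intended users: structural bioinformaticians building peptide datasets
from the PDB, and anyone who wants distance-pattern feature vectors for
peptide classification or retrieval.

## Worked example

```python
import pepsigna as pp

# a deterministic synthetic complex: 60-residue protein A, 10-residue peptide B
s = pp.make_synthetic_complex(60, 10, seed=1)

ok, reasons = pp.passes_criteria(s)          # collection criteria
entries = pp.enumerate_entries(s)            # peptide-protein entries
typed = pp.assign_types(s.chain("B"))        # pharmacophore typing
sig = pp.compute_signature(typed, peptide_id="SYN1_B")
props = pp.peptide_properties(s, "A", "B")

print(ok, [e.entry_id for e in entries], entries[0].n_contacts)
print(len(sig), int(sig.values.sum()))
print(props.sequence, round(props.molecular_weight, 2),
      round(props.isoelectric_point, 3), round(props.bsa_total, 2))
```

prints

```
True ['SYN1_A_B'] 19
3600 49162
WQPVFFPGFL 1237.45 6.1 370.0
```

The structure passes the collection criteria; its single protein–peptide
pair forms one entry with 19 heavy-atom contacts at the 5 Å cutoff; the
peptide's signature has 3,600 features whose counts sum to 49,162 pairs
over all category pairs and cutoffs; and the 10-residue peptide
WQPVFFPGFL weighs 1237.45 Da, has an isoelectric point of pH 6.1 and
buries ≈ 370 Å² of surface on binding.

The same pipeline from a shell:

```sh
pepsigna split --in syn1.pdb --outdir entries/     # one PDB + interface TSV per entry
pepsigna sign  --in entries/ --out signatures.csv  # 3,600-feature rows, id = PDBID_CHAIN
pepsigna props --in entries/ --out props.tsv
pepsigna eval  --signatures signatures.csv --labels labels.tsv --out report.json
```

`pepsigna fixtures --preset case-study-1 --out dir/` emits a synthetic
five-class, size-imbalanced labeled dataset (249 peptides, class sizes
113/41/36/32/27, coordinate noise σ = 0.1 Å) for end-to-end runs of the
evaluation protocol; on it, gradient boosting and kNN both reach
CA = 1.00 under the 70/30 triplicate protocol.

See `docs/methods.md` for the counting conventions, the typing table,
the SASA implementation and the evaluation protocol in detail.

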