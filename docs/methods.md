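# Methods

## The signature model

`pepsigna` represents a peptide structure as a graph whose nodes are its
heavy atoms, labelled with pharmacophore categories, and whose edges are
implied by inter-atomic distance. The **aCSM-ALL cutoff-scanning
signature** summarizes this graph as a vector of pair counts: for every
unordered pair of the eight categories *(acceptor, donor, aromatic,
hydrophobic, negative, neutral, positive, sulfide)* and every cutoff
`k · step` with `k = 1 … limit/step`, the feature value is the number of
unordered atom pairs `(i < j)` within that cutoff in which one atom
carries the first category and the other the second (for a diagonal
pair, both carry it).

Counting conventions, fixed because they define feature semantics:

- **Unordered pairs.** With 8 categories there are 36 unordered pairs
  with repetition; at the default 0.2 Å step and 20 Å limit this gives
  36 × 100 = 3,600 features, which is what forces the unordered reading.
- **Closed right bin edge.** A distance `d` is inside cutoff `c` when
  `d ≤ c`. `d = 0` cannot occur between distinct atoms.
- **Multi-label contribution.** An atom may carry several categories
  (a tyrosine OH is both donor and acceptor). An atom *pair* contributes
  to a category-pair feature at most once, however many label
  combinations match, so every feature is bounded by `n(n−1)/2`.
- **Cumulative vs interval.** The default is cumulative (count of all
  pairs with `d ≤ cutoff`, non-decreasing in the cutoff); `mode="interval"`
  counts pairs in `((k−1)·step, k·step]`. The two encode the same
  information — the cumulative series is the running sum of the interval
  series — so the choice is a serialization convention, not a model change.
- **No topological exclusion.** Bonded and intra-residue pairs are
  counted like any other pair; the scan is purely geometric.
- **Hydrogens excluded.** X-ray structures mostly lack them; including
  them only for NMR entries would make signatures incomparable across
  experiments.

Because features depend only on inter-atomic distances, signatures are
exactly invariant under rigid motion of the coordinates, and this is
asserted bit-for-bit in the tests.

## Atom typing

Typing is a pure lookup on `(residue name, atom name)` in a packaged
TSV (`data/typing_table.tsv`). The table covers every heavy atom of the
20 standard residues and follows standard pharmacophore chemistry:
carboxylate oxygens (Asp/Glu, C-terminal OXT) are negative + acceptor;
Lys NZ, Arg NE/NH1/NH2 and protonatable His ring nitrogens are
positive + donor; backbone and side-chain amide nitrogens are donors;
carbonyl and hydroxyl oxygens are acceptors (hydroxyls also donors);
Phe/Tyr/Trp/His ring atoms are aromatic (ring carbons additionally
hydrophobic); aliphatic carbons are hydrophobic; Cys/Met sulfur is
sulfide; the polar-neutral remainder (carbonyl carbons, amide carbons)
is neutral. One deliberate chemistry choice: the proline backbone
nitrogen is typed *neutral*, not donor, because it carries no amide
hydrogen. Atoms missing from the table degrade to `{neutral}` with a
warning tally rather than an error, so unusual atoms never abort a
batch run. The assignment used by the original signature datasets is
unpublished; this table is a documented reconstruction, and since it is
data, a single-label or alternative table is a configuration swap.

## Complex extraction

A chain is a *peptide* when its amino-acid length is within [2, 50]
(bounds inclusive), a *protein* above 50, *other* below 2. A structure
is admitted when it has ≥ 2 chains, at least one chain in the peptide
window, and an admissible experiment: NMR always, X-ray subject to a
resolution rule. The conventional quality filter (resolution ≤ 2.5 Å)
is the default; the comparator is explicit configuration
(`resolution_comparator="ge"`) because the opposite reading also
appears in the literature describing this criterion. Entries are the
Cartesian product of protein × peptide chains, kept when they share at
least one inter-chain heavy-atom pair within the contact cutoff
(default 5.0 Å, the conventional non-covalent contact radius). Each
entry is written as a two-chain PDB plus a TSV of contact pairs with
distances to 3 decimals. For NMR ensembles all models are parsed but
model 1 is the working model throughout. Alternate locations keep
altloc `A`/blank, then highest occupancy (ties alphabetical); waters
are dropped; HETATM groups carrying a peptide backbone (modified amino
acids) are kept as residues, other ligands are dropped.

## Physicochemical metadata

Per-entry peptide metadata comprises sequence statistics and buried
surface area:

- **Molecular weight** (average masses, Da), **aromaticity**
  (Lobry–Gautier F/W/Y frequency) and the **Guruprasad instability
  index** are computed through `Bio.SeqUtils.ProtParam`, which packages
  the DIWV dipeptide-weight table.
- **Isoelectric point**: bisection of the Henderson–Hasselbalch net
  charge over termini plus C, D, E, H, K, R, Y on pH ∈ [0, 14] to 1e-3,
  using the EMBOSS pKa set (`data/pka_emboss.tsv`). Other pKa scales
  shift the result by a few tenths of a pH unit; the scale is a data
  file, not code.
- **Hydrophobic fraction**: share of residues in {A, V, L, I, P, F, M, W}
  (the Kyte–Doolittle-positive set), configurable.
- **Binding area**: `BSA = SASA(protein) + SASA(peptide) − SASA(complex)`,
  reported both as the total and per side (total/2), from a
  Shrake–Rupley SASA with probe 1.4 Å, per-element van der Waals radii
  (`data/vdw_radii.tsv`) and a deterministic golden-spiral lattice of
  960 points per atom. The lattice makes results reproducible
  bit-for-bit for fixed inputs, but it is orientation-dependent: SASA
  values agree across rigid motions to lattice tolerance (≲ 1%), not
  exactly. An isolated atom returns the closed form `4π(r + 1.4)²`
  exactly up to lattice quadrature.

Non-standard residues contribute coordinates to SASA but are skipped in
sequence statistics.

## Evaluation protocol

The harness reproduces a stratified 70/30 train/test protocol run in
triplicate (seeds {1, 2, 3}, recorded in the report) over seven
classifier families with fixed hyperparameters: kNN (3 neighbours,
Manhattan, distance weights), linear SVM (C = 1, tol = 1e-3), a
300-unit ReLU/Adam MLP (α = 1e-3, 200 iterations), gradient boosting
(100 trees, rate 0.1, depth 3), ridge logistic regression (C = 1), a
decision tree (min leaf 2, min split 5, depth ≤ 100) and a random
forest (10 trees, min split 5). The stratified split allocates
`round(0.7·n)` training rows across classes by largest remainder;
classes with a single member stay whole in training with a warning.
Metrics are replicate averages of macro AUC (one-vs-rest over class
probabilities, or softmaxed margins for the uncalibrated SVM), CA, macro
F1/precision/recall, plus per-class accuracy (%) and a summed confusion
matrix. One engineering choice: the margin- and gradient-based learners
(SVM, MLP, logistic regression) are fit on standardized features,
because raw cumulative pair counts span orders of magnitude and stall
Adam outright; distance- and tree-based learners see raw counts so the
Manhattan-kNN semantics are untouched.

## Synthetic data

The generators produce everything the tests consume, so no structure
downloads are needed:

- `make_synthetic_complex` builds extended-backbone chains (N, CA, C,
  O, CB per residue, consecutive CA spacing 3.8 Å, jitter 0.02 Å) with
  the peptide placed at a configurable minimum distance (default 4 Å)
  from the protein, guaranteeing a contact interface at the 5 Å cutoff.
- `make_labeled_signature_dataset` draws, per class, one template
  peptide whose length and residue palette differ by class (so class
  signal exists in both geometry and atom-type channels), then perturbs
  every atom with isotropic Gaussian noise of σ Å per member. σ = 0
  yields identical within-class signatures; increasing σ monotonically
  degrades separability, which the tests assert over three σ values.
- The `case-study-1` preset emulates a five-cluster, size-imbalanced
  classification dataset at desk scale: class sizes 113/41/36/32/27
  (proportional to 503:183:161:142:122, n = 249), σ = 0.1 Å. Under the
  triplicate protocol, gradient boosting and kNN reach CA = 1.0 here.
  That demonstrates the pipeline is wired correctly and that signatures
  separate geometrically distinct conformational families; it does
  *not* emulate real crystallographic peptides, whose within-cluster
  variation includes sequence changes, packing effects and alternative
  conformations. Accuracy on real archive-scale data is a property of
  that data, not of this fixture.
- `make_criteria_corpus` spans the admission boundaries (lengths
  1/2/50/51, one vs two chains, X-ray 1.8/3.0 Å, NMR) with constructed
  ground truth; `make_malformed_corpus` covers truncated records,
  unparseable coordinates, missing element columns, altloc duplicates
  and multi-model files.

## Problem sizes and numerical notes

Tests run on peptides of ~50–100 heavy atoms and datasets of ≤ 249
signatures; the brute-force oracle comparisons use ≤ 50 atoms and
coarse bin grids (e.g. 1 Å × 10 bins), where the naive triple loop is
exact and fast. Bin assignment uses `searchsorted` against the rounded
cutoff grid; distances falling exactly on a bin edge are assigned to
that bin (closed right edge), matching the oracle's `d ≤ k·step`
comparison. Degenerate inputs: a single-atom or empty atom set yields
an all-zero signature (warning, not error); a zero-parsable-atom file
is a hard parse error; an empty chain selection on write is an error.

## Known limitations

- The typing table is a reconstruction; signatures are comparable
  *within* a table, not across tables.
- SASA uses a fixed quadrature; absolute areas carry ~1% lattice error.
- The classifier hyperparameters mirror the stated protocol but exact
  numeric parity with any particular GUI tool's internals is not
  promised.
- mmCIF input, assembly expansion and protonation-state prediction are
  out of scope.
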