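import numpy as np
import pytest

from pepsigna import (
    CollectionCriteria,
    classify_chains,
    enumerate_entries,
    extract_interface,
    make_synthetic_complex,
    passes_criteria,
)
from pepsigna.complex_pipeline import write_entry_files
from pepsigna.structure_io import ChainKind, Experiment, Structure, make_chain
from pepsigna.fixtures import make_criteria_corpus, make_four_chain_complex

from oracles import naive_contacts


def _structure(chain_lengths, experiment=Experiment.XRAY, resolution=1.8):
    rng = np.random.default_rng(5)
    chains = [
        make_chain(cid, n, rng, origin=(0.0, 8.0 * i, 0.0))
        for i, (cid, n) in enumerate(chain_lengths.items())
    ]
    return Structure(pdb_id="TEST", models=[chains],
                     experiment=experiment, resolution=resolution)


class TestPassesCriteria:
    def test_good_xray_structure_passes(self):
        ok, reasons = passes_criteria(_structure({"A": 120, "B": 10}))
        assert ok and reasons == []

    def test_single_chain_fails_on_chain_count(self):
        ok, reasons = passes_criteria(_structure({"B": 10}))
        assert not ok
        assert any("chain count" in r for r in reasons)

    def test_no_chain_in_peptide_window_fails(self):
        ok, reasons = passes_criteria(_structure({"A": 120, "B": 60}))
        assert not ok
        assert any("peptide length" in r for r in reasons)

    def test_low_resolution_xray_fails_by_default(self):
        ok, reasons = passes_criteria(_structure({"A": 120, "B": 10}, resolution=3.0))
        assert not ok
        assert any("resolution" in r for r in reasons)

    def test_literal_comparator_flips_resolution_rule(self):
        c = CollectionCriteria(resolution_comparator="ge")
        ok, _ = passes_criteria(_structure({"A": 120, "B": 10}, resolution=3.0), c)
        assert ok

    def test_nmr_passes_without_resolution(self):
        ok, _ = passes_criteria(
            _structure({"A": 120, "B": 10}, experiment=Experiment.NMR, resolution=None)
        )
        assert ok

    def test_missing_experiment_metadata_fails(self):
        ok, reasons = passes_criteria(
            _structure({"A": 120, "B": 10}, experiment=Experiment.OTHER)
        )
        assert not ok


class TestClassifyChains:
    @pytest.mark.parametrize(
        "lengths,expected",
        [
            ({"A": 120, "B": 9}, {"A": "protein", "B": "peptide"}),
            ({"A": 120, "B": 130}, {"A": "protein", "B": "protein"}),
            ({"A": 50, "B": 51}, {"A": "peptide", "B": "protein"}),
            ({"A": 2, "B": 60}, {"A": "peptide", "B": "protein"}),
            ({"A": 1, "B": 60}, {"A": "other", "B": "protein"}),
        ],
    )
    def test_length_thresholds(self, lengths, expected):
        kinds = classify_chains(_structure(lengths))
        assert {k: v.value for k, v in kinds.items()} == expected


class TestEnumerateEntries:
    def test_four_chain_worked_example(self):
        """Proteins {A,B} x peptides {C,D} in mutual contact -> 4 entries."""
        entries = enumerate_entries(make_four_chain_complex())
        assert [e.entry_id for e in entries] == [
            "SYN4_A_C", "SYN4_A_D", "SYN4_B_C", "SYN4_B_D",
        ]
        assert all(e.n_contacts >= 1 for e in entries)

    def test_distant_chains_yield_zero_entries(self):
        rng = np.random.default_rng(1)
        chains = [
            make_chain("A", 60, rng),
            make_chain("C", 10, rng, origin=(0.0, 100.0, 0.0)),
        ]
        s = Structure(pdb_id="FAR0", models=[chains],
                      experiment=Experiment.XRAY, resolution=1.8)
        assert enumerate_entries(s) == []

    def test_synthetic_complex_yields_exactly_one_entry(self, toy_complex):
        entries = enumerate_entries(toy_complex)
        assert [e.entry_id for e in entries] == ["SYN1_A_B"]

    def test_entry_count_bounded_by_pair_product(self):
        s = make_four_chain_complex()
        kinds = classify_chains(s)
        n_prot = sum(1 for k in kinds.values() if k == ChainKind.PROTEIN)
        n_pep = sum(1 for k in kinds.values() if k == ChainKind.PEPTIDE)
        assert len(enumerate_entries(s)) <= n_prot * n_pep

    def test_entry_files_written(self, toy_complex, tmp_path):
        entries = enumerate_entries(toy_complex)
        paths = write_entry_files(toy_complex, entries, tmp_path)
        assert (tmp_path / "SYN1_A_B.pdb").exists()
        tsv = (tmp_path / "SYN1_A_B.interface.tsv").read_text().splitlines()
        assert tsv[0] == "protein_atom\tpeptide_atom\tdistance"
        assert len(tsv) - 1 == entries[0].n_contacts


class TestExtractInterface:
    def _single_atom_chains(self, gap):
        rng = np.random.default_rng(0)
        a = make_chain("A", 1, rng, jitter=0.0)
        b = make_chain("B", 1, rng, origin=(0.0, gap, 0.0), jitter=0.0)
        # keep only the CA of each so the geometry is exact
        for ch in (a, b):
            ch.residues[0].atoms = [x for x in ch.residues[0].atoms if x.name == "CA"]
        return a, b

    def test_two_atoms_within_cutoff(self):
        a, b = self._single_atom_chains(3.0)
        rec = extract_interface(a, b, contact_cutoff=5.0)
        assert rec.n_contacts == 1
        assert rec.contact_pairs[0][2] == pytest.approx(3.0)

    def test_two_atoms_beyond_cutoff(self):
        a, b = self._single_atom_chains(3.0)
        assert extract_interface(a, b, contact_cutoff=2.0).n_contacts == 0

    def test_matches_naive_all_pairs_filter(self, toy_complex):
        prot, pep = toy_complex.chain("A"), toy_complex.chain("B")
        rec = extract_interface(prot, pep, contact_cutoff=5.0)
        expected = naive_contacts(
            [a.coord for a in prot.heavy_atoms()],
            [a.coord for a in pep.heavy_atoms()],
            5.0,
        )
        got = sorted((p, q, round(d, 6)) for p, q, d in rec.contact_pairs)
        want = sorted(
            (prot.heavy_atoms()[i].serial, pep.heavy_atoms()[j].serial, round(d, 6))
            for i, j, d in expected
        )
        assert got == want
        assert all(d <= 5.0 for _, _, d in rec.contact_pairs)

    def test_symmetric_under_side_swap(self, toy_complex):
        prot, pep = toy_complex.chain("A"), toy_complex.chain("B")
        fwd = extract_interface(prot, pep, 5.0)
        rev = extract_interface(pep, prot, 5.0)
        assert sorted((q, p) for p, q, _ in fwd.contact_pairs) == sorted(
            (p, q) for p, q, _ in rev.contact_pairs
        )


def test_criteria_corpus_ground_truth():
    """Boundary corpus: decisions and reasons match construction exactly."""
    corpus = make_criteria_corpus(seed=0, n_structures=50)
    assert len(corpus) == 50
    for s, expected_ok, expected_reasons in corpus:
        ok, reasons = passes_criteria(s)
        assert ok == expected_ok, (s.pdb_id, reasons, expected_reasons)
        for fragment in expected_reasons:
            assert any(fragment in r for r in reasons), (s.pdb_id, fragment, reasons)
        kinds = classify_chains(s)
        for chain in s.chains:
            L = len(chain)
            if 2 <= L <= 50:
                assert kinds[chain.chain_id] == ChainKind.PEPTIDE
            elif L > 50:
                assert kinds[chain.chain_id] == ChainKind.PROTEIN
            else:
                assert kinds[chain.chain_id] == ChainKind.OTHER


def test_entries_respect_peptide_length_bounds(toy_complex):
    for entry in enumerate_entries(toy_complex):
        assert 2 <= len(entry.peptide_chain) <= 50
        assert len(entry.protein_chain) > 50
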