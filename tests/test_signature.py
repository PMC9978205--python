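import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepsigna import (
    SignatureParams,
    compute_signature,
    distance_matrix,
    feature_schema,
    read_signature_csv,
    write_signature_csv,
)
from pepsigna.atom_typing import CATEGORIES, TypedAtomSet
from pepsigna.signature import CATEGORY_PAIRS
from pepsigna.structure_io import Atom

from conftest import random_typed_set
from oracles import naive_signature, naive_distance_matrix


def _atoms(coords, category_sets):
    atoms = [
        Atom(serial=i + 1, name="CA", element="C", residue_name="ALA",
             residue_seq=i + 1, icode=" ", chain_id="A", coord=c)
        for i, c in enumerate(coords)
    ]
    return TypedAtomSet(atoms=atoms, categories=[frozenset(s) for s in category_sets])


class TestFeatureSchema:
    @pytest.mark.parametrize(
        "step,limit,expected",
        [(0.2, 20.0, 3600), (1.0, 5.0, 180), (5.0, 5.0, 36)],
    )
    def test_lengths(self, step, limit, expected):
        schema = feature_schema(SignatureParams(cutoff_step=step, cutoff_limit=limit))
        assert len(schema) == expected

    def test_ordering_pair_outer_cutoff_inner(self):
        schema = feature_schema(SignatureParams(cutoff_step=1.0, cutoff_limit=2.0))
        assert schema[0] == "acceptor:acceptor@1"
        assert schema[1] == "acceptor:acceptor@2"
        assert schema[2] == "acceptor:aromatic@1"
        assert len(schema) == 72

    def test_non_integral_bin_count_rejected(self):
        with pytest.raises(ValueError):
            SignatureParams(cutoff_step=0.3, cutoff_limit=1.0)

    def test_category_pairs_are_36_unordered(self):
        assert len(CATEGORY_PAIRS) == 36
        assert all(c1 <= c2 for c1, c2 in CATEGORY_PAIRS)


class TestDistanceMatrix:
    def test_three_four_five(self):
        d = distance_matrix(np.array([[0, 0, 0], [3, 4, 0]]))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[1, 0] == pytest.approx(5.0)
        assert d[0, 0] == d[1, 1] == 0.0

    def test_single_atom(self):
        assert distance_matrix(np.zeros((1, 3))).shape == (1, 1)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(7)
        coords = rng.uniform(0, 10, size=(50, 3))
        assert np.allclose(distance_matrix(coords), naive_distance_matrix(coords))


class TestComputeSignature:
    def test_hand_enumerated_single_pair(self):
        """Two hydrophobic atoms 2.5 Å apart, 1 Å bins to 5 Å."""
        atoms = _atoms([[0, 0, 0], [2.5, 0, 0]], [{"hydrophobic"}] * 2)
        params = SignatureParams(cutoff_step=1.0, cutoff_limit=5.0)
        sig = compute_signature(atoms, params)
        assert sig.series("hydrophobic", "hydrophobic").tolist() == [0, 0, 1, 1, 1]
        for c1, c2 in CATEGORY_PAIRS:
            if (c1, c2) != ("hydrophobic", "hydrophobic"):
                assert sig.series(c1, c2).sum() == 0

    def test_single_atom_is_zero_vector_of_3600(self):
        sig = compute_signature(_atoms([[0, 0, 0]], [{"donor"}]))
        assert len(sig) == 3600
        assert sig.values.sum() == 0

    def test_empty_set_warns_not_errors(self):
        with pytest.warns(UserWarning):
            sig = compute_signature(TypedAtomSet(atoms=[], categories=[]))
        assert sig.values.sum() == 0 and len(sig) == 3600

    @pytest.mark.parametrize("mode", ["cumulative", "interval"])
    def test_oracle_equivalence_random_atoms(self, mode):
        """Feature-for-feature agreement with the naive triple-loop oracle."""
        rng = np.random.default_rng(11)
        params = SignatureParams(cutoff_step=1.0, cutoff_limit=14.0, mode=mode)
        for _ in range(3):
            atoms = random_typed_set(rng, n_atoms=30)
            sig = compute_signature(atoms, params)
            expected = naive_signature(
                atoms.coords, atoms.categories, 1.0, 14.0, mode=mode
            )
            for c1, c2 in CATEGORY_PAIRS:
                assert sig.series(c1, c2).tolist() == expected[(c1, c2)], (c1, c2)

    def test_multilabel_pair_counted_once_per_feature(self):
        """Both atoms carrying both categories still contribute 1 per feature."""
        both = {"donor", "acceptor"}
        atoms = _atoms([[0, 0, 0], [1.5, 0, 0]], [both, both])
        sig = compute_signature(atoms, SignatureParams(cutoff_step=1.0, cutoff_limit=5.0))
        assert sig.series("donor", "acceptor").max() == 1
        assert sig.series("donor", "donor").max() == 1
        assert sig.series("acceptor", "acceptor").max() == 1

    def test_rigid_motion_invariance(self, typed_peptide):
        """Rotation + translation leaves the signature bit-identical."""
        from scipy.spatial.transform import Rotation

        base = compute_signature(typed_peptide).values
        rng = np.random.default_rng(3)
        coords = typed_peptide.coords
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-50, 50, size=3)
            moved = _atoms(coords @ R.T + t, typed_peptide.categories)
            assert np.array_equal(compute_signature(moved).values, base)

    def test_cumulative_monotone_and_bounded(self, typed_peptide):
        sig = compute_signature(typed_peptide)
        n = len(typed_peptide)
        assert sig.values.max() <= n * (n - 1) // 2
        for c1, c2 in CATEGORY_PAIRS:
            series = sig.series(c1, c2)
            assert (np.diff(series) >= 0).all()

    def test_interval_cumsum_equals_cumulative(self, typed_peptide):
        cum = compute_signature(
            typed_peptide, SignatureParams(mode="cumulative")
        ).values
        inter = compute_signature(
            typed_peptide, SignatureParams(mode="interval")
        ).values
        n_bins = 100
        stacked = inter.reshape(36, n_bins).cumsum(axis=1).ravel()
        assert np.array_equal(stacked, cum)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_upper_bound_property(seed):
    """Every feature is bounded by n*(n-1)/2 regardless of typing."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 15))
    atoms = random_typed_set(rng, n_atoms=n, box=6.0)
    sig = compute_signature(atoms, SignatureParams(cutoff_step=2.0, cutoff_limit=10.0))
    assert sig.values.max() <= max(n * (n - 1) // 2, 0)


class TestCsvRoundTrip:
    def test_row_layout_and_roundtrip(self, typed_peptide, tmp_path):
        sig = compute_signature(typed_peptide, peptide_id="SYN1_B")
        path = tmp_path / "signatures.csv"
        write_signature_csv([sig], path)
        header, row = path.read_text().splitlines()[:2]
        assert header.split(",")[0] == "id"
        assert len(header.split(",")) == 3601
        assert row.split(",")[0] == "SYN1_B"
        back = read_signature_csv(path)
        assert len(back) == 1
        assert back[0].peptide_id == "SYN1_B"
        assert np.array_equal(back[0].values, sig.values)
        assert back[0].schema == sig.schema

    def test_empty_dataset_is_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_signature_csv([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("id,")

    def test_mixed_schemas_rejected(self, typed_peptide, tmp_path):
        a = compute_signature(typed_peptide, SignatureParams(), peptide_id="a")
        b = compute_signature(
            typed_peptide, SignatureParams(cutoff_step=1.0, cutoff_limit=5.0),
            peptide_id="b",
        )
        with pytest.raises(ValueError):
            write_signature_csv([a, b], tmp_path / "bad.csv")
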