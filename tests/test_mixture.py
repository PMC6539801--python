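import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sirmsmix.chemistry import (
    ALL_SCHEMES,
    CHARGE,
    Atom,
    Molecule,
    assign_atom_properties,
    parse_molecule,
)
from sirmsmix.mixture import (
    MixtureInputError,
    MixtureSample,
    build_descriptor_matrix,
    cross_compound_descriptors,
    cross_compound_simplexes,
    read_mixtures_csv,
    volume_to_mole,
    weighted_mixture_descriptors,
    weighted_single_descriptors,
)
from sirmsmix.simplex import canonical_simplex_name, single_compound_descriptors


class TestVolumeToMole:
    def test_identical_components_stay_equimolar(self):
        x1, x2, swapped = volume_to_mole(0.5, 0.5, 0.8, 0.8, 50.0, 50.0)
        assert x1 == pytest.approx(0.5) and x2 == pytest.approx(0.5)
        assert not swapped

    def test_vanishing_component(self):
        x1, x2, _ = volume_to_mole(0.0, 1.0, 0.8, 0.9, 50.0, 60.0)
        assert (x1, x2) == (0.0, 1.0)

    def test_ethanol_benzene_equal_volumes(self):
        # moles per mL: ethanol 0.789/46.07, benzene 0.876/78.11
        x1, x2, swapped = volume_to_mole(0.5, 0.5, 0.789, 0.876, 46.07, 78.11)
        x_ethanol = x2 if swapped else x1
        assert x_ethanol == pytest.approx(0.604, abs=5e-4)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(MixtureInputError):
            volume_to_mole(0.5, 0.5, -1.0, 0.9, 50.0, 60.0)


class TestMixingRules:
    def test_pure_limit_returns_other_compound(self):
        d1, d2 = {"a": 2.0, "b": 1.0}, {"a": 4.0, "c": 7.0}
        assert weighted_single_descriptors(d1, d2, 0.0, 1.0) == {
            "a": 4.0, "b": 0.0, "c": 7.0
        }

    def test_weighted_arithmetic(self):
        out = weighted_single_descriptors({"a": 2}, {"a": 4}, 0.25, 0.75)
        assert out["a"] == pytest.approx(3.5)

    def test_zero_fill_for_one_sided_names(self):
        out = weighted_single_descriptors({"a": 8}, {}, 0.3, 0.7)
        assert out["a"] == pytest.approx(2.4)

    def test_negative_fraction_rejected(self):
        with pytest.raises(MixtureInputError):
            weighted_single_descriptors({}, {}, -0.1, 1.1)

    def test_equimolar_keeps_cross_counts(self):
        assert weighted_mixture_descriptors({"m": 6}, 0.5)["m"] == pytest.approx(6.0)

    def test_vanishing_minor_component_zeroes_block(self):
        assert weighted_mixture_descriptors({"m": 9}, 0.0)["m"] == 0.0

    def test_doubled_minor_fraction(self):
        assert weighted_mixture_descriptors({"m": 5}, 0.2)["m"] == pytest.approx(2.0)

    def test_major_fraction_rejected(self):
        with pytest.raises(MixtureInputError):
            weighted_mixture_descriptors({"m": 5}, 0.7)

    @given(st.floats(0.0, 0.5))
    def test_convexity_and_bounds_of_mixing_rules(self, x1):
        d1, d2, d12 = {"n": 2.0}, {"n": 10.0}, {"n": 6.0}
        ds = weighted_single_descriptors(d1, d2, x1, 1.0 - x1)["n"]
        assert min(d1["n"], d2["n"]) - 1e-12 <= ds <= max(d1["n"], d2["n"]) + 1e-12
        dm = weighted_mixture_descriptors(d12, x1)["n"]
        assert -1e-12 <= dm <= d12["n"] + 1e-12


class TestCrossCompoundSimplexes:
    def test_ethane_propane_count(self):
        e = parse_molecule("CC", "ethane", add_hydrogens=False)
        p = parse_molecule("CCC", "propane", add_hydrogens=False)
        frags = cross_compound_simplexes(e, p)
        assert len(frags) == 5  # 2*C(3,3) + C(2,2)*C(3,2)
        assert all(f.scope == "M" for f in frags)

    def test_empty_molecule_gives_nothing(self):
        e = parse_molecule("CC", "ethane", add_hydrogens=False)
        empty = Molecule("void", [], [], explicit_hydrogens=False)
        assert cross_compound_simplexes(e, empty) == []

    def test_bonded_pairs_from_two_compounds_name(self):
        def two_atom(cid, charges):
            return Molecule(
                cid,
                [Atom("C", charge=c, lipophilicity=0.0, refractivity=2.0, hbond="I")
                 for c in charges],
                [(0, 1, 1.0)],
                explicit_hydrogens=False,
            )

        mol1 = two_atom("m1", (-0.1, -0.1))  # labels A, A
        mol2 = two_atom("m2", (-0.02, 0.02))  # labels B, C
        frags = cross_compound_simplexes(mol1, mol2)
        names = {canonical_simplex_name(f, CHARGE) for f in frags if f.size == 4}
        assert "|M|n|||4|||CHARGE|A-A.B-C" in names

    def test_factored_counts_match_literal_enumeration(self):
        """The fast per-part counting route must agree with materialising
        every cross fragment."""
        m1 = assign_atom_properties(parse_molecule("CCO", "ethanol"))
        m2 = assign_atom_properties(parse_molecule("CC(C)=O", "acetone",
                                                   add_hydrogens=False))
        fast = cross_compound_descriptors(m1, m2, ALL_SCHEMES)
        literal: dict[str, int] = {}
        for frag in cross_compound_simplexes(m1, m2):
            for scheme in ALL_SCHEMES:
                nm = canonical_simplex_name(frag, scheme)
                literal[nm] = literal.get(nm, 0) + 1
        assert fast == literal


@pytest.fixture(scope="module")
def two_mols():
    m1 = assign_atom_properties(parse_molecule("CCO", "ethanol"))
    m2 = assign_atom_properties(parse_molecule("CC(C)=O", "acetone"))
    return m1, m2


class TestDescriptorMatrix:
    def test_self_mixture_reproduces_own_descriptors(self, two_mols):
        m1, _ = two_mols
        sample = MixtureSample("s1", m1, m1, 0.5, 0.5)
        matrix = build_descriptor_matrix([sample], prune_constant=False)
        own = single_compound_descriptors(m1, ALL_SCHEMES)
        row = matrix.frame.iloc[0]
        for name, count in own.items():
            assert row[name] == pytest.approx(count)

    def test_identical_samples_give_identical_rows(self, two_mols):
        m1, m2 = two_mols
        samples = [
            MixtureSample("a", m1, m2, 0.3, 0.7),
            MixtureSample("b", m1, m2, 0.3, 0.7),
            MixtureSample("c", m1, m2, 0.45, 0.55),
        ]
        matrix = build_descriptor_matrix(samples)
        assert np.allclose(matrix.frame.loc["a"], matrix.frame.loc["b"])

    def test_swapping_compound_labels_leaves_row_unchanged(self, two_mols):
        m1, m2 = two_mols
        samples = [
            MixtureSample("fwd", m1, m2, 0.3, 0.7),
            MixtureSample("rev", m2, m1, 0.7, 0.3),
            MixtureSample("other", m1, m2, 0.5, 0.5),
        ]
        matrix = build_descriptor_matrix(samples)
        assert np.allclose(matrix.frame.loc["fwd"], matrix.frame.loc["rev"])

    def test_no_constant_columns_after_pruning(self, tiny_dataset):
        frame = tiny_dataset.matrix.frame
        assert (frame.nunique() > 1).all()

    def test_s_block_precedes_m_block(self, tiny_dataset):
        cols = list(tiny_dataset.matrix.frame.columns)
        first_m = next(i for i, c in enumerate(cols) if c.startswith("|M|"))
        assert all(c.startswith("|M|") for c in cols[first_m:])

    def test_duplicate_sample_ids_rejected(self, two_mols):
        m1, m2 = two_mols
        samples = [
            MixtureSample("dup", m1, m2, 0.3, 0.7),
            MixtureSample("dup", m1, m2, 0.4, 0.6),
        ]
        with pytest.raises(MixtureInputError, match="dup"):
            build_descriptor_matrix(samples)

    def test_fraction_invariants_enforced(self, two_mols):
        m1, m2 = two_mols
        with pytest.raises(MixtureInputError):
            MixtureSample("bad", m1, m2, 0.3, 0.8)
        s = MixtureSample("swap", m1, m2, 0.7, 0.3)  # reordered on construction
        assert s.x1 <= s.x2 and s.swapped


class TestMixturesCsv:
    def test_roundtrip_with_volume_rows(self, tmp_path):
        df = pd.DataFrame(
            {
                "sample_id": ["v1", "m1"],
                "smiles_1": ["CCO", "CCO"],
                "smiles_2": ["c1ccccc1", "CC(C)=O"],
                "frac_type": ["volume", "mole"],
                "frac_1": [0.5, 0.25],
                "frac_2": [0.5, 0.75],
                "density_1": [0.789, ""],
                "density_2": [0.876, ""],
                "mw_1": [46.07, ""],
                "mw_2": [78.11, ""],
                "ait_K": [600.0, None],
            }
        )
        path = tmp_path / "mix.csv"
        df.to_csv(path, index=False)
        samples = read_mixtures_csv(path)
        assert len(samples) == 2
        v1 = samples[0]
        assert v1.x1 + v1.x2 == pytest.approx(1.0)
        assert max(v1.x1, v1.x2) == pytest.approx(0.604, abs=5e-4)
        assert samples[1].ait_K is None  # prediction-only row

    def test_bad_frac_type_reports_line_number(self, tmp_path):
        path = tmp_path / "mix.csv"
        path.write_text(
            "sample_id,smiles_1,smiles_2,frac_type,frac_1,frac_2,"
            "density_1,density_2,mw_1,mw_2,ait_K\n"
            "x1,CCO,CCC,mass,0.5,0.5,,,,,600\n"
        )
        with pytest.raises(MixtureInputError, match="line 2"):
            read_mixtures_csv(path)
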