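"""Measure-level tests: published genotype-count MI vectors, analytic XOR
and parity oracles, independence zeros, and two-route equalities."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from symdelta.datamodel import Dataset
from symdelta.measures import (
    asymmetric_deltas3,
    compute_measure,
    interaction_information3,
    interaction_information4,
    mi_from_counts,
    mutual_information,
    symmetric_delta3,
    symmetric_delta4,
)
from symdelta.entropy import joint_entropy

from conftest import random_dataset

# Published MI test vectors: phenotype x genotype contingency counts for a
# binary case/control phenotype and a 3-level genotype, with the MI value
# each table yields in bits.
GENOTYPE_MI_VECTORS = [
    ((863, 1121, 350), (1693, 590, 46), 0.109292, 6),
    ((2776, 0, 0), (2755, 21, 0), 0.00379278, 8),
    ((2088, 593, 91), (2013, 711, 45), 0.00363657, None),
    ((128, 852, 1795), (123, 1015, 1636), 0.00282347, None),
]


def expand_counts(case_counts, ctrl_counts) -> Dataset:
    """Materialize a contingency table as per-sample phenotype/genotype
    code vectors (the search engine's native input form)."""
    pheno, geno = [], []
    for p, row in ((1, case_counts), (0, ctrl_counts)):
        for g, c in enumerate(row):
            pheno.extend([p] * c)
            geno.extend([g] * c)
    return Dataset.from_matrix(
        np.column_stack([pheno, geno]), ["AD", "SNP"],
        n_bins=[2, len(case_counts)],
    )


class TestMutualInformation:
    @pytest.mark.parametrize("case, ctrl, expected, digits",
                             GENOTYPE_MI_VECTORS)
    def test_published_contingency_tables(self, case, ctrl, expected, digits):
        """MI recomputed from printed genotype counts matches the printed
        value at printed precision (<= 1e-6 absolute)."""
        assert mi_from_counts([case, ctrl]) == pytest.approx(expected,
                                                             abs=1e-6)

    @pytest.mark.parametrize("case, ctrl, expected, digits",
                             GENOTYPE_MI_VECTORS[:2])
    def test_counts_route_equals_dataset_route(self, case, ctrl, expected,
                                               digits):
        ds = expand_counts(case, ctrl)
        mr = mutual_information(ds, 0, 1)
        assert mr.value == pytest.approx(mi_from_counts([case, ctrl]),
                                         abs=1e-12)
        assert mr.n_effective == sum(case) + sum(ctrl)

    def test_value_recomputable_from_components(self):
        ds = expand_counts(*GENOTYPE_MI_VECTORS[0][:2])
        mr = mutual_information(ds, 0, 1)
        c = mr.components
        assert mr.value == pytest.approx(c["h_x"] + c["h_y"] - c["h_xy"],
                                         abs=0)

    def test_independent_pair_has_zero_mi(self):
        ds = Dataset.from_matrix(
            np.array([[0, 0], [0, 1], [1, 0], [1, 1]]), ["X", "Y"])
        assert mutual_information(ds, 0, 1).value == pytest.approx(0,
                                                                   abs=1e-12)

    def test_mi_with_copy_equals_entropy(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, 100)
        ds = Dataset.from_matrix(np.column_stack([x, x]), ["X", "X2"])
        assert mutual_information(ds, 0, 1).value == pytest.approx(
            joint_entropy(ds, (0,)), abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_nonnegative_and_symmetric(self, seed):
        ds = random_dataset(seed, n_variables=2, n_samples=150, n_bins=3,
                            missing_rate=0.1)
        a = mutual_information(ds, 0, 1).value
        b = mutual_information(ds, 1, 0).value
        assert a == pytest.approx(b, abs=1e-12)
        assert a >= -1e-12


class TestInteractionInformation3:
    def test_xor_triple_is_minus_one_bit(self, xor_dataset):
        assert interaction_information3(xor_dataset, 0, 1, 2) == \
            pytest.approx(-1.0, abs=1e-12)

    def test_independent_triple_is_zero(self, independent_triple):
        assert interaction_information3(independent_triple, 0, 1, 2) == \
            pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_entropy_expansion_equals_conditional_route(self, seed):
        """I3 from the entropy expansion equals I(X,Y) - I(X,Y|Z) computed
        from per-stratum conditional tables."""
        ds = random_dataset(seed, n_variables=3, n_samples=200, n_bins=3)
        i3 = interaction_information3(ds, 0, 1, 2)
        # independent conditional-MI oracle
        x = ds.variables[0].codes
        y = ds.variables[1].codes
        z = ds.variables[2].codes
        mi_xy = mutual_information(ds, 0, 1).value
        cmi = 0.0
        for zv in np.unique(z):
            sel = z == zv
            sub = Dataset.from_matrix(
                np.column_stack([x[sel], y[sel]]), ["X", "Y"],
                n_bins=[3, 3])
            cmi += sel.mean() * mutual_information(sub, 0, 1).value
        assert i3 == pytest.approx(mi_xy - cmi, abs=1e-10)


class TestDeltas3:
    def test_xor_deltas_all_minus_one(self, xor_dataset):
        assert asymmetric_deltas3(xor_dataset, 0, 1, 2) == \
            pytest.approx((-1.0, -1.0, -1.0), abs=1e-12)

    def test_xor_symmetric_delta(self, xor_dataset):
        assert symmetric_delta3(xor_dataset, 0, 1, 2).value == \
            pytest.approx(-1.0, abs=1e-12)

    def test_independent_triple_deltas_vanish(self, independent_triple):
        assert asymmetric_deltas3(independent_triple, 0, 1, 2) == \
            pytest.approx((0.0, 0.0, 0.0), abs=1e-12)
        assert symmetric_delta3(independent_triple, 0, 1, 2).value == \
            pytest.approx(0.0, abs=1e-12)

    def test_variable_independent_of_dependent_pair(self):
        """Z independent of a dependent (X, Y): I3 = 0, dZ = -I(X,Y),
        dX = dY = 0, so the symmetric delta vanishes."""
        # 16 samples: (X, Y = X) crossed with independent uniform Z
        base = np.array([[0, 0], [1, 1]])
        rows = np.array([[x, y, z] for x, y in base for z in (0, 1)
                         for _ in range(4)])
        ds = Dataset.from_matrix(rows, ["X", "Y", "Z"])
        mi_xy = mutual_information(ds, 0, 1).value
        dx, dy, dz = asymmetric_deltas3(ds, 0, 1, 2)
        assert (dx, dy) == pytest.approx((0, 0), abs=1e-12)
        assert dz == pytest.approx(-mi_xy, abs=1e-12)
        assert symmetric_delta3(ds, 0, 1, 2).value == pytest.approx(
            0.0, abs=1e-12)

    def test_permutation_symmetry(self):
        ds = random_dataset(77, n_variables=3, n_samples=120, n_bins=3,
                            missing_rate=0.1)
        ref = symmetric_delta3(ds, 0, 1, 2).value
        for p in permutations((0, 1, 2)):
            assert symmetric_delta3(ds, *p).value == pytest.approx(
                ref, abs=1e-12)

    def test_d3_components_carry_pairwise_mis(self):
        ds = random_dataset(9, n_variables=3, n_samples=100)
        mr = symmetric_delta3(ds, 0, 1, 2)
        for a, b in ((0, 1), (0, 2), (1, 2)):
            assert mr.components[f"mi_{a}_{b}"] == pytest.approx(
                mutual_information(ds, a, b).value, abs=1e-12)
        # value recomputable from components
        assert mr.value == pytest.approx(
            mr.components["d_x"] * mr.components["d_y"] *
            mr.components["d_z"], abs=0)


class TestDelta4:
    def test_four_way_parity(self):
        rows = np.array([[a, b, c, a ^ b ^ c]
                         for a in (0, 1) for b in (0, 1) for c in (0, 1)])
        ds = Dataset.from_matrix(rows, list("WXYZ"))
        assert interaction_information4(ds, 0, 1, 2, 3) == pytest.approx(
            1.0, abs=1e-12)
        mr = symmetric_delta4(ds, 0, 1, 2, 3)
        assert mr.value == pytest.approx(1.0, abs=1e-12)
        for t in range(4):
            assert mr.components[f"d_{t}"] == pytest.approx(1.0, abs=1e-12)

    def test_tuple_with_independent_variable_vanishes(self):
        rows = np.array([[a, b, a ^ b, c]
                         for a in (0, 1) for b in (0, 1) for c in (0, 1)])
        ds = Dataset.from_matrix(rows, list("XYZW"))
        assert symmetric_delta4(ds, 0, 1, 2, 3).value == pytest.approx(
            0.0, abs=1e-12)

    def test_permutation_symmetry(self):
        ds = random_dataset(13, n_variables=4, n_samples=100, n_bins=2)
        ref = symmetric_delta4(ds, 0, 1, 2, 3).value
        for p in permutations(range(4)):
            assert symmetric_delta4(ds, *p).value == pytest.approx(
                ref, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_expansion_equals_recursive_definition(self, seed):
        """I4 via inclusion-exclusion equals I3 - I3|W from per-stratum
        conditional triples."""
        ds = random_dataset(seed, n_variables=4, n_samples=150, n_bins=2)
        i4 = interaction_information4(ds, 0, 1, 2, 3)
        w = ds.variables[3].codes
        i3 = interaction_information3(ds, 0, 1, 2)
        cond = 0.0
        for wv in np.unique(w):
            sel = w == wv
            sub = Dataset.from_matrix(
                np.column_stack([ds.variables[j].codes[sel]
                                 for j in range(3)]),
                ["X", "Y", "Z"], n_bins=[2, 2, 2])
            cond += sel.mean() * interaction_information3(sub, 0, 1, 2)
        assert i4 == pytest.approx(i3 - cond, abs=1e-10)


class TestDispatch:
    def test_unknown_measure_rejected(self):
        ds = random_dataset(1, n_variables=2)
        with pytest.raises(ValueError, match="unknown measure"):
            compute_measure(ds, "tc", (0, 1))

    def test_order_mismatch_rejected(self):
        ds = random_dataset(1, n_variables=3)
        with pytest.raises(ValueError, match="needs 3"):
            compute_measure(ds, "d3", (0, 1))
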