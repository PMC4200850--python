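"""Markov-Shannon entropy descriptor tests.

The independent oracle used throughout is brute-force enumeration of all
weighted k-step walks, which must agree with the matrix-power computation.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from almaentropy.descriptors import (
    MarkovShannonEncoder,
    MolecularGraph,
    build_graph,
    descriptor_block,
    entropy_theta,
    markov_profile,
    step_distributions,
    transition_matrix,
)
from almaentropy.electronegativity import PAULING
from almaentropy.errors import ConfigurationError, DataError, ParseError

# small molecules (all <= 6 heavy atoms) used for oracle cross-checks
SMALL_FIXTURES = ["C", "CO", "CCN", "C#CCN", "CC(C)=O", "c1ccccc1", "C1CCOC1"]


def walk_enumeration_distribution(graph: MolecularGraph, k: int) -> np.ndarray:
    """Oracle: k-step distribution by summing over every explicit walk."""
    pi = transition_matrix(graph)
    n = graph.n_atoms
    p0 = graph.chi / graph.chi.sum()
    out = np.zeros(n)
    for walk in itertools.product(range(n), repeat=k + 1):
        weight = p0[walk[0]]
        for a, b in zip(walk, walk[1:]):
            weight *= pi[a, b]
        out[walk[-1]] += weight
    return out


class TestBuildGraph:
    def test_methane_is_single_heavy_atom(self):
        g = build_graph("C", "methane")
        assert g.n_atoms == 1 and g.elements == ("C",)
        assert g.chi[0] == pytest.approx(PAULING["C"])
        assert not g.bonds

    def test_benzene_ring_topology(self):
        g = build_graph("c1ccccc1", "benzene")
        assert g.n_atoms == 6 and len(g.bonds) == 6
        assert all(len(g.neighbours(i)) == 2 for i in range(6))

    def test_propargylamine_fragment_is_a_path(self):
        # C#CCN: four heavy atoms in a chain, three bonds
        g = build_graph("C#CCN", "frag")
        assert g.n_atoms == 4
        assert g.bonds == frozenset({(0, 1), (1, 2), (2, 3)})
        assert g.elements == ("C", "C", "C", "N")

    def test_unparsable_smiles_names_the_string(self):
        with pytest.raises(ParseError, match="not-a-smiles"):
            build_graph("not-a-smiles", "bad")

    def test_salt_keeps_largest_component_by_default(self):
        g = build_graph("CCO.[Na+]", "salt")
        assert g.n_atoms == 3
        g_all = build_graph("CCO.[Na+]", "salt", keep_all_components=True)
        assert g_all.n_atoms == 4

    def test_unknown_element_raises_configuration_error(self):
        with pytest.raises(ConfigurationError, match="electronegativity"):
            build_graph("[U]", "uranium")


class TestTransitionMatrix:
    def test_single_atom_is_identity(self):
        pi = transition_matrix(build_graph("C", "x"))
        assert pi.shape == (1, 1) and pi[0, 0] == 1.0

    def test_benzene_rows_are_uniform_thirds(self):
        pi = transition_matrix(build_graph("c1ccccc1", "x"))
        nz = pi[pi > 0]
        assert np.allclose(nz, 1 / 3)

    def test_two_atom_heteronuclear_rows(self):
        g = build_graph("CN", "cn")
        pi = transition_matrix(g)
        chi_c, chi_n = PAULING["C"], PAULING["N"]
        total = chi_c + chi_n
        expected = np.array([[chi_c, chi_n], [chi_c, chi_n]]) / total
        assert np.allclose(pi, expected)

    @pytest.mark.parametrize("smiles", SMALL_FIXTURES)
    def test_rows_sum_to_one(self, smiles):
        pi = transition_matrix(build_graph(smiles, "x"))
        assert np.allclose(pi.sum(axis=1), 1.0, atol=1e-12)

    def test_isolated_atom_without_self_loops_is_an_error(self):
        with pytest.raises(DataError, match="self_loops"):
            transition_matrix(build_graph("C", "x"), self_loops=False)


class TestEntropy:
    def test_single_atom_entropy_is_zero_for_all_orders(self):
        g = build_graph("C", "x")
        assert all(entropy_theta(g, k) == 0.0 for k in range(6))

    @pytest.mark.parametrize("smiles,n", [("c1ccccc1", 6), ("C1CCCCC1", 6)])
    def test_vertex_transitive_uniform_chi_saturates_log2_n(self, smiles, n):
        g = build_graph(smiles, "x")
        for k in range(6):
            assert entropy_theta(g, k) == pytest.approx(np.log2(n), abs=1e-10)

    @pytest.mark.parametrize("smiles", SMALL_FIXTURES)
    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_matrix_power_equals_walk_enumeration(self, smiles, k):
        g = build_graph(smiles, "x")
        oracle = walk_enumeration_distribution(g, k)
        computed = step_distributions(g, k)[k]
        assert np.allclose(computed, oracle, atol=1e-10)

    def test_three_atom_path_order2_against_enumeration(self):
        # distinct chi values: C-N-O path from SMILES "CNO"
        g = build_graph("CNO", "x")
        oracle = walk_enumeration_distribution(g, 2)
        oracle = oracle[oracle > 0]
        expected = float(-(oracle * np.log2(oracle)).sum())
        assert entropy_theta(g, 2) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("smiles", SMALL_FIXTURES)
    def test_upper_bound_log2_n(self, smiles):
        g = build_graph(smiles, "x")
        for k in range(6):
            assert 0.0 <= entropy_theta(g, k) <= np.log2(g.n_atoms) + 1e-12

    @pytest.mark.parametrize("smiles", ["CCN", "C#CCN", "c1ccccc1"])
    def test_permutation_invariance(self, smiles):
        g = build_graph(smiles, "x")
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_atoms)
        inv = np.argsort(perm)
        permuted = MolecularGraph(
            identifier="perm",
            elements=tuple(g.elements[i] for i in perm),
            chi=g.chi[list(perm)],
            bonds=frozenset(
                (min(inv[a], inv[b]), max(inv[a], inv[b])) for a, b in g.bonds
            ),
        )
        for k in range(6):
            assert entropy_theta(permuted, k) == pytest.approx(
                entropy_theta(g, k), abs=1e-10
            )

    @pytest.mark.parametrize("smiles", ["CCO", "C#CCN", "CNO"])
    def test_connected_graph_positive_entropy_beyond_diameter(self, smiles):
        g = build_graph(smiles, "x")
        assert entropy_theta(g, g.n_atoms) > 0.0

    def test_negative_order_rejected(self):
        with pytest.raises(DataError):
            entropy_theta(build_graph("CC", "x"), -1)

    def test_profile_invariants(self):
        prof = markov_profile(build_graph("CC(C)=O", "x"), k_max=5)
        assert np.allclose(prof.transition.sum(axis=1), 1.0, atol=1e-12)
        for p in prof.step_distributions:
            assert np.all(p >= 0) and p.sum() == pytest.approx(1.0, abs=1e-12)


class TestDescriptorBlock:
    def test_single_atom_row_is_all_zero(self):
        block = descriptor_block([("a", "C")], k_max=5)
        assert len(block) == 1
        assert (block.loc[0, [f"theta{k}" for k in range(6)]] == 0).all()

    def test_duplicate_structures_get_identical_rows(self):
        block = descriptor_block([("a", "CCO"), ("b", "CCO")])
        cols = [f"theta{k}" for k in range(6)]
        assert np.allclose(block.loc[0, cols].astype(float),
                           block.loc[1, cols].astype(float))

    def test_batch_matches_single_molecule_calls(self):
        mols = [(f"m{i}", s) for i, s in enumerate(SMALL_FIXTURES)]
        block = descriptor_block(mols)
        for row, (_, smiles) in zip(block.itertuples(index=False), mols):
            g = build_graph(smiles, "x")
            for k in range(6):
                assert getattr(row, f"theta{k}") == pytest.approx(
                    entropy_theta(g, k), abs=1e-12
                )

    def test_bad_row_reported_without_aborting(self):
        block = descriptor_block([("ok", "CC"), ("bad", "xyz["), ("ok2", "CO")])
        assert block["error"].tolist()[0] == "" and block["error"].tolist()[2] == ""
        assert "xyz[" in block.loc[1, "error"]
        assert np.isnan(block.loc[1, "theta5"])


class TestEncoder:
    def test_transform_matrix_shape_and_values(self):
        enc = MarkovShannonEncoder(k_max=3)
        out = enc.fit_transform(["C", "c1ccccc1"])
        assert out.shape == (2, 4)
        assert np.allclose(out[0], 0.0)
        assert np.allclose(out[1], np.log2(6))

    def test_sklearn_params_round_trip(self):
        enc = MarkovShannonEncoder(k_max=4, self_loops=False)
        params = enc.get_params()
        assert params["k_max"] == 4 and params["self_loops"] is False
        enc2 = MarkovShannonEncoder().set_params(**params)
        assert enc2.k_max == 4

    def test_feature_names(self):
        enc = MarkovShannonEncoder(k_max=2).fit(["C"])
        assert list(enc.get_feature_names_out()) == ["theta0", "theta1", "theta2"]
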