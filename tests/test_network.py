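"""Node selection, interaction ranges, contacts and the ANM Hessian."""

import numpy as np
import pytest
import scipy.linalg

from anmkit import (ConfigError, DegenerateNetworkError, NodeScheme,
                    assign_ranges, build_contacts, build_hessian, parse_pdb,
                    select_nodes)
from anmkit import fixtures
from anmkit.network import read_range_table

from conftest import (brute_force_contacts, finite_difference_hessian,
                      make_atom, pdb_from_atoms, protein_nucleotide_pdb)


def nodes_from(pdb, scheme=None):
    return select_nodes(parse_pdb(pdb), scheme)


class TestSelectNodes:
    def test_three_nodes_per_complete_nucleotide(self):
        nodes = nodes_from(protein_nucleotide_pdb(n_res=3, n_nt=2))
        assert len(nodes) == 3 + 2 * 3
        assert [n.type_key for n in nodes][:3] == ["PRO:CA"] * 3
        assert sorted(n.type_key for n in nodes if n.type_key.startswith("NUC")) == \
            sorted(["NUC:P", "NUC:C4'", "NUC:C2"] * 2)

    def test_water_never_contributes_nodes(self):
        nodes = nodes_from(protein_nucleotide_pdb(with_water=True))
        assert all(n.atom_ref.residue_name != "HOH" for n in nodes)

    def test_include_ligands_false_drops_hetatm(self):
        pdb = protein_nucleotide_pdb() + ""
        text = pdb.replace("END\n", "") + \
            "HETATM   99  C1  LIG A  50       1.000   3.000   1.000  1.00 20.00           C\nEND\n"
        with_lig = nodes_from(text)
        without = nodes_from(text, NodeScheme(include_ligands=False))
        assert len(with_lig) == len(without) + 1

    def test_single_atom_nucleotide_scheme(self):
        scheme = NodeScheme(nucleotide_atoms=("P",))
        nodes = nodes_from(protein_nucleotide_pdb(n_res=3, n_nt=2), scheme)
        assert sum(1 for n in nodes if n.type_key.startswith("NUC")) == 2

    def test_missing_phosphate_contributes_fewer_nodes(self):
        pdb = fixtures.make_mixed_complex(3, 2, 4, seed=7)
        nodes = nodes_from(pdb)
        assert len(nodes) == 3 + (2 + 3) + 4  # first nucleotide lacks P

    def test_node_order_follows_file_order(self):
        nodes = nodes_from(protein_nucleotide_pdb(n_res=3, n_nt=1))
        serials = [n.atom_ref.serial for n in nodes]
        assert serials == sorted(serials)
        assert [n.index for n in nodes] == list(range(len(nodes)))

    def test_degenerate_single_node_raises(self):
        with pytest.raises(DegenerateNetworkError):
            nodes_from(pdb_from_atoms([make_atom(1, "CA", "ALA", "A", 1, (0, 0, 0))]))


class TestAssignRanges:
    def test_uniform_default_is_half_cutoff(self):
        nodes = nodes_from(protein_nucleotide_pdb(), NodeScheme(cutoff=15.0))
        assert np.allclose(nodes.ranges(), 7.5)

    def test_type_key_lookup(self):
        scheme = NodeScheme(range_table={"NUC:P": 9.0}, cutoff=15.0)
        nodes = nodes_from(protein_nucleotide_pdb(n_nt=2), scheme)
        for n in nodes:
            assert n.t == (9.0 if n.type_key == "NUC:P" else 7.5)

    def test_bare_atom_name_fallback(self):
        scheme = NodeScheme(range_table={"CA": 6.0}, cutoff=15.0)
        nodes = nodes_from(protein_nucleotide_pdb(), scheme)
        for n in nodes:
            assert n.t == (6.0 if n.type_key.endswith(":CA") else 7.5)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ConfigError):
            NodeScheme(range_table={"CA": -1.0})

    def test_range_table_parser(self):
        table = read_range_table("# comment\nNUC:P 9.0\nCA 6.5  # inline\n\n")
        assert table == {"NUC:P": 9.0, "CA": 6.5}
        with pytest.raises(ConfigError):
            read_range_table("CA notanumber\n")


class TestBuildContacts:
    def _nodes_at(self, positions, t=7.5):
        atoms = [make_atom(i + 1, "CA", "ALA", "A", i + 1, p)
                 for i, p in enumerate(positions)]
        return nodes_from(pdb_from_atoms(atoms), NodeScheme(cutoff=2 * t))

    def test_pair_inside_cutoff(self):
        assert len(build_contacts(self._nodes_at([(0, 0, 0), (10, 0, 0)]))) == 1

    def test_pair_outside_cutoff(self):
        assert len(build_contacts(self._nodes_at([(0, 0, 0), (16, 0, 0)]))) == 0

    def test_boundary_is_inclusive(self):
        assert len(build_contacts(self._nodes_at([(0, 0, 0), (15, 0, 0)]))) == 1

    def test_collinear_three_nodes(self):
        contacts = build_contacts(self._nodes_at([(0, 0, 0), (8, 0, 0), (16, 0, 0)]))
        assert sorted((i, j) for i, j, _, _ in contacts) == [(0, 1), (1, 2)]

    def test_coincident_nodes_named_in_error(self):
        with pytest.raises(DegenerateNetworkError, match="ALA A1 CA"):
            build_contacts(self._nodes_at([(0, 0, 0), (0, 0, 0)]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_uniform_reduction_matches_brute_force(self, seed):
        nodes = nodes_from(fixtures.make_random_cloud(40, seed=seed))
        got = sorted((i, j) for i, j, _, _ in build_contacts(nodes))
        want = brute_force_contacts(nodes.positions(), nodes.ranges())
        assert got == want
        # uniform ranges: identical to a direct single-cutoff rule
        pos = nodes.positions()
        direct = [(i, j) for i in range(len(nodes)) for j in range(i + 1, len(nodes))
                  if np.linalg.norm(pos[j] - pos[i]) <= 15.0]
        assert got == direct

    def test_heterogeneous_ranges_match_brute_force(self):
        scheme = NodeScheme(range_table={"NUC:P": 9.0, "CA": 5.0}, cutoff=12.0)
        nodes = nodes_from(protein_nucleotide_pdb(n_res=5, n_nt=3), scheme)
        got = sorted((i, j) for i, j, _, _ in build_contacts(nodes))
        assert got == brute_force_contacts(nodes.positions(), nodes.ranges())


class TestBuildHessian:
    def test_two_node_analytic_blocks_and_spectrum(self):
        nodes = nodes_from(fixtures.make_ca_chain(2, jitter=0.0, seed=0))
        h = build_hessian(nodes, build_contacts(nodes)).toarray()
        np.testing.assert_allclose(h[0:3, 3:6], -np.diag([1.0, 0, 0]), atol=1e-12)
        np.testing.assert_allclose(h, h.T, atol=1e-12)
        vals = np.sort(scipy.linalg.eigvalsh(h))
        np.testing.assert_allclose(vals, [0, 0, 0, 0, 0, 2], atol=1e-10)

    def test_super_row_sums_vanish(self):
        nodes = nodes_from(fixtures.make_random_cloud(20, seed=5))
        h = build_hessian(nodes, build_contacts(nodes)).toarray()
        n = len(nodes)
        blocks = h.reshape(n, 3, n, 3)
        np.testing.assert_allclose(blocks.sum(axis=2), 0.0, atol=1e-12)

    def test_matches_finite_difference_of_harmonic_energy(self):
        nodes = nodes_from(fixtures.make_random_cloud(10, seed=1))
        contacts = build_contacts(nodes)
        h = build_hessian(nodes, contacts).toarray()
        fd = finite_difference_hessian(nodes.positions(), list(contacts))
        assert np.max(np.abs(h - fd)) <= 1e-5

    def test_positive_semidefinite(self):
        nodes = nodes_from(fixtures.make_ca_chain(30, seed=2))
        h = build_hessian(nodes, build_contacts(nodes)).toarray()
        vals = scipy.linalg.eigvalsh(h)
        assert vals.min() >= -1e-8 * vals.max()

    def test_empty_contacts_raise(self):
        from anmkit.network import ContactList
        nodes = nodes_from(fixtures.make_ca_chain(5, seed=0))
        with pytest.raises(DegenerateNetworkError, match="disconnected"):
            build_hessian(nodes, ContactList(pairs=[]))

    def test_permutation_conjugates_hessian(self):
        rng = np.random.RandomState(7)
        pdb = fixtures.make_random_cloud(12, seed=3)
        st = parse_pdb(pdb)
        perm = rng.permutation(len(st.atoms))
        st_perm = parse_pdb(pdb)
        st_perm.atoms = [st_perm.atoms[k] for k in perm]
        h1 = build_hessian(*(lambda n: (n, build_contacts(n)))(select_nodes(st))).toarray()
        h2 = build_hessian(*(lambda n: (n, build_contacts(n)))(select_nodes(st_perm))).toarray()
        p = np.zeros_like(h1)
        for new, old in enumerate(perm):
            p[3 * new:3 * new + 3, 3 * old:3 * old + 3] = np.eye(3)
        np.testing.assert_allclose(h2, p @ h1 @ p.T, atol=1e-10)
        np.testing.assert_allclose(np.sort(scipy.linalg.eigvalsh(h1)),
                                   np.sort(scipy.linalg.eigvalsh(h2)), atol=1e-10)

    @pytest.mark.parametrize("n_components", [1, 2])
    def test_six_zero_modes_per_rigid_component(self, n_components):
        st = parse_pdb(fixtures.make_random_cloud(15, seed=4))
        atoms = list(st.atoms)
        if n_components == 2:
            far = parse_pdb(fixtures.make_random_cloud(15, seed=8)).atoms
            for k, a in enumerate(far):
                a.position = a.position + np.array([500.0, 0, 0])
                a.residue_number = 100 + k
            atoms += far
        st.atoms = atoms
        nodes = select_nodes(st)
        h = build_hessian(nodes, build_contacts(nodes)).toarray()
        vals = scipy.linalg.eigvalsh(h)
        assert np.sum(vals <= 1e-8 * vals.max()) == 6 * n_components

    def test_spectrum_invariant_under_generic_rotation(self):
        st = parse_pdb(fixtures.make_random_cloud(14, seed=6))
        nodes = select_nodes(st)
        h1 = build_hessian(nodes, build_contacts(nodes)).toarray()
        rot = fixtures.random_rotation(seed=13)
        for a in st.atoms:
            a.position = fixtures.rigid_transform(a.position[None], rot,
                                                  np.array([5., -3., 2.]))[0]
        nodes2 = select_nodes(st)
        h2 = build_hessian(nodes2, build_contacts(nodes2)).toarray()
        v1 = scipy.linalg.eigvalsh(h1)
        v2 = scipy.linalg.eigvalsh(h2)
        assert np.max(np.abs(v1 - v2)) <= 1e-8 * v1.max()
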