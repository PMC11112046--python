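import math

import gemmi
import numpy as np
import pandas as pd
import pytest

from _oracles import brute_centralities, random_graph, sphere_cap_buried_area
from ppamut.structure_features import (InterfaceRegion, StructureModel,
                                       StructureParseError, VDW_RADII,
                                       atom_sasa, build_contact_graph,
                                       classify_interface_region,
                                       compute_sasa,
                                       count_hbond_donors_acceptors,
                                       parse_structure, relative_sasa,
                                       residue_depth, site_centralities)
from ppamut.synthetic import make_toy_complex, make_toy_complex_files, write_pdb


def make_structure(atoms):
    """Build a StructureModel from (chain, resnum, aa, atom_name, element,
    xyz) tuples; radii from the standard vdW set."""
    res_rows, res_index = [], {}
    coords, radii, names, elements, res_of = [], [], [], [], []
    for chain, resnum, aa, name, element, xyz in atoms:
        key = (chain, resnum)
        if key not in res_index:
            res_index[key] = len(res_rows)
            res_rows.append((chain, resnum, aa))
        coords.append(xyz)
        radii.append(VDW_RADII[element])
        names.append(name)
        elements.append(element)
        res_of.append(res_index[key])
    return StructureModel(
        atom_coords=np.asarray(coords, float),
        atom_radii=np.asarray(radii, float),
        atom_names=np.asarray(names, object),
        atom_elements=np.asarray(elements, object),
        atom_residue=np.asarray(res_of, int),
        residues=pd.DataFrame(res_rows, columns=["chain", "number", "aa"]),
        chains=sorted({a[0] for a in atoms}),
    )


class TestParseStructure:
    def test_toy_pdb_roundtrip(self, tmp_path, toy_structure):
        assert toy_structure.chains == ["A", "B"]
        counts = toy_structure.residues.groupby("chain").size()
        assert counts["A"] == 36 and counts["B"] == 12

    def test_waters_only_is_content_error(self, tmp_path):
        pdb = tmp_path / "wat.pdb"
        pdb.write_text(
            "HETATM    1  O   HOH A   1       0.000   0.000   0.000"
            "  1.00  0.00           O\nEND\n")
        with pytest.raises(StructureParseError):
            parse_structure(pdb)

    def test_pdb_and_mmcif_give_identical_residue_tables(self, tmp_path):
        pdb_path, _ = make_toy_complex_files(tmp_path, seed=4)
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "toy1.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        a = parse_structure(pdb_path)
        b = parse_structure(cif_path)
        pd.testing.assert_frame_equal(a.residues, b.residues)


class TestSASA:
    @pytest.mark.parametrize("element", ["C", "O", "S"])
    def test_isolated_atom_matches_analytic_sphere(self, element):
        st = make_structure([("A", 1, "G", "CA", element, (0.0, 0.0, 0.0))])
        r = VDW_RADII[element]
        expected = 4 * math.pi * (r + 1.4) ** 2
        got = compute_sasa(st)[("A", 1)]
        assert got == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_fully_exposed(self):
        st = make_structure([
            ("A", 1, "G", "CA", "C", (0.0, 0.0, 0.0)),
            ("A", 2, "G", "CA", "C", (100.0, 0.0, 0.0)),
        ])
        full = 4 * math.pi * (VDW_RADII["C"] + 1.4) ** 2
        sasa = compute_sasa(st)
        assert sasa[("A", 1)] == pytest.approx(full, rel=0.01)
        assert sasa[("A", 2)] == pytest.approx(full, rel=0.01)

    def test_caged_atom_is_fully_buried(self):
        # 32 occluders at 3.0 A in quasi-uniform directions cover every
        # surface dot of the central atom (61-degree cap per occluder)
        golden = math.pi * (1 + math.sqrt(5))
        cage = []
        for i in range(32):
            phi = math.acos(1 - 2 * (i + 0.5) / 32)
            theta = golden * (i + 0.5)
            cage.append((3.0 * math.cos(theta) * math.sin(phi),
                         3.0 * math.sin(theta) * math.sin(phi),
                         3.0 * math.cos(phi)))
        atoms = [("A", 1, "G", "CA", "C", (0.0, 0.0, 0.0))]
        atoms += [("A", 2, "G", f"C{i}", "C", xyz) for i, xyz in enumerate(cage)]
        st = make_structure(atoms)
        assert compute_sasa(st)[("A", 1)] == pytest.approx(0.0, abs=1e-9)

    def test_two_atom_overlap_matches_spherical_cap(self):
        # independent closed-form oracle: buried area of the expanded
        # sphere equals the analytic cap inside the neighbour's sphere
        d = 3.0
        st = make_structure([
            ("A", 1, "G", "CA", "C", (0.0, 0.0, 0.0)),
            ("A", 2, "G", "CA", "C", (d, 0.0, 0.0)),
        ])
        r_exp = VDW_RADII["C"] + 1.4
        full = 4 * math.pi * r_exp ** 2
        expected = full - sphere_cap_buried_area(r_exp, r_exp, d)
        per_atom = atom_sasa(st)
        assert per_atom[0] == pytest.approx(expected, rel=0.01)


class TestRelativeSASAAndRegions:
    def test_reference_normalisation(self):
        assert relative_sasa(129.0, "A") == pytest.approx(1.0)
        assert relative_sasa(0.0, "W") == 0.0
        assert relative_sasa(50.0, "G") < relative_sasa(60.0, "G")

    def test_unknown_residue(self):
        with pytest.raises(KeyError):
            relative_sasa(10.0, "X")

    @pytest.mark.parametrize("mono,comp,expected", [
        (0.60, 0.60, InterfaceRegion.SURFACE),
        (0.40, 0.10, InterfaceRegion.CORE),
        (0.40, 0.30, InterfaceRegion.RIM),
        (0.20, 0.10, InterfaceRegion.SUPPORT),
        (0.10, 0.10, InterfaceRegion.INTERIOR),
    ])
    def test_region_rules(self, mono, comp, expected):
        assert classify_interface_region(mono, comp) is expected

    def test_grid_totality_and_partition(self):
        grid = np.linspace(0.0, 1.2, 25)
        seen = set()
        for mono in grid:
            for comp in grid:
                if comp > mono + 1e-9:
                    continue  # complexation cannot increase accessibility
                seen.add(classify_interface_region(mono, comp))
        assert seen == set(InterfaceRegion)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            classify_interface_region(-0.1, 0.0)


class TestHydrogenBonds:
    def test_isolated_residue_has_no_bonds(self):
        st = make_structure([
            ("A", 1, "A", "N", "N", (0.0, 0.0, 0.0)),
            ("A", 1, "A", "O", "O", (2.0, 0.0, 0.0)),
        ])
        assert count_hbond_donors_acceptors(st, ("A", 1)) == (0, 0)

    def test_backbone_n_to_carbonyl_o_pair(self):
        st = make_structure([
            ("A", 1, "A", "N", "N", (0.0, 0.0, 0.0)),
            ("B", 1, "A", "O", "O", (2.9, 0.0, 0.0)),
        ])
        donors, acceptors = count_hbond_donors_acceptors(st, ("A", 1))
        assert donors >= 1
        d2, a2 = count_hbond_donors_acceptors(st, ("B", 1))
        assert a2 >= 1

    def test_proline_backbone_does_not_donate(self):
        st = make_structure([
            ("A", 1, "P", "N", "N", (0.0, 0.0, 0.0)),
            ("B", 1, "A", "O", "O", (2.9, 0.0, 0.0)),
        ])
        donors, _ = count_hbond_donors_acceptors(st, ("A", 1))
        assert donors == 0

    def test_counts_bounded_by_dictionary(self, toy_structure):
        for key in toy_structure.residue_keys()[:6]:
            donors, acceptors = count_hbond_donors_acceptors(
                toy_structure, key)
            assert 0 <= donors <= 4 and 0 <= acceptors <= 3

    def test_missing_residue_is_lookup_error(self, toy_structure):
        with pytest.raises(KeyError):
            count_hbond_donors_acceptors(toy_structure, ("Z", 999))


class TestResidueDepth:
    def test_single_atom_degenerates_to_expanded_radius(self):
        st = make_structure([("A", 1, "G", "CA", "C", (0.0, 0.0, 0.0))])
        assert residue_depth(st, ("A", 1)) == pytest.approx(
            VDW_RADII["C"] + 1.4, rel=1e-6)

    def test_buried_centre_is_deeper_than_surface(self):
        # dense cubic cluster: the central residue sits deeper
        atoms = []
        n = 0
        for x in range(4):
            for y in range(4):
                for z in range(4):
                    n += 1
                    atoms.append(("A", n, "G", "CA", "C",
                                  (2.0 * x, 2.0 * y, 2.0 * z)))
        st = make_structure(atoms)
        corner = st.residue_keys()[0]
        centre_idx = int(np.argmin(np.linalg.norm(
            st.atom_coords - st.atom_coords.mean(axis=0), axis=1)))
        centre = st.residue_keys()[st.atom_residue[centre_idx]]
        assert residue_depth(st, centre) > residue_depth(st, corner) >= 0

    def test_translation_invariance(self):
        atoms = [("A", i + 1, "G", "CA", "C", (3.8 * i, 0.0, 0.0))
                 for i in range(5)]
        st = make_structure(atoms)
        shifted = st.translated(np.array([10.0, -7.0, 3.0]))
        assert residue_depth(st, ("A", 3)) == pytest.approx(
            residue_depth(shifted, ("A", 3)), abs=1e-9)


class TestContactGraph:
    def _pair(self, dist):
        return make_structure([
            ("A", 1, "A", "CB", "C", (0.0, 0.0, 0.0)),
            ("A", 1, "A", "CA", "C", (0.0, 1.5, 0.0)),
            ("B", 1, "A", "CB", "C", (dist, 0.0, 0.0)),
            ("B", 1, "A", "CA", "C", (dist, 1.5, 0.0)),
        ])

    def test_strict_cutoff_boundary(self):
        assert build_contact_graph(self._pair(7.9)).has_edge(("A", 1), ("B", 1))
        assert not build_contact_graph(self._pair(8.0)).has_edge(
            ("A", 1), ("B", 1))

    def test_linear_chain_degree_symmetric(self):
        # brute-force pairwise distances: residue i contacts |i-j|<=2 at
        # 3.8 A spacing under the 8 A cutoff
        atoms = [("A", i + 1, "A", "CB", "C", (3.8 * i, 0.0, 0.0))
                 for i in range(7)]
        g = build_contact_graph(make_structure(atoms))
        degrees = [g.degree(("A", i + 1)) for i in range(7)]
        assert degrees == degrees[::-1]
        assert degrees == [2, 3, 4, 4, 4, 3, 2]

    def test_no_self_loops_and_rigid_invariance(self, toy_structure):
        g = build_contact_graph(toy_structure)
        assert all(u != v for u, v in g.edges)
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0],
                        [0, 0, 1.0]])
        moved = toy_structure.rotated(rot).translated(
            np.array([5.0, -3.0, 11.0]))
        g2 = build_contact_graph(moved)
        assert set(g.edges) == set(g2.edges)

    def test_min_heavy_mode_is_denser_or_equal(self, toy_structure):
        cb = build_contact_graph(toy_structure, atom_mode="cbeta")
        mh = build_contact_graph(toy_structure, atom_mode="min_heavy")
        assert mh.number_of_edges() >= cb.number_of_edges()


class TestCentralities:
    def _graph(self, nodes, edges):
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return g

    def test_path_midpoint(self):
        g = self._graph("abc", [("a", "b"), ("b", "c")])
        c = site_centralities(g, "b")
        assert c["degree"] == pytest.approx(1.0)
        assert c["betweenness"] == pytest.approx(1.0)
        assert c["closeness"] == pytest.approx(1.0)

    def test_complete_graph_symmetry(self):
        nodes = list(range(4))
        edges = [(i, j) for i in nodes for j in nodes if i < j]
        g = self._graph(nodes, edges)
        for node in nodes:
            c = site_centralities(g, node)
            assert c["degree"] == pytest.approx(1.0)
            assert c["betweenness"] == pytest.approx(0.0)
            assert c["eigenvector"] == pytest.approx(0.5)

    def test_star_hub_and_leaves(self):
        g = self._graph("hxyz", [("h", "x"), ("h", "y"), ("h", "z")])
        hub = site_centralities(g, "h")
        assert hub["degree"] == pytest.approx(1.0)
        assert hub["betweenness"] == pytest.approx(1.0)
        leaf = site_centralities(g, "x")
        assert leaf["degree"] == pytest.approx(1 / 3)

    def test_isolated_node_convention(self):
        g = self._graph([0, 1, 2], [(1, 2)])
        assert site_centralities(g, 0) == {
            "degree": 0.0, "betweenness": 0.0,
            "closeness": 0.0, "eigenvector": 0.0}

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            nodes, edges = random_graph(rng, max_nodes=10)
            g = self._graph(nodes, edges)
            oracle = brute_centralities(nodes, edges)
            for node in nodes:
                got = site_centralities(g, node)
                for key in ("degree", "closeness", "betweenness"):
                    assert got[key] == pytest.approx(
                        oracle[node][key], abs=1e-12), (node, key)
                assert got["eigenvector"] == pytest.approx(
                    oracle[node]["eigenvector"], abs=1e-6)
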