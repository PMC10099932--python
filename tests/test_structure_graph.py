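"""Mixture operators, relation graphs, defect algebra, queries."""

import dataclasses

import pytest

from ninchi import grammar_core as G
from ninchi import structure_graph as S


class TestParseMixture:
    def test_size_classes_with_fractions(self):
        mix = S.parse_mixture("{5 nm, 5–10 nm}:{0.5, 0.3}")
        assert mix.items == ("5 nm", "5-10 nm")
        assert mix.fractions == (0.5, 0.3)

    def test_media_fractions(self):
        mix = S.parse_mixture("{NaCl, glucose}:{0.0045,0.001}")
        assert mix.items == ("NaCl", "glucose")
        assert mix.fractions == (0.0045, 0.001)
        assert mix.unit is None

    def test_concentrations_keep_units(self):
        mix = S.parse_mixture("{A, B, C, D}:{96, 60, 60, 4}mg/L")
        assert mix.fractions == (96.0, 60.0, 60.0, 4.0)
        assert mix.unit == "mg/L"
        assert mix.fraction_kind == "mass"

    def test_items_without_fractions(self):
        mix = S.parse_mixture("{sphere, prism, rod}:{}")
        assert mix.items == ("sphere", "prism", "rod")
        assert mix.fractions == ()

    def test_elided_items_with_purity_expression(self):
        mix = S.parse_mixture("...:{cdf(1,0.995)}")
        assert mix.items_elided
        assert mix.fractions == ("cdf(1,0.995)",)

    def test_length_mismatch_recorded_not_fatal(self):
        mix = S.parse_mixture("{a, b, c}:{0.5}")
        assert mix.notes and "3 items vs 1 fractions" in mix.notes[0]

    def test_dimensionless_fraction_above_one_rejected(self):
        with pytest.raises(S.StructureError, match="> 1"):
            S.parse_mixture("{a, b}:{2, 0.1}")

    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(S.StructureError, match="sum"):
            S.parse_mixture("{a, b}:{0.7, 0.5}")


class TestMissingFraction:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("{5 nm, 5-10 nm}:{0.5, 0.3}", 0.2),
            ("{NaCl, glucose}:{0.0045,0.001}", 0.9945),
            ("{sphere, prism, rod}:{}", 1.0),
        ],
    )
    def test_unaccounted_share(self, text, expected):
        assert S.missing_fraction(S.parse_mixture(text)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_sum_plus_missing_is_one(self):
        mix = S.parse_mixture("{a, b, c}:{0.25, 0.5}")
        total = sum(f for f in mix.fractions if isinstance(f, float))
        assert total + S.missing_fraction(mix) == pytest.approx(1.0, abs=1e-15)

    def test_concentrations_need_total(self):
        with pytest.raises(S.StructureError, match="total"):
            S.missing_fraction(S.parse_mixture("{A}:{96}mg/L"))


class TestBuildGraph:
    def test_core_shell_edge_direction(self):
        rep = G.parse("1A/Au/msp/s20d-9!/O2Si/msh/s3t-9/y1&2")
        g = S.build_graph(rep)
        edges = g.edges()
        assert len(edges) == 1
        assert (edges[0].source, edges[0].relation, edges[0].target) == (2, "coats", 1)

    def test_single_component_graph(self):
        g = S.build_graph(G.parse("1A/Au/y1"))
        assert list(g.graph.nodes) == [1] and g.edges() == []

    def test_duplicate_index_makes_cycle(self):
        with pytest.raises(S.StructureError, match="cycle"):
            S.build_graph(G.parse("1A/Au!/Ag/y1&2&1"))

    def test_chain_has_n_minus_one_edges_and_no_cycle(self):
        rep = G.parse("1A/Au!/Ag!/C/y1&2&3")
        g = S.build_graph(rep)
        assert len(g.edges()) == 2

    def test_missing_structural_layer(self):
        with pytest.raises(S.StructureError, match="structural"):
            S.build_graph(G.parse("1A/Au"))

    def test_roundtrip_through_y_layer_is_fixed_point(self):
        rep = G.parse("1A/Au!/Ag/y1&2{1,2}:{0.3,0.7}/i2-1[bond:b;0.7]")
        g = S.build_graph(rep)
        rep2 = dataclasses.replace(rep, structural=g.to_structural_layer())
        g2 = S.build_graph(rep2)
        assert g2.edges() == g.edges()
        assert g2.mixture == g.mixture
        assert G.serialize(rep2) == G.serialize(rep)


class TestQuery:
    REP = G.parse("1A/Au/msp/s20d-9!/O2Si/msh/s3t-9/y1&2")

    def test_coats_wildcard(self):
        g = S.build_graph(self.REP)
        matches = S.query(g, "coats(*, 1)")
        assert [(e.source, e.target) for e in matches] == [(2, 1)]

    def test_no_bond_edges(self):
        g = S.build_graph(self.REP)
        assert S.query(g, "bonded(*,*)") == []

    def test_three_chain_inner_to_outer_path(self):
        g = S.build_graph(G.parse("1A/Au!/Ag!/C/y1&2&3"))
        paths = S.containment_paths(g, 1, 3)
        assert paths == [[1, 2, 3]]  # one path, length 2

    def test_malformed_pattern(self):
        g = S.build_graph(self.REP)
        with pytest.raises(S.StructureError, match="pattern"):
            S.query(g, "coats 2 1")

    def test_edge_list_export(self):
        g = S.build_graph(G.parse("1A/Au!/Ag/y1&2/i2-1[bond:b;0.7]"))
        text = g.to_edgelist_text()
        lines = text.splitlines()
        assert "2\tbonded\t1\tb\t0.7" in lines
        assert "2\tcoats\t1\t-\t-" in lines


class TestDefects:
    def graph(self):
        return S.build_graph(G.parse("1A/Au/y1"))

    def test_purity_constraint_attaches(self):
        g = S.apply_defect(self.graph(), 1, S.DefectSpec("impurity", "cdf(1,0.995)"))
        assert g.node_defects(1)[0].extent == "cdf(1,0.995)"

    def test_zero_extent_is_identity_semantically(self):
        g0 = self.graph()
        g = S.apply_defect(g0, 1, S.DefectSpec("vacancy", 0.0))
        assert g.edges() == g0.edges()
        assert sum(isinstance(d.extent, float) and d.extent > 0 for d in g.node_defects(1)) == 0

    def test_extent_out_of_range(self):
        with pytest.raises(S.StructureError, match="extent"):
            S.DefectSpec("vacancy", 1.5)

    def test_missing_node(self):
        with pytest.raises(S.StructureError, match="node"):
            S.apply_defect(self.graph(), 9, S.DefectSpec("vacancy", 0.1))

    def test_disjoint_union_adds_extents(self):
        assert S.combine_extents(0.01, 0.02, "union") == pytest.approx(0.03)

    @pytest.mark.parametrize("e1,e2", [(0.01, 0.02), (0.5, 0.7), (0.9, 0.9)])
    def test_inclusion_exclusion_bounds(self, e1, e2):
        u = S.combine_extents(e1, e2, "union")
        assert max(e1, e2) <= u + 1e-15
        assert u <= min(1.0, e1 + e2) + 1e-15
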