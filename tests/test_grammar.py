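"""Line-notation grammar: parsing fidelity, round trips, validation."""

import dataclasses

import pytest

from ninchi import grammar_core as G
from ninchi.distributions import DistExpr


GOLD_TWO_COMPONENT = "1A/Au/msp/s20d-9!/O2Si/msh/s3t-9/y1&2"
GOLD_CRYSTAL = "1A/Au/msp/s30d-9/k[P4_2/mnm]/y1"


class TestParsePrintedStrings:
    def test_two_component_core_shell(self):
        rep = G.parse(GOLD_TWO_COMPONENT)
        assert rep.version == "1A"
        assert len(rep.components) == 2
        au, sio2 = rep.components
        assert au.composition == "Au"
        assert au.morphology.category == "sphere"
        assert au.size == G.SizeLayer(20.0, "d", -9)
        assert sio2.composition == "O2Si"
        assert sio2.morphology.category == "shell"
        assert sio2.size == G.SizeLayer(3.0, "t", -9)
        assert rep.structural.ordering == (1, 2)

    def test_crystal_token_opaque(self):
        rep = G.parse(GOLD_CRYSTAL)
        assert len(rep.components) == 1
        assert rep.components[0].crystal == "P4_2/mnm"
        assert rep.structural.ordering == (1,)

    def test_minimal_incremental(self):
        rep = G.parse("1A/Au")
        comp = rep.components[0]
        assert comp.composition == "Au"
        assert comp.morphology is None and comp.size is None
        assert comp.crystal is None and comp.chirality is None
        assert rep.structural is None

    @pytest.mark.parametrize("s", [GOLD_TWO_COMPONENT, GOLD_CRYSTAL, "1A/Au"])
    def test_serialize_is_identity_on_printed_strings(self, s):
        assert G.serialize(G.parse(s)) == s

    def test_optional_ninchi_prefix(self):
        rep = G.parse("NInChI=" + GOLD_CRYSTAL)
        assert rep.components[0].crystal == "P4_2/mnm"
        assert G.serialize(rep) == "NInChI=" + GOLD_CRYSTAL
        assert G.serialize(rep, prefix=False) in (GOLD_CRYSTAL, "NInChI=" + GOLD_CRYSTAL)


class TestLayerParsing:
    def test_bracketed_distribution_size(self):
        rep = G.parse("1A/Au/msp/s[pdf(30,sd=2)]d-9/y1")
        size = rep.components[0].size
        assert isinstance(size.quantity, DistExpr)
        assert size.quantity.canonical() == "pdf(30,sd=2)"
        assert size.qualifier == "d" and size.exponent == -9

    def test_unicode_sigma_and_dash_normalized(self):
        rep = G.parse("1A/Au/s[pdf(30,σ=2)]d−9")
        assert rep.components[0].size.quantity.canonical() == "pdf(30,sd=2)"
        assert rep.components[0].size.exponent == -9

    def test_harmonic_morphology_expression(self):
        rep = G.parse("1A/Au/m[Y(0,0)*scale(4,1,1)]/s20d-9")
        assert rep.components[0].morphology.expr == "Y(0,0)*scale(4,1,1)"

    def test_chirality_token_opaque_roundtrip(self):
        s = "1A/C/w(6,5)"
        rep = G.parse(s)
        assert rep.components[0].chirality == "(6,5)"
        assert G.serialize(rep) == s

    def test_unknown_prefix_preserved_with_warning(self):
        s = "1A/Au/q42foo/y1"
        rep = G.parse(s)
        assert rep.components[0].extras == (("q", "42foo"),)
        assert any("unknown layer prefix" in w for w in rep.warnings)
        assert G.serialize(rep) == s

    def test_mixture_and_interface_cross_layers(self):
        s = "1A/Au!/Ag/y1&2{1,2}:{0.3,0.7}/i2-1[bond:b;0.7]"
        rep = G.parse(s)
        mix = rep.structural.mixture
        assert mix.items == (1, 2) and mix.fractions == (0.3, 0.7)
        spec = rep.structural.interfaces[0]
        assert (spec.source, spec.target, spec.relation) == (2, 1, "bonded")
        assert spec.bond_label == "b" and spec.fraction == 0.7
        assert G.serialize(rep) == s

    def test_comment_and_macro_cross_layers(self):
        s = '1A/Au/y1/c{Zpotential[-35;mV;urlx]}/d{Anatase := 2O.Ti/k[Ir_1/amd]}'
        rep = G.parse(s)
        assert rep.comments[0].header_title == "Zpotential"
        assert rep.comments[0].values == ("-35", "mV", "urlx")
        assert rep.macro_defs[0].name == "Anatase"
        assert G.serialize(rep) == s


class TestParseErrors:
    @pytest.mark.parametrize(
        "text,fragment",
        [
            ("1A/Au/msp/msh", "duplicate 'm' layer"),
            ("1A/Au/s20d-9/s3t-9", "duplicate 's' layer"),
            ("1A/Au/y2", "references component 2 of 1"),
            ("1A/Au!/Ag/y1&3", "references component 3 of 2"),
            ("nonsense", "version token"),
            ("1A/Au/s[pdf(]d-9", "malformed size distribution"),
            ("1A/Au/sxyz", "malformed size layer"),
        ],
    )
    def test_malformed_inputs_raise_with_offset(self, text, fragment):
        with pytest.raises(G.NotationParseError) as exc:
            G.parse(text)
        assert fragment in str(exc.value)
        assert exc.value.offset >= 0

    def test_offset_points_at_failing_layer(self):
        with pytest.raises(G.NotationParseError) as exc:
            G.parse("1A/Au/msp/msh")
        assert exc.value.offset == len("1A/Au/msp/")


class TestValidate:
    def test_valid_representation_has_no_issues(self):
        assert G.validate(G.parse(GOLD_TWO_COMPONENT)) == []

    def test_dangling_ordering_index(self):
        rep = G.parse(GOLD_TWO_COMPONENT)
        bad = dataclasses.replace(rep, structural=G.StructuralLayer((1, 3)))
        errors = [i for i in G.validate(bad) if i.severity == "error"]
        assert len(errors) == 1
        assert "out of range" in errors[0].message

    def test_fraction_sum_above_one(self):
        from ninchi.structure_graph import MixtureSpec

        rep = G.parse(GOLD_TWO_COMPONENT)
        mix = MixtureSpec.__new__(MixtureSpec)
        object.__setattr__(mix, "items", (1, 2))
        object.__setattr__(mix, "fractions", (0.7, 0.5))
        object.__setattr__(mix, "unit", None)
        object.__setattr__(mix, "fraction_kind", "unknown")
        object.__setattr__(mix, "items_elided", False)
        object.__setattr__(mix, "notes", ())
        bad = dataclasses.replace(
            rep, structural=G.StructuralLayer((1, 2), mix)
        )
        errors = [i for i in G.validate(bad) if i.severity == "error"]
        assert any("sum" in e.message for e in errors)

    def test_nonpositive_scalar_size(self):
        rep = G.NanoRepresentation(
            components=(G.Component("Au", size=G.SizeLayer(-3.0, "d", -9)),)
        )
        errors = [i for i in G.validate(rep) if i.severity == "error"]
        assert any("strictly positive" in e.message for e in errors)


class TestFixturesAndRoundTrip:
    def test_determinism(self):
        assert G.fixture_generate(7, 25) == G.fixture_generate(7, 25)

    def test_roundtrip_and_validity(self):
        reps = G.fixture_generate(0, 250)
        for rep in reps:
            s = G.serialize(rep)
            assert G.parse(s) == rep
            assert not [i for i in G.validate(rep) if i.severity == "error"]

    def test_component_count_matches_bang_segments(self):
        for rep in G.fixture_generate(3, 50):
            s = G.serialize(rep)
            assert s.count("!") == len(rep.components) - 1

    def test_incrementality_dropping_optional_layers(self):
        # removing any optional layer from a valid string keeps it valid
        base = GOLD_TWO_COMPONENT
        for layer in ("/msp", "/s20d-9", "/msh", "/s3t-9", "/y1&2"):
            reduced = base.replace(layer, "", 1)
            rep = G.parse(reduced)
            assert not [i for i in G.validate(rep) if i.severity == "error"]
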