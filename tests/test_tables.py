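"""Activity/trait table parsing, provenance, joins and round-trips."""

import pytest
from hypothesis import given, settings, strategies as st

import herbvec as hv
from herbvec.tables import (
    MISSING,
    SchemaError,
    ValidationError,
    parse_properties,
    write_activity_table,
)


def _write(tmp_path, text, name="t.tsv"):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadActivityTable:
    def test_parses_measured_row(self, activity_profiles):
        row = {p.herb_id: p for p in activity_profiles}["c_chinensis"]
        assert [row.numeric(e) for e in ("LNE", "LE", "XO", "L5", "COX1", "L12")] == [
            57, 17, 79, 44, 11, 30
        ]
        assert all(
            v.provenance == "measured" for v in row.values.values()
        )

    def test_missing_cells_preserved(self, activity_profiles):
        row = {p.herb_id: p for p in activity_profiles}["s_baicalensis"]
        assert row.value("XO").is_missing and row.value("L12").is_missing
        assert row.numeric("LNE") == 2 and row.numeric("LE") == 1

    def test_literature_provenance_suffix(self, activity_profiles):
        row = {p.herb_id: p for p in activity_profiles}["a_dahurica"]
        v = row.value("COX1")
        assert v.provenance == "literature" and v.citation == "hwang2002"
        assert v.value == 25

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = _write(tmp_path, "herb_id\tdisplay_name\tLNE\tLE\n")
        assert hv.read_activity_table(p) == []

    def test_comma_delimited_accepted(self, tmp_path):
        p = _write(tmp_path, "herb_id,display_name,LNE,LE\nh1,Herb 1,10,20\n")
        [prof] = hv.read_activity_table(p)
        assert prof.numeric("LNE") == 10 and prof.numeric("LE") == 20

    def test_unknown_endpoint_column_is_schema_error(self, tmp_path):
        p = _write(tmp_path, "herb_id\tdisplay_name\tBOGUS\nh1,Herb,5\n")
        with pytest.raises(SchemaError):
            hv.read_activity_table(p)

    def test_negative_value_rejected(self, tmp_path):
        p = _write(tmp_path, "herb_id\tdisplay_name\tLNE\nh1\tHerb\t-5\n")
        with pytest.raises(ValidationError):
            hv.read_activity_table(p)

    def test_duplicate_herb_id_rejected(self, tmp_path):
        p = _write(tmp_path, "herb_id\tdisplay_name\tLNE\nh1\tA\t5\nh1\tB\t6\n")
        with pytest.raises(ValidationError):
            hv.read_activity_table(p)

    def test_enhancer_values_above_100_are_valid(self, activity_profiles):
        row = {p.herb_id: p for p in activity_profiles}["a_dahurica"]
        assert row.value("LE").is_enhancer and row.numeric("LE") == 149


class TestFixtureInvariants:
    def test_panel_shape(self, activity_profiles):
        assert len(activity_profiles) == 15
        assert all(len(p.values) == 6 for p in activity_profiles)

    def test_stored_missing_pattern(self, activity_profiles):
        missing = sorted(
            (p.herb_id, e)
            for p in activity_profiles
            for e, v in p.values.items()
            if v.is_missing
        )
        assert missing == [
            ("a_dahurica", "L12"),
            ("a_sinensis", "L12"),
            ("c_pilosula", "L12"),
            ("s_baicalensis", "L12"),
            ("s_baicalensis", "XO"),
        ]

    def test_literature_cells_match_footnotes(self, activity_profiles):
        lit = sorted(
            (p.herb_id, e)
            for p in activity_profiles
            for e, v in p.values.items()
            if v.provenance == "literature"
        )
        assert lit == [
            ("a_dahurica", "COX1"),
            ("a_sinensis", "COX1"),
            ("f_suspensa", "COX1"),
            ("s_baicalensis", "COX1"),
            ("s_baicalensis", "L5"),
        ]


class TestRoundTrip:
    def test_fixture_roundtrip_bit_exact(self, activity_profiles, tmp_path):
        out = tmp_path / "rt.tsv"
        write_activity_table(activity_profiles, out)
        again = hv.read_activity_table(out)
        assert again == activity_profiles

    @given(
        values=st.lists(
            st.one_of(
                st.none(),
                st.floats(0, 250, allow_nan=False).map(lambda x: round(x, 2)),
            ),
            min_size=6,
            max_size=6,
        ),
        lit_mask=st.lists(st.booleans(), min_size=6, max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_property(self, tmp_path_factory, values, lit_mask):
        panel = hv.DEFAULT_PANEL
        vals = {}
        for e, v, is_lit in zip(panel, values, lit_mask):
            if v is None:
                vals[e.id] = MISSING
            elif is_lit:
                vals[e.id] = hv.ActivityValue(v, "literature", "tag")
            else:
                vals[e.id] = hv.ActivityValue(v)
        prof = hv.ActivityProfile("h1", "Herb one", vals)
        out = tmp_path_factory.mktemp("rt") / "x.tsv"
        write_activity_table([prof], out)
        [back] = hv.read_activity_table(out)
        assert back == prof


class TestTraitTable:
    def test_fixture_traits(self, trait_profiles):
        by_id = {t.herb_id: t for t in trait_profiles}
        cc = by_id["c_chinensis"]
        assert cc.nature == "cold" and cc.flavors == {"bitter"}
        assert cc.meridians == {"heart", "stomach", "large_intestine", "liver"}
        pc = by_id["p_cocos"]
        assert pc.nature == "neutral" and pc.flavors == {"sweet", "bland"}
        ap = by_id["a_pubescens"]
        assert ap.nature == "slightly_warm" and ap.flavors == {"pungent", "bitter"}

    @pytest.mark.parametrize(
        "text, nature, flavors",
        [
            ("Bitter, cold.", "cold", {"bitter"}),
            ("Sweet, bland, neutral.", "neutral", {"sweet", "bland"}),
            ("Pungent, bitter, slightly warm.", "slightly_warm", {"pungent", "bitter"}),
            ("Bitter, slightly pungent, cold.", "cold", {"bitter", "pungent"}),
            ("Bitter, sour, sweet, slightly cold.", "slightly_cold",
             {"bitter", "sour", "sweet"}),
        ],
    )
    def test_parse_properties(self, text, nature, flavors):
        got_nature, got_flavors = parse_properties(text)
        assert got_nature == nature and got_flavors == flavors

    def test_properties_without_nature_token_fatal(self):
        with pytest.raises(ValidationError):
            parse_properties("Bitter, sweet.")

    def test_unknown_flavor_warns_not_fatal(self, tmp_path):
        p = _write(
            tmp_path,
            "herb_id\tnature\tflavors\nh1\tcold\tbitter, umami\n",
        )
        with pytest.warns(UserWarning, match="umami"):
            [t] = hv.read_trait_table(p)
        assert "bitter" in t.flavors

    def test_nature_collapse_map(self):
        assert hv.collapse_nature("slightly_cold") == "cold"
        assert hv.collapse_nature("hot") == "warm"
        assert hv.collapse_nature("neutral") == "neutral"


class TestJoin:
    def test_full_join(self, activity_profiles, trait_profiles):
        joined = hv.join_panel(activity_profiles, trait_profiles)
        assert len(joined) == 15
        assert joined.orphan_activity == () and joined.orphan_traits == ()

    def test_orphan_reported(self, activity_profiles, trait_profiles):
        extra = hv.TraitProfile("ghost_herb", "cold", frozenset({"bitter"}))
        joined = hv.join_panel(activity_profiles, list(trait_profiles) + [extra])
        assert len(joined) == 15
        assert joined.orphan_traits == ("ghost_herb",)

    def test_disjoint_sets_error(self, activity_profiles):
        stranger = hv.TraitProfile("nobody", "cold", frozenset({"bitter"}))
        with pytest.raises(ValidationError):
            hv.join_panel(activity_profiles, [stranger])


class TestMaskLiterature:
    def test_literature_cells_become_missing(self, activity_profiles):
        masked = hv.mask_literature(activity_profiles)
        by_id = {p.herb_id: p for p in masked}
        assert by_id["a_dahurica"].value("COX1").is_missing
        # measured cells untouched
        assert by_id["a_dahurica"].numeric("LNE") == 94
        n_missing = sum(v.is_missing for p in masked for v in p.values.values())
        assert n_missing == 5 + 5
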