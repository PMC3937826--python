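import logging

import pytest

from oxymet.data_model_io import (
    OxygenClassification,
    ReactionLink,
    SpeciesRecord,
    derive_metabolite_classification,
    parse_reaction_links,
    read_annotations,
    read_classification_lists,
    read_id_list,
    read_property_table,
    read_reaction_enzymes,
    read_species_metadata,
    select_species,
    write_annotations,
    write_reaction_enzymes,
    write_reaction_links,
    write_species_metadata,
    EC_RE,
    R_RE,
)
from oxymet.errors import FormatError, ParseError, ValidationError

HEADER = "organism_id\tdomain\toxygen_requirement\tmulticellular\tlifestyle\tthermo_class\tgenome_year\n"


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestSpeciesMetadata:
    def test_basic_row_maps_fields(self, tmp_path):
        p = _write(tmp_path, "m.tsv", HEADER + "eco\tbacteria\tfacultative\tfalse\tfree_living\tmesophile\t1997\n")
        (rec,) = read_species_metadata(p)
        assert rec.organism_id == "eco"
        assert rec.oxygen_requirement == "facultative"
        assert rec.multicellular is False
        assert rec.genome_year == 1997

    def test_enum_values_normalized_case_insensitively(self, tmp_path):
        p = _write(tmp_path, "m.tsv", HEADER + "eco\tBacteria\tAEROBIC\tFalse\tFree_Living\tMesophile\t1997\n")
        (rec,) = read_species_metadata(p)
        assert rec.oxygen_requirement == "aerobic"
        assert rec.domain == "bacteria"

    def test_duplicate_organism_id_rejected(self, tmp_path):
        rows = "eco\tbacteria\taerobic\tfalse\tfree_living\tmesophile\t1997\n" * 2
        p = _write(tmp_path, "m.tsv", HEADER + rows)
        with pytest.raises(ValidationError, match="eco"):
            read_species_metadata(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = _write(tmp_path, "m.tsv", "organism_id\tdomain\neco\tbacteria\n")
        with pytest.raises(FormatError, match="oxygen_requirement"):
            read_species_metadata(p)

    def test_unmappable_enum_row_rejected_and_reported(self, tmp_path, caplog):
        p = _write(
            tmp_path, "m.tsv",
            HEADER
            + "eco\tbacteria\taerobic\tfalse\tfree_living\tmesophile\t1997\n"
            + "xyz\tbacteria\tsometimes\tfalse\tfree_living\tmesophile\t1998\n",
        )
        with caplog.at_level(logging.WARNING, logger="oxymet"):
            records = read_species_metadata(p)
        assert [r.organism_id for r in records] == ["eco"]
        assert "sometimes" in caplog.text

    def test_round_trip(self, tmp_path, small_bundle):
        p = tmp_path / "meta.tsv"
        write_species_metadata(small_bundle.metadata, p)
        assert read_species_metadata(p) == small_bundle.metadata

    def test_csv_dialect_detected(self, tmp_path):
        p = _write(tmp_path, "m.csv", HEADER.replace("\t", ",")
                   + "eco,bacteria,aerobic,false,free_living,mesophile,1997\n")
        (rec,) = read_species_metadata(p)
        assert rec.organism_id == "eco"


class TestIdLists:
    def test_valid_ids_and_comments(self, tmp_path):
        p = _write(tmp_path, "ec.txt", "# oxic\n1.13.11.1\n1.14.13.2\n\n")
        assert read_id_list(p, EC_RE, "EC") == {"1.13.11.1", "1.14.13.2"}

    def test_wildcard_ec_accepted_verbatim(self, tmp_path):
        p = _write(tmp_path, "ec.txt", "1.1.-.-\n")
        assert read_id_list(p, EC_RE, "EC") == {"1.1.-.-"}

    def test_reaction_id(self, tmp_path):
        p = _write(tmp_path, "r.txt", "R00010\n")
        assert read_id_list(p, R_RE, "R") == {"R00010"}

    def test_malformed_id_reports_line_number(self, tmp_path):
        p = _write(tmp_path, "ec.txt", "1.1.1.1\nEC:banana\n")
        with pytest.raises(ParseError, match="2"):
            read_id_list(p, EC_RE, "EC")

    def test_empty_classification_list_rejected(self, tmp_path):
        for name in ("oe", "ae", "orx", "arx"):
            _write(tmp_path, name, "1.1.1.1\n" if name.endswith("e") else "R00001\n")
        _write(tmp_path, "empty", "# nothing\n")
        with pytest.raises(ValidationError, match="empty"):
            read_classification_lists(
                tmp_path / "oe", tmp_path / "empty", tmp_path / "orx", tmp_path / "arx"
            )


class TestReactionLinks:
    def test_single_line(self, tmp_path):
        p = _write(tmp_path, "r.lst", "R00010: 00500: C01083 => C00031 + C00031\n")
        links = parse_reaction_links(p)
        assert links["R00010"].substrates == {"C01083"}
        assert links["R00010"].products == {"C00031"}
        assert links["R00010"].direction == "forward"

    def test_reversible_and_reverse_arrows(self, tmp_path):
        p = _write(tmp_path, "r.lst",
                   "R00001: 00010: C00001 <=> C00002\nR00002: 00010: C00003 <= C00004\n")
        links = parse_reaction_links(p)
        assert links["R00001"].direction == "reversible"
        assert links["R00002"].direction == "reverse"

    def test_repeated_reaction_merged_by_union(self, tmp_path):
        p = _write(tmp_path, "r.lst",
                   "R00010: 00500: C01083 => C00031\nR00010: 00520: C00999 => C00031 + C00100\n")
        links = parse_reaction_links(p)
        assert links["R00010"].substrates == {"C01083", "C00999"}
        assert links["R00010"].products == {"C00031", "C00100"}
        assert links["R00010"].metabolites == {"C01083", "C00999", "C00031", "C00100"}

    def test_bad_arrow_token_is_parse_error(self, tmp_path):
        p = _write(tmp_path, "r.lst", "R00001: 00010: C00001 ~ C00002\n")
        with pytest.raises(ParseError, match="arrow"):
            parse_reaction_links(p)

    def test_round_trip(self, tmp_path, small_bundle):
        p = tmp_path / "links.lst"
        write_reaction_links(small_bundle.links, p)
        assert parse_reaction_links(p) == small_bundle.links


class TestMetaboliteClassification:
    @staticmethod
    def _cls(**kw):
        base = dict(
            oxic_reactions=frozenset({"R00001"}),
            anoxic_reactions=frozenset({"R00002"}),
        )
        base.update(kw)
        return OxygenClassification(**base)

    @staticmethod
    def _links():
        return {
            "R00001": ReactionLink(frozenset({"C00001"}), frozenset({"C00002"}), "forward"),
            "R00002": ReactionLink(frozenset({"C00002"}), frozenset({"C00003"}), "forward"),
        }

    def test_anoxic_priority_assigns_overlap_to_anoxic(self):
        out = derive_metabolite_classification(self._cls(), self._links(), "anoxic_priority")
        assert out.oxic_metabolites == {"C00001"}
        assert out.anoxic_metabolites == {"C00002", "C00003"}

    def test_oxic_priority_and_drop_overlap(self):
        out = derive_metabolite_classification(self._cls(), self._links(), "oxic_priority")
        assert out.oxic_metabolites == {"C00001", "C00002"}
        out = derive_metabolite_classification(self._cls(), self._links(), "drop_overlap")
        assert out.oxic_metabolites == {"C00001"}
        assert out.anoxic_metabolites == {"C00003"}

    def test_augmented_reactions_contribute_nothing(self):
        cls = self._cls(augmented_reactions=frozenset({"R00001"}))
        out = derive_metabolite_classification(cls, self._links())
        assert out.oxic_metabolites == set()

    def test_empty_anoxic_reactions_rejected(self):
        cls = self._cls(anoxic_reactions=frozenset())
        with pytest.raises(ValidationError):
            derive_metabolite_classification(cls, self._links())

    @pytest.mark.parametrize("policy", ["anoxic_priority", "oxic_priority", "drop_overlap"])
    def test_sets_disjoint_for_every_policy(self, small_bundle, policy):
        out = derive_metabolite_classification(small_bundle.classification, small_bundle.links, policy)
        assert not out.oxic_metabolites & out.anoxic_metabolites
        assert out.oxic_metabolites and out.anoxic_metabolites


class TestSelectSpecies:
    @staticmethod
    def _rec(org, year=2000, genus="Escherichia", domain="bacteria", oxy="aerobic",
             lifestyle="free_living", thermo="mesophile", multicellular=False):
        return SpeciesRecord(org, domain, oxy, multicellular, lifestyle, thermo, year, genus=genus)

    def test_earliest_year_within_genus_wins(self):
        groups = select_species([self._rec("aaa", 2003), self._rec("bbb", 1998)],
                                "nonredundant_groups")
        assert groups["aerobic_bacteria"] == ["bbb"]

    def test_year_tie_broken_lexicographically(self):
        groups = select_species([self._rec("zzz", 1998), self._rec("aaa", 1998)],
                                "nonredundant_groups")
        assert groups["aerobic_bacteria"] == ["aaa"]

    def test_facultative_excluded_from_aerobic_bacteria(self):
        groups = select_species(
            [self._rec("aaa"), self._rec("bbb", genus="Bacillus", oxy="facultative")],
            "nonredundant_groups",
        )
        assert groups["aerobic_bacteria"] == ["aaa"]

    def test_symbionts_and_thermophiles_excluded(self):
        records = [
            self._rec("aaa"),
            self._rec("bbb", genus="Buchnera", lifestyle="symbiotic_or_parasitic"),
            self._rec("ccc", genus="Thermus", thermo="other"),
        ]
        groups = select_species(records, "nonredundant_groups")
        assert groups["aerobic_bacteria"] == ["aaa"]

    def test_archaea_excluded_from_groups(self):
        records = [self._rec("aaa"), self._rec("arc", genus="Sulfolobus", domain="archaea")]
        groups = select_species(records, "nonredundant_groups")
        assert all("arc" not in members for members in groups.values())

    def test_phylo_mode_restricts_to_tree(self):
        records = [self._rec("aaa"), self._rec("bbb", genus="Bacillus")]
        groups = select_species(records, "phylo", tree_tip_labels=["aaa", "xxx"])
        assert groups == {"phylo": ["aaa"]}

    def test_one_species_per_genus_invariant(self, small_bundle, small_groups):
        meta = {r.organism_id: r for r in small_bundle.metadata}
        for members in small_groups.values():
            genera = [meta[o].genus_key() for o in members]
            assert len(genera) == len(set(genera))
            for o in members:
                assert meta[o].lifestyle == "free_living"
                assert meta[o].thermo_class == "mesophile"


class TestOtherTables:
    def test_property_table_round_trip(self, tmp_path, small_bundle):
        from oxymet.data_model_io import write_property_table

        p = tmp_path / "props.tsv"
        write_property_table(small_bundle.properties, p)
        df = read_property_table(p)
        assert df.equals(small_bundle.properties)

    def test_annotation_round_trip(self, tmp_path, small_bundle):
        p = tmp_path / "ann.tsv"
        write_annotations(small_bundle.annotations, p)
        assert read_annotations(p) == small_bundle.annotations

    def test_reaction_enzyme_round_trip(self, tmp_path, small_bundle):
        p = tmp_path / "r2ec.tsv"
        write_reaction_enzymes(small_bundle.r2ec, p)
        assert read_reaction_enzymes(p) == small_bundle.r2ec
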