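import random

import pytest

from semaplex.arch import ProteinRecord, parse_architecture
from semaplex.classify import (
    classify_all,
    classify_family,
    classify_record,
    classify_semaphorin,
    summarize_classes,
    summarize_counts,
)
from semaplex.errors import ClassificationError
from semaplex.taxa import clade_of


def record(arch, species="Mbrev", topology="transmembrane", protein_id="x"):
    return ProteinRecord(
        protein_id=protein_id,
        species=species,
        clade=clade_of(species),
        topology=topology,
        architecture=parse_architecture(arch),
    )


class TestFamilyRules:
    def test_canonical_plexin_is_full_length(self):
        c = classify_family(record("SEMA-PSI-IPT-PSI-IPT-PSI-IPT-IPT-IPT-IPT-TM-RASGAP"))
        assert (c.family, c.plexin_intracellular) == ("PLEXIN", "full")

    def test_plexin_without_rasgap_is_truncated(self):
        c = classify_family(record("SEMA-PSI-IPT-PSI-IPT-PSI-IPT-IPT-IPT-IPT-TM"))
        assert (c.family, c.plexin_intracellular) == ("PLEXIN", "truncated")

    def test_met_truncated_ectodomain_with_kinase(self):
        c = classify_family(record("SEMA-PSI-IPT-IPT-IPT-IPT-TM-TYRKIN", species="Ctele"))
        assert c.family == "MET"

    def test_met_lp_complete_plexin_ectodomain_with_kinase(self):
        c = classify_family(
            record("SEMA-PSI-IPT-PSI-IPT-PSI-IPT-IPT-IPT-IPT-TM-TYRKIN", species="Ctele")
        )
        assert c.family == "MET_LP"

    def test_bare_sema_psi_is_semaphorin(self):
        c = classify_family(record("SEMA-PSI-TM", species="Aquee"))
        assert c.family == "SEMAPHORIN"

    def test_no_sema_domain_rejected(self):
        with pytest.raises(ClassificationError):
            classify_family(record("PSI-IPT", topology="secreted"))

    def test_kinase_without_ipt_unclassified(self):
        c = classify_family(record("SEMA-PSI-TM-TYRKIN"))
        assert c.family == "UNCLASSIFIED"
        assert c.rationale

    def test_rationale_records_fired_rules(self):
        c = classify_family(record("SEMA-PSI-IPT-PSI-IPT-PSI-IPT-IPT-IPT-IPT-TM-RASGAP"))
        assert any("PLEXIN" in r for r in c.rationale)


SEMA_CASES = [
    # (architecture, species, topology, expected class)
    ("SEMA-PSI-FN3-FN3-FN3-FN3-FN3-FN3-SEA-TM", "Mbrev", "transmembrane", "SEMA_FN"),
    ("SEMA-PSI-IG-IG-TM", "Mleid", "transmembrane", "SEMA_IG"),
    ("SEMA-PSI", "Aplan", "secreted", "SEMA_SP"),
    ("SEMA-PSI_LIKE-IG", "Aplan", "secreted", "SEMA_SI"),
    ("SEMA-PSI_LIKE", "Aplan", "secreted", "SEMA_SI"),  # Ig-less member
    ("SEMA-PSI-TSP1-TSP1-TSP1-TSP1-TSP1-TSP1-TSP1-TM", "Tadha", "transmembrane", "SEMA5"),
    ("SEMA-PSI-TM", "Aquee", "transmembrane", "SEMA1"),
    ("SEMA-PSI", "Mleid", "secreted", "SEMA1"),  # ctenophore class-1-like, secreted
    ("SEMA-PSI-IG", "Ctele", "secreted", "SEMA2"),
    ("SEMA-PSI-IG", "Hsapi", "secreted", "SEMA3"),
    ("SEMA-PSI-IG-TM", "Hsapi", "transmembrane", "SEMA4"),
    ("SEMA-PSI-TM", "Bbelc", "transmembrane", "SEMA6"),
    ("SEMA-PSI-TM", "Aplan", "transmembrane", "SEMA6"),
    ("SEMA-PSI-IG", "Hsapi", "gpi_anchored", "SEMA7"),
]


class TestSemaphorinRules:
    @pytest.mark.parametrize("arch,species,topology,expected", SEMA_CASES)
    def test_class_assignment(self, arch, species, topology, expected):
        c = classify_semaphorin(record(arch, species=species, topology=topology))
        assert c.semaphorin_class == expected

    def test_psi_like_outranks_sema_sp(self):
        """An Ig-less Sema-SI member must not fall through to Sema-SP."""
        c = classify_semaphorin(record("SEMA-PSI_LIKE", species="Aplan", topology="secreted"))
        assert c.semaphorin_class == "SEMA_SI"

    def test_tsp1_outranks_everything(self):
        c = classify_semaphorin(
            record("SEMA-PSI-TSP1-IG-TM", species="Hsapi", topology="transmembrane")
        )
        assert c.semaphorin_class == "SEMA5"

    def test_non_semaphorin_rejected(self):
        with pytest.raises(ClassificationError):
            classify_semaphorin(record("SEMA-PSI-IPT-TM"))

    def test_no_rule_fires_is_unclassified_with_tested_rules(self):
        # bare Sema+PSI, secreted vertebrate: no lineage rule covers it
        c = classify_semaphorin(record("SEMA-PSI", species="Hsapi", topology="secreted"))
        assert c.family == "UNCLASSIFIED"
        assert any("tested" in r for r in c.rationale)


class TestClassifyAll:
    def test_sponge_counts(self, fixture_records):
        table = classify_all([r for r in fixture_records if r.species == "Aquee"])
        counts = summarize_counts(table)
        assert counts.loc["Aquee", "PLEXIN"] == 6
        assert counts.loc["Aquee", "SEMAPHORIN"] == 4
        truncated = table[
            (table.family == "PLEXIN") & (table.plexin_intracellular == "truncated")
        ]
        assert len(truncated) == 4

    def test_order_invariance(self, fixture_records):
        table = classify_all(fixture_records)
        shuffled = list(fixture_records)
        random.Random(7).shuffle(shuffled)
        table2 = classify_all(shuffled)
        key = ["species", "protein_id"]
        assert (
            table.sort_values(key).reset_index(drop=True).equals(
                table2.sort_values(key).reset_index(drop=True)
            )
        )

    def test_class_counts_marginalize_to_semaphorin_count(self, fixture_records):
        table = classify_all(fixture_records)
        classes = summarize_classes(table)
        counts = summarize_counts(table)
        assert (classes.sum(axis=1) == counts["SEMAPHORIN"]).all()

    def test_empty_input(self):
        table = classify_all([])
        assert table.empty
        assert summarize_counts(table).empty

    def test_fixture_fully_classified(self, fixture_records):
        table = classify_all(fixture_records)
        assert (table.family == "UNCLASSIFIED").sum() == 0

    def test_record_level_and_table_level_agree(self, fixture_records):
        rec = fixture_records[0]
        table = classify_all([rec])
        assert table.iloc[0].family == classify_record(rec).family
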