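import pytest

from phytoassay.literature_db import (
    CommunitySample,
    LineageLabel,
    MicrobeReport,
    TissueCategory,
    TissueMappingError,
    assign_lineage,
    collection_coverage,
    community_table,
    filter_communities,
    normalize_tissue,
    read_report_table,
    species_level_subset,
    taxon_key,
    taxon_overlap,
    write_report_table,
)


def report(**kwargs):
    base = dict(
        report_id="r1",
        taxon_name="Alternaria alternata",
        taxonomic_rank="species",
        group="fungus",
        study_id="s1",
        continent="Europe",
        country="Germany",
        tissue="leaf",
    )
    base.update(kwargs)
    return MicrobeReport(**base)


class TestMicrobeReport:
    def test_group_vocabulary_closed(self):
        with pytest.raises(ValueError):
            report(group="alga")

    def test_continent_vocabulary_closed(self):
        with pytest.raises(ValueError):
            report(continent="Atlantis")

    def test_implausible_year(self):
        with pytest.raises(ValueError):
            report(collection_year=1500)


class TestAssignLineage:
    def test_old_central_western_north_america(self):
        r = report(continent="North America", country="United States",
                   region_hint="Michigan", collection_year=1905)
        assert assign_lineage(r) is LineageLabel.AMERICANUS

    def test_longitude_boundary(self):
        west = report(continent="North America", country="United States",
                      longitude=-95.0, collection_year=1900)
        east = report(continent="North America", country="United States",
                      longitude=-75.0, collection_year=1900)
        assert assign_lineage(west) is LineageLabel.AMERICANUS
        assert assign_lineage(east) is LineageLabel.UNCERTAIN

    def test_recent_central_western_not_americanus(self):
        r = report(continent="North America", country="United States",
                   region_hint="Michigan", collection_year=1990)
        assert assign_lineage(r) is LineageLabel.UNCERTAIN

    @pytest.mark.parametrize("country", ["Spain", "Portugal", "Italy"])
    def test_mediterranean_europe(self, country):
        assert assign_lineage(report(country=country)) is LineageLabel.ALTISSIMUS

    @pytest.mark.parametrize("country,continent", [("Egypt", "Africa"), ("Morocco", "Africa")])
    def test_mediterranean_africa(self, country, continent):
        assert assign_lineage(report(country=country, continent=continent)) is LineageLabel.ALTISSIMUS

    def test_romania_uncertain(self):
        assert assign_lineage(report(country="Romania")) is LineageLabel.UNCERTAIN

    def test_remaining_europe_australis(self):
        assert assign_lineage(report(country="Germany")) is LineageLabel.AUSTRALIS

    @pytest.mark.parametrize(
        "continent,country",
        [("Asia", "China"), ("Asia", "Saudi Arabia"), ("Australia", "Australia"), ("Africa", "Kenya")],
    )
    def test_other_regions_australis(self, continent, country):
        assert assign_lineage(report(continent=continent, country=country)) is LineageLabel.AUSTRALIS

    def test_stated_lineage_beats_geography(self):
        r = report(country="Spain", host_lineage_stated="americanus")
        assert assign_lineage(r) is LineageLabel.AMERICANUS

    def test_gulf_excluded(self):
        r = report(continent="North America", host_lineage_stated="Gulf")
        assert assign_lineage(r) is LineageLabel.GULF_EXCLUDED

    @pytest.mark.parametrize("alias", ["Delta", "Greeny"])
    def test_gulf_coast_aliases_map_to_australis(self, alias):
        r = report(continent="North America", host_lineage_stated=alias)
        assert assign_lineage(r) is LineageLabel.AUSTRALIS

    def test_missing_continent_errors(self):
        with pytest.raises(ValueError):
            assign_lineage(report(continent=""))

    def test_deterministic_and_total(self):
        """Every valid combination yields exactly one label, repeatably."""
        reports = [
            report(continent=c, country=co, report_id=f"{c}:{co}")
            for c, co in [
                ("Europe", "Germany"), ("Europe", "Spain"), ("Europe", "Romania"),
                ("Asia", "Japan"), ("Africa", "Egypt"), ("Australia", "Australia"),
                ("South America", "Argentina"),
            ]
        ]
        first = [assign_lineage(r) for r in reports]
        second = [assign_lineage(r) for r in reports]
        assert first == second
        assert all(isinstance(lab, LineageLabel) for lab in first)


class TestNormalizeTissue:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("rhizome", TissueCategory.ROOT_ASSOCIATED),
            ("root", TissueCategory.ROOT_ASSOCIATED),
            ("leaf blade", TissueCategory.LEAF),
            ("culm", TissueCategory.STEM),
            ("  Leaf  Sheath ", TissueCategory.SHEATH),
            ("rhizosphere soil", TissueCategory.RHIZOSPHERE_SOIL),
        ],
    )
    def test_mapping(self, raw, expected):
        assert normalize_tissue(raw) is expected

    def test_unknown_term_errors_with_term(self):
        with pytest.raises(TissueMappingError, match="xylem"):
            normalize_tissue("xylem")

    def test_compartments(self):
        assert TissueCategory.LEAF.compartment == "phyllosphere"
        assert TissueCategory.ROOT_ASSOCIATED.compartment == "rhizosphere"
        assert TissueCategory.RHIZOSPHERE_SOIL.compartment == "soil"


class TestFilterCommunities:
    def make_reports(self, study, n, tissue="leaf", culture=True, taxon="Alternaria alternata"):
        return [
            report(
                report_id=f"{study}:{tissue}:{i}", study_id=study, tissue=tissue,
                culture_dependent=culture, taxon_name=taxon,
            )
            for i in range(n)
        ]

    def test_spec_fixture_counts(self):
        # 3 studies x 2 tissues with counts {12, 10, 9, 15, 3, 11} -> 4 pass
        reports = (
            self.make_reports("s1", 12, "leaf") + self.make_reports("s1", 10, "stem")
            + self.make_reports("s2", 9, "leaf") + self.make_reports("s2", 15, "stem")
            + self.make_reports("s3", 3, "leaf") + self.make_reports("s3", 11, "stem")
        )
        samples = filter_communities(reports)
        assert len(samples) == 4
        assert {s.n_isolates for s in samples} == {12, 10, 15, 11}

    def test_nine_isolates_excluded(self):
        assert filter_communities(self.make_reports("s1", 9)) == []

    def test_culture_independent_excluded(self):
        assert filter_communities(self.make_reports("s1", 100, culture=False)) == []

    def test_dead_tissue_excluded(self):
        reports = [
            report(report_id=f"d{i}", study_id="s1", tissue="stem", tissue_alive=False)
            for i in range(12)
        ]
        assert filter_communities(reports) == []

    def test_row_order_invariant(self):
        reports = self.make_reports("s1", 12) + self.make_reports("s2", 10, "root")
        forward = filter_communities(reports)
        backward = filter_communities(list(reversed(reports)))
        assert [(s.sample_id, s.taxon_counts) for s in forward] == [
            (s.sample_id, s.taxon_counts) for s in backward
        ]

    def test_community_table_shape(self):
        reports = self.make_reports("s1", 12) + self.make_reports("s2", 10, taxon="Fusarium solani")
        table = community_table(filter_communities(reports))
        assert table.shape == (2, 2)
        assert table.to_numpy().sum() == 22


class TestTaxonOverlap:
    def test_identical_sets(self):
        res = taxon_overlap({"A": {"x", "y"}, "B": {"x", "y"}})
        assert res.region_counts["A&B"] == 2
        assert res.region_counts["A"] == 0
        assert res.shared_two_or_more == 2

    def test_disjoint(self):
        res = taxon_overlap({"A": {"x"}, "B": {"y"}})
        assert res.region_counts["A&B"] == 0
        assert res.shared_two_or_more == 0

    def test_hand_enumeration(self):
        res = taxon_overlap({"A": {"a", "b", "c", "d"}, "B": {"c", "d", "e"}})
        shared, frac_a, frac_b = res.pairwise[("A", "B")]
        assert shared == 2
        assert frac_a == pytest.approx(2 / 4)
        assert frac_b == pytest.approx(2 / 3)

    def test_three_sets_regions_sum_to_union(self):
        sets = {"A": {1, 2, 3, 4}, "B": {3, 4, 5}, "C": {4, 5, 6, 7}}
        res = taxon_overlap(sets)
        assert sum(res.region_counts.values()) == res.union_size == 7
        assert res.region_counts["A&B&C"] == 1  # {4}

    def test_four_sets_pairwise_only(self):
        res = taxon_overlap({k: {k} for k in "ABCD"})
        assert res.region_counts is None
        assert len(res.pairwise) == 6


class TestSpeciesLevelSubset:
    def test_mixed_fixture(self):
        reports = (
            [report(report_id=f"sp{i}") for i in range(3)]
            + [report(report_id="sh", taxonomic_rank="genus", sh_code="SH0000001.08FU")]
            + [report(report_id=f"g{i}", taxonomic_rank="genus") for i in range(6)]
        )
        kept, pct = species_level_subset(reports)
        assert len(kept) == 4
        assert pct == 40

    def test_all_species_level(self):
        kept, pct = species_level_subset([report()])
        assert pct == 100

    def test_paper_scale_marginals(self):
        reports = [report(report_id=f"s{i}") for i in range(2829)] + [
            report(report_id=f"g{i}", taxonomic_rank="genus") for i in range(10514 - 2829)
        ]
        kept, pct = species_level_subset(reports)
        assert (len(kept), pct) == (2829, 27)


class TestCollectionCoverage:
    def test_full_and_zero(self):
        reported = {"fungi": {"a", "b"}}
        assert collection_coverage({"a", "b"}, reported)["fungi"] == 100
        assert collection_coverage({"z"}, reported)["fungi"] == 0

    def test_partial(self):
        reported = {"fungi": {f"t{i}" for i in range(20)}}
        assert collection_coverage({f"t{i}" for i in range(5)}, reported)["fungi"] == 25

    def test_empty_reported_errors(self):
        with pytest.raises(ValueError):
            collection_coverage({"a"}, {"fungi": set()})


class TestTaxonKeyAndRoundTrip:
    def test_sh_code_wins(self):
        r = report(sh_code="SH123.08FU")
        assert taxon_key(r) == "SH123.08FU"

    def test_name_normalized(self):
        assert taxon_key("  Alternaria   Alternata ") == "alternaria alternata"

    def test_table_round_trip(self, tmp_path):
        reports = [
            report(report_id="a", collection_year=1905, latitude=42.5, longitude=-83.1),
            report(report_id="b", taxonomic_rank="genus", tissue_alive=False,
                   culture_dependent=False, host_lineage_stated="americanus"),
        ]
        path = tmp_path / "reports.tsv"
        write_report_table(reports, path)
        back = read_report_table(path)
        assert back == reports
        assert [assign_lineage(r) for r in back] == [assign_lineage(r) for r in reports]
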