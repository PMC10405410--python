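"""CDI, cis/trans partitioning and classification, distances, unk regions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from charlink import Annotation, GeneRecord
from charlink import contact_statistics as cs
from charlink import synthetic_data as synth
from charlink.pipeline import truth_as_contacts


class TestCDI:
    @pytest.mark.parametrize(
        "per_chrom, expected",
        [
            ({"chr1": 100}, 1.0),
            ({f"chr{i}": 10 for i in range(1, 7)}, 1 / 6),
            ({"chr1": 50, "chr2": 30, "chr3": 20}, 0.5),
        ],
    )
    def test_forced_arithmetic(self, per_chrom, expected):
        assert cs.compute_cdi(per_chrom) == pytest.approx(expected)

    def test_zero_contacts_undefined(self):
        with pytest.raises(ValueError, match="zero contacts"):
            cs.compute_cdi({"chr1": 0})

    def test_bounds_and_concentration_iff_one(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            k = int(rng.integers(1, 7))
            counts = {f"chr{i}": int(rng.integers(1, 50))
                      for i in range(1, k + 1)}
            cdi = cs.compute_cdi(counts)
            assert 1 / k <= cdi <= 1
            assert (cdi == 1) == (k == 1)


class TestTally:
    @pytest.fixture()
    def toy(self):
        ann = Annotation([
            GeneRecord("gA", "lncRNA", "chr1", 100, 200, "+"),
            GeneRecord("gB", "mRNA", "chr2", 100, 200, "+"),
        ])
        contacts = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(4)],
            "rna_gene_id": ["gA"] * 4,
            "rna_class": ["lncRNA"] * 4,
            "rna_chrom": ["chr1"] * 4,
            "rna_pos": [110] * 4,
            "dna_chrom": ["chr1", "chr1", "chr1", "chr2"],
            "dna_pos": [500, 600, 700, 800],
            "replicate": ["rep1"] * 4,
        })
        return ann, contacts

    def test_per_chrom_counts_and_total(self, toy):
        ann, contacts = toy
        profiles, not_detected = cs.tally(contacts, ann)
        assert len(profiles) == 1
        p = profiles[0]
        assert p.per_chrom == {"chr1": 3, "chr2": 1}
        assert p.total_contacts == 4
        assert p.cdi == pytest.approx(0.75)
        assert not_detected == ["gB"]

    def test_unknown_gene_errors(self, toy):
        ann, contacts = toy
        contacts.loc[0, "rna_gene_id"] = "ghost"
        with pytest.raises(ValueError, match="unknown genes"):
            cs.tally(contacts, ann)

    def test_tallies_equal_planted_counts(self, truth_small, contacts_small,
                                          annotation_small):
        profiles, _ = cs.tally(contacts_small, annotation_small)
        planted = (
            truth_small.table[truth_small.table["gene_id"] != "intergenic"]
            .groupby("gene_id", observed=True).size()
        )
        assert {p.gene_id: p.total_contacts for p in profiles} == \
            planted.to_dict()


GENE = GeneRecord("g", "lncRNA", "chr2", 100_000, 102_000, "+")


class TestPartitionAndClassify:
    @pytest.mark.parametrize(
        "chrom, pos, category",
        [
            ("chr2", 105_000, "cis_proximal"),  # 3 kb from the span
            ("chr2", 101_000, "cis_proximal"),  # inside the span
            ("chr2", 500_000, "cis_distal"),
            ("chr2", 112_000, "cis_distal"),    # exactly 10 kb: not < 10 kb
            ("chr5", 1_000, "trans"),
        ],
    )
    def test_single_contact_category(self, chrom, pos, category):
        f = cs.partition(GENE, [chrom], [pos])
        expected = {"cis_proximal": (1, 0, 0), "cis_distal": (0, 1, 0),
                    "trans": (0, 0, 1)}[category]
        assert f == expected

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(9)
        chroms = rng.choice(["chr1", "chr2", "chr5"], size=200)
        pos = rng.integers(1, 1_000_000, size=200)
        f = cs.partition(GENE, chroms, pos)
        assert sum(f) == pytest.approx(1.0, abs=1e-9)

    def test_zero_contacts_undefined(self):
        with pytest.raises(ValueError, match="no contacts"):
            cs.partition(GENE, [], [])

    @pytest.mark.parametrize(
        "fracs, label",
        [
            ((0.60, 0.20, 0.20), "cis_proximal"),
            ((0.20, 0.20, 0.60), "trans_acting"),
            ((0.50, 0.10, 0.40), "unclassified"),  # 0.50 is not > 0.50
        ],
    )
    def test_classify_threshold_is_strict(self, fracs, label):
        assert cs.classify(*fracs) == label

    def test_same_chromosome_scheme(self):
        assert cs.classify_same_chrom(0.2) == "cis_acting"
        assert cs.classify_same_chrom(0.7) == "trans_acting"
        assert cs.classify_same_chrom(0.5) == "unclassified"

    def test_planted_classes_recovered(self, genome_small):
        ann = synth.make_annotation(genome_small, 91,
                                    class_counts={"lncRNA": 40})
        ids = [g.gene_id for g in ann.by_class["lncRNA"]]
        assignment = {g: ("cis_proximal" if i < 30 else "trans_acting")
                      for i, g in enumerate(ids)}
        truth = synth.plant_contacts(
            ann, genome_small, 92, lncrna_class_assignment=assignment,
            per_gene_counts={g: 150 for g in ids})
        profiles = cs.gene_profiles(truth_as_contacts(truth), ann,
                                    genome_small)
        called = profiles.set_index("gene_id")["classification"]
        acc = np.mean([called[g] == assignment[g] for g in ids])
        assert acc >= 0.99


class TestDistanceProfile:
    def test_midpoint_distances(self):
        gene = GeneRecord("g", "lncRNA", "chr1", 900, 1_100, "+")
        d = cs.distances_from_locus(gene, [900, 1_100, 5_000])
        assert list(d) == [100, 100, 4_000]

    def test_cap_excludes_distant_contacts(self):
        gene = GeneRecord("g", "lncRNA", "chr1", 900, 1_100, "+")
        hist = cs.distance_profile(gene, [1_500, 26_000], caps=[20_000])
        counts, _ = hist[20_000]
        assert counts.sum() == 1  # the 25 kb-away contact is outside the cap

    def test_empty_contacts_give_empty_histogram(self):
        gene = GeneRecord("g", "lncRNA", "chr1", 900, 1_100, "+")
        hist = cs.distance_profile(gene, [])
        assert all(c.sum() == 0 for c, _ in hist.values())


class TestConcatCoordinates:
    def test_first_chromosome_has_zero_offset(self, genome_small):
        assert cs.concat_position("chr1", 5, genome_small) == 5

    def test_second_chromosome_offset_by_first_length(self, genome_small):
        L1 = genome_small.lengths["chr1"]
        assert cs.concat_position("chr2", 1, genome_small) == L1 + 1

    def test_position_beyond_chromosome_errors(self, genome_small):
        with pytest.raises(ValueError, match="outside"):
            cs.concat_position("chr1", genome_small.lengths["chr1"] + 1,
                               genome_small)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(min_value=1, max_value=6 * 50_000))
    def test_round_trip_identity(self, genome_small, global_pos):
        chrom, pos = cs.invert_concat_position(global_pos, genome_small)
        assert cs.concat_position(chrom, pos, genome_small) == global_pos


class TestUnkRegions:
    @pytest.fixture()
    def scenario(self, genome_small):
        ann = Annotation([
            GeneRecord("m1", "mRNA", "chr1", 25_000, 26_000, "+"),
        ])
        rows = []
        # 600 unassigned RNA-side hits in a clean tile (chr1 tile 0-10k)
        rows += [("chr1", 5_000)] * 600
        # 800 hits in the tile overlapping the mRNA (chr1 20k-30k)
        rows += [("chr1", 22_000)] * 800
        # 100 hits in another clean tile (chr2)
        rows += [("chr2", 45_000)] * 100
        contacts = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(len(rows))],
            "rna_gene_id": ["unassigned"] * len(rows),
            "rna_class": ["unkRNA"] * len(rows),
            "rna_chrom": [c for c, _ in rows],
            "rna_pos": [p for _, p in rows],
            "dna_chrom": ["chr3"] * len(rows),
            "dna_pos": [1_000] * len(rows),
            "replicate": ["rep1"] * len(rows),
        })
        return ann, contacts

    def test_qualifying_tile_reported_with_count(self, scenario,
                                                 genome_small):
        ann, contacts = scenario
        regions = cs.detect_unk_regions(contacts, ann, genome_small)
        assert len(regions) == 1
        r = regions[0]
        assert (r.chrom, r.window_start, r.window_end) == ("chr1", 1, 10_000)
        assert r.n_contacts == 600

    def test_tile_overlapping_gene_excluded_despite_count(self, scenario,
                                                          genome_small):
        ann, contacts = scenario
        regions = cs.detect_unk_regions(contacts, ann, genome_small,
                                        min_contacts=500)
        assert not any(r.window_start <= 25_000 <= r.window_end
                       and r.chrom == "chr1" for r in regions)

    def test_below_threshold_not_reported(self, scenario, genome_small):
        ann, contacts = scenario
        regions = cs.detect_unk_regions(contacts, ann, genome_small,
                                        min_contacts=500)
        assert not any(r.chrom == "chr2" for r in regions)
        lowered = cs.detect_unk_regions(contacts, ann, genome_small,
                                        min_contacts=50)
        assert any(r.chrom == "chr2" and r.n_contacts == 100
                   for r in lowered)

    def test_bed_output(self, scenario, genome_small, tmp_path):
        ann, contacts = scenario
        regions = cs.detect_unk_regions(contacts, ann, genome_small)
        p = tmp_path / "unk.bed"
        cs.unk_regions_to_bed(regions, p)
        fields = p.read_text().splitlines()[0].split("\t")
        assert fields[:3] == ["chr1", "0", "10000"]
        assert fields[4] == "600"


class TestProfilesTable:
    def test_fraction_columns_sum_to_one(self, contacts_small,
                                         annotation_small, genome_small):
        profiles = cs.gene_profiles(contacts_small, annotation_small,
                                    genome_small)
        total = (profiles["f_cis_proximal"] + profiles["f_cis_distal"]
                 + profiles["f_trans"])
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_detection_summary_counts_genes_with_contacts(
            self, contacts_small, annotation_small, genome_small):
        profiles = cs.gene_profiles(contacts_small, annotation_small,
                                    genome_small)
        detected, annotated, pct = cs.detection_summary(
            profiles, annotation_small, "lncRNA")
        assert annotated == 30
        assert detected == profiles["rna_class"].eq("lncRNA").sum()
        assert pct == pytest.approx(100 * detected / annotated)
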