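"""Generator contracts: determinism, planted composition, emitted formats."""

import numpy as np
import pytest

from charlink import Annotation, GenomeModel, reverse_complement
from charlink.linker import DEFAULT_LINKER
from charlink import synthetic_data as synth


class TestLinker:
    def test_tag_rc_is_reverse_complement_of_tag(self):
        assert DEFAULT_LINKER.tag_rc == reverse_complement(DEFAULT_LINKER.tag)
        assert DEFAULT_LINKER.tag == "ACCGGCGTCCAAG"
        assert DEFAULT_LINKER.tag_rc == "CTTGGACGCCGGT"

    def test_arms_reassemble_the_top_strand(self):
        l = DEFAULT_LINKER
        assert l.upstream_arm + l.tag + l.downstream_arm == l.top_strand

    def test_realized_top_has_no_n(self):
        rng = np.random.default_rng(0)
        top = DEFAULT_LINKER.realized_top(rng)
        assert "N" not in top
        assert DEFAULT_LINKER.tag in top


class TestMakeGenome:
    def test_concat_length_is_additive(self):
        g = synth.make_genome(1, n_assembled=6, assembled_lengths=100_000,
                              n_scaffolds=4)
        assert len(g.names) == 10
        assert g.total_length == sum(g.lengths.values())
        assert g.total_length == 6 * 100_000 + sum(
            g.lengths[s] for s in g.scaffold_names)

    def test_same_seed_gives_byte_identical_fasta(self, tmp_path):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        synth.make_genome(5, assembled_lengths=10_000, n_scaffolds=2
                          ).to_fasta(p1)
        synth.make_genome(5, assembled_lengths=10_000, n_scaffolds=2
                          ).to_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_no_scaffolds_leaves_chromosomes_only(self):
        g = synth.make_genome(2, n_assembled=3, assembled_lengths=5_000,
                              n_scaffolds=0)
        assert g.names == ["chr1", "chr2", "chr3"]

    def test_concat_order_and_offsets(self):
        g = synth.make_genome(3, n_assembled=2, assembled_lengths=5_000,
                              n_scaffolds=3)
        assert g.names[:2] == ["chr1", "chr2"]
        assert g.names[2:] == sorted(g.names[2:])
        offs = [g.offsets[n] for n in g.names]
        assert offs == sorted(offs)
        for a, b in zip(g.names, g.names[1:]):
            assert g.offsets[b] == g.offsets[a] + g.lengths[a]

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError, match="1 kb"):
            synth.make_genome(1, n_assembled=1, assembled_lengths=500,
                              n_scaffolds=0)

    def test_gatc_occurs_at_background_rate(self, genome_small):
        seq = genome_small.sequences["chr1"]
        n = seq.count("GATC")
        expected = len(seq) / 256
        assert abs(n - expected) < 5 * np.sqrt(expected)

    def test_fasta_round_trip(self, genome_small, tmp_path):
        p = tmp_path / "g.fa"
        genome_small.to_fasta(p)
        g2 = GenomeModel.from_fasta(p)
        assert g2.names == genome_small.names
        assert g2.sequences == genome_small.sequences
        assert g2.assembled_names == genome_small.assembled_names


class TestMakeAnnotation:
    def test_exact_per_class_counts(self, annotation_small):
        counts = {c: len(annotation_small.by_class[c])
                  for c in ("rRNA", "msrpRNA", "snRNA", "snoRNA", "lncRNA",
                            "mRNA")}
        assert counts == {"rRNA": 2, "msrpRNA": 2, "snRNA": 6, "snoRNA": 5,
                          "lncRNA": 30, "mRNA": 40}

    def test_genes_do_not_overlap(self, annotation_small):
        by_chrom = {}
        for g in annotation_small:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_single_gene_gff3_round_trip(self, genome_small, tmp_path):
        ann = synth.make_annotation(genome_small, 7,
                                    class_counts={"lncRNA": 1})
        p = tmp_path / "one.gff3"
        ann.to_gff3(p)
        back = Annotation.from_gff3(p)
        assert len(back) == 1
        assert back.genes[0] == ann.genes[0]

    def test_full_gff3_round_trip(self, annotation_small, tmp_path):
        p = tmp_path / "ann.gff3"
        annotation_small.to_gff3(p)
        back = Annotation.from_gff3(p)
        assert sorted(back.genes, key=lambda g: g.gene_id) == sorted(
            annotation_small.genes, key=lambda g: g.gene_id)

    def test_gene_longer_than_chromosome_errors(self, genome_small):
        with pytest.raises(ValueError, match="cannot place"):
            synth.make_annotation(
                genome_small, 8, class_counts={"lncRNA": 1},
                length_ranges={"lncRNA": (60_000, 60_000)},
            )


class TestPlantContacts:
    def test_composition_matches_mixture_within_3_se(self, annotation_small,
                                                     genome_small):
        n = 100_000
        truth = synth.plant_contacts(annotation_small, genome_small, 21,
                                     n_contacts=n)
        t = truth.table
        assigned = t[t["gene_id"] != "intergenic"]
        inter_frac = synth.DEFAULT_INTERGENIC_FRACTION
        for cls, p in synth.LIVER_PROFILE.items():
            expected = p * (1 - inter_frac)
            got = float((t["rna_class"] == cls).mean())
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(got - expected) <= 3 * se + 1e-12, cls
        # shares among gene-assigned contacts track the published profile
        r_share = float((assigned["rna_class"] == "rRNA").mean())
        assert abs(r_share - synth.LIVER_PROFILE["rRNA"]) < 0.01

    def test_degenerate_p_cis_puts_every_contact_in_window(
            self, annotation_small, genome_small):
        lnc = annotation_small.by_class["lncRNA"][0]
        truth = synth.plant_contacts(
            annotation_small, genome_small, 22,
            lncrna_class_assignment={lnc.gene_id: "cis_proximal"},
            per_gene_counts={lnc.gene_id: 500}, p_cis=1.0,
        )
        t = truth.table
        assert (t["dna_chrom"].astype(str) == lnc.chrom).all()
        dist = np.maximum(
            np.maximum(lnc.start - t["dna_pos"], t["dna_pos"] - lnc.end), 0)
        assert (dist < 10_000).all()

    def test_degenerate_p_trans_avoids_own_chromosome(self, annotation_small,
                                                      genome_small):
        lnc = annotation_small.by_class["lncRNA"][1]
        truth = synth.plant_contacts(
            annotation_small, genome_small, 23,
            lncrna_class_assignment={lnc.gene_id: "trans_acting"},
            per_gene_counts={lnc.gene_id: 500}, p_trans=1.0,
        )
        assert (truth.table["dna_chrom"].astype(str) != lnc.chrom).all()

    def test_zero_contacts_gives_empty_truth(self, annotation_small,
                                             genome_small):
        truth = synth.plant_contacts(annotation_small, genome_small, 24,
                                     n_contacts=0)
        assert len(truth) == 0

    def test_bad_mixture_rejected(self, annotation_small, genome_small):
        with pytest.raises(ValueError, match="sums to"):
            synth.plant_contacts(annotation_small, genome_small, 25,
                                 class_mixture={"rRNA": 0.5, "lncRNA": 0.6},
                                 n_contacts=10)

    def test_dpnii_anchored_positions_start_at_gatc(self, annotation_small,
                                                    genome_small):
        truth = synth.plant_contacts(annotation_small, genome_small, 26,
                                     n_contacts=2_000, dpnII_anchor=True)
        t = truth.table.head(200)
        at_gatc = 0
        for row in t.itertuples(index=False):
            seq = genome_small.sequences[str(row.dna_chrom)]
            if seq[row.dna_pos - 1:row.dna_pos + 3] == "GATC":
                at_gatc += 1
        assert at_gatc >= 195  # rare off-site fallbacks only


class TestEmitBridgeReads:
    def test_forward_only_reads_carry_tag_exactly_once_on_mate1(
            self, truth_small, genome_small, annotation_small):
        for _rid, m1, _m2 in list(synth.iter_bridge_reads(
                truth_small, genome_small, 31, annotation=annotation_small,
                orientation_mix=0.0))[:300]:
            assert m1.count(DEFAULT_LINKER.tag) == 1
            assert DEFAULT_LINKER.tag_rc not in m1

    def test_reverse_only_reads_carry_tag_rc(self, truth_small, genome_small,
                                             annotation_small):
        for _rid, m1, _m2 in list(synth.iter_bridge_reads(
                truth_small, genome_small, 32, annotation=annotation_small,
                orientation_mix=1.0))[:300]:
            assert DEFAULT_LINKER.tag_rc in m1

    def test_fastq_emission_is_byte_deterministic(self, truth_small,
                                                  genome_small,
                                                  annotation_small, tmp_path):
        paths = []
        for tag in ("a", "b"):
            f1 = tmp_path / f"{tag}_1.fq"
            f2 = tmp_path / f"{tag}_2.fq"
            synth.emit_bridge_reads(truth_small, genome_small, 33, f1, f2,
                                    annotation=annotation_small)
            paths.append((f1.read_bytes(), f2.read_bytes()))
        assert paths[0] == paths[1]

    def test_read_length_below_tag_rejected(self, truth_small, genome_small):
        with pytest.raises(ValueError, match="tag"):
            list(synth.iter_bridge_reads(truth_small, genome_small, 34,
                                         read_length=10))

    def test_fragment_range_validation(self, truth_small, genome_small):
        with pytest.raises(ValueError, match="rna_frag_range"):
            list(synth.iter_bridge_reads(truth_small, genome_small, 35,
                                         rna_frag_range=(0, 500)))


class TestEmitCoverageTrack:
    def test_zero_reads_gives_all_zero_rpkm(self, genome_small):
        with pytest.warns(UserWarning, match="zero mapped"):
            _reads, track = synth.emit_coverage_track(genome_small, 41,
                                                      n_reads=0)
        assert all((v == 0).all() for v in track.values.values())

    def test_site_outside_genome_rejected(self, genome_small):
        with pytest.raises(ValueError, match="chr1:999999"):
            synth.emit_coverage_track(
                genome_small, 42,
                contact_sites_enriched=[("chr1", 999_999)], effect_size=2.0)

    def test_effect_size_below_one_rejected(self, genome_small):
        with pytest.raises(ValueError, match="effect_size"):
            synth.emit_coverage_track(genome_small, 43, effect_size=0.5)

    def test_enrichment_raises_local_coverage(self, genome_small):
        sites = [("chr1", 10_000), ("chr1", 30_000)]
        _r, track = synth.emit_coverage_track(
            genome_small, 44, contact_sites_enriched=sites, effect_size=8.0,
            n_reads=80_000)
        local = track.values["chr1"][10_000 // 50]
        background = float(np.median(track.values["chr2"]))
        assert local > 3 * max(background, 1e-9)


class TestEmitTpmMatrix:
    def test_shape_and_columns(self):
        tpm = synth.emit_tpm_matrix(["a", "b", "c"], 51)
        assert tpm.shape == (3, 75)
        assert sum(c.startswith("embryonic") for c in tpm.columns) == 47
        assert sum(c.startswith("adult") for c in tpm.columns) == 28

    def test_deterministic_per_seed(self):
        a = synth.emit_tpm_matrix(["x", "y"], 52)
        b = synth.emit_tpm_matrix(["x", "y"], 52)
        assert a.equals(b)

    def test_group_fold_shifts_high_group(self):
        genes = [f"g{i}" for i in range(40)]
        assign = {g: ("high" if i < 20 else "low")
                  for i, g in enumerate(genes)}
        tpm = synth.emit_tpm_matrix(genes, 53, group_assignment=assign,
                                    group_fold=8.0)
        high = tpm.iloc[:20].median(axis=1).median()
        low = tpm.iloc[20:].median(axis=1).median()
        assert high > 2 * low

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            synth.emit_tpm_matrix([], 54)
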