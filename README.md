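# charlink

RNA–chromatin contact analysis from ChAR-seq bridge reads.

ChAR-seq (Chromatin-Associated RNA sequencing) captures RNA molecules that
were in contact with genomic DNA: a short biotinylated linker is ligated
between each RNA's cDNA and the adjacent DpnII-cut DNA, and the resulting
chimeric cDNA–linker–DNA molecules are sequenced as 150 nt paired-end
reads.  `charlink` turns such reads into a genome-wide RNA–DNA contact map
and the downstream statistics used to characterize long non-coding RNAs
(lncRNAs) in a species with sparse functional annotation:

- **Bridge parsing** — the 13-mer linker tag `ACCGGCGTCCAAG` (or its
  reverse complement `CTTGGACGCCGGT`) is located in each read pair; the
  sequence 5′ of the linker is the RNA side, the sequence 3′ of it the DNA
  side.  Pairs whose RNA or DNA fragment is shorter than 18 bp are
  discarded, as are reads with ambiguous tag occurrences.
- **Unique mapping** — RNA fragments are placed on the transcriptome and
  genome, DNA fragments on the genome; only fragments with a *single* exact
  placement across both strands are kept (multimappers are discarded), and
  both sides are joined by read id into valid contacts.
- **Contact statistics** — per-gene and per-class contact tallies; the
  Contact Distribution Index `CDI = max_c n_c / Σ_c n_c` (contacts on the
  most-contacted chromosome over all contacts: ≈1 means concentrated,
  ≈1/n_chrom means dispersed); the partition of each gene's contacts into
  *cis*-proximal (< 10 kb around the locus), *cis*-distal (same chromosome,
  further) and *trans* (other chromosomes); classification of lncRNAs as
  cis-proximal or trans-acting when one category holds > 50% of contacts;
  distance-from-locus histograms; concatenated dot-plot coordinates; and
  sliding-window detection of transcribed regions that overlap no annotated
  gene (unkRNA).
- **Chromatin-mark association** — a mark's coverage (RPKM in 50 bp bins)
  at a lncRNA's DNA-contact sites is compared with 100,000 random genomic
  positions by a two-sided Mann–Whitney U test, with Benjamini–Hochberg
  FDR control across the lncRNAs tested and a higher/lower direction call
  from the sample medians.
- **Expression targets** — genes with contacts within ±5 kb of their TSS
  are called putative targets of a trans-acting lncRNA, and the TPM
  expression of target sets is compared with the same rank-sum machinery.

Because real ChAR-seq libraries run to billions of reads, the package ships
a first-class synthetic study generator (`charlink.synthetic_data`) that
emulates every input at desk scale — genome with unassembled scaffolds,
six-class annotation, planted per-lncRNA cis/trans contact propensities,
chimeric read pairs in both tag orientations, coverage tracks with planted
enrichment, TPM tables with planted group differences — while recording
the ground truth of every emitted read, so each stage is tested by
parameter recovery.

## Worked example

```python
from charlink import synthetic_data as synth
from charlink import bridge_parser, fragment_mapper, contact_statistics as cs

genome = synth.make_genome(seed=1, n_assembled=6, assembled_lengths=100_000,
                           n_scaffolds=4)
annotation = synth.make_annotation(
    genome, seed=2,
    class_counts={"rRNA": 3, "msrpRNA": 3, "snRNA": 20, "snoRNA": 10,
                  "lncRNA": 60, "mRNA": 80})
truth = synth.plant_contacts(annotation, genome, seed=3, n_contacts=50_000)

reads = synth.iter_bridge_reads(truth, genome, seed=4, annotation=annotation)
stats = bridge_parser.ParseStats()
fragments = bridge_parser.parse_pairs(reads, stats=stats)
contacts, map_stats = fragment_mapper.build_contacts(fragments, genome,
                                                     annotation)
print(f"valid contacts: {map_stats.valid} of {stats.pairs_in} read pairs")

profiles = cs.gene_profiles(contacts, annotation, genome)
print(cs.class_summary(profiles).round(3).to_string(index=False))
split = cs.classification_split(profiles, "lncRNA")
print(f"lncRNAs: {split['pct_cis_proximal']:.1f}% cis-proximal, "
      f"{split['pct_trans_acting']:.1f}% trans-acting")
```

prints

```
valid contacts: 50000 of 50000 read pairs
rna_class  n_genes  total_contacts  median_contacts  median_cdi  contact_share_pct
   lncRNA       60            6240            104.0       0.918             13.877
     mRNA       80            5820             73.0       0.577             12.943
  msrpRNA        3             457            146.0       0.206              1.016
     rRNA        3           31522          10535.0       0.162             70.099
    snRNA       20             909             46.5       0.237              2.021
   snoRNA        8              20              2.5       0.500              0.044
lncRNAs: 91.7% cis-proximal, 8.3% trans-acting
```

All 50,000 planted contacts survive parsing and unique mapping at zero
sequencing error, the recovered class shares track the planted liver
mixture (rRNA ≈ 70%, lncRNA ≈ 14%, mRNA ≈ 13%, …), lncRNAs show a high
median CDI (their nascent-like contacts concentrate on their own
chromosome) while rRNA contacts spread genome-wide (CDI ≈ 1/6), and most
lncRNAs classify as cis-proximal.  Two snoRNAs received no contacts at all
under the 0.04% class share, hence `n_genes = 8` of the 10 annotated.

The same stages are available from the shell:

```sh
charlink run --outdir out --seed 7          # full pipeline + report.json
charlink simulate --config sim.yaml         # inputs only
charlink parse --fq1 r1.fq --fq2 r2.fq --out parsed/
charlink contacts --rna parsed/rna.fq --dna parsed/dna.fq \
    --genome out/genome.fa --gff out/annotation.gff3 --out contacts.tsv
charlink stats --contacts contacts.tsv --gff out/annotation.gff3 \
    --genome out/genome.fa --outdir stats/
# also: charlink unk, chip-assoc, targets, expr-compare (see --help)
```

A bundled demo configuration lives at `src/charlink/data/demo.yaml`.

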